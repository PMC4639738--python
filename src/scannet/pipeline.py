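"""End-to-end orchestration: data -> networks -> measures -> models -> post-hocs.

A run is described by a :class:`RunConfig` (YAML/JSON on disk).  Input is
either a pair of roster/scan CSVs or a synthetic specification; for every
behaviour x period the pipeline builds the weighted network per group,
assembles the measure table, fits and reduces the mixed model for each of
the two measures, and runs the post-hoc rank tests.  Every exclusion
(undefined disparity rows, classes below the minimum n) is logged at INFO,
because such exclusions are findings in their own right.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .data import (
    Roster,
    ScanRecordSet,
    read_roster_table,
    read_scan_table,
    write_roster_table,
    write_scan_table,
)
from .lmm import DEFAULT_TERMS, NetworkMeasureLMMResults, SelectionStep, backward_select
from .measures import metrics_table
from .networks import (
    GROOMING_GIVEN,
    PROXIMITY,
    WeightedNetwork,
    build_grooming_network,
    build_proximity_network,
    export_network,
)
from .posthoc import posthoc_pairwise
from .simulate import (
    BehaviourParams,
    default_params,
    default_roster,
    simulate_study,
)

__all__ = ["RunConfig", "SyntheticConfig", "ModelReport", "ReportBundle", "run_analysis"]

logger = logging.getLogger("scannet")

BEHAVIOURS = (PROXIMITY, GROOMING_GIVEN)
MEASURES = ("strength_centrality", "disparity_deviation")


@dataclass(frozen=True)
class SyntheticConfig:
    """Synthetic-input specification (study-like defaults)."""

    n_scans: int = 500
    periods: tuple[str, ...] = ("2003", "2005")
    params: BehaviourParams | None = None
    roster: Roster | None = None

    def resolve(self) -> tuple[Roster, BehaviourParams]:
        return (
            self.roster if self.roster is not None else default_roster(),
            self.params if self.params is not None else default_params(),
        )


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one analysis run."""

    seed: int = 0
    alpha: float = 0.05
    min_class_n: int = 3
    random_by: str = "group"  # group | group_size
    behaviours: tuple[str, ...] = BEHAVIOURS
    synthetic: SyntheticConfig | None = None
    roster_path: str | None = None
    scans_path: str | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha = {self.alpha} outside (0, 1)")
        if self.min_class_n < 1:
            raise ValueError("min_class_n must be >= 1")
        if self.random_by not in ("group", "group_size"):
            raise ValueError(f"unknown random_by {self.random_by!r}")
        unknown = [b for b in self.behaviours if b not in BEHAVIOURS]
        if unknown:
            raise ValueError(f"unknown behaviours {unknown}")
        if self.synthetic is None and (self.roster_path is None or self.scans_path is None):
            raise ValueError("either a synthetic spec or roster/scan paths are required")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        syn = None
        if "synthetic" in raw and raw["synthetic"] is not None:
            s = dict(raw.pop("synthetic"))
            params = None
            if "params" in s and s["params"] is not None:
                p = dict(s.pop("params"))
                params = BehaviourParams(
                    sociability=dict(p["sociability"]),
                    grooming=dict(p["grooming"]),
                    selectivity=dict(p["selectivity"]),
                    gamma_logit_sd=float(p.get("gamma_logit_sd", 0.6)),
                    sigma_logit_sd=float(p.get("sigma_logit_sd", 0.25)),
                )
            syn = SyntheticConfig(
                n_scans=int(s.get("n_scans", 500)),
                periods=tuple(str(x) for x in s.get("periods", ("2003", "2005"))),
                params=params,
            )
        inp = dict(raw.pop("input", {}) or {})
        return cls(
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
            min_class_n=int(raw.get("min_class_n", 3)),
            random_by=str(raw.get("random_by", "group")),
            behaviours=tuple(raw.get("behaviours", BEHAVIOURS)),
            synthetic=syn,
            roster_path=inp.get("roster"),
            scans_path=inp.get("scans"),
            outdir=raw.get("outdir"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out: dict = {
            "seed": self.seed,
            "alpha": self.alpha,
            "min_class_n": self.min_class_n,
            "random_by": self.random_by,
            "behaviours": list(self.behaviours),
        }
        if self.synthetic is not None:
            _, params = self.synthetic.resolve()
            out["synthetic"] = {
                "n_scans": self.synthetic.n_scans,
                "periods": list(self.synthetic.periods),
                "params": {
                    "sociability": dict(params.sociability),
                    "grooming": dict(params.grooming),
                    "selectivity": dict(params.selectivity),
                    "gamma_logit_sd": params.gamma_logit_sd,
                    "sigma_logit_sd": params.sigma_logit_sd,
                },
            }
        if self.roster_path:
            out["input"] = {"roster": self.roster_path, "scans": self.scans_path}
        return out


@dataclass
class ModelReport:
    """Selection outcome for one (behaviour, period, measure)."""

    behaviour: str
    period: str
    measure: str
    results: NetworkMeasureLMMResults | None
    reml_results: NetworkMeasureLMMResults | None
    ledger: list[SelectionStep]
    retained_terms: tuple[str, ...]
    note: str = ""


@dataclass
class ReportBundle:
    """Everything one run produced, plus a reproducibility manifest."""

    roster: Roster
    records: dict[tuple[str, str], ScanRecordSet]
    networks: dict[tuple[str, str, str], WeightedNetwork]  # (behaviour, group, period)
    measures: pd.DataFrame
    models: dict[tuple[str, str, str], ModelReport]
    posthocs: pd.DataFrame
    manifest: dict


def _load_inputs(config: RunConfig) -> tuple[Roster, dict[tuple[str, str], ScanRecordSet]]:
    if config.synthetic is not None:
        roster, params = config.synthetic.resolve()
        records = simulate_study(
            roster, params, config.synthetic.n_scans, config.synthetic.periods,
            seed=config.seed,
        )
        return roster, records
    roster = read_roster_table(config.roster_path)
    records = read_scan_table(config.scans_path, roster)
    return roster, records


def _grouping_column(table: pd.DataFrame, random_by: str) -> str:
    if random_by == "group":
        return "group_id"
    table["group_size_label"] = table["group_size"].astype(str)
    return "group_size_label"


def _class_filter(df: pd.DataFrame, response: str, min_class_n: int) -> pd.DataFrame:
    present = df.dropna(subset=[response])
    counts = present["deprivation_class"].value_counts()
    small = sorted(counts.index[counts < min_class_n])
    if small:
        logger.info(
            "excluding classes %s (n < %d) from %s analysis",
            small, min_class_n, response,
        )
    return df[~df["deprivation_class"].isin(small)]


def run_analysis(config: RunConfig) -> ReportBundle:
    """Execute the full pipeline for every behaviour x period x measure."""
    roster, records = _load_inputs(config)
    periods = sorted({p for (_, p) in records})

    networks: dict[tuple[str, str, str], WeightedNetwork] = {}
    for (group, period), rs in sorted(records.items()):
        if PROXIMITY in config.behaviours:
            networks[(PROXIMITY, group, period)] = build_proximity_network(rs, roster)
        if GROOMING_GIVEN in config.behaviours:
            networks[(GROOMING_GIVEN, group, period)] = build_grooming_network(rs, roster)

    measures = metrics_table(networks.values(), roster)

    models: dict[tuple[str, str, str], ModelReport] = {}
    posthoc_frames: list[pd.DataFrame] = []
    for behaviour in config.behaviours:
        for period in periods:
            sub = measures[
                (measures["behaviour"] == behaviour) & (measures["period"] == period)
            ].copy()
            for measure in MEASURES:
                n_undef = int(sub[measure].isna().sum())
                if n_undef:
                    logger.info(
                        "%s/%s: %d/%d rows undefined for %s — excluded",
                        behaviour, period, n_undef, len(sub), measure,
                    )
                table = _class_filter(sub, measure, config.min_class_n)
                gcol = _grouping_column(table, config.random_by)
                report = ModelReport(
                    behaviour=behaviour, period=period, measure=measure,
                    results=None, reml_results=None, ledger=[], retained_terms=(),
                )
                try:
                    best, ledger = backward_select(
                        table, measure, DEFAULT_TERMS, groups=gcol
                    )
                    retained = ledger[-1].terms
                    reml = None
                    if not best.perfect_fit:
                        reml = type(best.model)(
                            table, measure, retained, groups=gcol
                        ).fit(reml=True)
                    report = ModelReport(
                        behaviour=behaviour, period=period, measure=measure,
                        results=best, reml_results=reml, ledger=ledger,
                        retained_terms=retained,
                    )
                except ValueError as exc:
                    report.note = f"model skipped: {exc}"
                    logger.info("%s/%s %s: %s", behaviour, period, measure, report.note)
                models[(behaviour, period, measure)] = report

                ph = posthoc_pairwise(
                    table, measure,
                    retained_terms=report.retained_terms,
                    alpha=config.alpha, min_class_n=config.min_class_n,
                )
                if len(ph):
                    ph.insert(0, "measure", measure)
                    ph.insert(0, "period", period)
                    ph.insert(0, "behaviour", behaviour)
                    posthoc_frames.append(ph)

    posthocs = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame()
    )

    cfg_dict = config.to_dict()
    manifest = {
        "scannet_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_individuals": len(roster),
        "n_group_periods": len(records),
    }
    bundle = ReportBundle(
        roster=roster, records=records, networks=networks, measures=measures,
        models=models, posthocs=posthocs, manifest=manifest,
    )
    if config.outdir:
        write_bundle(bundle, config)
    return bundle


def _model_table(models: Mapping[tuple[str, str, str], ModelReport]) -> pd.DataFrame:
    rows = []
    for (behaviour, period, measure), rep in sorted(models.items()):
        source = rep.reml_results or rep.results
        if source is None:
            rows.append(
                {"behaviour": behaviour, "period": period, "measure": measure,
                 "term": None, "F": None, "df1": None, "df2": None, "p": None,
                 "retained": None, "note": rep.note}
            )
            continue
        ftab = source.f_test_terms()
        for r in ftab.itertuples():
            rows.append(
                {"behaviour": behaviour, "period": period, "measure": measure,
                 "term": r.term, "F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p,
                 "retained": r.term == "Intercept" or r.term in rep.retained_terms,
                 "note": rep.note}
            )
    return pd.DataFrame(rows)


def _ledger_table(models: Mapping[tuple[str, str, str], ModelReport]) -> pd.DataFrame:
    rows = []
    for (behaviour, period, measure), rep in sorted(models.items()):
        for step in rep.ledger:
            for cand, value in sorted(step.candidates.items()):
                rows.append(
                    {"behaviour": behaviour, "period": period, "measure": measure,
                     "step": step.step, "model_terms": "+".join(step.terms),
                     "model_aicc": step.aicc, "candidate_drop": cand,
                     "candidate_aicc": value, "dropped": cand == step.dropped}
                )
            if not step.candidates:
                rows.append(
                    {"behaviour": behaviour, "period": period, "measure": measure,
                     "step": step.step, "model_terms": "+".join(step.terms),
                     "model_aicc": step.aicc, "candidate_drop": None,
                     "candidate_aicc": None, "dropped": False}
                )
    return pd.DataFrame(rows)


def write_bundle(bundle: ReportBundle, config: RunConfig) -> None:
    """Write every artefact of a run under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_roster_table(bundle.roster, out / "roster.csv")
    write_scan_table(bundle.records.values(), out / "scans.csv")
    for (behaviour, group, period), net in bundle.networks.items():
        stem = f"network_{behaviour}_{group}_{period}"
        export_network(net, out / f"{stem}.graphml", "graphml")
        export_network(net, out / f"{stem}.csv", "edgelist")
    bundle.measures.to_csv(out / "measures.csv", index=False)
    for (behaviour, period), sub in bundle.measures.groupby(["behaviour", "period"]):
        sub.to_csv(out / f"measures_{behaviour}_{period}.csv", index=False)
    _model_table(bundle.models).to_csv(out / "models.csv", index=False)
    _ledger_table(bundle.models).to_csv(out / "selection_ledger.csv", index=False)
    bundle.posthocs.to_csv(out / "posthocs.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    logger.info("report bundle written to %s", out)
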