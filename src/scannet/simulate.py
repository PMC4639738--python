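"""Synthetic scan-sampling data with known, class-graded social behaviour.

The generator emulates a multi-group study of captive chimpanzees in which
individuals belong to deprivation classes that differ in three behavioural
dimensions:

* **sociability** ``sigma_c`` — a dyad (i, j) is within arm's reach in a
  given scan with probability ``sigma_i * sigma_j``;
* **grooming propensity** ``gamma_c`` — the probability that an individual
  grooms somebody in a given scan;
* **partner selectivity** ``kappa_c`` — the total concentration of the
  Dirichlet prior from which each individual's stable grooming-partner
  preference vector ``pi_i`` is drawn once (small kappa => the preference
  mass lands on one or two partners => high edge weight disparity).

Individual heterogeneity: realised per-individual rates are the class rates
jittered on the logit scale (SDs ``gamma_logit_sd`` / ``sigma_logit_sd``),
so that members of a class differ as real animals do.  Rates of exactly 0
or 1 are fixed points and are never jittered.

Everything is deterministic given the seed; preferences and realised rates
are drawn from a sub-stream separate from the per-scan stream, so that a
pre-drawn :class:`Realization` can be re-used without disturbing the scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    AGE_CLASSES,
    DEPRIVATION_CLASSES,
    SEXES,
    Individual,
    Roster,
    Scan,
    ScanRecordSet,
)

__all__ = [
    "BehaviourParams",
    "GroupSpec",
    "Realization",
    "default_params",
    "null_params",
    "default_group_specs",
    "default_roster",
    "make_roster",
    "draw_traits",
    "simulate_scans",
    "simulate_study",
    "expected_measures",
]


@dataclass(frozen=True)
class BehaviourParams:
    """Per-class behaviour rates driving the generator."""

    sociability: Mapping[str, float]
    grooming: Mapping[str, float]
    selectivity: Mapping[str, float]
    gamma_logit_sd: float = 0.6
    sigma_logit_sd: float = 0.25

    def __post_init__(self) -> None:
        for name, table in (("sociability", self.sociability), ("grooming", self.grooming)):
            for cls, v in table.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{cls!r}] = {v} outside [0, 1]")
        for cls, v in self.selectivity.items():
            if v <= 0:
                raise ValueError(f"selectivity[{cls!r}] = {v} must be > 0")
        if self.gamma_logit_sd < 0 or self.sigma_logit_sd < 0:
            raise ValueError("logit SDs must be >= 0")

    def sigma(self, cls: str) -> float:
        return float(self.sociability[cls])

    def gamma(self, cls: str) -> float:
        return float(self.grooming[cls])

    def kappa(self, cls: str) -> float:
        return float(self.selectivity[cls])


def default_params() -> BehaviourParams:
    """Study-condition defaults.

    Grooming propensities follow the study conditions (ELD 0.05, LLD 0.2,
    EMD 0.2, ND 0.35).  Sociability is graded so that ex-laboratory classes
    tolerate far fewer partners close-by than zoo classes, and selectivity
    concentrations are ordered kappa_ND >> kappa_ELD so non-deprived animals
    spread grooming evenly while early-deprived animals concentrate on one
    or two partners.
    """
    return BehaviourParams(
        sociability={"ELD": 0.15, "LLD": 0.25, "EMD": 0.55, "ND": 0.60},
        grooming={"ELD": 0.05, "LLD": 0.20, "EMD": 0.20, "ND": 0.35},
        selectivity={"ELD": 0.3, "LLD": 0.5, "EMD": 2.0, "ND": 8.0},
    )


def null_params() -> BehaviourParams:
    """All classes behaviourally identical (for type-I-error checks)."""
    classes = ("ELD", "LLD", "EMD", "ND")
    return BehaviourParams(
        sociability={c: 0.45 for c in classes},
        grooming={c: 0.25 for c in classes},
        selectivity={c: 3.0 for c in classes},
    )


@dataclass(frozen=True)
class GroupSpec:
    """Composition of one synthetic group.

    ``composition`` rows are (deprivation_class, sex, age_class, count).
    """

    group_id: str
    composition: tuple[tuple[str, str, str, int], ...]

    def __post_init__(self) -> None:
        size = sum(c for *_, c in self.composition)
        if size < 2:
            raise ValueError(f"group {self.group_id!r} has size {size} < 2")
        for cls, sex, age, cnt in self.composition:
            if cls not in DEPRIVATION_CLASSES:
                raise ValueError(f"unknown deprivation class {cls!r}")
            if sex not in SEXES:
                raise ValueError(f"unknown sex {sex!r}")
            if age not in AGE_CLASSES:
                raise ValueError(f"unknown age class {age!r}")
            if cnt < 1:
                raise ValueError("composition counts must be >= 1")

    @property
    def size(self) -> int:
        return sum(c for *_, c in self.composition)


def default_group_specs() -> tuple[GroupSpec, ...]:
    """41 adults in 4 groups: two sanctuary groups (ELD+LLD) and two zoo
    groups (EMD+ND); class totals ELD 10 / LLD 8 / EMD 7 / ND 16, sex totals
    27 females / 14 males."""
    return (
        GroupSpec(
            "S1",
            (("ELD", "female", "old", 2), ("ELD", "male", "old", 3),
             ("LLD", "female", "mature", 2), ("LLD", "male", "mature", 2)),
        ),
        GroupSpec(
            "S2",
            (("ELD", "female", "old", 2), ("ELD", "male", "old", 3),
             ("LLD", "female", "mature", 2), ("LLD", "male", "mature", 2)),
        ),
        GroupSpec(
            "Z1",
            (("EMD", "female", "old", 3), ("EMD", "male", "old", 1),
             ("ND", "female", "mature", 6), ("ND", "female", "old", 1),
             ("ND", "male", "mature", 1)),
        ),
        GroupSpec(
            "Z2",
            (("EMD", "female", "old", 3),
             ("ND", "female", "mature", 5), ("ND", "female", "old", 1),
             ("ND", "male", "mature", 2)),
        ),
    )


def make_roster(group_specs: Sequence[GroupSpec], seed: int = 0) -> Roster:
    """Deterministic roster matching the given compositions exactly.

    Ids encode group, class and sex (e.g. ``S1-ELD-F1``).  The seed is part
    of the signature for interface symmetry with the samplers; composition
    is explicit so the same seed always yields the same roster.
    """
    del seed  # composition is fully explicit
    individuals: list[Individual] = []
    for spec in group_specs:
        counter: dict[tuple[str, str], int] = {}
        for cls, sex, age, cnt in spec.composition:
            for _ in range(cnt):
                k = (cls, sex)
                counter[k] = counter.get(k, 0) + 1
                individuals.append(
                    Individual(
                        id=f"{spec.group_id}-{cls}-{sex[0].upper()}{counter[k]}",
                        group_id=spec.group_id,
                        sex=sex,
                        age_class=age,
                        deprivation_class=cls,
                    )
                )
    return Roster(tuple(individuals))


def default_roster() -> Roster:
    return make_roster(default_group_specs())


@dataclass(frozen=True)
class Realization:
    """Realised per-individual traits for one group."""

    ids: tuple[str, ...]
    sigma: np.ndarray  # (N,) realised sociability
    gamma: np.ndarray  # (N,) realised grooming propensity
    preferences: np.ndarray = field(repr=False)  # (N, N), zero diagonal, rows sum to 1


def _jitter(rate: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Logit-normal jitter; 0 and 1 are fixed points."""
    out = rate.astype(float).copy()
    if sd == 0:
        return out
    interior = (out > 0) & (out < 1)
    logit = np.log(out[interior] / (1 - out[interior]))
    logit = logit + rng.normal(0.0, sd, size=logit.shape)
    out[interior] = 1.0 / (1.0 + np.exp(-logit))
    return out


def draw_traits(
    roster: Roster, group_id: str, params: BehaviourParams, seed: int
) -> Realization:
    """Draw stable traits (rates and partner preferences) for one group."""
    members = roster.members(group_id)
    ids = tuple(sorted(i.id for i in members))
    cls = {i.id: i.deprivation_class for i in members}
    n = len(ids)
    rng = np.random.default_rng([seed, 0])
    sigma = _jitter(
        np.array([params.sigma(cls[i]) for i in ids]), params.sigma_logit_sd, rng
    )
    gamma = _jitter(
        np.array([params.gamma(cls[i]) for i in ids]), params.gamma_logit_sd, rng
    )
    prefs = np.zeros((n, n))
    for row, ident in enumerate(ids):
        kappa = params.kappa(cls[ident])
        alpha = np.full(n - 1, kappa / (n - 1))
        p = rng.dirichlet(alpha)
        prefs[row, np.arange(n) != row] = p
    return Realization(ids=ids, sigma=sigma, gamma=gamma, preferences=prefs)


def simulate_scans(
    roster: Roster,
    params: BehaviourParams,
    n_scans: int,
    seed: int,
    group_id: str | None = None,
    period_id: str = "1",
    realization: Realization | None = None,
) -> ScanRecordSet:
    """Simulate one group-period of scan sampling.

    Per scan: every dyad (i, j) is in proximity independently with
    probability ``sigma_i * sigma_j``; every individual grooms with
    probability ``gamma_i``, its partner drawn from its preference vector.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if group_id is None:
        if len(roster.group_ids) != 1:
            raise ValueError("group_id required when the roster has several groups")
        group_id = roster.group_ids[0]
    if realization is None:
        realization = draw_traits(roster, group_id, params, seed)
    ids = realization.ids
    n = len(ids)
    rng = np.random.default_rng([seed, 1])

    iu, ju = np.triu_indices(n, k=1)
    dyad_p = realization.sigma[iu] * realization.sigma[ju]
    prox = rng.random((n_scans, len(iu))) < dyad_p  # (scans, dyads)

    grooms = rng.random((n_scans, n)) < realization.gamma  # (scans, N)
    partners = np.full((n_scans, n), -1, dtype=int)
    for i in range(n):
        hits = np.flatnonzero(grooms[:, i])
        if hits.size:
            partners[hits, i] = rng.choice(n, size=hits.size, p=realization.preferences[i])

    scans: list[Scan] = []
    for s in range(n_scans):
        pairs = frozenset(
            (ids[iu[k]], ids[ju[k]]) for k in np.flatnonzero(prox[s])
        )
        events = frozenset(
            (ids[i], ids[partners[s, i]]) for i in np.flatnonzero(partners[s] >= 0)
        )
        scans.append(Scan(pairs, events))
    return ScanRecordSet(group_id=group_id, period_id=period_id, scans=tuple(scans))


def simulate_study(
    roster: Roster,
    params: BehaviourParams,
    n_scans: int,
    periods: Iterable[str],
    seed: int,
) -> dict[tuple[str, str], ScanRecordSet]:
    """Simulate every group over every period with decorrelated sub-seeds.

    Traits are re-drawn per group-period: relationships are stable within a
    period but allowed to reorganise between periods (as after
    re-socialisation).
    """
    out: dict[tuple[str, str], ScanRecordSet] = {}
    for g_idx, group_id in enumerate(roster.group_ids):
        for p_idx, period in enumerate(periods):
            sub_seed = [seed, 2, g_idx, p_idx]
            rng_seed = int(np.random.default_rng(sub_seed).integers(2**31 - 1))
            realization = draw_traits(roster, group_id, params, rng_seed)
            out[(group_id, str(period))] = simulate_scans(
                roster,
                params,
                n_scans,
                rng_seed,
                group_id=group_id,
                period_id=str(period),
                realization=realization,
            )
    return out


def expected_measures(
    roster: Roster, params: BehaviourParams, realization: Realization
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expected network measures given the realised traits (recovery oracle).

    Returns a per-individual table with the expected grooming strength
    centrality ``100 * gamma_i / (N - 1)``, the expected grooming disparity
    ``sum_j pi_ij^2``, and the expected proximity strength centrality, plus
    the full expected proximity weight matrix ``W_ij = 100 * sigma_i sigma_j``.
    """
    ids = realization.ids
    n = len(ids)
    w_prox = 100.0 * np.outer(realization.sigma, realization.sigma)
    np.fill_diagonal(w_prox, 0.0)
    rows = []
    for i, ident in enumerate(ids):
        pi = realization.preferences[i]
        rows.append(
            {
                "id": ident,
                "exp_grooming_strength_centrality": 100.0 * realization.gamma[i] / (n - 1),
                "exp_grooming_disparity": float(np.sum(pi**2)),
                "exp_proximity_strength_centrality": float(np.sum(w_prox[i]) / (n - 1)),
            }
        )
    return pd.DataFrame(rows), w_prox
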