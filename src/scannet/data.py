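"""Canonical data model for scan-sampling observations, plus CSV I/O.

Scan sampling records, at regular intervals, the instantaneous social state
of every adult in a group: which unordered pairs are within arm's reach
(*passive close proximity*) and which ordered groomer->groomee pairs are
grooming.  The roster carries the per-individual covariates used downstream
(sex, age class, deprivation class, group membership).

Input tables are tidy CSV: one row per individual (roster) or one row per
observed event (scan table).  See :data:`ROSTER_COLUMNS` and
:data:`SCAN_COLUMNS` for the exact headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "SEXES",
    "AGE_CLASSES",
    "DEPRIVATION_CLASSES",
    "ROSTER_COLUMNS",
    "SCAN_COLUMNS",
    "FormatError",
    "ValidationError",
    "Individual",
    "Roster",
    "Scan",
    "ScanRecordSet",
    "Violation",
    "ValidationReport",
    "assign_age_class",
    "make_scan",
    "read_roster_table",
    "write_roster_table",
    "read_scan_table",
    "write_scan_table",
    "validate_records",
]

SEXES = ("female", "male")
AGE_CLASSES = ("mature", "old")
#: ND = zoo-born non-deprived; EMD = wild-caught early maternally deprived;
#: ELD / LLD = ex-laboratory early / late long-term deprived; LMD = late
#: maternally deprived (typically excluded from analysis for small n).
DEPRIVATION_CLASSES = ("ND", "EMD", "ELD", "LLD", "LMD", "other")

ROSTER_COLUMNS = ("id", "group_id", "sex", "age_class", "deprivation_class")
SCAN_COLUMNS = ("group", "period", "scan", "behaviour", "actor", "recipient")
SCAN_BEHAVIOURS = ("proximity", "grooming", "none")


class FormatError(ValueError):
    """A table does not have the expected shape (missing columns etc.)."""


class ValidationError(ValueError):
    """A table parses but violates a data-model invariant."""


def assign_age_class(sex: str, age_years: float) -> str:
    """Age class from sex and age: mature = females 13-33 / males 16-33, old > 33."""
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if age_years > 33:
        return "old"
    lower = 13 if sex == "female" else 16
    if age_years >= lower:
        return "mature"
    raise ValueError(f"age {age_years} is below the adult threshold for {sex}")


@dataclass(frozen=True)
class Individual:
    """One adult subject with its analysis covariates."""

    id: str
    group_id: str
    sex: str
    age_class: str
    deprivation_class: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("individual id must be non-empty")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} for {self.id!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"unknown age class {self.age_class!r} for {self.id!r}"
            )
        if self.deprivation_class not in DEPRIVATION_CLASSES:
            raise ValidationError(
                f"unknown deprivation class {self.deprivation_class!r} for {self.id!r}"
            )


@dataclass(frozen=True)
class Roster:
    """Validated collection of individuals; groups must have >= 2 members."""

    individuals: tuple[Individual, ...]
    _by_id: Mapping[str, Individual] = field(
        init=False, repr=False, compare=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValidationError("roster is empty")
        by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in by_id:
                raise ValidationError(f"duplicate individual id {ind.id!r}")
            by_id[ind.id] = ind
        sizes: dict[str, int] = {}
        for ind in self.individuals:
            sizes[ind.group_id] = sizes.get(ind.group_id, 0) + 1
        small = sorted(g for g, n in sizes.items() if n < 2)
        if small:
            raise ValidationError(
                f"groups {small} have fewer than 2 members; networks are undefined"
            )
        object.__setattr__(self, "_by_id", by_id)

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(sorted({ind.group_id for ind in self.individuals}))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.individuals)

    def members(self, group_id: str) -> tuple[Individual, ...]:
        out = tuple(i for i in self.individuals if i.group_id == group_id)
        if not out:
            raise KeyError(f"unknown group {group_id!r}")
        return out

    def group_size(self, group_id: str) -> int:
        return len(self.members(group_id))

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ind in self.individuals:
            out[ind.deprivation_class] = out.get(ind.deprivation_class, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": i.id,
                    "group_id": i.group_id,
                    "sex": i.sex,
                    "age_class": i.age_class,
                    "deprivation_class": i.deprivation_class,
                }
                for i in self.individuals
            ]
        )


@dataclass(frozen=True)
class Scan:
    """One scan: unordered proximity pairs and ordered grooming events.

    A plain container — invariants (no self-pairs, roster membership) are
    checked by :func:`validate_records`, so that deliberately corrupted
    records can still be represented and reported on.
    """

    proximity_pairs: frozenset[tuple[str, str]] = frozenset()
    grooming_events: frozenset[tuple[str, str]] = frozenset()


def make_scan(
    proximity_pairs: Iterable[tuple[str, str]] = (),
    grooming_events: Iterable[tuple[str, str]] = (),
) -> Scan:
    """Build a scan, normalising proximity pair orientation and deduplicating."""
    pairs = frozenset(tuple(sorted(p)) for p in proximity_pairs)
    events = frozenset((a, r) for a, r in grooming_events)
    return Scan(pairs, events)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ScanRecordSet:
    """All scans for one group over one observation period."""

    group_id: str
    period_id: str
    scans: tuple[Scan, ...]

    @property
    def n_scans(self) -> int:
        return len(self.scans)


@dataclass(frozen=True)
class Violation:
    kind: str  # self_pair | unknown_id | wrong_group
    scan_index: int  # 1-based
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    group_id: str
    period_id: str
    n_scans: int
    n_proximity_pairs: int
    n_grooming_events: int
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_records(records: ScanRecordSet, roster: Roster) -> ValidationReport:
    """Check every ScanRecordSet invariant against the roster; report, don't raise."""
    violations: list[Violation] = []
    try:
        member_ids = {i.id for i in roster.members(records.group_id)}
    except KeyError:
        member_ids = set()
    n_pairs = 0
    n_events = 0
    for s_idx, scan in enumerate(records.scans, start=1):
        n_pairs += len(scan.proximity_pairs)
        n_events += len(scan.grooming_events)
        for a, b in scan.proximity_pairs:
            if a == b:
                violations.append(Violation("self_pair", s_idx, f"proximity {a!r}-{b!r}"))
            for x in (a, b):
                if x not in roster:
                    violations.append(Violation("unknown_id", s_idx, repr(x)))
                elif x not in member_ids:
                    violations.append(
                        Violation("wrong_group", s_idx, f"{x!r} not in {records.group_id!r}")
                    )
        for a, b in scan.grooming_events:
            if a == b:
                violations.append(Violation("self_pair", s_idx, f"grooming {a!r}->{b!r}"))
            for x in (a, b):
                if x not in roster:
                    violations.append(Violation("unknown_id", s_idx, repr(x)))
                elif x not in member_ids:
                    violations.append(
                        Violation("wrong_group", s_idx, f"{x!r} not in {records.group_id!r}")
                    )
    return ValidationReport(
        group_id=records.group_id,
        period_id=records.period_id,
        n_scans=records.n_scans,
        n_proximity_pairs=n_pairs,
        n_grooming_events=n_events,
        violations=tuple(violations),
    )


# ---------------------------------------------------------------------------
# CSV I/O


def read_roster_table(path: str | Path) -> Roster:
    """Read a roster CSV with columns ``id,group_id,sex,age_class,deprivation_class``."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"roster table {path} is missing columns {missing}")
    individuals = tuple(
        Individual(
            id=row.id,
            group_id=row.group_id,
            sex=row.sex,
            age_class=row.age_class,
            deprivation_class=row.deprivation_class,
        )
        for row in df.itertuples()
    )
    return Roster(individuals)


def write_roster_table(roster: Roster, path: str | Path) -> None:
    roster.to_frame().to_csv(path, index=False)


def _scan_rows(df: pd.DataFrame, path: str | Path, roster: Roster) -> None:
    """Row-level checks with the offending 1-based data row index in messages."""
    member_ids = {g: {i.id for i in roster.members(g)} for g in roster.group_ids}
    for pos, row in enumerate(df.itertuples(), start=1):
        if row.behaviour not in SCAN_BEHAVIOURS:
            raise FormatError(
                f"{path} row {pos}: unknown behaviour {row.behaviour!r}"
            )
        if row.behaviour == "none":
            continue
        if row.actor == row.recipient:
            raise ValidationError(
                f"{path} row {pos}: actor equals recipient ({row.actor!r})"
            )
        if row.group not in member_ids:
            raise ValidationError(f"{path} row {pos}: unknown group {row.group!r}")
        for who in (row.actor, row.recipient):
            if who not in roster:
                raise ValidationError(f"{path} row {pos}: id {who!r} not in roster")
            if who not in member_ids[row.group]:
                raise ValidationError(
                    f"{path} row {pos}: id {who!r} is not a member of group {row.group!r}"
                )


def read_scan_table(
    path: str | Path, roster: Roster
) -> dict[tuple[str, str], ScanRecordSet]:
    """Read a long-format scan CSV into one ScanRecordSet per (group, period).

    Columns: ``group,period,scan,behaviour,actor,recipient`` with behaviour in
    {proximity, grooming, none}.  Scan indices are 1-based; the number of scans
    for a group-period is the largest index seen, so indices with no rows count
    as scans in which nothing was observed.  Proximity rows may appear in either
    orientation and are deduplicated.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"scan table {path} is missing columns {missing}")
    try:
        df["scan"] = df["scan"].astype(int)
    except ValueError as exc:
        raise FormatError(f"scan table {path}: non-integer scan index") from exc
    if (df["scan"] < 1).any():
        raise FormatError(f"scan table {path}: scan indices must be >= 1")
    _scan_rows(df, path, roster)

    out: dict[tuple[str, str], ScanRecordSet] = {}
    for (group, period), sub in df.groupby(["group", "period"], sort=True):
        n_scans = int(sub["scan"].max())
        pairs: list[set[tuple[str, str]]] = [set() for _ in range(n_scans)]
        events: list[set[tuple[str, str]]] = [set() for _ in range(n_scans)]
        for row in sub.itertuples():
            if row.behaviour == "proximity":
                pairs[row.scan - 1].add(tuple(sorted((row.actor, row.recipient))))
            elif row.behaviour == "grooming":
                events[row.scan - 1].add((row.actor, row.recipient))
        scans = tuple(
            Scan(frozenset(p), frozenset(e)) for p, e in zip(pairs, events)
        )
        out[(str(group), str(period))] = ScanRecordSet(str(group), str(period), scans)
    return out


def write_scan_table(
    recordsets: Iterable[ScanRecordSet], path: str | Path
) -> None:
    """Write ScanRecordSets as a long-format CSV (round-trips with the reader).

    Scans with no events are written as a single ``none`` marker row so that
    trailing empty scans survive a round trip.
    """
    rows: list[dict[str, object]] = []
    for rs in recordsets:
        for s_idx, scan in enumerate(rs.scans, start=1):
            base = {"group": rs.group_id, "period": rs.period_id, "scan": s_idx}
            if not scan.proximity_pairs and not scan.grooming_events:
                rows.append({**base, "behaviour": "none", "actor": "", "recipient": ""})
                continue
            for a, b in sorted(scan.proximity_pairs):
                rows.append({**base, "behaviour": "proximity", "actor": a, "recipient": b})
            for a, b in sorted(scan.grooming_events):
                rows.append({**base, "behaviour": "grooming", "actor": a, "recipient": b})
    pd.DataFrame(rows, columns=list(SCAN_COLUMNS)).to_csv(path, index=False)
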