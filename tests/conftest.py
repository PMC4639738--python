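import numpy as np
import pytest

from scannet.data import Individual, Roster, ScanRecordSet, make_scan
from scannet.simulate import default_params, default_roster


@pytest.fixture(scope="session")
def roster5() -> Roster:
    """One group of five (mixed classes and sexes)."""
    return Roster(
        (
            Individual("Ada", "MS1", "female", "mature", "ND"),
            Individual("Bert", "MS1", "male", "old", "ELD"),
            Individual("Cleo", "MS1", "female", "mature", "EMD"),
            Individual("Dino", "MS1", "male", "mature", "LLD"),
            Individual("Erna", "MS1", "female", "old", "ND"),
        )
    )


@pytest.fixture(scope="session")
def study_roster() -> Roster:
    return default_roster()


@pytest.fixture(scope="session")
def study_params():
    return default_params()


def records_from_scans(roster: Roster, group: str, period: str, scans) -> ScanRecordSet:
    return ScanRecordSet(group, period, tuple(scans))


def random_records(roster: Roster, group: str, n_scans: int, rng: np.random.Generator,
                   p_prox: float = 0.3, p_groom: float = 0.2) -> ScanRecordSet:
    """Uniform random records for oracle comparisons (no class structure)."""
    ids = sorted(i.id for i in roster.members(group))
    scans = []
    for _ in range(n_scans):
        pairs = [
            (a, b)
            for k, a in enumerate(ids)
            for b in ids[k + 1:]
            if rng.random() < p_prox
        ]
        events = [
            (a, b)
            for a in ids
            for b in ids
            if a != b and rng.random() < p_groom / len(ids)
        ]
        scans.append(make_scan(pairs, events))
    return ScanRecordSet(group, "P1", tuple(scans))
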