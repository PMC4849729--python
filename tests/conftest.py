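import numpy as np
import pytest
from hypothesis import settings

from drugspread.events_io import EventTable, ObservationWindow, StudyRecord
from drugspread.synthetic_data import SimulationConfig, simulate_dataset

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def small_events() -> EventTable:
    """Hand-built table: two drugs, three diseases, known first pairings."""
    return EventTable(
        [
            StudyRecord(time=2001.0, drug_id="A", study_id="s1", diseases=frozenset({"X"})),
            StudyRecord(time=2004.0, drug_id="A", study_id="s2", diseases=frozenset({"X", "Y"})),
            StudyRecord(time=2006.5, drug_id="A", study_id="s3", diseases=frozenset()),
            StudyRecord(time=1999.0, drug_id="B", study_id="s4", diseases=frozenset({"Z"})),
            StudyRecord(time=2003.0, drug_id="B", study_id="s5", diseases=frozenset({"X"})),
            StudyRecord(time=2007.0, drug_id="B", study_id="s6", diseases=frozenset({"Z"})),
        ]
    )


@pytest.fixture(scope="session")
def cascade_dataset():
    """Dense 5-disease cascade with ~2000 drugs for recovery checks."""
    cfg = SimulationConfig(
        n_diseases=5,
        edge_density=1.0,
        lambda_low=0.05,
        lambda_high=0.5,
        drugs_per_year=100.0,
        year_span=(1990.0, 2010.0),
        rng_seed=42,
    )
    events, adoptions, truth = simulate_dataset(cfg)
    return cfg, events, adoptions, truth


def random_study_records(rng: np.random.Generator, n: int = 50) -> list[StudyRecord]:
    """Small random study table for brute-force comparisons."""
    drugs = [f"d{i}" for i in range(8)]
    diseases = [f"D{i}" for i in range(5)]
    records = []
    for k in range(n):
        n_dis = int(rng.integers(0, 3))
        records.append(
            StudyRecord(
                time=float(1990 + 20 * rng.random()),
                drug_id=str(rng.choice(drugs)),
                study_id=f"s{k}",
                diseases=frozenset(rng.choice(diseases, size=n_dis, replace=False).tolist()),
            )
        )
    return records
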