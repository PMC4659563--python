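import numpy as np
import pandas as pd
import pytest

from perio16s.abundance import OtuTable


def make_table(counts: np.ndarray, otu_ids=None, sample_ids=None) -> OtuTable:
    counts = np.asarray(counts)
    n_otus, n_samples = counts.shape
    otu_ids = otu_ids or [f"OTU{i+1:03d}" for i in range(n_otus)]
    sample_ids = sample_ids or [f"S{j+1:03d}" for j in range(n_samples)]
    df = pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"),
                      columns=sample_ids)
    return OtuTable(df)


def make_metadata(statuses, scores=None, sample_ids=None) -> pd.DataFrame:
    n = len(statuses)
    sample_ids = sample_ids or [f"S{j+1:03d}" for j in range(n)]
    if scores is None:
        scores = [0.0 if s == "health" else 2.0 for s in statuses]
    return pd.DataFrame(
        {
            "health_status": list(statuses),
            "avg_gingivitis_score": list(scores),
            "age": [5.0] * n,
            "sex": ["F"] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


@pytest.fixture
def toy_table():
    """3 OTUs x 6 samples, 2 per health group."""
    counts = np.array(
        [
            [50, 60, 40, 30, 20, 10],
            [30, 20, 40, 50, 60, 70],
            [20, 20, 20, 20, 20, 20],
        ]
    )
    return make_table(counts)


@pytest.fixture
def toy_metadata():
    return make_metadata(
        ["health", "health", "gingivitis", "gingivitis", "pd1", "pd1"],
        scores=[0.0, 0.0, 1.5, 2.0, 2.5, 3.0],
    )


def random_table(rng: np.random.Generator, n_otus=20, n_samples=9,
                 max_count=200) -> OtuTable:
    counts = rng.integers(0, max_count, size=(n_otus, n_samples))
    counts[0] += 1  # keep every sample total positive
    return make_table(counts)


def random_statuses(rng: np.random.Generator, n_samples: int):
    """Random status vector guaranteed to contain all three groups."""
    assert n_samples >= 3
    statuses = ["health", "gingivitis", "pd1"]
    extra = rng.choice(statuses, size=n_samples - 3).tolist()
    out = statuses + extra
    rng.shuffle(out)
    return out
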