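import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pneumobiome.cohort import Cohort, CohortConfig, generate_cohort
from pneumobiome.diversity import default_rarefaction_depth, rarefy
from pneumobiome.io_formats import (AnalyteLimits, CountTable, ResponsePanel,
                                    SampleMetadata)


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        ["s1", "s2", "s3"],
        ["Bacteroides", "Faecalibacterium", "Finegoldia", "Roseburia"],
        np.array([[10, 10, 10, 10], [7, 0, 0, 0], [2, 1, 1, 0]]),
    )


@pytest.fixture
def small_metadata(small_table) -> SampleMetadata:
    n = small_table.n_samples
    df = pd.DataFrame({
        "group": ["CAP", "CAP", "control"],
        "timepoint": ["admission", "month", "none"],
        "age": [70.0, 71.0, 65.0],
        "sex": ["male", "female", "male"],
        **{c: [False] * n for c in ("copd", "cardiovascular", "diabetes",
                                    "malignancy", "immunosuppressed",
                                    "gastrointestinal", "renal")},
        "prior_antibiotics": [True, False, False],
    }, index=small_table.sample_ids)
    return SampleMetadata(df)


@pytest.fixture
def small_panel() -> ResponsePanel:
    values = pd.DataFrame(
        {"TNFa_LPS": [120.0, 3500.0, np.nan], "IL10_LPS": [5.0, 80.0, 15.0]},
        index=["s1", "s2", "s3"])
    analytes = pd.DataFrame(
        {"stimulus": ["LPS", "LPS"], "cell_type": ["monocyte", "monocyte"]},
        index=["TNFa_LPS", "IL10_LPS"])
    return ResponsePanel(values, analytes)


@pytest.fixture
def small_limits() -> AnalyteLimits:
    return AnalyteLimits(pd.DataFrame(
        {"lower": [10.0, 2.0], "upper": [3000.0, 500.0]},
        index=["TNFa_LPS", "IL10_LPS"]))


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The default synthetic cohort (150 samples, 50 genera, seed 0)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def pooled_rarefied(default_cohort) -> tuple[CountTable, np.ndarray]:
    """All 150 samples pooled and rarefied, with generating labels."""
    tables = default_cohort.counts
    ids = sum((t.sample_ids for t in tables.values()), [])
    counts = np.vstack([t.counts for t in tables.values()])
    pooled = CountTable(ids, list(tables["admission"].taxon_ids), counts)
    depth = default_rarefaction_depth(pooled)
    rare = rarefy(pooled, depth, seed=42)
    labels = default_cohort.ground_truth.components[rare.sample_ids].to_numpy()
    return rare, labels
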