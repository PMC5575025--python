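"""Shared fixtures: tiny hand-written tables and small synthetic bundles."""

import pandas as pd
import pytest

from ocuscrub import (
    CountTable,
    LuminosityTable,
    SampleMetadata,
    SimulationConfig,
    TaxonomyMap,
    generate_experiment,
)


@pytest.fixture
def tiny_counts() -> CountTable:
    df = pd.DataFrame(
        [[5, 0, 1], [2, 2, 4], [0, 7, 3]],
        index=["A", "B", "C"],
        columns=["OTU1", "OTU2", "OTU3"],
    )
    return CountTable(df)


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {
            "sample_type": ["subject", "subject", "blank_control", "water_control"],
            "subject_id": ["P1", "P1", pd.NA, pd.NA],
            "time_point": ["baseline", "month1", pd.NA, pd.NA],
        },
        index=["A", "B", "C", "D"],
    )
    return SampleMetadata(df)


@pytest.fixture
def tiny_taxonomy() -> TaxonomyMap:
    df = pd.DataFrame(
        {
            "phylum": ["Actinobacteria", "Actinobacteria", "Firmicutes"],
            "class": ["Actinomycetia", "Actinomycetia", "Bacilli"],
            "order": ["Corynebacteriales", "Corynebacteriales", "Bacillales"],
            "family": ["Corynebacteriaceae", "Corynebacteriaceae", "Staphylococcaceae"],
            "genus": ["Corynebacterium", "Corynebacterium", "Staphylococcus"],
        },
        index=["OTU1", "OTU2", "OTU3"],
    )
    return TaxonomyMap(df)


@pytest.fixture
def tiny_luminosity() -> LuminosityTable:
    return LuminosityTable(pd.Series({"A": 200.0, "B": 100.0, "C": 50.0, "D": 10.0}))


#: small-but-complete study: fast enough for per-test generation
SMALL_CONFIG = SimulationConfig(
    n_subjects=6,
    n_times=3,
    n_blank_controls=4,
    n_water_controls=3,
    n_true_otus=12,
    n_contaminant_otus=40,
    core_size_per_subject=4,
    depth_mean=20000.0,
    depth_sd=5000.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_experiment(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_experiment(SimulationConfig(seed=7))
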