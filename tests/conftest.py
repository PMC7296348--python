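import warnings

import numpy as np
import pandas as pd
import pytest

import cortexfate as cf
from cortexfate.io import CountMatrix


@pytest.fixture(scope="session")
def sim149():
    """Default study-design simulation: 27 lines, 149 differentiations."""
    return cf.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def log2_149(sim149):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = cf.normalize_dataset(sim149.counts)
    return cf.log2_transform(cf.filter_expressed(norm))


@pytest.fixture(scope="session")
def sim_small():
    return cf.simulate_dataset(n_lines=6, diffs_per_line=3, seed=2)


def toy_count_matrix() -> CountMatrix:
    """Hand-computable 3-sample normalization fixture (counts are powers of 2).

    Expected by hand: background 0 everywhere; positive geomeans (8, 64, 8)
    with dataset reference 16 -> factors (2, 0.25, 2); housekeeping geomeans
    after the positive step (64, 128, 256) with reference 128 -> factors
    (2, 1, 0.5); G1 -> (32, 8, 2), G2 -> (8, 2, 100).
    """
    counts = pd.DataFrame(
        {
            "NEG1": [0, 0, 0], "NEG2": [0, 0, 0],
            "POS1": [4, 16, 4], "POS2": [16, 256, 16],
            "HK1": [16, 256, 64], "HK2": [64, 1024, 256],
            "G1": [8, 32, 2], "G2": [2, 8, 100],
        },
        index=pd.Index(["A", "B", "C"], name="sample_id"),
    )
    classes = pd.Series(
        {
            "NEG1": "negative", "NEG2": "negative",
            "POS1": "positive", "POS2": "positive",
            "HK1": "housekeeping", "HK2": "housekeeping",
            "G1": "endogenous", "G2": "endogenous",
        }
    )
    return CountMatrix(counts=counts, probe_class=classes, codeset_id="toy")


def scale_invariance_matrix() -> CountMatrix:
    """All-even counts with control factors well inside the QC bounds."""
    counts = pd.DataFrame(
        {
            "NEG1": [2, 4, 2], "NEG2": [4, 2, 4],
            "POS1": [100, 120, 90],
            "POS2": [400, 500, 360],
            "HK1": [900, 1100, 800], "HK2": [300, 380, 260],
            "G1": [50, 80, 20], "G2": [200, 150, 300],
        },
        index=pd.Index(["A", "B", "C"], name="sample_id"),
    )
    classes = pd.Series(
        {"NEG1": "negative", "NEG2": "negative", "POS1": "positive",
         "POS2": "positive", "HK1": "housekeeping", "HK2": "housekeeping",
         "G1": "endogenous", "G2": "endogenous"})
    return CountMatrix(counts=counts, probe_class=classes, codeset_id="toy")


TOY_EXPECTED = pd.DataFrame(
    {"G1": [32.0, 8.0, 2.0], "G2": [8.0, 2.0, 100.0]},
    index=pd.Index(["A", "B", "C"], name="sample_id"),
)


@pytest.fixture
def toy_counts():
    return toy_count_matrix()
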