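import numpy as np
import pandas as pd
import pytest

from gcomics import preprocess
from gcomics.containers import AbundanceMatrix
from gcomics.simulate import (GcConfig, RegenConfig, generate_gc_multiomic,
                              generate_knowledge_tables,
                              generate_regen_lipidome)


@pytest.fixture(scope="session")
def gc_bundle():
    """Default growth-cone bundle, seed 1 (the canonical study design)."""
    return generate_gc_multiomic(GcConfig(), seed=1)


@pytest.fixture(scope="session")
def regen_bundle():
    """Default regeneration bundle, seed 42."""
    return generate_regen_lipidome(RegenConfig(), seed=42)


@pytest.fixture(scope="session")
def knowledge(gc_bundle):
    return generate_knowledge_tables(gc_bundle.truth, seed=1)


@pytest.fixture(scope="session")
def gc_protein_log(gc_bundle):
    """Total-intensity normalized, log2 proteome."""
    return preprocess.normalize(
        gc_bundle.protein_matrix, "total_intensity").to_log2()


@pytest.fixture(scope="session")
def gc_lipid_log(gc_bundle):
    return preprocess.normalize(
        gc_bundle.lipid_matrix, "total_intensity").to_log2()


def small_matrix(values, space="raw", features=None, samples=None):
    """Helper: AbundanceMatrix from a plain nested list / array."""
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return AbundanceMatrix(pd.DataFrame(arr, index=features, columns=samples), space)
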