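import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import broaddomain as bd

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg() -> bd.SynthConfig:
    return bd.SynthConfig(seed=0)


@pytest.fixture(scope="session")
def sim(default_cfg):
    """One full simulated dataset at the shipped defaults (seed 0)."""
    genes = bd.simulate_genome(default_cfg)
    peaks_control, peaks_mutant, truth = bd.simulate_peaks(genes, default_cfg)
    return {
        "cfg": default_cfg,
        "genes": genes,
        "peaks_control": peaks_control,
        "peaks_mutant": peaks_mutant,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def sim_counts(sim):
    return bd.simulate_counts(sim["truth"], sim["cfg"])


@pytest.fixture(scope="session")
def sim_classified(sim):
    assignment = bd.assign_peaks_to_genes(sim["peaks_control"], sim["genes"])
    table = bd.gene_breadth(assignment)
    return bd.classify_breadth(table)


def make_count_matrix(arr, features=None, samples=None, conditions=None) -> bd.CountMatrix:
    arr = np.asarray(arr)
    n, m = arr.shape
    features = features or [f"f{i + 1}" for i in range(n)]
    samples = samples or [f"s{j + 1}" for j in range(m)]
    if conditions is None:
        half = m // 2
        conditions = ["control"] * half + ["mutant"] * (m - half)
    df = pd.DataFrame(arr, index=pd.Index(features, name="feature_id"), columns=samples)
    return bd.CountMatrix(counts=df, sample_condition=dict(zip(samples, conditions)))
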