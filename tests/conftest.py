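import numpy as np
import pandas as pd
import pytest

from exohem import EDBiomarkerModel, SimulationConfig, simulate_cohort
from exohem.expression import PairedCounts


def make_counts(matrix, sample_ids=None, biotypes=None, pairs=None) -> PairedCounts:
    """PairedCounts from a plain array; samples default to p1_pre, p1_post, ..."""
    mat = np.asarray(matrix)
    n_rna, n_samp = mat.shape
    if sample_ids is None:
        assert n_samp % 2 == 0
        sample_ids = []
        for i in range(n_samp // 2):
            sample_ids += [f"p{i + 1}_pre", f"p{i + 1}_post"]
    if pairs is None:
        pairs = {
            s[: -len("_pre")]: (s, s[: -len("_pre")] + "_post")
            for s in sample_ids
            if s.endswith("_pre")
        }
    rna_ids = [f"r{i}" for i in range(n_rna)]
    counts = pd.DataFrame(mat, index=pd.Index(rna_ids, name="rna_id"), columns=sample_ids)
    bt = pd.Series(biotypes if biotypes is not None else "mRNA", index=counts.index)
    return PairedCounts(counts, bt, pairs)


def correlated_columns(rng, n, targets):
    """Columns with exact sample correlations to a base column.

    Returns a DataFrame whose column 'c0' is standardized noise and each
    further column has empirical Pearson correlation targets[i] with c0.
    """
    base = rng.normal(size=n)
    base = (base - base.mean()) / base.std()
    cols = {"c0": base}
    for i, t in enumerate(targets):
        e = rng.normal(size=n)
        e = e - e.mean()
        e = e - base * (base @ e) / (base @ base)  # orthogonalize
        e = e / e.std()
        cols[f"c{i + 1}"] = t * base + np.sqrt(1 - t**2) * e
    return pd.DataFrame(cols)


@pytest.fixture(scope="session")
def sim_cohort():
    """Default synthetic cohort with the three planted drivers (seed 7)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def fitted(sim_cohort):
    recs, counts, truth = sim_cohort
    return EDBiomarkerModel(recs, counts).fit(), truth
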