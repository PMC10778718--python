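"""Key-RNA selection: exhaustive all-subsets regression with
inclusion-frequency thresholds, and the all-five-CBC coverage criterion.

The subset search fits ordinary least squares of the outcome (by default the
binary early-death indicator, a linear probability model) on every
combination of network-RNA log2FC profiles up to ``max_k`` predictors, keeps
the best model per size by adjusted R-squared, and scores each RNA by its
inclusion frequency over those per-size champions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import NC_BIOTYPES


@dataclass
class SubsetSearchResult:
    """Per-size best subsets and RNA inclusion frequencies.

    ``best_models`` has one row per subset size k with the member tuple and
    both plain and adjusted R-squared (plain R2 is monotone in k; adjusted
    R2 need not be). ``inclusion_freq`` is the fraction of retained (per-size
    best) models containing each RNA.
    """

    best_models: pd.DataFrame
    inclusion_freq: pd.Series
    outcome_name: str
    dropped: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        out = self.best_models.copy()
        out["members"] = out["members"].map(lambda m: ",".join(m))
        out.to_csv(path, sep="\t", index=False)


def _subset_rss_batch(G: np.ndarray, b: np.ndarray, yty: float, combos: np.ndarray) -> np.ndarray:
    """RSS of centered OLS for each predictor subset (rows of ``combos``)."""
    Gs = G[combos[:, :, None], combos[:, None, :]]
    bs = b[combos]
    try:
        beta = np.linalg.solve(Gs, bs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.empty_like(bs)
        for i in range(len(combos)):
            beta[i] = np.linalg.lstsq(Gs[i], bs[i], rcond=None)[0]
    rss = yty - np.einsum("ij,ij->i", beta, bs)
    return np.maximum(rss, 0.0)


def exhaustive_subsets(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    max_k: int | None = None,
    standardize: bool = True,
    outcome_name: str = "ED",
    max_enumeration: int = 5_000_000,
    chunk: int = 100_000,
) -> SubsetSearchResult:
    """Enumerate every predictor subset of size 1..max_k and keep the best
    model per size by adjusted R-squared.

    Exactly collinear predictors (pairwise |r| = 1 to machine tolerance) are
    dropped with a warning, later column first. Ties in adjusted R-squared
    break lexicographically on the sorted member ids. ``max_k`` defaults to
    min(10, n_patients // 4, n_predictors).
    """
    X = X.copy()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y length mismatch")
    # deterministic lexicographic predictor order
    X = X[sorted(X.columns)]
    dropped: list[str] = []
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0)
    const = sd == 0
    if const.any():
        dropped += [c for c, bad in zip(X.columns, const) if bad]
        X = X.loc[:, ~const]
        Xv = X.to_numpy(dtype=float)
        sd = sd[~const]
    # exact duplicates / perfect collinearity (pairwise)
    Z = (Xv - Xv.mean(axis=0)) / sd
    C = (Z.T @ Z) / n
    dup = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        if dup[j]:
            continue
        clones = np.where(np.abs(C[j, j + 1:]) > 1 - 1e-12)[0] + j + 1
        dup[clones] = True
    if dup.any():
        names = [c for c, bad in zip(X.columns, dup) if bad]
        warnings.warn(f"dropping perfectly collinear predictors: {names}", stacklevel=2)
        dropped += names
        X = X.loc[:, ~dup]
        Xv = X.to_numpy(dtype=float)
    p = X.shape[1]
    if p == 0:
        raise ValueError("no usable predictors")
    if max_k is None:
        max_k = min(10, n // 4, p)
    max_k = min(max_k, p, n - 2)
    if max_k < 1:
        raise ValueError(f"too few patients (n={n}) for any subset model")
    import math

    total = sum(math.comb(p, k) for k in range(1, max_k + 1))
    if total > max_enumeration:
        raise ValueError(
            f"enumeration of {total} subsets exceeds max_enumeration={max_enumeration}; "
            "lower max_k or raise the limit"
        )
    Xc = Xv - Xv.mean(axis=0)
    if standardize:
        Xc = Xc / Xc.std(axis=0)
    yc = y - y.mean()
    yty = float(yc @ yc)
    if yty == 0:
        raise ValueError("outcome is constant")
    G = Xc.T @ Xc
    b = Xc.T @ yc
    cols = np.array(X.columns)
    best_rows = []
    for k in range(1, max_k + 1):
        best_rss = np.inf
        best_combo: tuple[int, ...] | None = None
        it = itertools.combinations(range(p), k)
        while True:
            block = np.fromiter(
                itertools.chain.from_iterable(itertools.islice(it, chunk)),
                dtype=np.int64,
            ).reshape(-1, k)
            if block.size == 0:
                break
            rss = _subset_rss_batch(G, b, yty, block)
            i = int(np.argmin(rss))
            # strict < keeps the lexicographically first tie (combinations
            # iterate in lexicographic order of the sorted column ids)
            if rss[i] < best_rss:
                best_rss = float(rss[i])
                best_combo = tuple(block[i])
        assert best_combo is not None
        r2 = 1.0 - best_rss / yty
        dfree = n - k - 1
        adj = 1.0 - (1.0 - r2) * (n - 1) / dfree if dfree > 0 else np.nan
        best_rows.append(
            dict(k=k, members=tuple(cols[list(best_combo)]), r2=r2, adj_r2=adj)
        )
    best_models = pd.DataFrame(best_rows)
    counts = pd.Series(0, index=cols, dtype=float)
    for members in best_models["members"]:
        for m in members:
            counts[m] += 1
    freq = counts / len(best_models)
    return SubsetSearchResult(best_models, freq.rename("inclusion_freq"), outcome_name, dropped)


# ---------------------------------------------------------------------------
# Key-RNA selection
# ---------------------------------------------------------------------------

@dataclass
class KeyRNASet:
    key_ncrnas: list[str]
    key_mrnas: list[str]
    all_cbc_rnas: list[str]
    triple: list[tuple[str, int]] = field(default_factory=list)  # (rna, ED sign)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "key_ncrnas": self.key_ncrnas,
                    "key_mrnas": self.key_mrnas,
                    "all_cbc_rnas": self.all_cbc_rnas,
                    "triple": [{"rna": r, "ed_sign": s} for r, s in self.triple],
                },
                fh,
                sort_keys=False,
            )


def select_key_rnas(
    results: list[SubsetSearchResult],
    biotypes: pd.Series,
    nc_thresh: float = 0.5,
    m_thresh: float = 0.6,
) -> tuple[list[str], list[str]]:
    """ncRNAs with inclusion frequency strictly above ``nc_thresh`` and
    mRNAs strictly above ``m_thresh``, as the union over the per-network
    subset-search results (thresholds are 'more than', so exact equality is
    excluded)."""
    ncs: set[str] = set()
    ms: set[str] = set()
    for res in results:
        for rna, f in res.inclusion_freq.items():
            bt = biotypes.get(rna)
            if bt == "mRNA":
                if f > m_thresh:
                    ms.add(rna)
            elif bt in NC_BIOTYPES:
                if f > nc_thresh:
                    ncs.add(rna)
    return sorted(ncs), sorted(ms)


def all_cbc_coverage(annotation_flags: pd.DataFrame, nodes: list[str]) -> list[str]:
    """RNAs among ``nodes`` linked to all five cell types (via any of the
    c0, c1, c2, c3 or nadir variables of each)."""
    if annotation_flags.attrs.get("variant") not in (None, "network_annotation"):
        raise ValueError("coverage requires flags computed with variant='network_annotation'")
    present = [r for r in nodes if r in annotation_flags.index]
    sub = annotation_flags.loc[present]
    return sorted(sub.index[sub["n_cell_types"] == 5])
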