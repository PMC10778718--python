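"""RNA-CBC-outcome correlation matrices, link-flag semantics and the
baseline-vs-recovery (homeostasis) screen.

Significance throughout this module is a two-sided Pearson p < alpha with no
multiple-testing correction: the thresholds here define a *screening* rule
feeding the network-admission step, not inferential claims about single
RNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cbc import CELL_TYPES, RATIOS
from .expression import Log2FCTable, NC_BIOTYPES


@dataclass
class AssociationMatrix:
    """Pairwise-complete Pearson correlations of per-patient RNA log2FC
    against CBC-dynamics variables and outcome indicators.

    ``r``, ``p`` and ``n`` are RNA x variable DataFrames; constant columns
    yield missing (NaN) entries, never 0.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    biotype: pd.Series

    @property
    def variables(self) -> pd.Index:
        return self.r.columns

    def to_tsv(self, path) -> None:
        long = (
            self.r.stack(future_stack=True)
            .rename("R")
            .to_frame()
            .join(self.p.stack(future_stack=True).rename("p"))
            .join(self.n.stack(future_stack=True).rename("n"))
        )
        long.index.names = ["rna", "variable"]
        long.reset_index().to_csv(path, sep="\t", index=False)


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized Pearson r and two-sided t-based p of each column of X vs y,
    over rows where y is finite. Constant columns give NaN."""
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    n = X.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 patients for correlation analysis")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    r[(sx == 0) | (sy == 0)] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    p[np.abs(r) == 1.0] = 0.0
    return r, p, n


def correlate_all(
    lfc: Log2FCTable,
    dyn: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> AssociationMatrix:
    """Correlate every RNA's per-patient log2FC with every CBC-dynamics
    variable and with the outcome indicators.

    ``outcomes`` must carry boolean/0-1 columns ``ED`` (early disease
    -specific death) and ``EP`` (early progression); extra numeric columns
    (e.g. survival time) are correlated as-is.
    """
    patients = lfc.lfc.index
    dyn = dyn.reindex(patients)
    outcomes = outcomes.reindex(patients)
    variables = pd.concat([dyn, outcomes.astype(float)], axis=1)
    X = lfc.lfc.to_numpy(dtype=float)
    r_cols, p_cols, n_cols = {}, {}, {}
    for v in variables.columns:
        r, p, n = _pearson_columns(X, variables[v].to_numpy(dtype=float))
        r_cols[v], p_cols[v], n_cols[v] = r, p, n
    rnas = lfc.lfc.columns
    return AssociationMatrix(
        r=pd.DataFrame(r_cols, index=rnas),
        p=pd.DataFrame(p_cols, index=rnas),
        n=pd.DataFrame(n_cols, index=rnas),
        biotype=lfc.biotype.reindex(rnas),
    )


# ---------------------------------------------------------------------------
# Link flags
# ---------------------------------------------------------------------------

#: variable lists defining "linked to cell type c" per flag variant
ADMISSION_VARS = {c: (f"{c}0", f"min_{c}", f"{c}1") for c in CELL_TYPES}
ANNOTATION_VARS = {c: (f"{c}0", f"{c}1", f"{c}2", f"{c}3", f"min_{c}") for c in CELL_TYPES}
RATIO_VARS = {r: (f"{r}0", f"{r}1") for r in RATIOS}


def cbc_link_flags(
    assoc: AssociationMatrix,
    alpha: float = 0.05,
    variant: str = "network_admission",
) -> pd.DataFrame:
    """Per-RNA link flags against the five cell types and three ratios.

    ``variant='network_admission'`` links a cell type through {c0, min_c, c1};
    ``variant='network_annotation'`` through {c0, c1, c2, c3, min_c}. An RNA
    is linked when significant (p < alpha) against at least one variable of
    the list. Also reports ED/EP significance, the ED correlation and its
    sign, the count of linked cell types (of 5) and of hematological groups
    (of 8).
    """
    if variant == "network_admission":
        cell_vars = ADMISSION_VARS
    elif variant == "network_annotation":
        cell_vars = ANNOTATION_VARS
    else:
        raise ValueError(f"unknown variant {variant!r}")
    sig = assoc.p < alpha
    out = pd.DataFrame(index=assoc.r.index)
    for c, vars_ in cell_vars.items():
        out[f"linked_{c}"] = sig[list(vars_)].any(axis=1)
    for r_, vars_ in RATIO_VARS.items():
        out[f"linked_{r_}"] = sig[list(vars_)].any(axis=1)
    out["n_cell_types"] = out[[f"linked_{c}" for c in CELL_TYPES]].sum(axis=1)
    out["n_hematologic"] = out[
        [f"linked_{c}" for c in CELL_TYPES] + [f"linked_{r_}" for r_ in RATIOS]
    ].sum(axis=1)
    out["ed_sig"] = sig["ED"]
    out["ep_sig"] = sig["EP"]
    out["r_ed"] = assoc.r["ED"]
    out["ed_sign"] = np.sign(assoc.r["ED"]).fillna(0).astype(int)
    out.attrs["variant"] = variant
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# Homeostasis screen
# ---------------------------------------------------------------------------

#: plotting convention: line style encodes cell type, color encodes ED sign
_STYLE = {"ANC": "solid", "PLT": "solid", "Hb": "dashed", "Mo": "dashed", "ALC": "dashed"}


def homeostasis_screen(
    assoc: AssociationMatrix,
    dyn: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen for RNAs that explain a negative baseline-recovery relation.

    For cell type c and baseline b in {c0, c1}: an RNA is flagged when
    (i) the cohort-level correlation corr(b, c3) is negative, (ii) the RNA is
    significantly correlated with b AND with c3, and (iii) those two RNA
    correlations carry opposite signs — the RNA moves with the baseline and
    against the recovery (or vice versa), consistent with a homeostatic
    mechanism. The quadrant class combines the sign vs the baseline, the
    sign vs c3 and the ED sign (color red = ED-positive, blue = ED-negative;
    solid lines for ANC/PLT, dashed for Hb/Mo/ALC).

    Returns a long DataFrame, one row per (rna, cell_type), flagged rows
    only, plus a ``summary`` attribute with per-cell-type counts and the
    ED-associated subset size.
    """
    sig = assoc.p < alpha
    ed_sig = sig["ED"]
    ed_sign = np.sign(assoc.r["ED"])
    rows = []
    for c in CELL_TYPES:
        c3 = f"{c}3"
        if c3 not in dyn.columns or dyn[c3].isna().all():
            continue  # skip with note in summary
        for b in (f"{c}0", f"{c}1"):
            cohort_r = dyn[b].corr(dyn[c3])
            if not (cohort_r < 0):
                continue
            flagged = sig[b] & sig[c3] & (np.sign(assoc.r[b]) * np.sign(assoc.r[c3]) < 0)
            for rna in assoc.r.index[flagged]:
                rows.append(
                    dict(
                        rna=rna,
                        cell_type=c,
                        baseline=b,
                        r_baseline=assoc.r.loc[rna, b],
                        r_c3=assoc.r.loc[rna, c3],
                        cohort_r=cohort_r,
                        ed_sig=bool(ed_sig.loc[rna]),
                        ed_sign=int(ed_sign.loc[rna]) if np.isfinite(ed_sign.loc[rna]) else 0,
                        color="red" if ed_sign.loc[rna] > 0 else "blue",
                        style=_STYLE[c],
                    )
                )
    cols = ["rna", "cell_type", "baseline", "r_baseline", "r_c3", "cohort_r",
            "ed_sig", "ed_sign", "color", "style"]
    out = pd.DataFrame(rows, columns=cols)
    # collapse to one row per (rna, cell type); keep the first qualifying baseline
    out = out.drop_duplicates(subset=["rna", "cell_type"], keep="first").reset_index(drop=True)
    summary = (
        out.groupby("cell_type")
        .agg(n_flagged=("rna", "size"), n_ed=("ed_sig", "sum"))
        .reindex(CELL_TYPES)
        .infer_objects(copy=False)
        .fillna(0)
        .astype(int)
    )
    out.attrs["summary"] = summary
    return out


def screen_summary_tsv(screen: pd.DataFrame, path) -> None:
    screen.attrs["summary"].to_csv(path, sep="\t", index_label="cell_type")
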