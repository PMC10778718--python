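"""Paired RNA count handling: detection filtering, TMM normalization and
per-patient log2 fold changes (week-2 on-treatment vs pre-treatment).

The normalization implements the trimmed mean of M-values (TMM) scheme of
Robinson & Oshlack: between-sample scaling factors computed from doubly
trimmed, precision-weighted log-ratios against a reference sample, so that
fold changes are comparable across libraries of different size and
composition. Factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

BIOTYPES = ("miRNA", "piRNA", "snoRNA", "snRNA", "tRNA", "yRNA", "lncRNA", "mRNA")

NC_BIOTYPES = frozenset(b for b in BIOTYPES if b != "mRNA")


class PairingError(ValueError):
    """A patient lacks exactly one pre and one post sample."""


@dataclass
class PairedCounts:
    """RNA x sample integer read counts with biotype labels and a pre/post
    pairing map ``patient_id -> (pre_sample, post_sample)``."""

    counts: pd.DataFrame  # index: rna ids, columns: sample ids
    biotype: pd.Series  # index: rna ids
    pairs: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.biotype = self.biotype.rename("biotype")
        if not self.biotype.index.equals(self.counts.index):
            self.biotype = self.biotype.reindex(self.counts.index)
            if self.biotype.isna().any():
                missing = self.biotype.index[self.biotype.isna()][:5].tolist()
                raise ValueError(f"missing biotype for RNAs: {missing}")
        sample_set = set(self.counts.columns)
        for pid, (pre, post) in self.pairs.items():
            if pre not in sample_set or post not in sample_set:
                raise PairingError(f"patient {pid!r}: samples {pre!r}/{post!r} not in matrix")

    @property
    def rna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def patient_ids(self) -> list[str]:
        return list(self.pairs)

    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset(self, rna_ids) -> "PairedCounts":
        return PairedCounts(self.counts.loc[rna_ids], self.biotype.loc[rna_ids], dict(self.pairs))

    # ---- I/O ------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "biotype", self.biotype)
        out.to_csv(path, sep="\t", index_label="rna_id")

    @classmethod
    def from_tsv(cls, path, pairs: dict[str, tuple[str, str]] | None = None) -> "PairedCounts":
        df = pd.read_csv(path, sep="\t", index_col="rna_id")
        biotype = df.pop("biotype")
        if pairs is None:
            pairs = infer_pairs(df.columns)
        return cls(df.astype(np.int64), biotype, pairs)


def infer_pairs(sample_ids) -> dict[str, tuple[str, str]]:
    """Recover the pairing map from the ``<patient>_pre`` / ``<patient>_post``
    sample naming convention."""
    pre = {s[: -len("_pre")]: s for s in sample_ids if s.endswith("_pre")}
    post = {s[: -len("_post")]: s for s in sample_ids if s.endswith("_post")}
    if set(pre) != set(post):
        odd = set(pre) ^ set(post)
        raise PairingError(f"unpaired patients in sample names: {sorted(odd)}")
    return {p: (pre[p], post[p]) for p in sorted(pre)}


@dataclass
class Log2FCTable:
    """Patient x RNA matrix of per-patient log2 fold changes plus the
    normalization factors and a filter audit trail."""

    lfc: pd.DataFrame  # index: patient ids, columns: rna ids
    factors: pd.Series  # per sample
    lib_sizes: pd.Series
    biotype: pd.Series
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.lfc.isna().any().any():
            raise ValueError("log2FC table contains missing values")
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    def to_tsv(self, path) -> None:
        self.lfc.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path, biotype: pd.Series | None = None) -> "Log2FCTable":
        lfc = pd.read_csv(path, sep="\t", index_col="patient_id")
        nsamp = 2 * len(lfc)
        dummy = pd.Series(1.0, index=pd.RangeIndex(nsamp))
        bt = biotype if biotype is not None else pd.Series("mRNA", index=lfc.columns)
        return cls(lfc, dummy, dummy.copy(), bt)


# ---------------------------------------------------------------------------
# Detection filter
# ---------------------------------------------------------------------------

def detection_filter(counts: PairedCounts, min_detect_frac: float = 0.5) -> PairedCounts:
    """Drop RNAs undetected (zero count) in at least ``min_detect_frac`` of
    all samples; i.e. retain an RNA only if it has a positive count in
    strictly more than ``1 - min_detect_frac`` of samples.

    The retained object carries an ``audit`` attribute (DataFrame per removed
    RNA: biotype, detection fraction).
    """
    if counts.counts.shape[1] < 2:
        raise ValueError("detection filter needs at least 2 samples")
    detect_frac = (counts.counts > 0).mean(axis=1)
    keep = detect_frac > (1.0 - min_detect_frac)
    if not keep.any():
        raise ValueError(
            "detection filter removed every RNA; review the min_detect_frac threshold"
        )
    removed = counts.counts.index[~keep]
    audit = pd.DataFrame(
        {
            "biotype": counts.biotype.loc[removed],
            "detect_frac": detect_frac.loc[removed],
        }
    )
    out = counts.subset(counts.counts.index[keep])
    out.audit = audit  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM factor of one sample against the reference.

    M-values are trimmed symmetrically by ``logratio_trim`` and A-values by
    ``sum_trim``; the surviving M-values are combined by inverse-variance
    (binomial delta-method) weights.
    """
    both = (obs > 0) & (ref > 0)
    obs = obs[both].astype(float)
    ref = ref[both].astype(float)
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
    abs_e = 0.5 * (np.log2(obs / lib_obs) + np.log2(ref / lib_ref))
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: PairedCounts,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample, unless given, is the one whose upper-quartile
    (75th percentile of counts scaled by library size) is closest to the
    mean upper-quartile across samples.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = mat.sum(axis=0)
    zero = lib == 0
    if zero.any():
        bad = counts.sample_ids[zero].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    if ref_sample is None:
        f75 = np.quantile(mat / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.sample_ids.get_loc(ref_sample)
    ref = mat[:, ref_idx]
    lib_ref = lib[ref_idx]
    raw = np.array(
        [
            _tmm_pair(mat[:, j], ref, lib[j], lib_ref, logratio_trim, sum_trim)
            for j in range(mat.shape[1])
        ]
    )
    raw /= np.exp(np.mean(np.log(raw)))
    return pd.Series(raw, index=counts.sample_ids, name="tmm_factor")


# ---------------------------------------------------------------------------
# Per-patient log2 fold change
# ---------------------------------------------------------------------------

def paired_log2fc(
    counts: PairedCounts,
    factors: pd.Series,
    pseudocount: float | None = None,
) -> Log2FCTable:
    """Per-patient log2 fold change of effective-library-normalized abundance,
    post (week-2) over pre.

    abundance = count / (lib_size * factor); the pseudocount defaults to
    0.5 / mean(lib_size), i.e. half a read at the average depth, and is added
    on the abundance scale to both samples so the pre/post swap antisymmetry
    is exact.
    """
    missing = [s for s in counts.sample_ids if s not in factors.index]
    if missing:
        raise ValueError(f"normalization factors missing for samples: {missing[:5]}")
    lib = counts.lib_sizes().astype(float)
    if pseudocount is None:
        pseudocount = 0.5 / float(lib.mean())
    eff = lib * factors.loc[counts.sample_ids]
    abund = counts.counts / eff
    rows = {}
    for pid, (pre, post) in counts.pairs.items():
        rows[pid] = np.log2((abund[post] + pseudocount) / (abund[pre] + pseudocount))
    lfc = pd.DataFrame(rows).T
    lfc.index.name = "patient_id"
    audit = getattr(counts, "audit", pd.DataFrame())
    return Log2FCTable(
        lfc=lfc,
        factors=factors.loc[counts.sample_ids],
        lib_sizes=lib,
        biotype=counts.biotype,
        audit=audit,
    )
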