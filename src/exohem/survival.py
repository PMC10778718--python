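"""Three-RNA composite score and disease-specific survival stratification,
plus a local Fisher over-representation test for gene sets.

The composite score is the signed sum of the selected RNAs' per-patient
log2 fold changes, each entering with the sign of its early-death
correlation (the ED-positive ncRNA with +, the ED-negative RNAs with -), so
a score below zero marks the favorable profile. Survival is summarized by
Kaplan-Meier curves per score group, the log-rank test over the full
follow-up, and the disease-specific survival rate read off the curves at a
30-month horizon; deaths from non-disease causes are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .cbc import ClinicalRecord
from .expression import Log2FCTable


@dataclass
class CompositeScore:
    """Per-patient composite score and the score-0 dichotomy."""

    scores: pd.Series  # per patient
    triple: list[tuple[str, int]]  # (rna_id, ED sign in {+1, -1})

    @property
    def group(self) -> pd.Series:
        """'low' for score < 0 (favorable), 'high' for score >= 0."""
        return pd.Series(
            np.where(self.scores < 0, "low", "high"), index=self.scores.index, name="group"
        )


def composite_score(lfc: Log2FCTable, triple: list[tuple[str, int]]) -> CompositeScore:
    """Signed sum of the selected RNAs' log2FC values.

    ``triple`` lists (rna_id, ed_sign); each RNA contributes
    ``ed_sign * log2FC``. With the canonical three-RNA choice this is
    +lfc(positive ncRNA) - lfc(negative ncRNA) - lfc(negative mRNA).
    """
    if not triple:
        raise ValueError("empty RNA selection for composite score")
    for rna, sign in triple:
        if rna not in lfc.lfc.columns:
            raise KeyError(f"RNA {rna!r} missing from log2FC table")
        if sign not in (-1, 1):
            raise ValueError(f"RNA {rna!r}: ED sign must be +1 or -1, got {sign}")
    score = sum(sign * lfc.lfc[rna] for rna, sign in triple)
    return CompositeScore(score.rename("score"), list(triple))


@dataclass
class SurvivalReport:
    curves: dict[str, pd.DataFrame]  # per group: time, S, at_risk
    s_at_horizon: dict[str, float]
    horizon: float
    logrank_stat: float | None
    logrank_p: float | None
    wilcoxon_stat: float | None
    wilcoxon_p: float | None
    median_followup: float
    note: str = ""

    def to_tsv(self, path) -> None:
        rows = []
        for grp, curve in self.curves.items():
            for _, r in curve.iterrows():
                rows.append({"group": grp, **r})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _dss_time_event(rec: ClinicalRecord) -> tuple[float, int]:
    """Disease-specific survival: disease deaths are events; other deaths and
    living patients are censored at their last time."""
    if rec.death_time is not None and rec.death_cause == "disease":
        return rec.death_time, 1
    return rec.survival_time, 0


def km_logrank(
    scores: CompositeScore,
    recs: list[ClinicalRecord],
    horizon: float = 30.0,
    ed: pd.Series | None = None,
) -> SurvivalReport:
    """Kaplan-Meier disease-specific survival per composite-score group with
    a two-group log-rank test (full follow-up) and the survival probability
    at the horizon (right-continuous step convention: S(t) = P(T > t)).

    ``ed`` (boolean per patient), when given, adds a Wilcoxon rank-sum test
    of the composite score between ED and non-ED patients. Median follow-up
    is the reverse Kaplan-Meier median (censoring treated as the event).
    """
    by_id = {r.patient_id: r for r in recs}
    missing = [p for p in scores.scores.index if p not in by_id]
    if missing:
        raise ValueError(f"clinical records missing for patients: {missing[:5]}")
    times, events, groups = [], [], []
    for pid in scores.scores.index:
        t, e = _dss_time_event(by_id[pid])
        times.append(t)
        events.append(e)
    df = pd.DataFrame(
        {"time": times, "event": events, "group": scores.group}, index=scores.scores.index
    )
    curves: dict[str, pd.DataFrame] = {}
    s_at: dict[str, float] = {}
    for grp, sub in df.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(grp))
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curves[str(grp)] = pd.DataFrame(
            {"time": surv.index.to_numpy(), "S": surv.to_numpy(), "at_risk": at_risk.to_numpy()}
        )
        s_at[str(grp)] = float(kmf.predict(horizon))
    note = ""
    if df["group"].nunique() == 2:
        a = df[df["group"] == "low"]
        b = df[df["group"] == "high"]
        lr = logrank_test(a["time"], b["time"], a["event"], b["event"])
        lr_stat, lr_p = float(lr.test_statistic), float(lr.p_value)
    else:
        lr_stat = lr_p = None
        note = "single score group; log-rank skipped"
    if ed is not None:
        ed = ed.reindex(scores.scores.index).astype(bool)
        s_ed = scores.scores[ed].to_numpy()
        s_non = scores.scores[~ed].to_numpy()
        if len(s_ed) and len(s_non):
            w = stats.ranksums(s_ed, s_non)
            w_stat, w_p = float(w.statistic), float(w.pvalue)
        else:
            w_stat = w_p = None
    else:
        w_stat = w_p = None
    # reverse KM for median follow-up: censoring is the event
    rkm = KaplanMeierFitter()
    rkm.fit(df["time"], 1 - df["event"])
    median_fu = float(rkm.median_survival_time_)
    return SurvivalReport(curves, s_at, horizon, lr_stat, lr_p, w_stat, w_p, median_fu, note)


def plot_km(report: SurvivalReport, path) -> None:
    """Step plot of the per-group Kaplan-Meier curves (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, curve in report.curves.items():
        ax.step(curve["time"], curve["S"], where="post", label=f"score {grp}")
    ax.set_xlabel("months")
    ax.set_ylabel("disease-specific survival")
    ax.set_ylim(0, 1.05)
    if report.logrank_p is not None:
        ax.set_title(f"log-rank p = {report.logrank_p:.2g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Local over-representation analysis
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def local_ora(
    query: set[str],
    collections: dict[str, set[str]],
    background_size: int,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation per term with
    Benjamini-Hochberg FDR across terms.

    Table per term: k = |query & term|, K = |term|, n = |query|,
    N = background_size; p = hypergeometric upper tail P(X >= k).
    """
    from statsmodels.stats.multitest import multipletests

    if not query or not collections:
        raise ValueError("query and collections must be nonempty")
    n = len(query)
    if n > background_size:
        raise ValueError("query larger than background")
    rows = []
    for term, members in collections.items():
        K = len(members)
        if K > background_size:
            raise ValueError(f"term {term!r} larger than background")
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, background_size, K, n))
        denom = (n - k) * (K - k)
        odds = (k * (background_size - K - n + k)) / denom if denom > 0 else np.inf
        rows.append(dict(term=term, k=k, K=K, n=n, N=background_size, odds_ratio=odds, p=p))
    out = pd.DataFrame(rows).set_index("term")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p")
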