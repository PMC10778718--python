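"""Complete-blood-count (CBC) dynamics, outcome grouping, propensity-score
matching and matched group comparisons.

Per cell type c in {ANC, PLT, Hb, ALC, Mo} the derived features are

* ``c0``     pre-treatment value,
* ``min_c``  minimum over the on-treatment panels (nadir),
* ``c1``     geometric mean sqrt(c0 * min_c),
* ``c2``     week-2 on-treatment value,
* ``c3``     log(c2 / c0)  (natural log by default; base configurable),

plus the baseline and mid-treatment ratios NLR = ANC/ALC, PLR = PLT/ALC and
LMR = ALC/Mo formed from the 0- and 1-level features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CELL_TYPES = ("ANC", "PLT", "Hb", "ALC", "Mo")
RATIOS = ("NLR", "PLR", "LMR")

#: CBC units: ANC, ALC, Mo in cells/uL; PLT in 10^3 cells/uL; Hb in g/dL.
CBC_UNITS = {"ANC": "cells/uL", "PLT": "1e3 cells/uL", "Hb": "g/dL", "ALC": "cells/uL", "Mo": "cells/uL"}


class MissingPanelError(ValueError):
    """A required CBC panel (pre or week-2) is absent for a patient."""


@dataclass
class ClinicalRecord:
    """One patient: covariates, serial CBC panels and outcome times.

    ``cbc`` is a DataFrame indexed by time tag (``pre``, ``week1`` ... ) with
    one column per cell type. Times are in months; ``progression_time`` /
    ``death_time`` are None when the event was not observed, and
    ``follow_up`` is the last observation time.
    """

    patient_id: str
    age: float
    pathology: str
    stage: str
    rt_field: str
    cbc: pd.DataFrame
    progression_time: float | None = None
    death_time: float | None = None
    follow_up: float = 0.0
    death_cause: str = "alive"  # {'disease', 'other', 'alive'}

    def __post_init__(self) -> None:
        missing_ct = [c for c in CELL_TYPES if c not in self.cbc.columns]
        if missing_ct:
            raise ValueError(f"patient {self.patient_id}: CBC columns missing {missing_ct}")
        if (self.cbc[list(CELL_TYPES)] <= 0).any().any():
            raise ValueError(f"patient {self.patient_id}: nonpositive CBC value")
        if self.death_cause not in ("disease", "other", "alive"):
            raise ValueError(f"patient {self.patient_id}: bad death_cause {self.death_cause!r}")
        if (
            self.death_time is not None
            and self.progression_time is not None
            and self.death_time < self.progression_time
        ):
            raise ValueError(
                f"patient {self.patient_id}: death_time precedes progression_time"
            )

    @property
    def survival_time(self) -> float:
        """Time to death of any cause, or last follow-up if alive."""
        return self.death_time if self.death_time is not None else self.follow_up


@dataclass
class CBCDynamics:
    """Derived per-patient CBC features as a flat Series (see module docs)."""

    patient_id: str
    features: pd.Series

    def __getitem__(self, key: str) -> float:
        return float(self.features[key])


def feature_names() -> list[str]:
    names = []
    for c in CELL_TYPES:
        names += [f"{c}0", f"min_{c}", f"{c}1", f"{c}2", f"{c}3"]
    for r in RATIOS:
        names += [f"{r}0", f"{r}1"]
    return names


def derive_dynamics(rec: ClinicalRecord, log_base: float | None = None) -> CBCDynamics:
    """Compute the full CBC-dynamics feature vector for one patient.

    ``log_base=None`` means natural log for the c3 features. The nadir is the
    minimum over every on-treatment panel (all tags except ``pre``, the
    week-2 draw included).
    """
    if "pre" not in rec.cbc.index:
        raise MissingPanelError(f"patient {rec.patient_id}: no 'pre' panel")
    if "week2" not in rec.cbc.index:
        raise MissingPanelError(f"patient {rec.patient_id}: no 'week2' panel")
    on_tx = rec.cbc.drop(index="pre")
    if on_tx.empty:
        raise MissingPanelError(f"patient {rec.patient_id}: no on-treatment panel for nadir")
    log = math.log if log_base is None else (lambda x: math.log(x, log_base))
    feats: dict[str, float] = {}
    for c in CELL_TYPES:
        c0 = float(rec.cbc.loc["pre", c])
        c2 = float(rec.cbc.loc["week2", c])
        cmin = float(on_tx[c].min())
        feats[f"{c}0"] = c0
        feats[f"min_{c}"] = cmin
        feats[f"{c}1"] = math.sqrt(c0 * cmin)
        feats[f"{c}2"] = c2
        feats[f"{c}3"] = log(c2 / c0)
    for level in ("0", "1"):
        feats[f"NLR{level}"] = feats[f"ANC{level}"] / feats[f"ALC{level}"]
        feats[f"PLR{level}"] = feats[f"PLT{level}"] / feats[f"ALC{level}"]
        feats[f"LMR{level}"] = feats[f"ALC{level}"] / feats[f"Mo{level}"]
    return CBCDynamics(rec.patient_id, pd.Series(feats))


def dynamics_frame(recs: list[ClinicalRecord], log_base: float | None = None) -> pd.DataFrame:
    """Patients x features DataFrame of CBC dynamics."""
    rows = {r.patient_id: derive_dynamics(r, log_base).features for r in recs}
    df = pd.DataFrame(rows).T.loc[[r.patient_id for r in recs], feature_names()]
    df.index.name = "patient_id"
    return df


# ---------------------------------------------------------------------------
# Outcome groups
# ---------------------------------------------------------------------------

ED_GROUP, PROGRESSION_GROUP, NONPROGRESSION_GROUP = 1, 2, 3


def assign_groups(recs: list[ClinicalRecord]) -> pd.DataFrame:
    """Assign outcome groups.

    group 1 (early death): progression within 12 months and disease-specific
    death within 15 months; group 2 (progression): progression observed with
    overall survival beyond 30 months; group 3 (non-progression): no
    recurrence and follow-up beyond 60 months. Everyone else is unassigned
    (group <NA>). ``EP`` flags early progression (progression <= 12 months).
    """
    rows = []
    for r in recs:
        prog, death = r.progression_time, r.death_time
        group: int | None = None
        dsd = death is not None and r.death_cause == "disease"
        if prog is not None and prog <= 12 and dsd and death <= 15:
            group = ED_GROUP
        elif prog is not None and r.survival_time > 30:
            group = PROGRESSION_GROUP
        elif prog is None and r.follow_up > 60 and r.death_cause != "disease":
            group = NONPROGRESSION_GROUP
        rows.append(
            {
                "patient_id": r.patient_id,
                "group": group,
                "ED": group == ED_GROUP,
                "EP": prog is not None and prog <= 12,
            }
        )
    out = pd.DataFrame(rows).set_index("patient_id")
    out["group"] = out["group"].astype("Int64")
    return out


# ---------------------------------------------------------------------------
# Propensity-score matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    matches: pd.DataFrame  # columns: treated, control
    propensity: pd.Series  # logit scale
    smd_before: pd.Series
    smd_after: pd.Series
    fallback_used: bool = False


def _smd(df: pd.DataFrame, arm: pd.Series, covariates: list[str]) -> pd.Series:
    """Standardized mean differences; categorical covariates report the
    largest absolute SMD over their level indicators."""
    out = {}
    t = arm.astype(bool)
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            sub = [col]
            names = [cov]
        else:
            dummies = pd.get_dummies(col)
            sub = [dummies[c].astype(float) for c in dummies.columns]
            names = list(dummies.columns)
        vals = []
        for s in sub:
            mt, mc = s[t].mean(), s[~t].mean()
            vt, vc = s[t].var(ddof=1), s[~t].var(ddof=1)
            denom = math.sqrt((vt + vc) / 2.0) if (vt + vc) > 0 else np.nan
            vals.append(0.0 if not np.isfinite(denom) or denom == 0 else abs(mt - mc) / denom)
        out[cov] = max(vals)
    return pd.Series(out)


def _fit_propensity(df: pd.DataFrame, arm: pd.Series, covariates: list[str]) -> pd.Series | None:
    """Logit-scale propensity from a logistic regression; None on separation."""
    import statsmodels.api as sm

    X = pd.get_dummies(df[covariates], drop_first=True).astype(float)
    X = sm.add_constant(X, has_constant="add")
    y = arm.astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        probs = res.predict(X)
    except Exception:
        return None
    if not np.all(np.isfinite(res.params)):
        return None
    eps = 1e-9
    if ((probs < eps) | (probs > 1 - eps)).any():
        return None  # (quasi-)separation
    return pd.Series(np.log(probs / (1 - probs)), index=df.index)


def propensity_match(
    recs: list[ClinicalRecord],
    treat_label,
    control_label,
    covariates: list[str],
    groups: pd.Series | None = None,
    ratio: int = 1,
    caliper_sd: float | None = None,
) -> MatchResult:
    """Greedy 1:ratio nearest-neighbor matching without replacement on the
    logit propensity scale.

    ``groups`` maps patient_id to an arm label; when omitted the outcome
    groups from :func:`assign_groups` are used. Treated patients are
    processed in patient-id order, ties among controls broken by patient id,
    for determinism. ``caliper_sd`` (off by default) restricts matches to
    ``caliper_sd * SD(logit propensity)``. On complete separation of the
    arms the matching falls back to exact-stratum matching on the covariate
    tuple, with a warning.
    """
    if ratio not in (1, 2):
        raise ValueError("ratio must be 1 or 2")
    df = pd.DataFrame(
        {
            "age": [r.age for r in recs],
            "pathology": [r.pathology for r in recs],
            "stage": [r.stage for r in recs],
            "rt_field": [r.rt_field for r in recs],
        },
        index=pd.Index([r.patient_id for r in recs], name="patient_id"),
    )
    if groups is None:
        groups = assign_groups(recs)["group"]
    groups = groups.reindex(df.index)
    keep = groups.isin([treat_label, control_label])
    df = df.loc[keep]
    arm = (groups.loc[keep] == treat_label)
    n_t, n_c = int(arm.sum()), int((~arm).sum())
    if n_t < 1 or n_c < 2:
        raise ValueError("need at least 1 treated and 2 control patients")
    if n_c < ratio:
        raise ValueError(f"insufficient controls: need {ratio} per treated, have {n_c}")

    prop = _fit_propensity(df, arm, covariates)
    fallback = prop is None
    pairs: list[tuple[str, str]] = []
    if fallback:
        warnings.warn(
            "propensity model separation detected; falling back to exact stratum matching",
            stacklevel=2,
        )
        strata = df[covariates].astype(str).agg("|".join, axis=1)
        used: set[str] = set()
        for t_id in sorted(df.index[arm]):
            pool = sorted(
                c for c in df.index[~arm] if strata[c] == strata[t_id] and c not in used
            )
            for c_id in pool[:ratio]:
                pairs.append((t_id, c_id))
                used.add(c_id)
        prop = pd.Series(np.nan, index=df.index)
    else:
        sd = prop.std(ddof=1)
        cal = caliper_sd * sd if caliper_sd is not None else np.inf
        used = set()
        shortfall = []
        for t_id in sorted(df.index[arm]):
            avail = [(abs(prop[c] - prop[t_id]), c) for c in df.index[~arm] if c not in used]
            avail = [(d, c) for d, c in avail if d <= cal]
            avail.sort(key=lambda x: (x[0], x[1]))
            chosen = avail[:ratio]
            if len(chosen) < ratio:
                shortfall.append((t_id, ratio - len(chosen)))
            for _, c_id in chosen:
                pairs.append((t_id, c_id))
                used.add(c_id)
        if shortfall and caliper_sd is None:
            raise ValueError(f"insufficient controls for treated patients: {shortfall}")

    matches = pd.DataFrame(pairs, columns=["treated", "control"])
    matched_ids = pd.unique(matches.values.ravel()) if len(matches) else np.array([], dtype=object)
    smd_before = _smd(df, arm, covariates)
    if len(matched_ids):
        sub = df.loc[matched_ids]
        smd_after = _smd(sub, arm.loc[matched_ids], covariates)
    else:
        smd_after = pd.Series(np.nan, index=smd_before.index)
    return MatchResult(matches, prop, smd_before, smd_after, fallback)


# ---------------------------------------------------------------------------
# Group comparison (Table-1 machinery)
# ---------------------------------------------------------------------------

def compare_groups(
    dyn_a: pd.DataFrame,
    dyn_b: pd.DataFrame,
    variables: list[str] | None = None,
    categorical: dict[str, tuple[pd.Series, pd.Series]] | None = None,
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-arm comparison.

    Continuous variables: Shapiro-Wilk normality on both arms at
    ``alpha_normality``; Welch t-test if both arms pass, Wilcoxon rank-sum
    (normal approximation, no tie correction) otherwise. Categorical
    variables (passed as label Series per arm): chi-square without Yates
    correction. Flags mirror the significance marks: '*' for p < 0.05,
    '^' for p < 0.1.
    """
    if variables is None:
        variables = [v for v in dyn_a.columns if v in dyn_b.columns]
    rows = []
    for v in variables:
        a = dyn_a[v].dropna().to_numpy(dtype=float)
        b = dyn_b[v].dropna().to_numpy(dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"variable {v}: need >=3 patients per arm")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            rows.append(
                dict(variable=v, test="skipped", statistic=np.nan, p=np.nan,
                     direction="=", flag="", note="zero variance in both arms",
                     mean_a=a.mean(), mean_b=b.mean())
            )
            continue
        normal_a = np.ptp(a) > 0 and stats.shapiro(a).pvalue > alpha_normality
        normal_b = np.ptp(b) > 0 and stats.shapiro(b).pvalue > alpha_normality
        if normal_a and normal_b:
            res = stats.ttest_ind(a, b, equal_var=False)
            test = "welch_t"
        else:
            res = stats.ranksums(a, b)
            test = "wilcoxon_ranksum"
        diff = np.median(a) - np.median(b) if test == "wilcoxon_ranksum" else a.mean() - b.mean()
        direction = "A>B" if diff > 0 else ("A<B" if diff < 0 else "=")
        p = float(res.pvalue)
        flag = "*" if p < 0.05 else ("^" if p < 0.1 else "")
        rows.append(
            dict(variable=v, test=test, statistic=float(res.statistic), p=p,
                 direction=direction, flag=flag, note="",
                 mean_a=a.mean(), mean_b=b.mean())
        )
    if categorical:
        for v, (sa, sb) in categorical.items():
            tab = pd.crosstab(
                pd.concat([pd.Series("A", index=sa.index), pd.Series("B", index=sb.index)]),
                pd.concat([sa, sb]),
            )
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
            flag = "*" if p < 0.05 else ("^" if p < 0.1 else "")
            rows.append(
                dict(variable=v, test="chi2", statistic=float(chi2), p=float(p),
                     direction="", flag=flag, note="", mean_a=np.nan, mean_b=np.nan)
            )
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# Clinical table I/O
# ---------------------------------------------------------------------------

CBC_TIME_TAGS = ("pre", "week1", "week2", "week3", "week4", "week5", "week6")


def write_clinical_csv(recs: list[ClinicalRecord], path) -> None:
    rows = []
    for r in recs:
        row = {
            "patient_id": r.patient_id,
            "age": r.age,
            "pathology": r.pathology,
            "stage": r.stage,
            "rt_field": r.rt_field,
            "progression_time": r.progression_time,
            "death_time": r.death_time,
            "follow_up": r.follow_up,
            "death_cause": r.death_cause,
        }
        for tag in r.cbc.index:
            for c in CELL_TYPES:
                row[f"{c}_{tag}"] = r.cbc.loc[tag, c]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clinical_csv(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    recs = []
    tags = sorted(
        {col.split("_", 1)[1] for col in df.columns if col.startswith("ANC_")},
        key=lambda t: CBC_TIME_TAGS.index(t) if t in CBC_TIME_TAGS else 99,
    )
    for _, row in df.iterrows():
        cbc = pd.DataFrame(
            {c: [row[f"{c}_{t}"] for t in tags] for c in CELL_TYPES},
            index=pd.Index(tags, name="time_tag"),
        ).dropna(how="all")
        recs.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                pathology=str(row["pathology"]),
                stage=str(row["stage"]),
                rt_field=str(row["rt_field"]),
                cbc=cbc.dropna(),
                progression_time=None if pd.isna(row["progression_time"]) else float(row["progression_time"]),
                death_time=None if pd.isna(row["death_time"]) else float(row["death_time"]),
                follow_up=float(row["follow_up"]),
                death_cause=str(row["death_cause"]),
            )
        )
    return recs
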