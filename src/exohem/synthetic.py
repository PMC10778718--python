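"""Synthetic cohorts with known ground truth.

The generator emulates the data layout of a chemoradiotherapy biomarker
study: each patient contributes a pre-treatment and a week-2 on-treatment
plasma RNA sample (negative-binomial read counts with lognormal per-sample
size factors) plus serial weekly CBC panels, outcome-group labels and
survival times. A per-patient standard-normal latent severity ``u`` ties
everything together:

* a randomly chosen ``ed_fraction`` of patients form the early-death group
  and carry a latent shift of ``ed_latent_shift`` standard deviations —
  early death is modelled as a distinct fragile subgroup, not the tail of a
  continuum; ``u`` is standardized before use;
* each planted driver RNA shifts its post/pre log2 ratio by
  ``driver_effect * sign * u`` (sign +1 for the ED-positive role, -1 for the
  ED-negative roles);
* selected CBC features load on ``u`` with weight ``cbc_coupling``
  (baselines positively for ANC/PLT/Mo, negatively for Hb/ALC, and the
  week-2 log-ratios with the opposite sign, which plants the cohort-level
  negative baseline-recovery correlation the homeostasis screen targets).

Defaults describe a mid-size single-institution cohort (40 patients, ~2000
RNAs across eight biotypes) with biomarker-grade planted drivers; see
docs/methods.md for the reasoning behind each default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cbc import CELL_TYPES, ClinicalRecord
from .expression import BIOTYPES, PairedCounts


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


DEFAULT_RNA_COUNTS = {
    "miRNA": 150,
    "piRNA": 100,
    "snoRNA": 150,
    "snRNA": 200,
    "tRNA": 200,
    "yRNA": 100,
    "lncRNA": 300,
    "mRNA": 800,
}

#: (biotype, ED-correlation sign) of planted drivers, cycled when
#: n_driver_rnas > 3. The canonical triple mirrors the roles the pipeline
#: must recover: an ED-positive miRNA, an ED-negative lncRNA and an
#: ED-negative mRNA covering all five cell types.
DRIVER_ROLES = [("miRNA", +1), ("lncRNA", -1), ("mRNA", -1)]


@dataclass
class SimulationConfig:
    n_patients: int = 40
    n_rna_per_biotype: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_RNA_COUNTS))
    n_driver_rnas: int = 3
    driver_effect: float = 1.5
    cbc_coupling: float = 0.7
    dispersion: float = 0.15
    baseline_mean_counts: float = 200.0
    ed_fraction: float = 0.2
    progression_fraction: float = 0.3
    ed_latent_shift: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ConfigurationError("n_patients must be >= 4")
        bad = set(self.n_rna_per_biotype) - set(BIOTYPES)
        if bad:
            raise ConfigurationError(f"n_rna_per_biotype has unknown biotypes: {sorted(bad)}")
        total = sum(self.n_rna_per_biotype.values())
        if total <= 0:
            raise ConfigurationError("n_rna_per_biotype must sum to > 0")
        if self.n_driver_rnas < 0 or self.n_driver_rnas > total:
            raise ConfigurationError("n_driver_rnas must be between 0 and the total RNA count")
        if not 0 < self.ed_fraction < 1:
            raise ConfigurationError("ed_fraction must lie in (0, 1)")
        if not 0 <= self.progression_fraction < 1:
            raise ConfigurationError("progression_fraction must lie in [0, 1)")
        if self.ed_fraction + self.progression_fraction >= 1:
            raise ConfigurationError("ed_fraction + progression_fraction must be < 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.baseline_mean_counts <= 0:
            raise ConfigurationError("baseline_mean_counts must be > 0")
        if not 0 <= self.cbc_coupling <= 1:
            raise ConfigurationError("cbc_coupling must lie in [0, 1]")


@dataclass
class GroundTruth:
    driver_rna_ids: list[str]
    driver_signs: dict[str, int]
    latent_ed_score: pd.Series
    true_group: pd.Series  # {'ED', 'progression', 'non-progression'}


# CBC baseline geometry: lognormal medians and log-sd per cell type, in the
# units of cbc.CBC_UNITS; signs of the latent loading on the baseline.
_CBC_MEDIAN = {"ANC": 4000.0, "PLT": 250.0, "Hb": 12.8, "ALC": 1900.0, "Mo": 450.0}
_CBC_SDLOG0 = {"ANC": 0.25, "PLT": 0.20, "Hb": 0.08, "ALC": 0.25, "Mo": 0.25}
_CBC_SIGN0 = {"ANC": +1, "PLT": +1, "Hb": -1, "ALC": -1, "Mo": +1}
# maximal on-treatment log-decline (myelosuppression) and weekly noise
_CBC_DECLINE = {"ANC": 0.50, "PLT": 0.35, "Hb": 0.10, "ALC": 0.90, "Mo": 0.40}
_CBC_SDLOG3 = {"ANC": 0.25, "PLT": 0.20, "Hb": 0.08, "ALC": 0.25, "Mo": 0.25}
_WEEK_NOISE = 0.12
_WEEKS = ("week1", "week2", "week3", "week4", "week5", "week6")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; Poisson in the
    dispersion -> 0 limit (var = mu + dispersion * mu^2)."""
    if dispersion < 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def _rna_catalog(config: SimulationConfig) -> tuple[list[str], pd.Series, list[str], dict[str, int]]:
    """RNA ids, biotypes and planted-driver assignment."""
    ids: list[str] = []
    biotypes: list[str] = []
    for bt in BIOTYPES:
        n_bt = config.n_rna_per_biotype.get(bt, 0)
        for i in range(n_bt):
            ids.append(f"{bt}_{i:04d}")
            biotypes.append(bt)
    biotype = pd.Series(biotypes, index=pd.Index(ids, name="rna_id"))
    drivers: list[str] = []
    signs: dict[str, int] = {}
    per_bt_next: dict[str, int] = {bt: 0 for bt in BIOTYPES}
    for d in range(config.n_driver_rnas):
        bt, sign = DRIVER_ROLES[d % len(DRIVER_ROLES)]
        if config.n_rna_per_biotype.get(bt, 0) == 0:
            # fall back to the most abundant biotype available
            bt = max(config.n_rna_per_biotype, key=config.n_rna_per_biotype.get)
        idx = per_bt_next[bt]
        if idx >= config.n_rna_per_biotype.get(bt, 0):
            raise ConfigurationError(
                f"n_driver_rnas exceeds available RNAs of biotype {bt!r}"
            )
        per_bt_next[bt] += 1
        rid = f"{bt}_{idx:04d}"
        drivers.append(rid)
        signs[rid] = sign
    return ids, biotype, drivers, signs


def _simulate_counts(
    rng: np.random.Generator,
    config: SimulationConfig,
    u: np.ndarray,
    drivers: list[str],
    signs: dict[str, int],
) -> PairedCounts:
    ids, biotype, _, _ = _rna_catalog(config)
    n_rna, n_pat = len(ids), config.n_patients
    # lognormal abundance spectrum; drivers get biomarker-grade abundance so
    # their fold changes are count-noise limited, not detection limited
    log_q = rng.normal(math.log(config.baseline_mean_counts) - 1.0, 1.5, size=n_rna)
    q = np.exp(log_q)
    driver_pos = {rid: ids.index(rid) for rid in drivers}
    for rid, j in driver_pos.items():
        q[j] = config.baseline_mean_counts * math.exp(float(rng.normal(1.0, 0.2)))
    size_pre = np.exp(rng.normal(0.0, 0.3, size=n_pat))
    size_post = np.exp(rng.normal(0.0, 0.3, size=n_pat))
    delta = np.zeros((n_rna, n_pat))
    for rid, j in driver_pos.items():
        delta[j] = config.driver_effect * signs[rid] * u
    mu_pre = q[:, None] * size_pre[None, :]
    mu_post = q[:, None] * size_post[None, :] * np.exp2(delta)
    pre = _nb_draw(rng, mu_pre, config.dispersion)
    post = _nb_draw(rng, mu_post, config.dispersion)
    pids = [f"P{i + 1:03d}" for i in range(n_pat)]
    cols: dict[str, np.ndarray] = {}
    pairs: dict[str, tuple[str, str]] = {}
    for i, pid in enumerate(pids):
        cols[f"{pid}_pre"] = pre[:, i]
        cols[f"{pid}_post"] = post[:, i]
        pairs[pid] = (f"{pid}_pre", f"{pid}_post")
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="rna_id"), dtype=np.int64)
    return PairedCounts(counts, biotype, pairs)


def _simulate_clinical(
    rng: np.random.Generator,
    config: SimulationConfig,
    u: np.ndarray,
    ed_idx: set[int],
) -> tuple[list[ClinicalRecord], pd.Series]:
    n = config.n_patients
    pids = [f"P{i + 1:03d}" for i in range(n)]
    rest = [i for i in range(n) if i not in ed_idx]
    n_prog = round(config.progression_fraction * n)
    prog_idx = set(rng.choice(rest, size=min(n_prog, len(rest)), replace=False).tolist())
    kappa = config.cbc_coupling
    recs: list[ClinicalRecord] = []
    groups = {}
    for i, pid in enumerate(pids):
        # CBC panels; baselines load on the latent with weight kappa
        c0 = {}
        for c in CELL_TYPES:
            eps0 = rng.normal()
            z0 = _CBC_SIGN0[c] * kappa * u[i] + math.sqrt(1 - kappa**2) * eps0
            c0[c] = _CBC_MEDIAN[c] * math.exp(_CBC_SDLOG0[c] * z0)
        rows = {"pre": {c: c0[c] for c in CELL_TYPES}}
        for w, tag in enumerate(_WEEKS, start=1):
            rows[tag] = {}
            profile = min(w / 4.0, 1.0)
            for c in CELL_TYPES:
                if tag == "week2":
                    eps3 = rng.normal()
                    z3 = -_CBC_SIGN0[c] * kappa * u[i] + math.sqrt(1 - kappa**2) * eps3
                    logratio = -_CBC_DECLINE[c] * profile + _CBC_SDLOG3[c] * z3
                else:
                    logratio = -_CBC_DECLINE[c] * profile + _WEEK_NOISE * rng.normal()
                rows[tag][c] = c0[c] * math.exp(logratio)
        cbc = pd.DataFrame(rows).T[list(CELL_TYPES)]
        cbc.index.name = "time_tag"
        # outcomes
        if i in ed_idx:
            prog = float(rng.uniform(2.0, 12.0))
            death = float(min(prog + rng.uniform(1.0, 3.0), 15.0))
            rec = ClinicalRecord(
                pid, 0.0, "", "", "", cbc, progression_time=prog, death_time=death,
                follow_up=death, death_cause="disease",
            )
            groups[pid] = "ED"
        elif i in prog_idx:
            prog = float(rng.uniform(3.0, 30.0))
            if rng.uniform() < 0.4:
                death = float(rng.uniform(31.0, 60.0))
                rec = ClinicalRecord(
                    pid, 0.0, "", "", "", cbc, progression_time=prog, death_time=death,
                    follow_up=death, death_cause="disease",
                )
            else:
                fu = float(rng.uniform(36.0, 84.0))
                rec = ClinicalRecord(
                    pid, 0.0, "", "", "", cbc, progression_time=prog, death_time=None,
                    follow_up=fu, death_cause="alive",
                )
            groups[pid] = "progression"
        else:
            fu = float(rng.uniform(61.0, 96.0))
            rec = ClinicalRecord(
                pid, 0.0, "", "", "", cbc, progression_time=None, death_time=None,
                follow_up=fu, death_cause="alive",
            )
            groups[pid] = "non-progression"
        rec.age = float(np.clip(rng.normal(55.0, 10.0), 25.0, 85.0))
        rec.pathology = str(rng.choice(["SCC", "adenocarcinoma"], p=[0.8, 0.2]))
        rec.stage = str(rng.choice(["I", "II", "III", "IV"], p=[0.1, 0.45, 0.35, 0.1]))
        rec.rt_field = str(rng.choice(["pelvis", "extended"], p=[0.85, 0.15]))
        recs.append(rec)
    return recs, pd.Series(groups, name="true_group")


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[ClinicalRecord], PairedCounts, GroundTruth]:
    """Generate a complete synthetic cohort (clinical records, paired
    counts, ground truth). Identical configs (same seed) give bit-identical
    output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_ed = max(1, round(config.ed_fraction * n))
    ed_idx = set(rng.choice(n, size=n_ed, replace=False).tolist())
    z = rng.normal(size=n)
    u_raw = z + config.ed_latent_shift * np.isin(np.arange(n), list(ed_idx))
    u = (u_raw - u_raw.mean()) / u_raw.std()
    _, _, drivers, signs = _rna_catalog(config)
    recs, groups = _simulate_clinical(rng, config, u, ed_idx)
    counts = _simulate_counts(rng, config, u, drivers, signs)
    pids = [r.patient_id for r in recs]
    truth = GroundTruth(
        driver_rna_ids=drivers,
        driver_signs=signs,
        latent_ed_score=pd.Series(u, index=pids, name="latent_ed_score"),
        true_group=groups,
    )
    return recs, counts, truth


def simulate_null_counts(config: SimulationConfig) -> PairedCounts:
    """Paired counts with no planted drivers (marginal negative binomial
    with the configured mean and dispersion); for type-I-error suites."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    u = np.zeros(config.n_patients)
    return _simulate_counts(rng, config, u, drivers=[], signs={})


def write_cohort(recs, counts: PairedCounts, out_dir) -> None:
    """Write counts as TSV and the clinical table as CSV into ``out_dir``."""
    import os

    from .cbc import write_clinical_csv

    os.makedirs(out_dir, exist_ok=True)
    counts.to_tsv(os.path.join(out_dir, "counts.tsv"))
    write_clinical_csv(recs, os.path.join(out_dir, "clinical.csv"))
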