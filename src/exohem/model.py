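"""End-to-end biomarker-discovery model.

:class:`EDBiomarkerModel` wraps the full pipeline behind a statsmodels-style
surface: construct it from clinical records plus paired counts (or from the
TSV/CSV files), call :meth:`fit`, and read everything off the returned
:class:`EDBiomarkerResults` — log2FC table, association matrix, link flags,
homeostasis screen, networks at both edge thresholds, subset-search results,
the key-RNA set with the final signed triple, the composite scores and the
survival report. ``summary()`` renders a compact text report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import cbc as cbc_mod
from . import expression as expr_mod
from . import network as net_mod
from . import selection as sel_mod
from . import survival as surv_mod
from .expression import NC_BIOTYPES


def _budgeted_max_k(n: int, p: int, max_k: int | None, budget: int = 4_000_000) -> int:
    """Subset-search depth: min(10, n // 4, p), reduced when the full
    enumeration of all subsets up to that size would exceed ``budget``
    models (enumeration stays exact per size; only the depth shrinks)."""
    import math

    k = max_k if max_k is not None else min(10, n // 4, p)
    k = max(1, min(k, p))
    while k > 1 and sum(math.comb(p, j) for j in range(1, k + 1)) > budget:
        k -= 1
    return k


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters (defaults follow the study design)."""

    alpha: float = 0.05
    min_detect_frac: float = 0.5
    min_links: int = 3
    ed_r_threshold: float = 0.5
    edge_thresholds: tuple[float, ...] = (0.5, 0.6)
    nc_inclusion_thresh: float = 0.5
    m_inclusion_thresh: float = 0.6
    max_k: int | None = None  # default min(10, n // 4, p)
    log_base: float | None = None  # natural log for CBC3
    horizon: float = 30.0
    pseudocount: float | None = None


@dataclass
class EDBiomarkerResults:
    """Fitted pipeline state; see module docstring for the attribute map."""

    config: PipelineConfig
    groups: pd.DataFrame
    dynamics: pd.DataFrame
    log2fc: expr_mod.Log2FCTable
    association: assoc_mod.AssociationMatrix
    admission_flags: pd.DataFrame
    annotation_flags: pd.DataFrame
    screen: pd.DataFrame
    admitted: pd.DataFrame
    networks: dict[float, net_mod.RNANetwork]
    subset_results: dict[float, sel_mod.SubsetSearchResult | None]
    key_set: sel_mod.KeyRNASet
    scores: surv_mod.CompositeScore | None
    survival: surv_mod.SurvivalReport | None

    @property
    def triple(self) -> list[tuple[str, int]]:
        return self.key_set.triple

    def summary(self) -> str:
        lines = []
        n_pat = len(self.dynamics)
        n_ed = int(self.groups["ED"].sum())
        lines.append("Early-death biomarker pipeline")
        lines.append("=" * 46)
        lines.append(f"patients: {n_pat} (ED {n_ed}, EP {int(self.groups['EP'].sum())})")
        lines.append(f"RNAs after detection filter: {self.log2fc.lfc.shape[1]}")
        lines.append(f"admitted to network pool: {len(self.admitted)}")
        for thr, net in self.networks.items():
            lines.append(f"network |R| > {thr}: {net.n_nodes} nodes, {net.n_edges} edges")
        lines.append(f"key ncRNAs: {', '.join(self.key_set.key_ncrnas) or '-'}")
        lines.append(f"key mRNAs: {', '.join(self.key_set.key_mrnas) or '-'}")
        lines.append(f"all-five-CBC RNAs: {', '.join(self.key_set.all_cbc_rnas) or '-'}")
        trip = ", ".join(f"{'+' if s > 0 else '-'}{r}" for r, s in self.key_set.triple)
        lines.append(f"composite triple: {trip or '-'}")
        if self.survival is not None:
            sr = self.survival
            for grp in sorted(sr.s_at_horizon):
                lines.append(
                    f"  score {grp}: {sr.horizon:.0f}-month DSS = "
                    f"{100 * sr.s_at_horizon[grp]:.1f}%"
                )
            if sr.logrank_p is not None:
                lines.append(f"  log-rank p = {sr.logrank_p:.3g}")
            if sr.wilcoxon_p is not None:
                lines.append(f"  score ED vs non-ED Wilcoxon p = {sr.wilcoxon_p:.3g}")
            lines.append(f"  median follow-up (reverse KM) = {sr.median_followup:.1f} months")
        return "\n".join(lines)


class EDBiomarkerModel:
    """Full discovery pipeline from a clinical cohort and paired RNA counts.

    Parameters
    ----------
    clinical : list of ClinicalRecord
    counts : PairedCounts
    config : PipelineConfig, optional
    """

    def __init__(self, clinical, counts, config: PipelineConfig | None = None):
        self.clinical = list(clinical)
        self.counts = counts
        self.config = config or PipelineConfig()
        have = set(counts.patient_ids)
        self.clinical = [r for r in self.clinical if r.patient_id in have]
        if len(self.clinical) < 4:
            raise ValueError("need at least 4 patients with both clinical and count data")

    @classmethod
    def from_files(cls, clinical_csv, counts_tsv, config: PipelineConfig | None = None):
        recs = cbc_mod.read_clinical_csv(clinical_csv)
        counts = expr_mod.PairedCounts.from_tsv(counts_tsv)
        return cls(recs, counts, config)

    # ------------------------------------------------------------------
    def fit(self) -> EDBiomarkerResults:
        cfg = self.config
        dyn = cbc_mod.dynamics_frame(self.clinical, log_base=cfg.log_base)
        groups = cbc_mod.assign_groups(self.clinical)
        outcomes = groups[["ED", "EP"]].astype(float)

        filtered = expr_mod.detection_filter(self.counts, cfg.min_detect_frac)
        factors = expr_mod.tmm_factors(filtered)
        lfc = expr_mod.paired_log2fc(filtered, factors, pseudocount=cfg.pseudocount)

        assoc = assoc_mod.correlate_all(lfc, dyn, outcomes)
        adm_flags = assoc_mod.cbc_link_flags(assoc, cfg.alpha, "network_admission")
        ann_flags = assoc_mod.cbc_link_flags(assoc, cfg.alpha, "network_annotation")
        screen = assoc_mod.homeostasis_screen(assoc, dyn, cfg.alpha)

        admitted = net_mod.admit_rnas(
            assoc, adm_flags, cfg.alpha, cfg.min_links, cfg.ed_r_threshold
        )
        networks: dict[float, net_mod.RNANetwork] = {}
        subset_results: dict[float, sel_mod.SubsetSearchResult | None] = {}
        y = outcomes["ED"].reindex(lfc.lfc.index).to_numpy()
        import warnings

        for thr in cfg.edge_thresholds:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = net_mod.build_graph(lfc, admitted, thr, annotations=ann_flags)
            networks[thr] = net
            if net.n_nodes >= 1:
                X = lfc.lfc[net.nodes]
                max_k = _budgeted_max_k(len(y), net.n_nodes, cfg.max_k)
                subset_results[thr] = sel_mod.exhaustive_subsets(
                    X, y, max_k=max_k, outcome_name="ED"
                )
            else:
                subset_results[thr] = None

        usable = [r for r in subset_results.values() if r is not None]
        key_nc, key_m = sel_mod.select_key_rnas(
            usable, lfc.biotype, cfg.nc_inclusion_thresh, cfg.m_inclusion_thresh
        )
        wide_nodes = networks[min(cfg.edge_thresholds)].nodes if networks else []
        all_cbc = sel_mod.all_cbc_coverage(ann_flags, wide_nodes)
        triple = self._assemble_triple(key_nc, all_cbc, adm_flags, lfc.biotype)
        key_set = sel_mod.KeyRNASet(key_nc, key_m, all_cbc, triple)

        scores = survival = None
        if triple:
            scores = surv_mod.composite_score(lfc, triple)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                survival = surv_mod.km_logrank(
                    scores, self.clinical, horizon=cfg.horizon, ed=groups["ED"]
                )
        return EDBiomarkerResults(
            config=cfg,
            groups=groups,
            dynamics=dyn,
            log2fc=lfc,
            association=assoc,
            admission_flags=adm_flags,
            annotation_flags=ann_flags,
            screen=screen,
            admitted=admitted,
            networks=networks,
            subset_results=subset_results,
            key_set=key_set,
            scores=scores,
            survival=survival,
        )

    @staticmethod
    def _assemble_triple(
        key_ncrnas: list[str],
        all_cbc_rnas: list[str],
        flags: pd.DataFrame,
        biotypes: pd.Series,
    ) -> list[tuple[str, int]]:
        """Final signed triple: the strongest ED-positive key ncRNA (+), the
        strongest ED-negative key ncRNA (-), and the all-five-CBC mRNA with
        the strongest ED correlation (entering with its own ED sign). Slots
        without a qualifying RNA stay empty."""
        triple: list[tuple[str, int]] = []
        nc = [r for r in key_ncrnas if r in flags.index]
        pos = [r for r in nc if flags.loc[r, "ed_sign"] > 0]
        neg = [r for r in nc if flags.loc[r, "ed_sign"] < 0]
        if pos:
            best = max(pos, key=lambda r: (abs(flags.loc[r, "r_ed"]), r))
            triple.append((best, 1))
        if neg:
            best = max(neg, key=lambda r: (abs(flags.loc[r, "r_ed"]), r))
            triple.append((best, -1))
        mr = [
            r for r in all_cbc_rnas
            if biotypes.get(r) == "mRNA" and r in flags.index and flags.loc[r, "ed_sign"] != 0
        ]
        if mr:
            best = max(mr, key=lambda r: (abs(flags.loc[r, "r_ed"]), r))
            triple.append((best, int(flags.loc[best, "ed_sign"])))
        return triple
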