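"""Correlation matrices, link-flag semantics and the homeostasis screen."""

import numpy as np
import pandas as pd
import pytest

from exohem.association import (
    AssociationMatrix,
    cbc_link_flags,
    correlate_all,
    homeostasis_screen,
)
from exohem.cbc import feature_names
from exohem.expression import Log2FCTable

from conftest import correlated_columns


def make_lfc(df: pd.DataFrame, biotypes=None) -> Log2FCTable:
    fac = pd.Series(1.0, index=pd.RangeIndex(2 * len(df)))
    bt = pd.Series(
        biotypes if biotypes is not None else "mRNA", index=df.columns, name="biotype"
    )
    return Log2FCTable(df, fac, fac.copy(), bt)


def make_assoc(r: pd.DataFrame, p: pd.DataFrame, biotypes=None) -> AssociationMatrix:
    n = pd.DataFrame(40, index=r.index, columns=r.columns)
    bt = pd.Series(biotypes if biotypes is not None else "mRNA", index=r.index)
    return AssociationMatrix(r, p, n, bt)


def blank_frames(rnas, extra_vars=("ED", "EP")):
    cols = feature_names() + list(extra_vars)
    r = pd.DataFrame(0.0, index=pd.Index(rnas, name="rna_id"), columns=cols)
    p = pd.DataFrame(1.0, index=r.index, columns=cols)
    return r, p


class TestCorrelateAll:
    def _run(self, lfc_df, dyn, outcomes=None):
        if outcomes is None:
            n = len(lfc_df)
            outcomes = pd.DataFrame(
                {"ED": [1] * (n // 4) + [0] * (n - n // 4), "EP": [0] * n},
                index=lfc_df.index,
            )
        return correlate_all(make_lfc(lfc_df), dyn, outcomes)

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        dyn = pd.DataFrame({"ANC3": base}, index=range(20))
        lfc = pd.DataFrame({"rna_a": 2 * base, "rna_b": -base}, index=range(20))
        assoc = self._run(lfc, dyn)
        assert assoc.r.loc["rna_a", "ANC3"] == pytest.approx(1.0)
        assert assoc.p.loc["rna_a", "ANC3"] < 1e-12
        assert assoc.r.loc["rna_b", "ANC3"] == pytest.approx(-1.0)

    def test_independent_columns_band(self):
        """Null |R| at n=40 stays below 0.45 for ~99.7% of RNAs."""
        rng = np.random.default_rng(1)
        dyn = pd.DataFrame({"Hb0": rng.normal(size=40)}, index=range(40))
        lfc = pd.DataFrame(
            rng.normal(size=(40, 2000)), index=range(40),
            columns=[f"r{i}" for i in range(2000)],
        )
        assoc = self._run(lfc, dyn)
        assert (assoc.r["Hb0"].abs() >= 0.45).mean() < 0.01

    def test_constant_column_recorded_missing(self):
        rng = np.random.default_rng(2)
        dyn = pd.DataFrame({"Hb0": np.ones(12)}, index=range(12))
        lfc = pd.DataFrame({"rna_a": rng.normal(size=12)}, index=range(12))
        assoc = self._run(lfc, dyn)
        assert np.isnan(assoc.r.loc["rna_a", "Hb0"])
        assert np.isnan(assoc.p.loc["rna_a", "Hb0"])

    def test_too_few_patients(self):
        dyn = pd.DataFrame({"Hb0": [1.0, 2, 3]}, index=range(3))
        lfc = pd.DataFrame({"r0": [1.0, 2, 1]}, index=range(3))
        with pytest.raises(ValueError, match="n >= 4"):
            self._run(lfc, dyn, outcomes=pd.DataFrame({"ED": [0, 0, 1], "EP": [0, 0, 0]}))

    def test_sign_equivariance(self):
        """Negating an RNA's log2FC column negates its R row, preserves p."""
        rng = np.random.default_rng(3)
        dyn = pd.DataFrame(
            {"ANC0": rng.normal(size=30), "Hb3": rng.normal(size=30)}, index=range(30)
        )
        col = rng.normal(size=30)
        a1 = self._run(pd.DataFrame({"r0": col}, index=range(30)), dyn)
        a2 = self._run(pd.DataFrame({"r0": -col}, index=range(30)), dyn)
        for v in ("ANC0", "Hb3"):
            assert a2.r.loc["r0", v] == pytest.approx(-a1.r.loc["r0", v])
            assert a2.p.loc["r0", v] == pytest.approx(a1.p.loc["r0", v])


class TestLinkFlags:
    def test_single_variable_links_single_cell_type(self):
        r, p = blank_frames(["rna_a"])
        p.loc["rna_a", "Hb0"] = 0.01
        flags = cbc_link_flags(make_assoc(r, p), variant="network_annotation")
        assert bool(flags.loc["rna_a", "linked_Hb"])
        for c in ("ANC", "PLT", "ALC", "Mo"):
            assert not flags.loc["rna_a", f"linked_{c}"]

    def test_admission_variant_excludes_week2(self):
        """ANC2 significance does not create an ANC link under the admission
        variant (which looks only at ANC0, min ANC and ANC1)."""
        r, p = blank_frames(["rna_a"])
        p.loc["rna_a", "ANC2"] = 0.001
        adm = cbc_link_flags(make_assoc(r, p), variant="network_admission")
        ann = cbc_link_flags(make_assoc(r, p), variant="network_annotation")
        assert not adm.loc["rna_a", "linked_ANC"]
        assert bool(ann.loc["rna_a", "linked_ANC"])

    def test_five_cell_type_count(self):
        r, p = blank_frames(["rna_a"])
        for v in ("ANC1", "PLT2", "Hb3", "ALC0", "Mo3"):
            p.loc["rna_a", v] = 0.02
        flags = cbc_link_flags(make_assoc(r, p), variant="network_annotation")
        assert flags.loc["rna_a", "n_cell_types"] == 5

    def test_ratio_links(self):
        r, p = blank_frames(["rna_a"])
        p.loc["rna_a", "NLR1"] = 0.04
        flags = cbc_link_flags(make_assoc(r, p), variant="network_admission")
        assert bool(flags.loc["rna_a", "linked_NLR"])
        assert flags.loc["rna_a", "n_hematologic"] == 1


class TestHomeostasisScreen:
    def _dyn_negative_anc(self, rng, n=60):
        """Cohort where corr(ANC1, ANC3) < 0 by construction."""
        dyn = pd.DataFrame(
            np.nan, index=range(n), columns=feature_names(), dtype=float
        )
        cc = correlated_columns(rng, n, [-0.6])
        dyn["ANC1"] = cc["c0"].values
        dyn["ANC3"] = cc["c1"].values
        for v in dyn.columns:
            if dyn[v].isna().all():
                dyn[v] = rng.normal(size=n)
        return dyn

    def test_opposed_signs_flagged_red_solid(self):
        """An RNA rising with ANC1 and falling with ANC3, ED-positive, lands
        in the red/solid class (the miR-574-3p-like quadrant)."""
        rng = np.random.default_rng(4)
        n = 60
        dyn = self._dyn_negative_anc(rng, n)
        rna = 0.8 * dyn["ANC1"].values - 0.5 * dyn["ANC3"].values + 0.1 * rng.normal(size=n)
        ed = (rna + 0.3 * rng.normal(size=n)) > np.quantile(rna, 0.75)
        lfc = make_lfc(pd.DataFrame({"rna_a": rna}, index=dyn.index))
        assoc = correlate_all(
            lfc, dyn, pd.DataFrame({"ED": ed.astype(float), "EP": ed.astype(float)})
        )
        screen = homeostasis_screen(assoc, dyn)
        hit = screen[(screen.rna == "rna_a") & (screen.cell_type == "ANC")]
        assert len(hit) == 1
        assert hit.iloc[0]["color"] == "red"
        assert hit.iloc[0]["style"] == "solid"
        assert np.sign(hit.iloc[0]["r_baseline"]) != np.sign(hit.iloc[0]["r_c3"])

    def test_same_sign_not_flagged(self):
        rng = np.random.default_rng(5)
        n = 60
        dyn = self._dyn_negative_anc(rng, n)
        # significant vs both Hb0 and Hb3 with the same sign
        hb = correlated_columns(rng, n, [0.5])
        dyn["Hb0"], dyn["Hb3"] = hb["c0"].values, hb["c1"].values
        rna = dyn["Hb0"].values + dyn["Hb3"].values + 0.2 * rng.normal(size=n)
        lfc = make_lfc(pd.DataFrame({"rna_a": rna}, index=dyn.index))
        assoc = correlate_all(
            lfc, dyn, pd.DataFrame({"ED": np.r_[np.ones(15), np.zeros(45)], "EP": np.zeros(n)})
        )
        screen = homeostasis_screen(assoc, dyn)
        assert screen[(screen.rna == "rna_a") & (screen.cell_type == "Hb")].empty

    def test_planted_opposed_rnas_recovered_exactly(self):
        """Strong planted opposed-sign RNAs are flagged; independent noise
        RNAs are not."""
        rng = np.random.default_rng(6)
        n = 80
        dyn = self._dyn_negative_anc(rng, n)
        planted = {
            f"driver{i}": dyn["ANC1"].values - dyn["ANC3"].values + 0.05 * rng.normal(size=n)
            for i in range(3)
        }
        noise = {f"noise{i}": rng.normal(size=n) for i in range(30)}
        lfc = make_lfc(pd.DataFrame({**planted, **noise}, index=dyn.index))
        assoc = correlate_all(
            lfc, dyn, pd.DataFrame({"ED": np.r_[np.ones(20), np.zeros(60)], "EP": np.zeros(n)})
        )
        screen = homeostasis_screen(assoc, dyn)
        anc = set(screen[screen.cell_type == "ANC"].rna)
        assert anc == set(planted)

    def test_flag_implies_annotation_link(self, fitted):
        """Every screened (rna, cell type) is also linked under the
        annotation variant — the screen is a subset of the link flags."""
        res, _ = fitted
        screen = res.screen
        for _, row in screen.iterrows():
            assert bool(res.annotation_flags.loc[row["rna"], f"linked_{row['cell_type']}"])

    def test_summary_counts_partition(self, fitted):
        res, _ = fitted
        summary = res.screen.attrs["summary"]
        assert summary["n_flagged"].sum() == len(res.screen)
        assert (summary["n_ed"] <= summary["n_flagged"]).all()
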