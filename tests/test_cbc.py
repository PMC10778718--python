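"""CBC feature derivation, outcome grouping, matching and group tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exohem.cbc import (
    CELL_TYPES,
    ClinicalRecord,
    MissingPanelError,
    assign_groups,
    compare_groups,
    derive_dynamics,
    dynamics_frame,
    propensity_match,
    read_clinical_csv,
    write_clinical_csv,
)


def make_record(
    pid="P1",
    pre=None,
    week2=None,
    extra_weeks=None,
    prog=None,
    death=None,
    fu=80.0,
    cause="alive",
    **covs,
):
    pre = pre or dict(ANC=4000, PLT=250, Hb=13, ALC=1800, Mo=400)
    week2 = week2 or dict(ANC=2500, PLT=200, Hb=12, ALC=900, Mo=300)
    rows = {"pre": pre, "week2": week2}
    rows.update(extra_weeks or {})
    cbc = pd.DataFrame(rows).T[list(CELL_TYPES)]
    return ClinicalRecord(
        pid,
        covs.get("age", 55.0),
        covs.get("pathology", "SCC"),
        covs.get("stage", "II"),
        covs.get("rt_field", "pelvis"),
        cbc,
        progression_time=prog,
        death_time=death,
        follow_up=fu,
        death_cause=cause,
    )


class TestDeriveDynamics:
    def test_geometric_mean_and_log_ratio(self):
        rec = make_record(
            pre=dict(ANC=4000, PLT=250, Hb=13, ALC=1800, Mo=400),
            week2=dict(ANC=1000, PLT=200, Hb=13, ALC=900, Mo=300),
        )
        dyn = derive_dynamics(rec)
        assert dyn["ANC1"] == pytest.approx(2000.0)  # sqrt(4000 * 1000)
        assert dyn["Hb3"] == pytest.approx(0.0)  # week2 == pre
        assert dyn["ANC1"] ** 2 == pytest.approx(dyn["ANC0"] * dyn["min_ANC"])

    def test_log_base_configurable(self):
        rec = make_record(
            pre=dict(ANC=2000, PLT=250, Hb=13, ALC=1800, Mo=400),
            week2=dict(ANC=4000, PLT=250, Hb=13, ALC=1800, Mo=400),
            extra_weeks={"week3": dict(ANC=1800, PLT=240, Hb=12.5, ALC=1500, Mo=380)},
        )
        assert derive_dynamics(rec)["ANC3"] == pytest.approx(math.log(2), abs=1e-10)
        assert derive_dynamics(rec, log_base=10)["ANC3"] == pytest.approx(
            math.log10(2), abs=1e-10
        )

    def test_nadir_spans_all_on_treatment_panels(self):
        rec = make_record(
            week2=dict(ANC=2500, PLT=200, Hb=12, ALC=900, Mo=300),
            extra_weeks={"week4": dict(ANC=800, PLT=150, Hb=11, ALC=700, Mo=250)},
        )
        dyn = derive_dynamics(rec)
        assert dyn["min_ANC"] == 800
        assert dyn["min_ANC"] <= dyn["ANC2"] and dyn["min_ANC"] <= dyn["ANC0"]

    def test_ratios(self):
        dyn = derive_dynamics(make_record())
        assert dyn["NLR0"] == pytest.approx(dyn["ANC0"] / dyn["ALC0"])
        assert dyn["PLR1"] == pytest.approx(dyn["PLT1"] / dyn["ALC1"])
        assert dyn["LMR0"] == pytest.approx(dyn["ALC0"] / dyn["Mo0"])

    def test_missing_panel_errors_name_patient(self):
        rec = make_record(pid="P9")
        cbc = rec.cbc.drop(index="week2")
        rec2 = ClinicalRecord("P9", 55, "SCC", "II", "pelvis", cbc, follow_up=10)
        with pytest.raises(MissingPanelError, match="P9"):
            derive_dynamics(rec2)

    def test_nonpositive_cbc_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            make_record(pre=dict(ANC=0, PLT=250, Hb=13, ALC=1800, Mo=400))

    @given(k=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_consistency(self, k):
        """Scaling one cell type's whole series by k > 0 scales the level
        features by k and leaves the log-ratio feature unchanged."""
        base = make_record()
        scaled_cbc = base.cbc.copy()
        scaled_cbc["ANC"] = scaled_cbc["ANC"] * k
        scaled = ClinicalRecord("P1", 55, "SCC", "II", "pelvis", scaled_cbc, follow_up=80)
        d0, d1 = derive_dynamics(base), derive_dynamics(scaled)
        for f in ("ANC0", "min_ANC", "ANC1", "ANC2"):
            assert d1[f] == pytest.approx(k * d0[f], rel=1e-9)
        assert d1["ANC3"] == pytest.approx(d0["ANC3"], abs=1e-9)


class TestAssignGroups:
    def test_early_death(self):
        rec = make_record(prog=6, death=10, fu=10, cause="disease")
        assert assign_groups([rec]).loc["P1", "group"] == 1

    def test_non_progression(self):
        rec = make_record(prog=None, death=None, fu=72, cause="alive")
        assert assign_groups([rec]).loc["P1", "group"] == 3

    def test_late_progression_early_death_unassigned(self):
        rec = make_record(prog=20, death=25, fu=25, cause="disease")
        assert pd.isna(assign_groups([rec]).loc["P1", "group"])

    def test_progression_with_long_survival(self):
        rec = make_record(prog=8, death=None, fu=40, cause="alive")
        out = assign_groups([rec])
        assert out.loc["P1", "group"] == 2
        assert bool(out.loc["P1", "EP"])

    def test_inconsistent_times_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            make_record(prog=20, death=10, fu=20, cause="disease")


class TestPropensityMatch:
    def _cohort(self, ages_t, ages_c):
        recs, groups = [], {}
        for i, a in enumerate(ages_t):
            pid = f"T{i}"
            recs.append(make_record(pid=pid, age=a))
            groups[pid] = "treat"
        for i, a in enumerate(ages_c):
            pid = f"C{i}"
            recs.append(make_record(pid=pid, age=a))
            groups[pid] = "ctrl"
        return recs, pd.Series(groups)

    def test_exchangeable_arms_all_matched(self):
        rng = np.random.default_rng(0)
        ages = rng.normal(55, 8, size=24)
        recs, groups = self._cohort(ages[:12], ages[12:])
        res = propensity_match(recs, "treat", "ctrl", ["age"], groups=groups, ratio=1)
        assert len(res.matches) == 12
        assert res.matches["control"].is_unique  # without replacement
        assert (res.smd_after["age"] < 0.5) or np.isnan(res.smd_after["age"])

    def test_one_treated_two_nearest_controls(self):
        """1:2 matching picks the two controls nearest in propensity; with a
        single covariate the propensity is monotone in it, so brute-force
        nearest-in-age is the oracle."""
        recs, groups = self._cohort([50.0], [48.0, 60.0, 70.0])
        res = propensity_match(recs, "treat", "ctrl", ["age"], groups=groups, ratio=2)
        assert sorted(res.matches["control"]) == ["C0", "C1"]

    def test_separation_falls_back_to_exact_strata(self):
        recs, groups = self._cohort([40.0, 41.0, 42.0], [70.0, 71.0, 72.0])
        for r in recs:
            r.age = 55.0  # identical covariates -> exact strata exist
        # separating covariate: stage differs by arm
        for r, g in zip(recs, [1, 1, 1, 0, 0, 0]):
            r.stage = "III" if g else "II"
        with pytest.warns(UserWarning, match="separation"):
            res = propensity_match(recs, "treat", "ctrl", ["stage"], groups=groups)
        assert res.fallback_used

    def test_matching_without_replacement_bounded(self):
        recs, groups = self._cohort([50.0, 52.0], [51.0, 53.0, 55.0])
        res = propensity_match(recs, "treat", "ctrl", ["age"], groups=groups, ratio=1)
        assert len(res.matches) <= 2
        assert res.matches["control"].is_unique


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        a = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 100]})  # non-normal -> rank-sum
        rep = compare_groups(a, a.copy())
        assert rep.loc["x", "p"] == pytest.approx(1.0)

    def test_separated_samples(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame({"x": rng.normal(0, 1, 20)})
        b = pd.DataFrame({"x": rng.normal(10, 1, 20)})
        rep = compare_groups(b, a)
        assert rep.loc["x", "p"] < 1e-3
        assert rep.loc["x", "direction"] == "A>B"
        assert rep.loc["x", "flag"] == "*"

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame({"x": rng.normal(0, 1, 15)})
        b = pd.DataFrame({"x": rng.normal(0.8, 1, 15)})
        r1 = compare_groups(a, b)
        r2 = compare_groups(b, a)
        assert r1.loc["x", "p"] == pytest.approx(r2.loc["x", "p"])
        assert {r1.loc["x", "direction"], r2.loc["x", "direction"]} <= {"A>B", "A<B"}
        assert r1.loc["x", "direction"] != r2.loc["x", "direction"]

    def test_zero_variance_skipped(self):
        a = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        rep = compare_groups(a, a.copy())
        assert rep.loc["x", "test"] == "skipped"

    def test_categorical_chi2(self):
        sa = pd.Series(["SCC"] * 18 + ["adeno"] * 2, index=range(20))
        sb = pd.Series(["SCC"] * 5 + ["adeno"] * 15, index=range(20, 40))
        rep = compare_groups(
            pd.DataFrame({"x": np.r_[np.ones(19), 2.0]}, index=range(20)),
            pd.DataFrame({"x": np.r_[np.ones(19), 2.0]}, index=range(20, 40)),
            variables=[],
            categorical={"pathology": (sa, sb)},
        )
        assert rep.loc["pathology", "test"] == "chi2"
        assert rep.loc["pathology", "p"] < 0.01

    def test_ed_arm_shows_higher_anc1(self, sim_cohort):
        """Synthetic cohorts plant the adverse hematology profile: the ED arm
        runs higher on the ANC geometric-mean feature."""
        recs, _, truth = sim_cohort
        dyn = dynamics_frame(recs)
        ed_ids = truth.true_group[truth.true_group == "ED"].index
        rep = compare_groups(dyn.loc[ed_ids], dyn.drop(index=ed_ids), ["ANC1"])
        assert rep.loc["ANC1", "direction"] == "A>B"
        assert rep.loc["ANC1", "p"] < 0.05


def test_clinical_csv_roundtrip(tmp_path, sim_cohort):
    recs, _, _ = sim_cohort
    path = tmp_path / "clinical.csv"
    write_clinical_csv(recs, path)
    back = read_clinical_csv(path)
    assert len(back) == len(recs)
    for a, b in zip(recs, back):
        assert a.patient_id == b.patient_id
        pd.testing.assert_frame_equal(a.cbc, b.cbc.loc[a.cbc.index], check_exact=False)
        assert a.death_cause == b.death_cause
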