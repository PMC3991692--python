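"""Measurement error model: imprecision SD, variance components, group comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcmicro import (
    compare_group_imprecision,
    fit_measurement_error_model,
    imprecision_by_group,
    relative_imprecision,
)


def make_table(
    rng,
    n_subjects=20,
    n_both_eyes=0,
    subject_sd=2.0,
    eye_sd=1.0,
    resid_sd=0.5,
    mean=24.2,
    group="all",
    parameter="pore_diameter_mean",
):
    """Simulate a nested repeated-measurement table, 2 replicates per eye."""
    rows = []
    for s in range(n_subjects):
        subj_eff = rng.normal(0, subject_sd)
        eyes = ["OD", "OS"] if s < n_both_eyes else ["OD"]
        for e in eyes:
            eye_eff = rng.normal(0, eye_sd)
            for rep in (1, 2):
                rows.append(
                    {
                        "subject_id": f"S{s:03d}",
                        "eye_id": e,
                        "group": group,
                        "replicate": rep,
                        "parameter": parameter,
                        "value": mean + subj_eff + eye_eff + rng.normal(0, resid_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestFitBasics:
    def test_duplicate_replicates_give_zero_imprecision(self):
        rng = np.random.default_rng(0)
        t = make_table(rng, n_subjects=10, resid_sd=1.0)
        t2 = t[t.replicate == 1].copy()
        t2["replicate"] = 2
        dup = pd.concat([t[t.replicate == 1], t2])
        est = fit_measurement_error_model(dup, "pore_diameter_mean")
        assert est.imprecision_sd == 0.0
        assert relative_imprecision(est) == 0.0

    def test_balanced_one_eye_case_equals_closed_form(self):
        """With one eye per subject the REML residual is SD(differences)/sqrt(2)."""
        rng = np.random.default_rng(1)
        t = make_table(rng, n_subjects=25, n_both_eyes=0, resid_sd=0.7)
        est = fit_measurement_error_model(t, "pore_diameter_mean")
        wide = t.pivot_table(index=["subject_id", "eye_id"], columns="replicate", values="value")
        want = float(np.std(wide[2] - wide[1], ddof=1)) / np.sqrt(2)
        assert est.imprecision_sd == pytest.approx(want, abs=1e-8)

    def test_unbalanced_replicates_error_names_eyes(self):
        rng = np.random.default_rng(2)
        t = make_table(rng, n_subjects=5)
        t = t.drop(t[(t.subject_id == "S003") & (t.replicate == 2)].index)
        with pytest.raises(ValueError, match="S003"):
            fit_measurement_error_model(t, "pore_diameter_mean")

    def test_too_few_eyes_rejected(self):
        rng = np.random.default_rng(3)
        t = make_table(rng, n_subjects=2)
        with pytest.raises(ValueError, match="eyes"):
            fit_measurement_error_model(t, "pore_diameter_mean")

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            fit_measurement_error_model(pd.DataFrame({"value": [1.0]}), "x")

    def test_variance_components_recovered_roughly(self):
        rng = np.random.default_rng(4)
        t = make_table(rng, n_subjects=120, n_both_eyes=60, subject_sd=2.0, eye_sd=1.0)
        est = fit_measurement_error_model(t, "pore_diameter_mean")
        assert np.sqrt(est.subject_var) == pytest.approx(2.0, rel=0.35)
        assert np.sqrt(est.eye_within_subject_var) == pytest.approx(1.0, rel=0.45)


class TestRelativeImprecision:
    """The imprecision/mean arithmetic, checked against published value pairs."""

    @pytest.mark.parametrize(
        "imprecision,mean,expected_pct",
        [(1.0, 48.8, 2.0), (50.0, 1660.0, 3.0), (0.0, 10.0, 0.0)],
    )
    def test_known_pairs(self, imprecision, mean, expected_pct):
        assert 100.0 * imprecision / mean == pytest.approx(expected_pct, abs=0.05)

    def test_zero_mean_rejected(self):
        rows = []
        for i, v in enumerate((1.0, 2.0, 3.0)):
            for rep, sign in ((1, 1.0), (2, -1.0)):
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "eye_id": "OD",
                        "group": "g",
                        "replicate": rep,
                        "parameter": "x",
                        "value": sign * v,  # grand mean is exactly zero
                    }
                )
        with pytest.raises(ValueError, match="zero mean"):
            fit_measurement_error_model(pd.DataFrame(rows), "x")


class TestEstimatorProperties:
    @given(c=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
    @settings(max_examples=10, deadline=None)
    def test_scale_equivariance_and_shift_invariance(self, c, shift):
        rng = np.random.default_rng(6)
        t = make_table(rng, n_subjects=12, n_both_eyes=4)
        base = fit_measurement_error_model(t, "pore_diameter_mean")
        ts = t.copy()
        ts["value"] = ts["value"] * c
        scaled = fit_measurement_error_model(ts, "pore_diameter_mean")
        assert scaled.imprecision_sd == pytest.approx(base.imprecision_sd * c, rel=1e-9)
        assert scaled.relative_imprecision == pytest.approx(
            base.relative_imprecision, rel=1e-9
        )
        tsh = t.copy()
        tsh["value"] = tsh["value"] + shift
        shifted = fit_measurement_error_model(tsh, "pore_diameter_mean")
        assert shifted.imprecision_sd == pytest.approx(base.imprecision_sd, abs=1e-9)

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(7)
        t = make_table(rng, n_subjects=200, n_both_eyes=80, resid_sd=0.5)
        est = fit_measurement_error_model(t, "pore_diameter_mean")
        assert est.imprecision_sd == pytest.approx(0.5, rel=0.10)

    def test_nested_residual_not_above_naive_pooled_sd(self):
        """Ignoring the eye/subject levels inflates the error estimate."""
        rng = np.random.default_rng(8)
        t = make_table(rng, n_subjects=40, n_both_eyes=15, subject_sd=3.0, eye_sd=1.5)
        est = fit_measurement_error_model(t, "pore_diameter_mean")
        naive = float(t["value"].std(ddof=1))
        assert est.imprecision_sd <= naive


class TestByGroup:
    def test_single_group_matches_plain_fit(self):
        rng = np.random.default_rng(9)
        t = make_table(rng, n_subjects=10, group="g1")
        plain = fit_measurement_error_model(t, "pore_diameter_mean")
        grouped = imprecision_by_group(t, "pore_diameter_mean")
        assert grouped["g1"]["pore_diameter_mean"].imprecision_sd == pytest.approx(
            plain.imprecision_sd
        )

    def test_identical_groups_identical_estimates(self):
        rng = np.random.default_rng(10)
        t1 = make_table(rng, n_subjects=10, group="a")
        t2 = t1.copy()
        t2["group"] = "b"
        t2["subject_id"] = "B" + t2["subject_id"]
        out = imprecision_by_group(pd.concat([t1, t2]))
        a = out["a"]["pore_diameter_mean"]
        b = out["b"]["pore_diameter_mean"]
        assert a.imprecision_sd == pytest.approx(b.imprecision_sd)

    def test_group_residual_ratio_recovered(self):
        """Groups simulated with residual SD 0.3 vs 0.6 show a ~2x ratio."""
        rng = np.random.default_rng(2)
        ratios = []
        for _ in range(200):
            ta = make_table(rng, n_subjects=20, resid_sd=0.3, group="a")
            tb = make_table(rng, n_subjects=20, resid_sd=0.6, group="b")
            ea = fit_measurement_error_model(ta, "pore_diameter_mean")
            eb = fit_measurement_error_model(tb, "pore_diameter_mean")
            ratios.append(eb.imprecision_sd / ea.imprecision_sd)
        assert 1.6 <= np.mean(ratios) <= 2.4

    def test_small_group_skipped_with_warning(self):
        rng = np.random.default_rng(11)
        t1 = make_table(rng, n_subjects=10, group="big")
        t2 = make_table(rng, n_subjects=2, group="tiny")
        t2["subject_id"] = "T" + t2["subject_id"]
        with pytest.warns(UserWarning, match="tiny"):
            out = imprecision_by_group(pd.concat([t1, t2]))
        assert "pore_diameter_mean" in out["big"]
        assert "pore_diameter_mean" not in out["tiny"]


class TestGroupComparison:
    def test_identical_groups_ci_contains_one(self):
        rng = np.random.default_rng(12)
        t = make_table(rng, n_subjects=20)
        est = fit_measurement_error_model(t, "pore_diameter_mean")
        cmp = compare_group_imprecision(est, est, n_boot=500, seed=1)
        assert cmp.ci_low <= 1.0 <= cmp.ci_high
        assert cmp.variance_ratio == pytest.approx(1.0)

    def test_zero_denominator_variance_rejected(self):
        rng = np.random.default_rng(13)
        t = make_table(rng, n_subjects=10)
        t2 = t[t.replicate == 1].copy()
        t2["replicate"] = 2
        degenerate = fit_measurement_error_model(
            pd.concat([t[t.replicate == 1], t2]), "pore_diameter_mean"
        )
        ok = fit_measurement_error_model(t, "pore_diameter_mean")
        with pytest.raises(ValueError, match="zero residual"):
            compare_group_imprecision(ok, degenerate)

    def test_power_to_detect_fourfold_variance_ratio(self):
        """A 4x residual-variance difference is detected in most replications."""
        rng = np.random.default_rng(14)
        detected = 0
        for rep in range(100):
            ta = make_table(rng, n_subjects=20, resid_sd=0.5, group="a")
            tb = make_table(rng, n_subjects=20, resid_sd=1.0, group="b")
            ea = fit_measurement_error_model(ta, "pore_diameter_mean")
            eb = fit_measurement_error_model(tb, "pore_diameter_mean")
            cmp = compare_group_imprecision(eb, ea, n_boot=400, seed=rep)
            if cmp.ci_low > 1.0:
                detected += 1
        assert detected >= 80
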