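import numpy as np
import pandas as pd
import pytest

from _oracles import bh_bruteforce, lmm_ml_bruteforce
from vlcdprot.design import build_study_design
from vlcdprot.stats import (
    EXERCISE_RULE,
    VLCD_RULE,
    bh_adjust,
    fit_lmm_ml,
    fit_random_intercept_ml,
    fit_vlcd_models,
    flag_significant,
    independent_ttest,
    lrt_pvalue,
    paired_ttest,
    patient_frame,
)
from vlcdprot.stats import test_fixed_effect as lrt_fixed_effect


def paired_design_arrays(n_per_arm, rng=None, beta=(1.0, -0.5, 0.0, 0.0),
                         sigma_b=0.3, sigma_e=0.2):
    n_subj = 2 * n_per_arm
    subject = np.repeat(np.arange(n_subj), 2)
    t = np.tile([0.0, 1.0], n_subj)
    g = np.where(np.arange(n_subj) < n_per_arm, 0.5, -0.5)[subject]
    X = np.column_stack([np.ones(len(subject)), t, g, t * g])
    mean = X @ np.asarray(beta)
    if rng is None:
        return X, subject, mean
    u = rng.normal(0, sigma_b, n_subj)
    y = mean + u[subject] + rng.normal(0, sigma_e, len(subject))
    return X, subject, y


class TestLmmFitter:
    def test_noise_free_betas_recovered_exactly(self):
        X, subject, y = paired_design_arrays(10, beta=(1.0, -0.5, 0.2, 0.1))
        fit = fit_lmm_ml(y, X, subject)
        assert np.allclose(fit["beta"][0], [1.0, -0.5, 0.2, 0.1], atol=1e-8)
        assert fit["sigma_e2"][0] <= 1e-12

    def test_matches_bruteforce_profile_likelihood(self, rng):
        for _ in range(5):
            X, subject, y = paired_design_arrays(6, rng=rng)
            fit = fit_lmm_ml(y, X, subject)
            assert fit["loglik"][0] == pytest.approx(
                lmm_ml_bruteforce(y, X, subject), abs=1e-6)

    def test_matches_statsmodels_ml(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X, subject, y = paired_design_arrays(15, rng=rng)
        fit = fit_lmm_ml(y, X, subject)
        mf = sm.MixedLM(y, X, groups=subject).fit(reml=False)
        assert fit["loglik"][0] == pytest.approx(mf.llf, abs=1e-5)
        assert np.allclose(fit["beta"][0], mf.fe_params, atol=1e-5)

    def test_handles_singleton_subjects(self, rng):
        # mix of one- and two-observation subjects
        subject = np.array([0, 0, 1, 2, 2, 3])
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        y = rng.normal(size=6)
        fit = fit_lmm_ml(y, X, subject)
        assert fit["loglik"][0] == pytest.approx(
            lmm_ml_bruteforce(y, X, subject), abs=1e-6)

    def test_rejects_non_finite_input(self):
        X, subject, y = paired_design_arrays(5)
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_lmm_ml(y, X, subject)

    def test_parameter_recovery_within_3se(self):
        # a single replicate sits inside 3 SE ~99.7% of the time; ask for
        # at least 9 of 10 to keep the check sharp but not flaky
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(10):
            X, subject, y = paired_design_arrays(200, rng=rng)
            fit = fit_lmm_ml(y, X, subject)
            hits += abs(fit["beta"][0, 1] + 0.5) <= 3 * fit["se"][0, 1]
        assert hits >= 9


class TestLrt:
    def test_identical_fits_give_p_one(self):
        assert lrt_fixed_effect(-12.0, -12.0) == pytest.approx(1.0)

    def test_chi2_quantile_identity(self):
        # statistic 3.841 on 1 df is the alpha = 0.05 boundary
        assert lrt_fixed_effect(0.0, -3.841 / 2) == pytest.approx(0.05, abs=1e-4)

    def test_reduced_better_than_full_raises(self):
        with pytest.raises(RuntimeError, match="refit"):
            lrt_pvalue(-10.0, -9.0)


class TestModelWrappers:
    def test_requires_three_subjects_per_arm(self):
        d = build_study_design(2, 5, 0, 0)
        y = pd.Series(1.0, index=[s.sample_id for s in d.patient_samples])
        with pytest.raises(ValueError, match="3 subjects"):
            fit_random_intercept_ml(y, d)

    def test_single_group_time_effect_equals_mean_paired_difference(self):
        d = build_study_design(8, 0, 0, 0)
        rng = np.random.default_rng(3)
        frame = patient_frame(d)
        vals = {}
        for _, r in frame.iterrows():
            vals[r["sample_id"]] = rng.normal() + 0.4 * r["time"]
        y = pd.Series(vals)
        res = fit_random_intercept_ml(y, d)
        diffs = [y[f"{s.subject_id}_T16"] - y[f"{s.subject_id}_T0"]
                 for s in d.subjects]
        assert res.beta["time"] == pytest.approx(np.mean(diffs), abs=1e-10)
        assert np.isnan(res.p_interaction)

    def test_single_group_lrt_close_to_paired_t(self):
        """At n = 200 the chi-square LRT p and the paired-t p nearly agree."""
        d = build_study_design(200, 0, 0, 0)
        rng = np.random.default_rng(4)
        frame = patient_frame(d)
        subj_noise = {s.subject_id: rng.normal(0, 0.3) for s in d.subjects}
        vals = {r["sample_id"]: subj_noise[r["subject_id"]]
                + 0.03 * r["time"] + rng.normal(0, 0.2)
                for _, r in frame.iterrows()}
        y = pd.Series(vals)
        res = fit_random_intercept_ml(y, d)
        x0 = np.array([y[f"{s.subject_id}_T0"] for s in d.subjects])
        x1 = np.array([y[f"{s.subject_id}_T16"] for s in d.subjects])
        tt = paired_ttest(x0, x1)
        assert abs(res.p_time - tt.p) < 0.005

    def test_fit_vlcd_models_shapes_and_bh(self, study_design, rng):
        cols = [s.sample_id for s in study_design.patient_samples]
        ab = pd.DataFrame(rng.lognormal(0, 0.2, (6, len(cols))),
                          index=[f"g{i}" for i in range(6)], columns=cols)
        res = fit_vlcd_models(ab, study_design)
        assert (res["p_time_bh"] >= res["p_time"] - 1e-12).all()
        assert res["sigma_b2"].ge(0).all() and res["sigma_e2"].gt(0).all()

    def test_missing_values_rejected(self, study_design):
        cols = [s.sample_id for s in study_design.patient_samples]
        ab = pd.DataFrame(1.0, index=["g"], columns=cols)
        ab.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete-case"):
            fit_vlcd_models(ab, study_design)


class TestTTests:
    def test_paired_hand_example(self):
        res = paired_ttest([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-6)
        assert res.p == pytest.approx(0.0742, abs=2e-4)

    def test_paired_zero_variance_flagged(self):
        res = paired_ttest([1.0, 2.0], [1.0, 2.0])
        assert res.zero_variance and np.isnan(res.p)

    def test_paired_antisymmetric_diffs(self):
        res = paired_ttest([0.0, 0.0], [-1.0, 1.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_independent_hand_example(self):
        res = independent_ttest([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.p == pytest.approx(0.288, abs=5e-3)

    def test_independent_symmetry(self):
        a = independent_ttest([1, 2, 3], [2, 3, 5])
        b = independent_ttest([2, 3, 5], [1, 2, 3])
        assert a.t == pytest.approx(-b.t) and a.p == pytest.approx(b.p)

    def test_independent_identical_groups(self):
        res = independent_ttest([1.0, 1.0], [1.0, 1.0])
        assert res.zero_variance


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_stepup(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_matches_bruteforce(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            got = bh_adjust(p)
            assert (got >= p - 1e-12).all()
            assert np.allclose(got, bh_bruteforce(list(p)), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestSignificanceRules:
    def _frame(self):
        return pd.DataFrame({
            "p_time": [0.01, 0.04, 0.5],
            "p_time_bh": [0.04, 0.30, 0.7],
            "p_interaction": [0.2, 0.03, 0.9],
            "p_interaction_bh": [0.5, 0.2, 0.95],
            "beta_time": [-0.5, 0.2, 0.0],
            "beta_interaction": [0.1, -0.3, 0.0],
        }, index=["a", "b", "c"])

    def test_vlcd_dual_threshold(self):
        out = flag_significant(self._frame(), VLCD_RULE)
        assert out.loc["a", "significant"] and out.loc["a", "direction"] == "down"
        assert not out.loc["b", "significant"]  # raw ok but BH fails
        assert not out.loc["c", "significant"]

    def test_exercise_raw_threshold(self):
        out = flag_significant(self._frame(), EXERCISE_RULE)
        assert list(out["significant"]) == [False, True, False]
        assert out.loc["b", "direction"] == "down"
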