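"""Design construction, likelihood, map/mcmc fitting, LOO comparison."""

import copy

import numpy as np
import pandas as pd
import pytest

from iatdyn.data_io import TrialDataset
from iatdyn.errors import (ComparisonError, ParameterError, RequirementError,
                           StructuralError)
from iatdyn.exgauss import ExGaussParams, exgauss_logpdf
from iatdyn.synthetic_data import SyntheticConfig, simulate_iat
from iatdyn.trajectory_model import (ModelSpec, build_design, compare_loo,
                                     early_late_effect, extract_indices, fit,
                                     fit_null, model_loglik)

JOINT = {"estimator": "joint", "em_iterations": 1}

LEAN = ModelSpec(
    fixed_terms={"log_start": ["intercept", "compatibility"],
                 "log_rate": ["intercept", "compatibility"],
                 "log_asym": ["intercept", "compatibility"],
                 "log_gauss_mean": ["intercept", "word_vs_face"]},
    random_terms={"participant_id": {
        "log_asym": ["intercept", "compatibility"],
        "log_gauss_mean": ["intercept"]}})


@pytest.fixture(scope="module")
def lean_fit(small_dataset):
    return fit(small_dataset, LEAN, seed=0, control=JOINT)


class TestModelSpec:
    def test_intercept_required(self):
        with pytest.raises(StructuralError, match="intercept"):
            ModelSpec(fixed_terms={
                "log_start": ["compatibility"], "log_rate": ["intercept"],
                "log_asym": ["intercept"], "log_gauss_mean": ["intercept"]})

    def test_random_terms_must_be_fixed_terms(self):
        with pytest.raises(StructuralError, match="not fixed"):
            ModelSpec(
                fixed_terms={t: ["intercept"] for t in
                             ("log_start", "log_rate", "log_asym",
                              "log_gauss_mean")},
                random_terms={"participant_id":
                              {"log_start": ["compatibility"]}})

    def test_static_spec_forbids_rate_terms(self):
        with pytest.raises(StructuralError):
            ModelSpec(fixed_terms={"log_rate": ["intercept"],
                                   "log_asym": ["intercept"],
                                   "log_gauss_mean": ["intercept"]},
                      time_varying=False)

    def test_null_conversion_merges_start_into_asym(self):
        null = ModelSpec.study2_default().to_null()
        assert not null.time_varying
        assert set(null.fixed_terms) == {"log_asym", "log_gauss_mean"}
        assert "compatibility" in null.fixed_terms["log_asym"]

    def test_json_round_trip(self, tmp_path):
        spec = ModelSpec.study3_default()
        path = tmp_path / "spec.json"
        spec.to_json(path)
        again = ModelSpec.from_json(path)
        assert again.fixed_terms == spec.fixed_terms
        assert again.random_terms == spec.random_terms


class TestBuildDesign:
    def test_intercept_only_single_ones_column(self, small_dataset):
        spec = ModelSpec(fixed_terms={t: ["intercept"] for t in
                                      ("log_start", "log_rate", "log_asym",
                                       "log_gauss_mean")})
        d = build_design(spec, small_dataset)
        for tgt in d.targets:
            assert d.X[tgt].shape[1] == 1
            assert np.all(d.X[tgt] == 1.0)

    def test_compatibility_centered_on_balanced_data(self, small_dataset):
        d = build_design(LEAN, small_dataset)
        col = d.X["log_start"][:, d.columns["log_start"].index("compatibility")]
        assert abs(col.mean()) < 1e-12
        assert set(np.unique(col)) == {-0.5, 0.5}

    def test_learning_condition_design_matches_reference_layout(self):
        # 3 condition contrasts x incompatibility + gender + age covariates:
        # 10 columns per trajectory target including the intercept
        cfg = SyntheticConfig(n_participants=12, seed=2,
                              conditions=("none", "rep", "es", "combined"))
        ds, _ = simulate_iat(cfg)
        spec = ModelSpec.study4_default(("none", "rep", "es", "combined"))
        d = build_design(spec, ds)
        assert len(d.columns["log_start"]) == 10
        for term in ("condition[es]", "condition[es]:compatibility",
                     "gender", "age"):
            assert term in d.columns["log_start"]

    def test_missing_covariate_named(self, small_dataset):
        spec = ModelSpec(fixed_terms={
            "log_start": ["intercept", "condition[es]"],
            "log_rate": ["intercept"], "log_asym": ["intercept"],
            "log_gauss_mean": ["intercept"]})
        with pytest.raises(RequirementError, match="condition"):
            build_design(spec, small_dataset)


class TestModelLoglik:
    def test_reduces_to_iid_exgauss_when_static_in_effect(self, small_dataset):
        spec = ModelSpec(fixed_terms={t: ["intercept"] for t in
                                      ("log_start", "log_rate", "log_asym",
                                       "log_gauss_mean")})
        d = build_design(spec, small_dataset)
        theta = np.zeros(d.n_params)
        # identical start and asym intercepts: tau constant over trials
        theta[d.fixed_offsets["log_start"]] = 5.0
        theta[d.fixed_offsets["log_rate"]] = 2.0
        theta[d.fixed_offsets["log_asym"]] = 5.0
        theta[d.fixed_offsets["log_gauss_mean"]] = 6.1
        theta[d.sigma_index] = np.log(50.0)
        ll = model_loglik(small_dataset, spec, theta)
        params = ExGaussParams(np.exp(6.1), 50.0, np.exp(5.0))
        direct = exgauss_logpdf(d.rt, params)
        assert np.allclose(ll, direct, atol=1e-10)

    def test_static_model_ignores_trial_index(self, small_dataset):
        spec = ModelSpec(fixed_terms={"log_asym": ["intercept"],
                                      "log_gauss_mean": ["intercept"]},
                         time_varying=False)
        d = build_design(spec, small_dataset)
        theta = np.array([5.1, 6.1, np.log(50.0)])
        ll = model_loglik(small_dataset, spec, theta)
        shuffled = small_dataset.records.copy()
        shuffled["trial_index"] = shuffled.groupby(
            ["participant_id", "iat_type", "run_index"])[
            "trial_index"].transform(lambda s: s.sample(frac=1.0,
                                                        random_state=1).values)
        ll2 = model_loglik(TrialDataset(shuffled), spec, theta)
        assert np.sum(ll) == pytest.approx(np.sum(ll2))

    def test_dimension_mismatch(self, small_dataset):
        spec = ModelSpec(fixed_terms={t: ["intercept"] for t in
                                      ("log_start", "log_rate", "log_asym",
                                       "log_gauss_mean")})
        with pytest.raises(ParameterError, match="length"):
            model_loglik(small_dataset, spec, np.zeros(3))

    def test_truth_dominates_perturbed_parameters(self, small_dataset,
                                                  small_truth):
        spec = ModelSpec(
            fixed_terms={"log_start": ["intercept", "compatibility"],
                         "log_rate": ["intercept", "compatibility"],
                         "log_asym": ["intercept", "compatibility"],
                         "log_gauss_mean": ["intercept", "word_vs_face"]})
        d = build_design(spec, small_dataset)
        theta = np.zeros(d.n_params)
        fe = small_truth.fixed_effects
        for tgt in d.targets:
            o = d.fixed_offsets[tgt]
            for j, term in enumerate(d.columns[tgt]):
                theta[o + j] = fe.get(f"{tgt}.{term}", 0.0)
        theta[d.sigma_index] = np.log(50.0)
        ll_true = model_loglik(small_dataset, spec, theta).sum()
        rng = np.random.default_rng(0)
        worse = 0
        for _ in range(10):
            ll_pert = model_loglik(
                small_dataset, spec,
                theta + rng.normal(0, 0.25, d.n_params)).sum()
            worse += ll_pert < ll_true
        assert worse >= 9


class TestFit:
    def test_map_fit_is_bit_deterministic(self, small_dataset):
        a = fit(small_dataset, LEAN, seed=0, control=JOINT)
        b = fit(small_dataset, LEAN, seed=0, control=JOINT)
        assert np.array_equal(a.theta, b.theta)
        assert a.fixed_estimates.equals(b.fixed_estimates)

    def test_participant_order_invariance(self, small_dataset):
        a = fit(small_dataset, LEAN, seed=0, control=JOINT)
        reversed_df = (small_dataset.records
                       .sort_values(["participant_id", "iat_type",
                                     "run_index", "trial_index"],
                                    ascending=[False, True, True, True])
                       .reset_index(drop=True))
        b = fit(TrialDataset(reversed_df), LEAN, seed=0, control=JOINT)
        assert np.allclose(a.fixed_estimates["estimate"],
                           b.fixed_estimates["estimate"], atol=1e-5)

    def test_intervals_contain_estimates(self, lean_fit):
        fe = lean_fit.fixed_estimates
        assert (fe["ci_low"] <= fe["estimate"]).all()
        assert (fe["estimate"] <= fe["ci_high"]).all()
        assert len(lean_fit.pointwise_loglik) == 1200

    def test_single_participant_with_random_effects_rejected(self,
                                                             small_dataset):
        one = small_dataset.for_participant(small_dataset.participants[0])
        with pytest.raises(StructuralError, match="participants"):
            fit(one, LEAN, seed=0, control=JOINT)

    def test_null_fit_on_static_data_matches_full(self):
        ds, _ = simulate_iat(SyntheticConfig(n_participants=15, seed=23,
                                             static=True))
        full = fit(ds, LEAN, seed=0, control=JOINT)
        null = fit_null(ds, LEAN, seed=0, control=JOINT)
        # start-vs-asym contrast interval covers zero on static data
        fe = full.fixed_estimates.set_index(["target", "term"])
        i_s = full.design.fixed_offsets["log_start"]
        i_a = full.design.fixed_offsets["log_asym"]
        diff = fe.loc[("log_start", "intercept"), "estimate"] \
            - fe.loc[("log_asym", "intercept"), "estimate"]
        cov = full.laplace_cov
        se = np.sqrt(cov[i_s, i_s] + cov[i_a, i_a] - 2 * cov[i_s, i_a])
        assert abs(diff) <= 2.5 * se
        # log-likelihoods within noise of each other
        assert null.pointwise_loglik.sum() == pytest.approx(
            full.pointwise_loglik.sum(), abs=60)


class TestCompareLoo:
    def test_self_comparison_is_exact_zero(self, lean_fit, small_dataset):
        loo = compare_loo(lean_fit, lean_fit, small_dataset)
        assert loo.looic_diff == 0.0
        assert not loo.reliable
        assert loo.favors is None

    def test_mismatched_trial_sets_rejected(self, lean_fit, small_dataset):
        sub = TrialDataset(small_dataset.records.iloc[:600].copy())
        other = fit(sub, LEAN, seed=0, control=JOINT)
        with pytest.raises(ComparisonError):
            compare_loo(lean_fit, other, small_dataset)

    def test_time_varying_data_favors_full_model(self, small_dataset):
        full = fit(small_dataset, LEAN, seed=0, control=JOINT)
        null = fit_null(small_dataset, LEAN, seed=0, control=JOINT)
        loo = compare_loo(full, null, small_dataset, seed=0)
        assert loo.looic_diff < 0
        assert loo.reliable and loo.favors == "a"
        assert loo.looic_diff == pytest.approx(-2.0 * loo.elpd_diff)


class TestIndicesAndEffects:
    @pytest.fixture(scope="class")
    def rich_fit(self):
        cfg = SyntheticConfig(n_participants=25, seed=42,
                              sd_compat_log_asym=0.45,
                              sd_compat_log_start=0.35)
        ds, truth = simulate_iat(cfg)
        spec = ModelSpec.study2_default(order=True)
        return fit(ds, spec, seed=0, control=JOINT), truth

    def test_indices_track_truth(self, rich_fit):
        f, truth = rich_fit
        idx = extract_indices(f)
        m = idx.merge(truth.indices, on="participant_id",
                      suffixes=("_est", "_true"))
        from scipy.stats import spearmanr
        rho = spearmanr(m["asym_diff_ms_est"], m["asym_diff_ms_true"])
        assert rho.statistic > 0.6

    def test_zscored_indices_standardized(self, rich_fit):
        f, _ = rich_fit
        z = extract_indices(f, zscored=True)
        for col in ("start_diff_ms", "asym_diff_ms", "rate_trials"):
            assert z[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert z[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_fit_without_participant_terms_rejected(self, small_dataset):
        spec = ModelSpec(fixed_terms={t: ["intercept"] for t in
                                      ("log_start", "log_rate", "log_asym",
                                       "log_gauss_mean")})
        f = fit(small_dataset, spec, seed=0, control=JOINT)
        with pytest.raises(RequirementError):
            extract_indices(f)

    def test_zero_random_variance_gives_identical_indices(self, rich_fit):
        f, _ = rich_fit
        frozen = copy.copy(f)
        theta = f.theta.copy()
        for rb in f.design.random_blocks:
            theta[rb.offset:rb.offset + rb.size] = 0.0
        frozen.theta = theta
        idx = extract_indices(frozen)
        assert idx["asym_diff_ms"].nunique() == 1
        assert idx["rate_trials"].nunique() == 1

    def test_early_late_effect_negative_for_shrinking_differences(
            self, rich_fit):
        f, _ = rich_fit
        r = early_late_effect(f)
        assert r.effect_d < 0
        assert r.extra["mean_change_ms"] < 0

    def test_early_late_degenerate_when_participants_identical(self,
                                                               rich_fit):
        f, _ = rich_fit
        frozen = copy.copy(f)
        theta = f.theta.copy()
        for rb in f.design.random_blocks:
            theta[rb.offset:rb.offset + rb.size] = 0.0
        frozen.theta = theta
        r = early_late_effect(frozen)
        assert r.degenerate

    def test_static_fit_rejected(self, small_dataset):
        null = fit_null(small_dataset, LEAN, seed=0, control=JOINT)
        with pytest.raises(StructuralError):
            early_late_effect(null)


class TestMcmcBackend:
    def test_small_model_samples_and_compares(self):
        cfg = SyntheticConfig(n_participants=4, seed=5,
                              sd_compat_log_start=0.0,
                              sd_compat_log_asym=0.0)
        ds, _ = simulate_iat(cfg)
        spec = ModelSpec(
            fixed_terms={"log_start": ["intercept", "compatibility"],
                         "log_rate": ["intercept"],
                         "log_asym": ["intercept", "compatibility"],
                         "log_gauss_mean": ["intercept"]},
            random_terms={"participant_id": {"log_asym": ["intercept"]}})
        ctrl = {"estimator": "joint", "n_steps": 500, "n_burn": 200,
                "n_loglik_draws": 120}
        with pytest.warns(UserWarning):
            # short chains: convergence warning is expected behaviour
            full = fit(ds, spec, method="mcmc", seed=1, control=ctrl)
            null = fit_null(ds, spec, method="mcmc", seed=2, control=ctrl)
        assert full.pointwise_loglik.ndim == 2
        assert full.pointwise_loglik.shape[1] == 480
        assert "rhat_max" in full.diagnostics
        fe = full.fixed_estimates
        assert (fe["ci_low"] < fe["estimate"]).all()
        assert (fe["estimate"] < fe["ci_high"]).all()
        loo = compare_loo(full, null, ds)
        assert loo.method == "psis_loo"
        assert np.isfinite(loo.looic_diff)

    def test_mcmc_seed_determinism(self):
        cfg = SyntheticConfig(n_participants=3, seed=5,
                              sd_compat_log_start=0.0,
                              sd_compat_log_asym=0.0)
        ds, _ = simulate_iat(cfg)
        spec = ModelSpec(
            fixed_terms={"log_start": ["intercept"], "log_rate": ["intercept"],
                         "log_asym": ["intercept"],
                         "log_gauss_mean": ["intercept"]})
        ctrl = {"estimator": "joint", "n_steps": 120, "n_burn": 40,
                "n_loglik_draws": 20}
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            a = fit(ds, spec, method="mcmc", seed=3, control=ctrl)
            b = fit(ds, spec, method="mcmc", seed=3, control=ctrl)
        assert np.array_equal(a.draws, b.draws)
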