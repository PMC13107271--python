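import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielcorrect import (
    ActivityHistogram,
    DetectionDataset,
    MixtureModelSpec,
    SamplerSettings,
    TimeGrid,
    diagnostics,
    fit,
    grid_posterior_oracle,
    log_joint,
    posterior_activity,
    record_prob_skewed,
    record_prob_uniform,
)
from dielcorrect.model import PosteriorFit


def make_dataset(bins, status, n_bins=24):
    return DetectionDataset(
        bins=np.asarray(bins), status=np.asarray(status), grid=TimeGrid(n_bins)
    )


J2_TOY = make_dataset(
    bins=[0] * 20 + [1] * 10 + [0] * 6 + [1] * 4,
    status=[0] * 30 + [1] * 6 + [2] * 4,
    n_bins=2,
)


class TestRecordProbabilities:
    def test_pure_signal_limit(self):
        f = ActivityHistogram(np.full(24, 1 / 24))
        probs = np.zeros(24); probs[3] = 0.1; probs[4] = 0.9
        f = ActivityHistogram(probs)
        assert record_prob_uniform(3, 1.0, f) == pytest.approx(0.1)

    def test_pure_noise_limit_is_one_over_j(self):
        f = ActivityHistogram(np.full(24, 1 / 24))
        assert record_prob_uniform(5, 0.0, f) == pytest.approx(1 / 24)

    def test_uniform_mixture_hand_value(self):
        probs = np.full(24, 0.8 / 23); probs[7] = 0.2
        f = ActivityHistogram(probs)
        assert record_prob_uniform(7, 0.75, f) == pytest.approx(0.1604167, abs=1e-6)

    def test_skewed_limits_and_hand_value(self):
        ft = np.full(24, 0.7 / 23); ft[2] = 0.3
        fp = np.full(24, 0.9 / 23); fp[2] = 0.1
        ft, fp = ActivityHistogram(ft), ActivityHistogram(fp)
        assert record_prob_skewed(2, 1.0, ft, fp) == pytest.approx(0.3)
        assert record_prob_skewed(2, 0.0, ft, fp) == pytest.approx(0.1)
        assert record_prob_skewed(2, 0.5, ft, fp) == pytest.approx(0.2)

    def test_out_of_range_bin_rejected(self):
        f = ActivityHistogram(np.full(24, 1 / 24))
        with pytest.raises(ValueError):
            record_prob_uniform(24, 0.5, f)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 1.0))
    def test_mixture_normalizes_over_bins(self, seed, theta):
        rng = np.random.default_rng(seed)
        ft = rng.dirichlet(np.ones(24))
        fp = rng.dirichlet(np.ones(24))
        total_u = sum(record_prob_uniform(b, theta, ft) for b in range(24))
        total_s = sum(record_prob_skewed(b, theta, ft, fp) for b in range(24))
        assert total_u == pytest.approx(1.0, abs=1e-12)
        assert total_s == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 1.0), st.integers(0, 23))
    def test_skewed_model_nests_uniform_model(self, seed, theta, bin):
        rng = np.random.default_rng(seed)
        ft = rng.dirichlet(np.ones(24))
        flat = np.full(24, 1 / 24)
        assert record_prob_skewed(bin, theta, ft, flat) == record_prob_uniform(
            bin, theta, ft
        )


class TestLogJoint:
    def test_verified_true_only_maximized_at_empirical_proportions(self):
        bins = [0] * 6 + [1] * 3 + [2]
        ds = make_dataset(bins, [1] * 10, n_bins=3)
        empirical = np.array([0.6, 0.3, 0.1])
        best = log_joint(ds, 0.9, empirical)
        for shift in (0.05, -0.05):
            other = empirical + np.array([shift, -shift, 0.0])
            assert log_joint(ds, 0.9, other) < best

    def test_single_unverified_record_contribution(self):
        ds_one = make_dataset([5], [0])
        f = np.random.default_rng(0).dirichlet(np.ones(24))
        expected = np.log(0.5 * f[5] + 0.5 / 24)
        # prior terms vanish under flat priors, leaving the mixture term
        assert log_joint(ds_one, 0.5, f) == pytest.approx(expected)

    def test_verified_false_changes_only_theta_term_under_uniform(self):
        f = np.random.default_rng(1).dirichlet(np.ones(24))
        base = make_dataset([3, 7], [0, 0])
        with_vf_a = make_dataset([3, 7, 2], [0, 0, 2])
        with_vf_b = make_dataset([3, 7, 19], [0, 0, 2])
        # the verified-false bin does not matter, only the Bernoulli(θ) factor
        assert log_joint(with_vf_a, 0.7, f) == pytest.approx(
            log_joint(with_vf_b, 0.7, f)
        )
        assert log_joint(with_vf_a, 0.7, f) - log_joint(base, 0.7, f) == pytest.approx(
            np.log(0.3) + np.log(1 / 24)
        )

    def test_out_of_support_parameters_give_minus_inf(self):
        ds = make_dataset([0], [0])
        f = np.full(24, 1 / 24)
        assert log_joint(ds, 1.5, f) == -np.inf
        bad = np.full(24, 1 / 23)
        assert log_joint(ds, 0.5, bad) == -np.inf


class TestFitConjugateCases:
    def test_theta_posterior_matches_beta_conjugacy(self):
        # 150 verified true + 50 verified false -> Beta(151, 51)
        rng = np.random.default_rng(0)
        bins = rng.integers(0, 24, size=200)
        status = np.array([1] * 150 + [2] * 50)
        ds = make_dataset(bins, status)
        fitted = fit(ds, settings=SamplerSettings(seed=1))
        exact = 151 / 202  # ≈ 0.7475, the 0.75 point-estimate illustration
        se = fitted.theta_draws.std() / np.sqrt(400)
        assert fitted.theta_mean == pytest.approx(exact, abs=4 * se + 1e-3)

    def test_histogram_posterior_matches_dirichlet_conjugacy(self):
        rng = np.random.default_rng(2)
        bins = rng.integers(0, 24, size=300)
        ds = make_dataset(bins, np.ones(300, dtype=int))
        fitted = fit(ds, settings=SamplerSettings(seed=3))
        counts = np.bincount(bins, minlength=24)
        exact = (1 + counts) / (24 + 300)
        mean, _, _ = posterior_activity(fitted)
        assert np.abs(mean.probs - exact).max() < 0.004

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            make_dataset([], [])


class TestGridPosteriorOracle:
    def test_single_record_posterior_matches_hand_integration(self):
        # one unverified record in bin 0 at J=2: the joint density
        # θφ + (1−θ)/2 integrates to 1/2, the θ-marginal is flat (mean 1/2),
        # and E[φ] = (1/6 + 1/8) / (1/2) = 7/12 by direct integration
        ds = make_dataset([0], [0], n_bins=2)
        res = grid_posterior_oracle(ds)
        assert res["theta_mean"] == pytest.approx(0.5, abs=1e-9)
        assert res["f_true_mean"][0] == pytest.approx(7 / 12, abs=1e-9)

    def test_verified_only_matches_closed_forms(self):
        ds = make_dataset([0] * 6 + [1] * 2 + [0, 1], [1] * 8 + [2] * 2, n_bins=2)
        res = grid_posterior_oracle(ds)
        assert res["theta_mean"] == pytest.approx(9 / 12, abs=1e-9)  # Beta(1+8,1+2)
        assert res["f_true_mean"][0] == pytest.approx(7 / 10, abs=1e-9)  # Dir(1+6,1+2)

    def test_richardson_stability(self):
        coarse = grid_posterior_oracle(J2_TOY, n_nodes=120)
        fine = grid_posterior_oracle(J2_TOY, n_nodes=240)
        assert coarse["theta_mean"] == pytest.approx(fine["theta_mean"], abs=1e-6)
        assert coarse["f_true_mean"][0] == pytest.approx(
            fine["f_true_mean"][0], abs=1e-6
        )

    def test_rejects_larger_grids(self):
        ds = make_dataset([0, 1, 2], [0, 0, 0], n_bins=3)
        with pytest.raises(ValueError):
            grid_posterior_oracle(ds)


class TestFitAgainstOracle:
    @pytest.mark.parametrize("structure", ["uniform", "skewed"])
    def test_posterior_means_match_quadrature(self, structure):
        spec = MixtureModelSpec(error_structure=structure)
        oracle = grid_posterior_oracle(J2_TOY, spec)
        fitted = fit(J2_TOY, spec, SamplerSettings(seed=11))
        ess = min(fitted.report.ess.values())
        se_theta = oracle["theta_sd"] / np.sqrt(ess)
        se_f = oracle["f_true_sd"][0] / np.sqrt(ess)
        assert fitted.theta_mean == pytest.approx(
            oracle["theta_mean"], abs=3 * se_theta
        )
        mean, _, _ = posterior_activity(fitted)
        assert mean.probs[0] == pytest.approx(oracle["f_true_mean"][0], abs=3 * se_f)


class TestFitBehaviour:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        bins = rng.integers(0, 24, size=500)
        status = np.array([0] * 400 + [1] * 80 + [2] * 20)
        ds = make_dataset(bins, status)
        a = fit(ds, settings=SamplerSettings(seed=21))
        b = fit(ds, settings=SamplerSettings(seed=21))
        np.testing.assert_array_equal(a.theta_draws, b.theta_draws)
        np.testing.assert_array_equal(a.f_true_draws, b.f_true_draws)

    def test_skewed_without_verified_false_warns(self):
        rng = np.random.default_rng(6)
        bins = rng.integers(0, 24, size=100)
        ds = make_dataset(bins, np.zeros(100, dtype=int))
        with pytest.warns(UserWarning, match="weakly identified"):
            try:
                fit(
                    ds,
                    MixtureModelSpec(error_structure="skewed"),
                    SamplerSettings(seed=7),
                )
            except Exception:
                pass  # convergence is not the point of this test

    def test_posterior_activity_mean_is_normalized(self):
        rng = np.random.default_rng(8)
        bins = rng.integers(0, 24, size=300)
        ds = make_dataset(bins, np.array([0] * 250 + [1] * 40 + [2] * 10))
        fitted = fit(ds, settings=SamplerSettings(seed=9))
        mean, lower, upper = posterior_activity(fitted)
        assert mean.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(lower <= upper)
        assert np.all(lower <= mean.probs + 1e-9)

    def test_degenerate_draws_give_zero_width_intervals(self):
        draw = np.full(24, 1 / 24)
        fitted = PosteriorFit(
            theta_draws=np.full((2, 10), 0.5),
            f_true_draws=np.tile(draw, (2, 10, 1)),
            f_fp_draws=None,
            spec=MixtureModelSpec(),
            settings=SamplerSettings(seed=0),
            grid=TimeGrid(24),
        )
        mean, lower, upper = posterior_activity(fitted)
        np.testing.assert_allclose(mean.probs, draw)
        np.testing.assert_allclose(lower, upper)

    def test_diagnostics_require_two_chains(self):
        fitted = PosteriorFit(
            theta_draws=np.random.default_rng(0).uniform(size=(1, 200)),
            f_true_draws=np.random.default_rng(0).dirichlet(np.ones(24), 200)[None],
            f_fp_draws=None,
            spec=MixtureModelSpec(),
            settings=SamplerSettings(seed=0, chains=1),
            grid=TimeGrid(24),
        )
        with pytest.raises(ValueError):
            diagnostics(fitted)


class TestSamplerCrossImplementation:
    def test_numpy_reference_agrees_with_compiled_kernel(self):
        """Both sampler paths target the same posterior: their posterior
        means must agree within Monte-Carlo error on a mixed dataset."""
        from dielcorrect.model import _run_gibbs, _run_gibbs_numpy

        rng = np.random.default_rng(10)
        bins = rng.integers(0, 24, size=400)
        status = np.array([0] * 300 + [1] * 80 + [2] * 20)
        ds = make_dataset(bins, status)
        st_ = SamplerSettings(seed=13)
        a = _run_gibbs(ds, MixtureModelSpec(), st_, np.random.SeedSequence(13))
        b = _run_gibbs_numpy(ds, MixtureModelSpec(), st_, np.random.SeedSequence(13))
        assert a.theta_draws.mean() == pytest.approx(b.theta_draws.mean(), abs=0.01)
        assert np.abs(
            a.f_true_draws.mean(axis=(0, 1)) - b.f_true_draws.mean(axis=(0, 1))
        ).max() < 0.01


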