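"""Binomial-model density, likelihood fitting, goodness of fit, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from lamicro import quantal, synthetic
from lamicro.types import ParameterError, QuantalParams


class TestDensity:
    def test_collapses_to_noise_when_p_zero(self):
        p = QuantalParams(5, 0.0, 460.0, v0=10.0, sigma_noise=30.0)
        v = np.linspace(-100, 150, 40)
        assert np.allclose(
            quantal.binomial_density(v, p), stats.norm.pdf(v, 10.0, 30.0)
        )

    @pytest.mark.parametrize(
        "params",
        [
            QuantalParams(5, 0.5, 460.0, sigma_noise=30.0, sigma_q=40.0),
            QuantalParams(1, 0.9, 100.0, sigma_noise=5.0),
            QuantalParams(14, 0.1, 50.0, sigma_noise=20.0, variance_model="flat",
                          sigma_q=15.0),
            QuantalParams(3, 0.5, 200.0, v0=-20.0, sigma_noise=25.0, p_stim=0.7),
        ],
    )
    def test_integrates_to_one(self, params):
        f = lambda v: quantal.binomial_density(v, params)
        lo = params.v0 - 10 * params.sigma_noise - params.q_size
        hi = params.v0 + params.n_sites * params.q_size + 10 * (
            params.sigma_noise + params.sigma_q
        )
        val, _ = quad(f, lo, hi, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_single_site_half_p_is_symmetric_two_gaussian(self):
        p = QuantalParams(1, 0.5, 460.0, sigma_noise=30.0, sigma_q=0.0)
        d0 = quantal.binomial_density(0.0, p)
        d1 = quantal.binomial_density(460.0, p)
        assert d0 == pytest.approx(d1, rel=1e-9)
        mid = quantal.binomial_density(0.0 + 15.0, p)
        assert mid == pytest.approx(quantal.binomial_density(460.0 - 15.0, p), rel=1e-9)

    def test_nonfinite_input_rejected(self):
        p = QuantalParams(2, 0.5, 100.0, sigma_noise=10.0)
        with pytest.raises(ParameterError):
            quantal.binomial_density(np.array([np.nan]), p)


class TestMoments:
    def test_closed_form_values(self):
        mean, sd = quantal.moments(QuantalParams(5, 0.5, 460.0, sigma_noise=1.0))
        assert mean == pytest.approx(1150.0)
        assert sd == pytest.approx(460.0 * np.sqrt(1.25))  # ~514.3

    def test_degenerate_corners(self):
        _, sd = quantal.moments(QuantalParams(5, 1.0, 460.0))
        assert sd == 0.0
        mean, _ = quantal.moments(QuantalParams(5, 0.0, 460.0))
        assert mean == 0.0

    def test_true_params_beat_perturbed_on_large_samples(self, quantal_truth):
        amps = synthetic.simulate_quantal_amplitudes(quantal_truth, 5000, seed=5)
        ll_true = quantal.log_likelihood(amps, quantal_truth)
        for factor in (0.8, 1.2):
            perturbed = QuantalParams(
                5, 0.5, 460.0 * factor, sigma_noise=30.0
            )
            assert ll_true > quantal.log_likelihood(amps, perturbed)


class TestFit:
    def test_parameter_recovery_single_dataset(self, quantal_truth):
        amps = synthetic.simulate_quantal_amplitudes(quantal_truth, 150, seed=42)
        fit = quantal.fit_quantal(amps, noise_sd=30.0, seed=0)
        assert fit.converged and not fit.excluded
        assert fit.params.q_size == pytest.approx(460.0, rel=0.15)
        assert abs(fit.params.n_sites - 5) <= 1

    def test_pure_noise_sample_flagged_unidentifiable(self, rng):
        amps = rng.normal(0.0, 30.0, 60)
        with pytest.warns(UserWarning):
            fit = quantal.fit_quantal(amps[:25], noise_sd=30.0, seed=1)
        fit = quantal.fit_quantal(amps, noise_sd=30.0, seed=1)
        assert fit.excluded and "unidentifiable" in fit.excluded_reason

    def test_boundary_site_count_discarded(self):
        """A fit that lands on the 14-site cap is flagged as unresolved."""
        truth = QuantalParams(14, 0.5, 460.0, sigma_noise=30.0)
        amps = synthetic.simulate_quantal_amplitudes(truth, 200, seed=2)
        fit = quantal.fit_quantal(amps, noise_sd=30.0, n_min=14, seed=2)
        assert fit.params.n_sites == 14
        assert fit.excluded and "cap" in fit.excluded_reason

    def test_unit_rescaling_invariance(self, quantal_truth):
        """Fitting in mV instead of µV rescales q by the same factor."""
        amps = synthetic.simulate_quantal_amplitudes(quantal_truth, 150, seed=3)
        fit_uv = quantal.fit_quantal(amps, noise_sd=30.0, seed=0)
        fit_mv = quantal.fit_quantal(amps / 1000.0, noise_sd=0.03, seed=0)
        assert fit_mv.params.n_sites == fit_uv.params.n_sites
        assert fit_mv.params.q_size * 1000.0 == pytest.approx(
            fit_uv.params.q_size, rel=0.02
        )


class TestGof:
    def test_zero_sims_errors(self, quantal_truth):
        fit = quantal.QuantalFit(quantal_truth, 0.0, [])
        with pytest.raises(ParameterError):
            quantal.gof_monte_carlo(fit, np.zeros(50), n_sims=0)

    def test_well_specified_model_not_rejected(self, quantal_truth):
        amps = synthetic.simulate_quantal_amplitudes(quantal_truth, 200, seed=6)
        fit = quantal.QuantalFit(quantal_truth, 0.0, [])
        p = quantal.gof_monte_carlo(fit, amps, n_sims=300, seed=1)
        assert p > 0.05

    def test_gross_misfit_rejected(self, quantal_truth):
        """Data from a model with doubled q: chi^2 p-value collapses."""
        wrong = QuantalParams(5, 0.5, 920.0, sigma_noise=30.0)
        rejections = 0
        for s in range(10):
            amps = synthetic.simulate_quantal_amplitudes(quantal_truth, 200, seed=60 + s)
            fit = quantal.QuantalFit(wrong, 0.0, [])
            if quantal.gof_monte_carlo(fit, amps, n_sims=200, seed=s) < 0.05:
                rejections += 1
        assert rejections >= 9

    def test_calibration_near_nominal(self, quantal_truth):
        """Simulating from the tested model itself: ~5% rejections at alpha=.05."""
        rejections = 0
        n_rep = 60
        for s in range(n_rep):
            amps = synthetic.simulate_quantal_amplitudes(quantal_truth, 150, seed=900 + s)
            fit = quantal.QuantalFit(quantal_truth, 0.0, [])
            if quantal.gof_monte_carlo(fit, amps, n_sims=200, seed=s) < 0.05:
                rejections += 1
        # binomial(60, .05): >9 rejections has probability < 1e-3
        assert rejections <= 9


class TestStability:
    def test_stationary_series_kept(self):
        res = quantal.stability_filter(np.full(40, 400.0))
        assert res.keep and res.drift == 0.0

    def test_run_down_excluded(self):
        series = np.concatenate([np.full(20, 400.0), np.full(20, 200.0)])
        res = quantal.stability_filter(series)
        assert not res.keep
        assert res.drift == pytest.approx(0.5)

    def test_exact_30pct_boundary_kept(self):
        series = np.concatenate([np.full(10, 100.0), np.full(10, 70.0)])
        res = quantal.stability_filter(series)
        assert res.keep  # strict '>' at the 30% boundary
        assert res.drift == pytest.approx(0.30)

    def test_too_few_trials_not_evaluable(self):
        res = quantal.stability_filter(np.full(10, 400.0))
        assert not res.evaluable and res.keep

    def test_literal_first_trial_reading(self):
        series = np.concatenate([[200.0], np.full(39, 100.0)])
        # literal first trial: |200 - 100| / 200 = 50% -> exclude
        assert not quantal.stability_filter(series, reference="first").keep
        # first-ten mean = 110: |110 - 100| / 110 ~ 9% -> keep
        default = quantal.stability_filter(series)
        assert default.keep
        assert default.drift == pytest.approx(10 / 110)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    n=st.integers(1, 14),
    p=st.floats(0.05, 0.95),
    q=st.floats(50.0, 1000.0),
    sq=st.floats(0.0, 50.0),
)
def test_density_normalization_property(n, p, q, sq):
    """The mixture density integrates to ~1 across the parameter space."""
    params = QuantalParams(n, p, q, sigma_noise=25.0, sigma_q=sq)
    grid = np.linspace(-500.0, n * q + 500.0, 6000)
    mass = np.trapezoid(quantal.binomial_density(grid, params), grid)
    assert mass == pytest.approx(1.0, abs=1e-4)
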