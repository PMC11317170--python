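"""Unit and property tests for the empirical force-extension model."""

import numpy as np
import pytest

from dnamech import (
    EmpiricalParams,
    ForceExtensionCurve,
    eval_empirical,
    fit_empirical,
    init_empirical_params,
    overstretch_metrics,
)
from dnamech.errors import (
    InitializationError,
    InvalidParameterError,
    PoleError,
)
from dnamech.synthetic_data import SimulationConfig, gen_fec_empirical


class TestCurveContainer:
    def test_sorts_and_averages_duplicates(self):
        x = np.array([3.0, 1.0, 2.0, 2.0] + list(np.linspace(4, 10, 7)))
        f = np.array([3.0, 1.0, 2.0, 4.0] + [0.0] * 7)
        fec = ForceExtensionCurve(x, f)
        assert np.all(np.diff(fec.extension) > 0)
        # the two x=2 points were averaged
        assert fec.force[np.searchsorted(fec.extension, 2.0)] == 3.0

    def test_rejects_short_curves(self):
        with pytest.raises(InvalidParameterError):
            ForceExtensionCurve(np.arange(5.0), np.arange(5.0))

    def test_rejects_non_finite_forces(self):
        x = np.linspace(0, 1, 12)
        f = np.full(12, np.nan)
        with pytest.raises(InvalidParameterError):
            ForceExtensionCurve(x, f)

    def test_rejects_negative_concentration(self):
        x = np.linspace(0, 1, 12)
        with pytest.raises(InvalidParameterError):
            ForceExtensionCurve(x, x, tmpyp=-1.0)


class TestEvalEmpirical:
    def test_sigmoid_midpoint_is_half(self, empirical_params):
        _, f1, _, _ = eval_empirical(empirical_params.p1, empirical_params,
                                     components=True)
        assert f1 == pytest.approx(0.5, abs=1e-15)

    def test_sigmoid_three_quarters_point(self, empirical_params):
        x = empirical_params.p1 + empirical_params.p2 * np.log(3.0)
        _, f1, _, _ = eval_empirical(x, empirical_params, components=True)
        assert f1 == pytest.approx(0.75, rel=1e-12)

    def test_component_values_at_25um(self):
        p = EmpiricalParams(16, 0.3, 2, 60, 32, 10)
        f4, f1, f2, f3 = eval_empirical(25.0, p, components=True)
        assert f2 == pytest.approx(110.0)
        assert f3 == pytest.approx(10.0 / 7.0)
        assert f1 == pytest.approx(1.0, abs=1e-13)
        assert f4 == pytest.approx(111.42857142857143, rel=1e-10)

    def test_pole_rejected(self, empirical_params):
        with pytest.raises(PoleError):
            eval_empirical(empirical_params.p5, empirical_params)
        with pytest.raises(PoleError):
            eval_empirical(empirical_params.p5 + 1.0, empirical_params)

    def test_bad_p2_rejected(self):
        with pytest.raises(InvalidParameterError):
            EmpiricalParams(16, -0.1, 2, 60, 32, 10)

    def test_f1_bounded_and_increasing(self, empirical_params):
        # stay within ~27 logistic widths of the midpoint, where the
        # sigmoid is strictly inside (0, 1) in double precision
        p = empirical_params
        x = np.linspace(p.p1 - 8.0, p.p1 + 8.0, 4001)
        _, f1, _, _ = eval_empirical(x, empirical_params, components=True)
        assert np.all(f1 > 0) and np.all(f1 < 1)
        assert np.all(np.diff(f1) > 0)

    def test_divergence_towards_pole(self, empirical_params):
        eps = np.array([1e-2, 1e-4, 1e-6, 1e-8])
        f = eval_empirical(empirical_params.p5 - eps, empirical_params)
        assert np.all(np.diff(f) > 0)
        assert f[-1] > 1e6


class TestInitialization:
    def test_initial_guess_close_to_truth(self, empirical_params,
                                          noiseless_fec):
        init = init_empirical_params(noiseless_fec)
        assert init.p1 == pytest.approx(empirical_params.p1, rel=0.2)
        assert init.p4 == pytest.approx(empirical_params.p4, rel=0.2)

    def test_flat_curve_fails(self):
        x = np.linspace(1, 10, 50)
        with pytest.raises(InitializationError):
            init_empirical_params(ForceExtensionCurve(x, np.zeros(50)))

    def test_short_curve_fails_at_construction(self):
        with pytest.raises(InvalidParameterError):
            ForceExtensionCurve(np.linspace(0, 1, 5), np.linspace(0, 1, 5))


class TestFit:
    def test_noiseless_round_trip_random_params(self):
        """50 random parameter draws within physical bounds recover to
        <= 1e-6 relative error on noiseless 200-point curves."""
        rng = np.random.default_rng(12345)
        for _ in range(50):
            p = EmpiricalParams(
                p1=rng.uniform(14, 18), p2=rng.uniform(0.2, 0.8),
                p3=rng.uniform(1, 4), p4=rng.uniform(40, 70),
                p5=rng.uniform(28, 33), p6=rng.uniform(5, 20),
            )
            grid = np.linspace(10.0, 0.97 * p.p5, 200)
            fec = gen_fec_empirical(p, SimulationConfig(
                seed=0, force_noise_sd=0.0, extension_grid=grid))
            fit, _ = fit_empirical(fec)
            for name in ("p1", "p2", "p3", "p4", "p5", "p6"):
                assert getattr(fit, name) == pytest.approx(
                    getattr(p, name), rel=1e-6), name

    def test_noisy_residual_sd_near_noise_level(self, empirical_params):
        grid = np.linspace(10.0, 0.97 * empirical_params.p5, 200)
        fec = gen_fec_empirical(empirical_params, SimulationConfig(
            seed=42, force_noise_sd=0.37, extension_grid=grid))
        _, diag = fit_empirical(fec)
        assert 0.3 <= diag.residual_sd <= 0.45

    def test_residual_sd_converges_with_n(self, empirical_params):
        grid = np.linspace(10.0, 0.97 * empirical_params.p5, 2000)
        fec = gen_fec_empirical(empirical_params, SimulationConfig(
            seed=7, force_noise_sd=0.37, extension_grid=grid))
        _, diag = fit_empirical(fec)
        assert diag.residual_sd == pytest.approx(0.37, rel=0.10)

    def test_pole_kept_outside_data(self, empirical_params):
        # initialization proposing a pole below the data max must still
        # converge: the fitter clamps P5 into (max x, 3 max x]
        grid = np.linspace(10.0, 0.97 * empirical_params.p5, 300)
        fec = gen_fec_empirical(empirical_params, SimulationConfig(
            seed=3, force_noise_sd=0.0, extension_grid=grid))
        bad_init = EmpiricalParams(p1=16.0, p2=0.4, p3=2.0, p4=55.0,
                                   p5=grid.max() * 0.9, p6=8.0)
        fit, _ = fit_empirical(fec, init=bad_init)
        assert fit.p5 > grid.max()
        assert fit.p5 == pytest.approx(empirical_params.p5, rel=1e-4)

    def test_fit_is_deterministic(self, noiseless_fec):
        a, _ = fit_empirical(noiseless_fec)
        b, _ = fit_empirical(noiseless_fec)
        assert a == b


class TestOverstretchMetrics:
    @pytest.mark.parametrize("p3,p4,expected", [
        (2.0, 10.0, 60.0),
        (1.2, 30.5, 60.5),
    ])
    def test_plateau_height(self, p3, p4, expected):
        p = EmpiricalParams(16, 0.3, p3, p4, 32, 10)
        m = overstretch_metrics(p)
        assert m.plateau_height_at_25um == pytest.approx(expected)
        assert m.plateau_slope == p3
        assert m.cooperativity_proxy == pytest.approx(1.0 / p3)

    def test_zero_slope_gives_infinite_cooperativity(self):
        p = EmpiricalParams(16, 0.3, 0.0, 60, 32, 10)
        assert overstretch_metrics(p).cooperativity_proxy == np.inf

    def test_pole_below_reference_extension(self):
        p = EmpiricalParams(16, 0.3, 2, 60, 24.0, 10)
        with pytest.raises(PoleError):
            overstretch_metrics(p)
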