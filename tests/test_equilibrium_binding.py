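"""Tests for ΔL extraction, isotherm fitting and concentration analysis."""

import numpy as np
import pytest

from dnamech import (
    DeltaLCurve,
    ForceExtensionCurve,
    IsothermParams,
    PolymerParams,
    ThermalConstants,
    delta_length_curve,
    ewlc_force,
    fit_double_exponential,
    fit_isotherm,
    isotherm_delta_length,
    length_at_force,
    zero_force_lengthening,
)
from dnamech.equilibrium_binding import double_exponential
from dnamech.errors import CoverageError, ReadoutError, UnderdeterminedError


@pytest.fixture
def printed_equilibrium_params():
    """Equilibrium binding parameters reported for 0.1 M NaCl."""
    return IsothermParams(dx_eq_nm=0.64, n=4.0, k0_per_m=4.6e5)


class TestLengthAtForce:
    def test_linear_curve(self):
        x = np.linspace(0.0, 1.0, 50)
        fec = ForceExtensionCurve(x, 10.0 * x)
        assert length_at_force(fec, 5.0) == pytest.approx(0.5)

    def test_below_range_raises(self):
        x = np.linspace(0.1, 1.0, 50)
        fec = ForceExtensionCurve(x, 10.0 * x)
        with pytest.raises(ReadoutError):
            length_at_force(fec, 0.5)

    def test_inverse_of_ewlc_forward_model(self, dsdna_params, thermal):
        z = np.linspace(5.0, 16.3, 400)
        fec = ForceExtensionCurve(z, ewlc_force(z, dsdna_params, thermal))
        z10 = length_at_force(fec, 10.0)
        assert ewlc_force(z10, dsdna_params, thermal) == pytest.approx(
            10.0, rel=1e-3)


class TestDeltaLengthCurve:
    def _curve(self, shift=0.0, tmpyp=0.0):
        x = np.linspace(1.0, 20.0, 300) + shift
        f = np.linspace(0.5, 25.0, 300)
        return ForceExtensionCurve(x, f, tmpyp=tmpyp)

    def test_identical_curves_zero(self):
        dl = delta_length_curve(self._curve(), self._curve())
        assert np.allclose(dl.delta_l, 0.0, atol=1e-12)

    def test_uniform_shift(self):
        dl = delta_length_curve(self._curve(shift=1.0, tmpyp=100.0),
                                self._curve())
        assert np.allclose(dl.delta_l, 1.0, atol=1e-12)
        assert dl.tmpyp == 100.0

    def test_explicit_grid_coverage_error(self):
        with pytest.raises(CoverageError):
            delta_length_curve(self._curve(), self._curve(),
                               force_grid=[0.0, 10.0, 30.0])

    def test_matches_isotherm_generator(self, printed_equilibrium_params,
                                        dsdna_params, thermal):
        # treated curve built by shifting the control per the isotherm
        z = np.linspace(5.0, 16.3, 2000)
        f = ewlc_force(z, dsdna_params, thermal)
        control = ForceExtensionCurve(z, f)
        shift = isotherm_delta_length(f, printed_equilibrium_params, 100.0,
                                      thermal)
        treated = ForceExtensionCurve(z + shift, f, tmpyp=100.0)
        grid = np.arange(2.0, 16.0)
        dl = delta_length_curve(treated, control, grid)
        expected = isotherm_delta_length(grid, printed_equilibrium_params,
                                         100.0, thermal)
        assert np.allclose(dl.delta_l, expected, rtol=5e-3, atol=2e-3)


class TestIsotherm:
    def test_saturation_limit(self, printed_equilibrium_params):
        # ΔL_max = Δx_eq Nbp / n
        assert printed_equilibrium_params.delta_l_max_um == pytest.approx(
            7.76, abs=0.005)
        high_f = isotherm_delta_length(1e4, printed_equilibrium_params, 100.0)
        assert high_f == pytest.approx(
            printed_equilibrium_params.delta_l_max_um, rel=1e-9)

    def test_zero_force_intercept(self, printed_equilibrium_params):
        # n K0 C = 4 * 4.6e5 * 100e-9 = 0.184 -> ΔL(0) ≈ 1.206 μm
        dl0 = isotherm_delta_length(0.0, printed_equilibrium_params, 100.0)
        assert dl0 == pytest.approx(1.206, abs=0.002)

    def test_limits_in_concentration(self, printed_equilibrium_params):
        assert isotherm_delta_length(0.0, printed_equilibrium_params, 0.0) == 0.0
        big = isotherm_delta_length(0.0, printed_equilibrium_params, 1e12)
        assert big == pytest.approx(printed_equilibrium_params.delta_l_max_um,
                                    rel=1e-3)

    def test_monotone_in_force_and_concentration(self,
                                                 printed_equilibrium_params):
        F = np.linspace(0.0, 60.0, 100)
        for conc in (5.0, 100.0, 1000.0):
            y = isotherm_delta_length(F, printed_equilibrium_params, conc)
            assert np.all(np.diff(y) > 0)
        concs = np.logspace(0, 4, 50)
        y = np.array([isotherm_delta_length(10.0, printed_equilibrium_params,
                                            ci) for ci in concs])
        assert np.all(np.diff(y) > 0)

    def test_noiseless_round_trip(self, printed_equilibrium_params, thermal):
        F = np.arange(1.0, 21.0)
        y = isotherm_delta_length(F, printed_equilibrium_params, 100.0, thermal)
        fit, report = fit_isotherm(DeltaLCurve(F, y, tmpyp=100.0), thermal)
        assert fit.dx_eq_nm == pytest.approx(0.64, rel=1e-4)
        assert fit.n == pytest.approx(4.0, rel=1e-4)
        assert fit.k0_per_m == pytest.approx(4.6e5, rel=1e-4)
        assert not report.flags

    def test_k0_recovery_under_noise(self, printed_equilibrium_params,
                                     thermal):
        """Median K0 error over 100 seeded replicates stays below 25%
        (20 force points, 0.05 μm ΔL noise)."""
        F = np.arange(1.0, 21.0)
        clean = isotherm_delta_length(F, printed_equilibrium_params, 100.0,
                                      thermal)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            dl = DeltaLCurve(F, clean + rng.normal(0, 0.05, F.size),
                             tmpyp=100.0)
            fit, _ = fit_isotherm(dl, thermal)
            errs.append(abs(fit.k0_per_m / 4.6e5 - 1.0))
        assert np.median(errs) < 0.25

    def test_all_zero_curve_flagged(self, thermal):
        dl = DeltaLCurve(np.arange(1.0, 11.0), np.zeros(10), tmpyp=100.0)
        _, report = fit_isotherm(dl, thermal)
        assert "degenerate_all_zero" in report.flags

    def test_zero_force_lengthening_from_fits(self, printed_equilibrium_params):
        out = zero_force_lengthening([(100.0, printed_equilibrium_params)])
        assert out[100.0] == pytest.approx(1.206, abs=0.002)


class TestDoubleExponential:
    CONCS = np.array([5, 10, 20, 40, 80, 160, 320, 640, 1280, 2560], float)

    def test_noiseless_round_trip(self):
        from dnamech import DoubleExpParams

        truth = DoubleExpParams(1.0, 20.0, 3.0, 800.0)
        y = double_exponential(self.CONCS, truth)
        fit, report = fit_double_exponential(self.CONCS, y)
        assert fit.a_fast_um == pytest.approx(1.0, rel=1e-3)
        assert fit.c_fast_nm == pytest.approx(20.0, rel=1e-3)
        assert fit.a_slow_um == pytest.approx(3.0, rel=1e-3)
        assert fit.c_slow_nm == pytest.approx(800.0, rel=1e-3)
        assert fit.c_fast_nm < fit.c_slow_nm
        assert not report.flags

    def test_single_exponential_flagged_or_degenerate(self):
        y = 2.0 * (1.0 - np.exp(-self.CONCS / 100.0))
        fit, report = fit_double_exponential(self.CONCS, y)
        assert ("ill_conditioned" in report.flags
                or min(fit.a_fast_um, fit.a_slow_um) < 1e-3)

    def test_zero_at_zero_concentration(self):
        from dnamech import DoubleExpParams

        truth = DoubleExpParams(1.0, 20.0, 3.0, 800.0)
        assert double_exponential(0.0, truth) == 0.0

    def test_too_few_concentrations(self):
        with pytest.raises(UnderdeterminedError):
            fit_double_exponential([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
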