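"""Tests for trace segmentation, rate extraction and rate decomposition."""

import numpy as np
import pytest

from dnamech import (
    BellParams,
    KineticTrace,
    LinearRateParams,
    RatePoint,
    ThermalConstants,
    bell_rate,
    decompose_rates,
    fit_bell,
    fit_monoexponential,
    segment_trace,
)
from dnamech.errors import SegmentationError, UnderdeterminedError
from dnamech.synthetic_data import SimulationConfig, gen_kinetic_trace


def _staircase_trace(n_steps=12, dt=0.002, step_s=1.0, step_pn=5.0):
    """Unlabeled force staircase with instantaneous 5 pN steps."""
    per = int(step_s / dt)
    t = dt * np.arange(n_steps * per)
    f = step_pn * (1 + np.repeat(np.arange(n_steps), per)).astype(float)
    L = 15.0 + 0.01 * f
    return KineticTrace(time=t, length=L, force=f, protocol="force_jump")


class TestSegmentation:
    def test_staircase_yields_all_windows(self):
        tr = _staircase_trace(n_steps=12)
        windows = segment_trace(tr, settle=0.05)
        assert len(windows) == 12
        # transitions are at t = k * 1.0 s; start boundaries within one
        # sample (+settle) of truth
        for k, w in enumerate(windows):
            expected = k * 1.0 + (0.05 if k > 0 else 0.0)
            assert abs(w.t_start - expected) <= 0.002 + 1e-9 + 0.05 * (k == 0)

    def test_constant_force_raises(self):
        t = np.linspace(0, 10, 1000)
        tr = KineticTrace(time=t, length=np.full(t.size, 15.0),
                          force=np.full(t.size, 20.0))
        with pytest.raises(SegmentationError):
            segment_trace(tr)

    def test_label_passthrough(self):
        t = np.linspace(0, 4, 2001)
        labels = np.where(t < 2.0, "zero_tmpyp", "high_tmpyp")
        tr = KineticTrace(time=t, length=np.zeros(t.size) + 15,
                          force=np.full(t.size, 20.0), phase=labels,
                          protocol="concentration_jump")
        windows = segment_trace(tr, settle=0.3)
        assert [w.label for w in windows] == ["zero_tmpyp", "high_tmpyp"]
        assert windows[1].t_start == pytest.approx(2.0 + 0.3, abs=0.01)


class TestMonoExponential:
    def test_exact_recovery_noiseless(self):
        t = np.linspace(0, 3, 200)
        L = 16.0 - 0.5 * np.exp(-2.0 * t)
        fit = fit_monoexponential(t, L)
        assert fit.rate == pytest.approx(2.0, rel=1e-6)
        assert fit.asymptote == pytest.approx(16.0, rel=1e-9)
        assert not fit.unreliable

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(123)
        t = np.linspace(0, 5, 500)
        L = 16.0 - 0.5 * np.exp(-1.0 * t) + rng.normal(0, 0.01, t.size)
        fit = fit_monoexponential(t, L)
        assert fit.rate == pytest.approx(1.0, rel=0.05)

    def test_constant_trace_flagged(self):
        t = np.linspace(0, 5, 100)
        rng = np.random.default_rng(5)
        fit = fit_monoexponential(t, 15.0 + rng.normal(0, 1e-4, t.size))
        assert fit.unreliable
        assert abs(fit.amplitude) < 1e-3

    def test_short_observation_flagged(self):
        # k * duration << 0.2: the decay is barely sampled
        t = np.linspace(0, 0.05, 60)
        L = 16.0 - 0.5 * np.exp(-0.5 * t)
        fit = fit_monoexponential(t, L)
        assert fit.unreliable


class TestBell:
    def test_zero_force_rate_is_k0(self, thermal):
        p = BellParams(k0=7.1, dx_nm=0.2)
        assert bell_rate(0.0, p, thermal) == pytest.approx(7.1)

    def test_scalar_evaluation_at_one_thermal_length(self, thermal):
        # F Δx = kBT at F = 20.57 pN, Δx = 0.2 nm -> k = k0 * e
        p = BellParams(k0=7.1, dx_nm=0.2)
        assert bell_rate(20.57, p, thermal) == pytest.approx(19.30, abs=0.01)

    def test_round_trip(self, thermal):
        truth = BellParams(k0=3.0, dx_nm=0.5)
        F = np.arange(5.0, 45.0, 5.0)
        pts = [RatePoint(f, bell_rate(f, truth, thermal)) for f in F]
        fit, _ = fit_bell(pts, thermal)
        assert fit.k0 == pytest.approx(3.0, rel=1e-6)
        assert fit.dx_nm == pytest.approx(0.5, rel=1e-6)

    def test_negative_distance_allowed(self, thermal):
        # rates that slow down with force (dissociation under load)
        truth = BellParams(k0=0.9, dx_nm=-0.3)
        F = np.arange(10.0, 55.0, 10.0)
        pts = [RatePoint(f, bell_rate(f, truth, thermal)) for f in F]
        fit, _ = fit_bell(pts, thermal)
        assert fit.dx_nm == pytest.approx(-0.3, rel=1e-6)

    def test_scale_equivariance(self, thermal):
        truth = BellParams(k0=2.0, dx_nm=0.4)
        F = np.arange(5.0, 45.0, 5.0)
        rng = np.random.default_rng(9)
        noisy = bell_rate(F, truth, thermal) * np.exp(
            rng.normal(0, 0.1, F.size))
        base, _ = fit_bell([RatePoint(f, k) for f, k in zip(F, noisy)],
                           thermal)
        scaled, _ = fit_bell([RatePoint(f, 3.0 * k)
                              for f, k in zip(F, noisy)], thermal)
        assert scaled.k0 == pytest.approx(3.0 * base.k0, rel=1e-6)
        assert scaled.dx_nm == pytest.approx(base.dx_nm, rel=1e-6)

    def test_insufficient_span_rejected(self, thermal):
        pts = [RatePoint(f, 1.0) for f in (5.0, 10.0, 15.0)]
        with pytest.raises(Exception):
            fit_bell(pts, thermal)


class TestDecomposeRates:
    def test_force_jump_printed_rates(self):
        # zero-force rates 7.1 s^-1 at 5 nM and 57.9 s^-1 at 80 nM
        params, _ = decompose_rates([(5.0, 7.1), (80.0, 57.9)])
        assert params.k_on == pytest.approx(0.68, abs=0.005)
        assert params.k_off == pytest.approx(3.7, abs=0.05)

    def test_concentration_jump_printed_rates(self):
        params, _ = decompose_rates([(5.0, 0.85), (80.0, 1.01)])
        assert params.k_on == pytest.approx(0.002, abs=5e-4)
        assert params.k_off == pytest.approx(0.84, abs=0.005)

    def test_identical_rates(self):
        params, _ = decompose_rates([(5.0, 2.5), (80.0, 2.5)])
        assert params.k_on == 0.0
        assert params.k_off == pytest.approx(2.5)

    def test_single_concentration_rejected(self):
        with pytest.raises(UnderdeterminedError):
            decompose_rates([(5.0, 7.1), (5.0, 7.3)])

    def test_two_points_exact_line(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = np.sort(rng.uniform(1, 100, 2))
            k = rng.uniform(0.1, 50, 2)
            params, diag = decompose_rates(list(zip(c, k)))
            slope = (k[1] - k[0]) / (c[1] - c[0])
            assert params.k_on == pytest.approx(max(slope, slope), rel=1e-12)
            assert diag["r_squared"] == 1.0


class TestEndToEnd:
    def test_pipeline_recovers_generating_rates(self, thermal):
        """segment -> mono-exponential -> Bell -> linear decomposition
        recovers k_on and k_off within 15% (median over 50 seeds)."""
        truth = LinearRateParams(k_on=0.68, k_off=3.7)
        forces = list(range(5, 45, 5))

        def one_seed(seed):
            k0s = []
            for i, conc in enumerate((5.0, 80.0)):
                tr = gen_kinetic_trace(
                    "force_jump", truth, 0.2, conc, forces,
                    SimulationConfig(seed=seed * 10 + i))
                pts = []
                for w in segment_trace(tr, settle=0.03):
                    t, L, F = w.select(tr)
                    if t.size < 10:
                        continue
                    fit = fit_monoexponential(t, L)
                    if not fit.unreliable:
                        pts.append(RatePoint(float(np.median(F)), fit.rate,
                                             fit.se_rate))
                bell, _ = fit_bell(pts, thermal)
                k0s.append((conc, bell.k0))
            lin, _ = decompose_rates(k0s)
            return lin

        results = [one_seed(s) for s in range(50)]
        kon_err = np.median([abs(r.k_on / 0.68 - 1.0) for r in results])
        koff_err = np.median([abs(r.k_off / 3.7 - 1.0) for r in results])
        assert kon_err < 0.15
        assert koff_err < 0.15
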