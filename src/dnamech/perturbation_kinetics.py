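"""Perturbation-kinetics analysis: force jumps and concentration jumps.

After a sudden change of force or ligand concentration, the DNA length
relaxes mono-exponentially towards its new equilibrium,
``L(t) = L_inf - ΔL * exp(-k_obs t)``.  The observed rate depends on
force through the Bell relation

.. math:: k_{obs}(F) = k_0 \\, e^{F \\Delta x / k_B T}

(Δx may be negative for rates that slow down under load), and the
zero-force rate depends linearly on ligand concentration,

.. math:: k_0 = k_{on} [L] + k_{off}

so that an ordinary least-squares line through k0-vs-concentration data
decomposes the kinetics into the bimolecular association rate k_on
(1/(nM·s)) and the dissociation rate k_off (1/s).  At zero ligand the
observed rate is k_off alone; at high ligand it is k_on[L] + k_off.

Trace segmentation finds the constant-condition windows of a recording,
either from explicit phase labels or by detecting force steps (a change
above 2 pN within 100 ms), and discards a settle time after each
transition because only data collected after force/stage stabilization
report on the reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import lmfit
import numpy as np
from scipy import stats

from ._optim import fit_converged
from .constants import ThermalConstants
from .errors import (
    ConvergenceError,
    DomainError,
    InvalidParameterError,
    SegmentationError,
    UnderdeterminedError,
)

__all__ = [
    "KineticTrace",
    "RatePoint",
    "BellParams",
    "LinearRateParams",
    "PhaseWindow",
    "MonoExpFit",
    "segment_trace",
    "fit_monoexponential",
    "fit_bell",
    "decompose_rates",
    "bell_rate",
]

#: Step-detection threshold: force change (pN) within the lookback time (s).
STEP_THRESHOLD_PN = 2.0
STEP_LOOKBACK_S = 0.1

#: Default settle exclusions after a transition (s).
SETTLE_FORCE_JUMP_S = 0.05
SETTLE_CONC_JUMP_S = 0.3


@dataclass(frozen=True)
class KineticTrace:
    """Time-resolved length/force record of one perturbation experiment."""

    time: np.ndarray  # s, strictly increasing
    length: np.ndarray  # μm
    force: np.ndarray  # pN
    phase: Optional[np.ndarray] = None  # per-sample labels
    tmpyp: float = 0.0  # nM
    protocol: str = "force_jump"  # or "concentration_jump"

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        L = np.asarray(self.length, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if not (t.size == L.size == f.size):
            raise InvalidParameterError("time/length/force lengths differ")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("time must be strictly increasing")
        if self.protocol not in ("force_jump", "concentration_jump"):
            raise InvalidParameterError(f"unknown protocol {self.protocol!r}")
        ph = self.phase
        if ph is not None:
            ph = np.asarray(ph)
            if ph.size != t.size:
                raise InvalidParameterError("phase labels length differs")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "length", L)
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "phase", ph)


@dataclass(frozen=True)
class RatePoint:
    force: float  # pN
    k_obs: float  # 1/s
    se: float = float("nan")  # 1/s

    def __post_init__(self):
        if not self.k_obs > 0:
            raise DomainError(f"k_obs must be > 0, got {self.k_obs}")


@dataclass(frozen=True)
class BellParams:
    k0: float  # 1/s
    dx_nm: float  # apparent length change; may be negative

    def __post_init__(self):
        if not self.k0 > 0:
            raise DomainError(f"k0 must be > 0, got {self.k0}")


@dataclass(frozen=True)
class LinearRateParams:
    k_on: float  # 1/(nM·s)
    k_off: float  # 1/s


@dataclass(frozen=True)
class PhaseWindow:
    label: str
    t_start: float
    t_end: float

    def select(self, tr: KineticTrace):
        """(t, L, F) arrays of the trace samples inside this window."""
        m = (tr.time >= self.t_start) & (tr.time <= self.t_end)
        return tr.time[m], tr.length[m], tr.force[m]


@dataclass(frozen=True)
class MonoExpFit:
    rate: float  # 1/s
    amplitude: float  # μm (signed: L_inf - L(0))
    asymptote: float  # μm
    se_rate: float
    residual_sd: float
    unreliable: bool = False


def _label_runs(labels: np.ndarray) -> List[Tuple[int, int]]:
    """(start, stop) index pairs of runs of equal consecutive labels."""
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return list(zip(starts, stops))


def segment_trace(tr: KineticTrace, settle: Optional[float] = None
                  ) -> List[PhaseWindow]:
    """Constant-condition windows of a kinetic trace.

    Uses explicit phase labels when present; otherwise detects force
    steps (> 2 pN change within 100 ms).  Each window starts ``settle``
    seconds after its transition (the first window starts at the trace
    start).  Defaults: 0.05 s for force jumps, 0.3 s for concentration
    jumps.

    Raises
    ------
    SegmentationError
        No labels and no detectable transitions.
    """
    if settle is None:
        settle = (SETTLE_FORCE_JUMP_S if tr.protocol == "force_jump"
                  else SETTLE_CONC_JUMP_S)
    t = tr.time
    if tr.phase is not None and np.unique(tr.phase).size > 1:
        runs = _label_runs(tr.phase)
        windows = []
        for a, b in runs:
            # every labeled run starts at a transition into that phase,
            # including the first (the recording begins with its ramp)
            t0 = t[a] + settle
            t1 = t[b - 1]
            if t1 > t0:
                windows.append(PhaseWindow(str(tr.phase[a]), float(t0), float(t1)))
        if not windows:
            raise SegmentationError("all label runs shorter than the settle time")
        return windows

    # step detection on force
    f = tr.force
    dt = np.median(np.diff(t))
    look = max(1, int(round(STEP_LOOKBACK_S / dt)))
    jump = np.zeros(t.size, dtype=bool)
    jump[look:] = np.abs(f[look:] - f[:-look]) > STEP_THRESHOLD_PN
    if not jump.any():
        raise SegmentationError("no force transitions detected")
    # collapse contiguous flagged stretches into transitions; the settle
    # clock of each window starts at the first flagged sample (step onset)
    idx = np.flatnonzero(jump)
    coarse = idx[np.concatenate(([True], np.diff(idx) > 1))]
    # refine each onset: the threshold crossing lags the true step start
    # by up to one lookback window, so backtrack to where the force first
    # left its pre-step baseline
    onset = []
    for o in coarse:
        base_lo = max(0, o - 2 * look)
        base_hi = max(base_lo + 1, o - look)
        baseline = np.median(f[base_lo:base_hi])
        j0 = max(1, o - look)
        moved = np.flatnonzero(np.abs(f[j0:o + 1] - baseline) > 0.5)
        onset.append(int(j0 + moved[0]) if moved.size else int(o))
    starts = [0] + onset
    stops = onset + [t.size]
    windows = []
    for i, (a, b) in enumerate(zip(starts, stops)):
        if b - a < 2:
            continue
        t0 = t[a] + (settle if i > 0 else 0.0)
        t1 = t[b - 1]
        if t1 <= t0:
            continue
        seg_t, seg_f = t[a:b], f[a:b]
        setpoint = np.median(seg_f[seg_t >= t0])
        windows.append(PhaseWindow(f"F={setpoint:.1f}pN", float(t0), float(t1)))
    if not windows:
        raise SegmentationError("no usable windows after settle exclusion")
    return windows


def fit_monoexponential(t: Sequence[float], L: Sequence[float]
                        ) -> MonoExpFit:
    """Fit ``L(t) = L_inf - ΔL exp(-k (t - t0))`` to a relaxation.

    Initialization: the asymptote from the mean of the last 10% of
    points, the rate from a log-linear fit of the residual decay.  The
    result is flagged ``unreliable`` when the optimizer fails, when the
    observed span covers less than 0.2 relaxation times, or when the
    amplitude is indistinguishable from the residual noise.
    """
    t = np.asarray(t, dtype=float)
    L = np.asarray(L, dtype=float)
    if t.size < 10:
        raise InvalidParameterError("need >= 10 points for a rate fit")
    ts = t - t[0]
    duration = ts[-1]
    n_tail = max(1, t.size // 10)
    linf0 = float(np.mean(L[-n_tail:]))
    amp0 = linf0 - float(L[0])
    resid0 = np.abs(linf0 - L)
    floor = max(1e-12, 0.05 * max(abs(amp0), 1e-12))
    mask = resid0 > floor
    mask[int(0.8 * t.size):] = False  # tail is asymptote-noise dominated
    if mask.sum() >= 3 and abs(amp0) > 0:
        slope, _, _, _, _ = stats.linregress(ts[mask], np.log(resid0[mask]))
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(duration, 1e-9)

    pars = lmfit.Parameters()
    pars.add("k", value=k0, min=1e-9)
    pars.add("amp", value=amp0 if amp0 != 0 else 1e-6)
    pars.add("linf", value=linf0)

    def residual(pars):
        v = pars.valuesdict()
        return v["linf"] - v["amp"] * np.exp(-v["k"] * ts) - L

    result = lmfit.minimize(residual, pars, method="leastsq",
                            max_nfev=10_000, xtol=1e-14, ftol=1e-14)
    v = result.params.valuesdict()
    r = residual(result.params)
    dof = max(r.size - result.nvarys, 1)
    resid_sd = float(np.sqrt(np.sum(r**2) / dof))
    se = result.params["k"].stderr
    unreliable = (
        (not fit_converged(result))
        or v["k"] * duration < 0.2
        or abs(v["amp"]) <= 3.0 * resid_sd
    )
    return MonoExpFit(
        rate=float(v["k"]),
        amplitude=float(v["amp"]),
        asymptote=float(v["linf"]),
        se_rate=float(se) if se is not None else float("nan"),
        residual_sd=resid_sd,
        unreliable=bool(unreliable),
    )


def bell_rate(force, p: BellParams, c: ThermalConstants = ThermalConstants()):
    """Bell-model observed rate k0*exp(F*dx/kBT) (1/s)."""
    F = np.asarray(force, dtype=float)
    out = p.k0 * np.exp(F * p.dx_nm / c.kbt)
    return out if out.ndim else float(out)


def fit_bell(points: Sequence[RatePoint],
             c: ThermalConstants = ThermalConstants()):
    """Fit the Bell relation to force-dependent observed rates.

    Requires >= 3 points spanning >= 15 pN.  Points carrying a finite
    standard error are weighted by 1/se; otherwise the fit is
    unweighted.  Initialization comes from the log-linear regression of
    ln(k_obs) on force.

    Returns
    -------
    (BellParams, dict)
        Fitted zero-force rate and distance parameter (nm; sign free),
        plus a diagnostics dict with standard errors.
    """
    F = np.array([p.force for p in points], dtype=float)
    k = np.array([p.k_obs for p in points], dtype=float)
    se = np.array([p.se for p in points], dtype=float)
    if F.size < 3:
        raise UnderdeterminedError("need >= 3 rate points")
    if F.max() - F.min() < 15.0:
        raise DomainError(
            f"rate points must span >= 15 pN, got {F.max() - F.min():.1f}"
        )
    slope, intercept, _, _, _ = stats.linregress(F, np.log(k))
    pars = lmfit.Parameters()
    pars.add("k0", value=float(np.exp(intercept)), min=1e-12)
    pars.add("dx", value=float(slope * c.kbt))
    w = np.where(np.isfinite(se) & (se > 0), 1.0 / se, np.nan)
    weights = w if np.all(np.isfinite(w)) else np.ones_like(k)

    def residual(pars):
        v = pars.valuesdict()
        return (v["k0"] * np.exp(F * v["dx"] / c.kbt) - k) * weights

    result = lmfit.minimize(residual, pars, method="leastsq",
                            max_nfev=10_000, xtol=1e-14, ftol=1e-14)
    if not fit_converged(result):
        raise ConvergenceError(
            f"Bell fit did not converge: {result.message}",
            last_params=result.params.valuesdict(),
        )
    v = result.params.valuesdict()
    diag = {
        "stderr": {name: (result.params[name].stderr
                          if result.params[name].stderr is not None
                          else float("nan"))
                   for name in result.params},
        "nfev": result.nfev,
        "weighted": bool(np.all(np.isfinite(w))),
    }
    return BellParams(k0=float(v["k0"]), dx_nm=float(v["dx"])), diag


def decompose_rates(k0_by_concentration: Sequence[Tuple[float, float]]):
    """Split zero-force rates into k_on and k_off by a straight line.

    Ordinary least squares of k0 against concentration (nM): the slope is
    the bimolecular association rate k_on (1/(nM·s)), the intercept the
    dissociation rate k_off (1/s).  With exactly two points the line is
    exact.  Tiny negative estimates (numerical noise) are clipped to 0;
    materially negative ones are kept and flagged.
    """
    data = np.asarray(k0_by_concentration, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise InvalidParameterError("expected a sequence of (nM, 1/s) pairs")
    C, k0 = data[:, 0], data[:, 1]
    if np.unique(C).size < 2:
        raise UnderdeterminedError(
            "need >= 2 distinct concentrations to separate k_on from k_off"
        )
    if np.unique(C).size == 2 and C.size == 2:
        slope = (k0[1] - k0[0]) / (C[1] - C[0])
        intercept = k0[0] - slope * C[0]
        se_s = se_i = 0.0
        r2 = 1.0
    else:
        res = stats.linregress(C, k0)
        slope, intercept = res.slope, res.intercept
        se_s, se_i = res.stderr, res.intercept_stderr
        r2 = res.rvalue**2
    flags = []
    for name, val in (("k_on", slope), ("k_off", intercept)):
        if val < 0 and val > -1e-9:
            if name == "k_on":
                slope = 0.0
            else:
                intercept = 0.0
        elif val < 0:
            flags.append(f"negative_{name}")
    params = LinearRateParams(k_on=float(slope), k_off=float(intercept))
    diag = {"se_k_on": float(se_s), "se_k_off": float(se_i),
            "r_squared": float(r2), "flags": tuple(flags)}
    return params, diag
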