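"""Empirical force-extension model for overstretched dsDNA.

A measured force-extension curve (FEC) of torsionally open dsDNA shows four
regimes: entropic, enthalpic, the cooperative overstretch plateau and an
asymptotic high-force branch.  The whole curve is described here by the
product of three elementary components,

.. math::

    f_1(x) &= \\frac{1}{1 + e^{-(x - P_1)/P_2}} \\\\
    f_2(x) &= P_3 x + P_4 \\\\
    f_3(x) &= \\frac{-P_6}{x - P_5} \\\\
    f_4(x) &= f_1(x)\\,\\bigl(f_2(x) + f_3(x)\\bigr)

with extension ``x`` in μm and force in pN.  The six parameters map onto
physical features of the molecule:

* ``P1`` (μm) — sigmoid midpoint; scales with the dsDNA contour length.
* ``P2`` (μm) — sigmoid step width; scales with dsDNA compliance.
* ``P3`` (pN/μm) — plateau slope; inverse of overstretch cooperativity.
* ``P4`` (pN) — plateau intercept; scales with duplex stability.
* ``P5`` (μm) — hyperbola asymptote; maximal (ssDNA-like) length.
* ``P6`` (pN·μm) — hyperbola curvature.

The model has a pole at ``x = P5``; evaluation is only defined for
``x < P5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import lmfit
import numpy as np
from scipy.special import expit

from ._optim import fit_converged
from .errors import (
    ConvergenceError,
    InitializationError,
    InvalidParameterError,
    PoleError,
)

__all__ = [
    "ForceExtensionCurve",
    "EmpiricalParams",
    "OverstretchMetrics",
    "FitDiagnostics",
    "eval_empirical",
    "init_empirical_params",
    "fit_empirical",
    "overstretch_metrics",
]


@dataclass(frozen=True)
class ForceExtensionCurve:
    """A single stretch or relax force-extension record.

    Extension/force pairs are sorted ascending in extension on
    construction and duplicate extensions are averaged, so downstream
    interpolation and fitting always see a strictly increasing grid.

    Parameters
    ----------
    extension : array
        Molecular extension in μm.
    force : array
        Measured force in pN; must be finite.
    tmpyp : float
        Ligand (TMPyP) concentration in nM.
    nacl : float
        NaCl concentration in M.
    pulling_rate : float
        Trap/stage speed in μm/s.
    direction : {"stretch", "relax"}
    label : str
        Free-text identifier.
    """

    extension: np.ndarray
    force: np.ndarray
    tmpyp: float = 0.0
    nacl: float = 0.0
    pulling_rate: float = 0.0
    direction: str = "stretch"
    label: str = ""

    def __post_init__(self):
        x = np.asarray(self.extension, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if x.ndim != 1 or f.ndim != 1 or x.size != f.size:
            raise InvalidParameterError(
                "extension and force must be 1-D arrays of equal length"
            )
        if x.size < 10:
            raise InvalidParameterError(
                f"a force-extension curve needs >= 10 points, got {x.size}"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(f))):
            raise InvalidParameterError("extension and force must be finite")
        if self.tmpyp < 0 or self.nacl < 0:
            raise InvalidParameterError("concentrations must be >= 0")
        if self.direction not in ("stretch", "relax"):
            raise InvalidParameterError(
                f"direction must be 'stretch' or 'relax', got {self.direction!r}"
            )
        order = np.argsort(x, kind="stable")
        x, f = x[order], f[order]
        # average duplicate extensions so the grid is strictly increasing
        xu, inverse = np.unique(x, return_inverse=True)
        if xu.size != x.size:
            f = np.bincount(inverse, weights=f) / np.bincount(inverse)
            x = xu
        object.__setattr__(self, "extension", x)
        object.__setattr__(self, "force", f)

    @property
    def n(self) -> int:
        return self.extension.size

    def with_force(self, force: np.ndarray) -> "ForceExtensionCurve":
        """Return a copy with the force column replaced (same grid)."""
        return replace(self, force=np.asarray(force, dtype=float))


@dataclass(frozen=True)
class EmpiricalParams:
    """The six parameters of the empirical FEC model (units in class doc)."""

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float

    def __post_init__(self):
        if not self.p1 > 0:
            raise InvalidParameterError(f"P1 must be > 0, got {self.p1}")
        if not self.p2 > 0:
            raise InvalidParameterError(f"P2 must be > 0, got {self.p2}")
        if not self.p6 > 0:
            raise InvalidParameterError(f"P6 must be > 0, got {self.p6}")

    def as_dict(self) -> dict:
        return {
            "P1": self.p1,
            "P2": self.p2,
            "P3": self.p3,
            "P4": self.p4,
            "P5": self.p5,
            "P6": self.p6,
        }


@dataclass(frozen=True)
class OverstretchMetrics:
    """Plateau-derived summary numbers of a fitted empirical model."""

    plateau_height_at_25um: float  # pN
    plateau_slope: float  # pN/μm
    cooperativity_proxy: float  # 1/(pN/μm); +inf when slope <= 0


@dataclass(frozen=True)
class FitDiagnostics:
    """Residual statistics and per-parameter uncertainties of a fit."""

    residual_sd: float  # pN
    stderr: dict = field(default_factory=dict)
    nfev: int = 0
    success: bool = True
    message: str = ""


def eval_empirical(x, p: EmpiricalParams, components: bool = False):
    """Evaluate the empirical FEC model at extension(s) ``x``.

    Parameters
    ----------
    x : float or array
        Extension in μm, strictly below the pole ``P5``.
    p : EmpiricalParams
    components : bool
        If True, return ``(f4, f1, f2, f3)`` instead of just ``f4``.

    Returns
    -------
    force in pN (``f4``), optionally with the per-component values.

    Raises
    ------
    PoleError
        If any ``x >= P5``.
    InvalidParameterError
        If ``P2 <= 0`` (guarded again here because callers may bypass the
        dataclass).
    """
    if not p.p2 > 0:
        raise InvalidParameterError(f"P2 must be > 0, got {p.p2}")
    x = np.asarray(x, dtype=float)
    if np.any(x >= p.p5):
        raise PoleError(
            f"extension must lie below the hyperbola pole P5 = {p.p5} μm"
        )
    f1 = expit((x - p.p1) / p.p2)
    f2 = p.p3 * x + p.p4
    f3 = -p.p6 / (x - p.p5)
    f4 = f1 * (f2 + f3)
    if components:
        return f4, f1, f2, f3
    return f4


def _plateau_window(fec: ForceExtensionCurve):
    """Indices of the overstretch-plateau band.

    The plateau is the flattest stretch of the curve, hence (on a
    uniform extension grid) the densest force band: take the modal force
    histogram bin between 30% and 100% of the 95th-percentile force and
    keep points within 10% of it.  Falls back to the band
    [0.8, 1.0] x 95th percentile when the histogram is too sparse.
    """
    f = fec.force
    fq = np.quantile(f, 0.95)
    cand = f[(f >= 0.3 * fq) & (f <= fq)]
    if cand.size >= 10:
        hist, edges = np.histogram(cand, bins=30)
        i = int(np.argmax(hist))
        center = 0.5 * (edges[i] + edges[i + 1])
        width = max(0.1 * abs(center), edges[1] - edges[0])
        mask = np.abs(f - center) <= width
    else:
        mask = (f >= 0.8 * fq) & (f <= fq)
    if mask.sum() < 2:
        mask = np.zeros_like(f, dtype=bool)
        mask[np.argsort(f)[-5:]] = True
    return mask, fq


def init_empirical_params(fec: ForceExtensionCurve) -> EmpiricalParams:
    """Heuristic initial guess for :func:`fit_empirical`.

    P3/P4 come from a straight line through the plateau band, P1 from the
    extension at which force first exceeds half the plateau estimate, P2
    from the 25%->75% rise width of the force front, P5 from 1.05x the
    maximal extension and P6 from the high-force residual above the
    plateau line.

    Raises
    ------
    InitializationError
        If the curve has no monotone force rise to anchor the sigmoid.
    """
    x, f = fec.extension, fec.force
    mask, fq = _plateau_window(fec)
    if fq <= 0 or (f.max() - f.min()) <= max(1e-9, 0.05 * abs(f.max())):
        raise InitializationError("curve has no monotone force rise")
    p3, p4 = np.polyfit(x[mask], f[mask], 1)
    plateau_est = float(np.median(f[mask]))
    if plateau_est <= 0:
        raise InitializationError("non-positive plateau force estimate")

    def first_crossing(level):
        above = np.flatnonzero(f > level)
        return None if above.size == 0 else x[above[0]]

    x_half = first_crossing(0.5 * plateau_est)
    if x_half is None:
        raise InitializationError("force never exceeds half the plateau estimate")
    x25 = first_crossing(0.25 * plateau_est)
    x75 = first_crossing(0.75 * plateau_est)
    if x25 is not None and x75 is not None and x75 > x25:
        p2 = (x75 - x25) / (2.0 * np.log(3.0))
    else:
        p2 = 0.05 * (x.max() - x.min())
    p2 = max(p2, 1e-3)
    p5 = 1.05 * x.max()
    p6 = (f[-1] - (p3 * x[-1] + p4)) * (p5 - x[-1])
    p6 = max(p6, 0.5)
    p1 = max(float(x_half), 1e-6)
    return EmpiricalParams(p1=p1, p2=float(p2), p3=float(p3), p4=float(p4),
                           p5=float(p5), p6=float(p6))


def fit_empirical(
    fec: ForceExtensionCurve,
    init: Optional[EmpiricalParams] = None,
    max_nfev: int = 10_000,
):
    """Fit the empirical model ``f4`` to a stretch FEC by least squares.

    Levenberg-Marquardt with lmfit's internal bound transform; bounds keep
    ``P2, P6 > 0`` and the pole ``P5`` inside ``(max extension,
    3 x max extension]`` so the hyperbola stays singular only beyond the
    data.  The fit is unweighted and deterministic for identical input and
    initialization.

    Returns
    -------
    (EmpiricalParams, FitDiagnostics)
        Best-fit parameters, residual SD in pN and per-parameter standard
        errors (where the covariance estimate exists).

    Raises
    ------
    ConvergenceError
        If the optimizer reports failure; carries the last iterate.
    """
    if init is None:
        init = init_empirical_params(fec)
    x, f = fec.extension, fec.force
    xmax = x.max()
    span = x.max() - x.min()
    pars = lmfit.Parameters()
    # the sigmoid midpoint lies inside the recorded extension range and
    # its width cannot exceed the data span, else the model degenerates
    pars.add("p1", value=float(np.clip(init.p1, x.min(), xmax)),
             min=min(x.min(), 1e-6), max=xmax)
    pars.add("p2", value=float(np.clip(init.p2, 1e-6, span)),
             min=1e-6, max=span)
    pars.add("p3", value=init.p3)
    pars.add("p4", value=init.p4)
    p5_lo = xmax * (1.0 + 1e-9)
    p5_hi = 3.0 * xmax
    pars.add("p5", value=float(np.clip(init.p5, p5_lo * (1 + 1e-6), p5_hi)),
             min=p5_lo, max=p5_hi)
    pars.add("p6", value=max(init.p6, 1e-9), min=1e-12)

    def residual(pars):
        v = pars.valuesdict()
        f1 = expit((x - v["p1"]) / v["p2"])
        f23 = v["p3"] * x + v["p4"] - v["p6"] / (x - v["p5"])
        return f1 * f23 - f

    result = lmfit.minimize(
        residual, pars, method="leastsq",
        max_nfev=max_nfev, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    values = {k: result.params[k].value for k in result.params}
    fitted = EmpiricalParams(**values)
    if not fit_converged(result):
        raise ConvergenceError(
            f"empirical fit did not converge: {result.message}",
            last_params=fitted,
        )
    r = residual(result.params)
    dof = max(r.size - result.nvarys, 1)
    diagnostics = FitDiagnostics(
        residual_sd=float(np.sqrt(np.sum(r**2) / dof)),
        stderr={k: (result.params[k].stderr if result.params[k].stderr is not None
                    else float("nan"))
                for k in result.params},
        nfev=result.nfev,
        success=bool(fit_converged(result)),
        message=str(result.message),
    )
    return fitted, diagnostics


def overstretch_metrics(p: EmpiricalParams) -> OverstretchMetrics:
    """Plateau height at 25 μm, plateau slope and cooperativity proxy.

    The plateau height is read from the linear component alone,
    ``f2(25) = 25*P3 + P4``, i.e. the overstretch-plateau line evaluated
    at the conventional 25 μm reference extension.

    Raises
    ------
    PoleError
        If the pole lies at or below 25 μm, where the reference
        extension is no longer inside the model's domain.
    """
    if 25.0 >= p.p5:
        raise PoleError(
            f"reference extension 25 μm is not below the pole P5 = {p.p5} μm"
        )
    slope = p.p3
    height = p.p3 * 25.0 + p.p4
    proxy = 1.0 / slope if slope > 0 else float("inf")
    return OverstretchMetrics(
        plateau_height_at_25um=float(height),
        plateau_slope=float(slope),
        cooperativity_proxy=float(proxy),
    )
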