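"""Ligand-induced DNA lengthening: ΔL(F) curves and binding isotherms.

The force-dependent equilibrium length change of dsDNA carrying a
multi-site intercalating ligand is

.. math::

    \\Delta L(F) = \\frac{\\Delta x_{eq} N_{bp}}{n}
        \\left(1 + \\frac{e^{-F\\Delta x_{eq}/k_BT}}{n K_0 [L]}\\right)^{-1}

with Δx_eq the length change per bound ligand (nm), n the binding-site
footprint in base pairs, K0 the zero-force affinity (1/M), Nbp the
number of base pairs and [L] the free ligand concentration (M).  ΔL is
monotone increasing in both force and concentration and saturates at
``ΔL_max = Δx_eq * Nbp / n``.

ΔL(F) data are obtained by subtracting the control (ligand-free) DNA
length from the treated length read out at the same force on the
pre-plateau monotone segment of each curve.  The concentration
dependence of ΔL at fixed force is described by a double-exponential
saturation, whose two decay constants are the characteristic fast and
slow ligand concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import lmfit
import numpy as np

from ._optim import fit_converged
from .constants import LAMBDA_PHAGE_BP, NM_PER_UM, ThermalConstants, nM_to_M
from .errors import (
    CoverageError,
    DomainError,
    ReadoutError,
    UnderdeterminedError,
)
from .fec_model import ForceExtensionCurve

__all__ = [
    "IsothermParams",
    "DeltaLCurve",
    "DoubleExpParams",
    "isotherm_delta_length",
    "double_exponential",
    "length_at_force",
    "delta_length_curve",
    "fit_isotherm",
    "zero_force_lengthening",
    "fit_double_exponential",
]

#: Default ΔL readout force grid: the low-force regime, 1 pN steps.
DEFAULT_FORCE_GRID = np.arange(0.0, 21.0)


@dataclass(frozen=True)
class IsothermParams:
    """Parameters of the multi-site binding isotherm."""

    dx_eq_nm: float  # equilibrium length change per bound ligand
    n: float  # footprint, base pairs per ligand
    k0_per_m: float  # zero-force affinity constant, 1/M
    nbp: int = LAMBDA_PHAGE_BP

    def __post_init__(self):
        if not self.dx_eq_nm > 0:
            raise DomainError(f"dx_eq must be > 0, got {self.dx_eq_nm}")
        if not self.n >= 1:
            raise DomainError(f"footprint n must be >= 1, got {self.n}")
        if not self.k0_per_m > 0:
            raise DomainError(f"K0 must be > 0, got {self.k0_per_m}")

    @property
    def delta_l_max_um(self) -> float:
        """Saturation lengthening ΔL_max = Δx_eq * Nbp / n, in μm."""
        return self.dx_eq_nm * self.nbp / self.n / NM_PER_UM


@dataclass(frozen=True)
class DeltaLCurve:
    """Length change vs force at one ligand concentration."""

    force: np.ndarray  # pN, increasing
    delta_l: np.ndarray  # μm
    tmpyp: float  # nM
    nacl: float = 0.0  # M

    def __post_init__(self):
        f = np.asarray(self.force, dtype=float)
        d = np.asarray(self.delta_l, dtype=float)
        if f.size != d.size:
            raise DomainError("force and delta_l lengths differ")
        if np.any(np.diff(f) <= 0):
            raise DomainError("forces must be strictly increasing")
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "delta_l", d)


@dataclass(frozen=True)
class DoubleExpParams:
    """Double-exponential saturation of ΔL vs ligand concentration."""

    a_fast_um: float
    c_fast_nm: float
    a_slow_um: float
    c_slow_nm: float

    def __post_init__(self):
        if self.a_fast_um < 0 or self.a_slow_um < 0:
            raise DomainError("amplitudes must be >= 0")
        if not (0 < self.c_fast_nm <= self.c_slow_nm):
            raise DomainError("need 0 < c_fast <= c_slow")


@dataclass(frozen=True)
class FitReport:
    residual_sd: float
    stderr: dict = field(default_factory=dict)
    flags: tuple = ()


def isotherm_delta_length(force, p: IsothermParams, tmpyp_nm: float,
                          c: ThermalConstants = ThermalConstants()):
    """Evaluate the binding isotherm ΔL(F) in μm.

    ``force`` in pN (scalar or array), ``tmpyp_nm`` in nM.
    """
    if tmpyp_nm <= 0:
        return np.zeros_like(np.asarray(force, dtype=float)) + 0.0
    F = np.asarray(force, dtype=float)
    conc_m = nM_to_M(tmpyp_nm)
    occ = 1.0 / (1.0 + np.exp(-F * p.dx_eq_nm / c.kbt) / (p.n * p.k0_per_m * conc_m))
    out = p.delta_l_max_um * occ
    return out if out.ndim else float(out)


def double_exponential(conc_nm, p: DoubleExpParams):
    """ΔL(C) = A_fast(1-e^{-C/c_fast}) + A_slow(1-e^{-C/c_slow}), μm."""
    C = np.asarray(conc_nm, dtype=float)
    out = (p.a_fast_um * (1.0 - np.exp(-C / p.c_fast_nm))
           + p.a_slow_um * (1.0 - np.exp(-C / p.c_slow_nm)))
    return out if out.ndim else float(out)


def _monotone_envelope(fec: ForceExtensionCurve):
    """Strict record-high force envelope: the pre-plateau monotone readout."""
    f, x = fec.force, fec.extension
    prev_max = np.maximum.accumulate(np.concatenate(([-np.inf], f[:-1])))
    keep = f > prev_max
    return f[keep], x[keep]


def length_at_force(fec: ForceExtensionCurve, force_pn: float) -> float:
    """Extension (μm) at which the curve first carries ``force_pn``.

    Linear interpolation on the strictly increasing force envelope of the
    curve (record highs), which is the monotone pre-plateau readout even
    in the presence of noise.

    Raises
    ------
    ReadoutError
        ``force_pn`` below the first or above the last envelope force.
    """
    fm, xm = _monotone_envelope(fec)
    if fm.size < 2:
        raise ReadoutError("curve has no monotone force rise")
    if not (fm[0] <= force_pn <= fm[-1]):
        raise ReadoutError(
            f"force {force_pn} pN outside monotone range "
            f"[{fm[0]:.3g}, {fm[-1]:.3g}] pN"
        )
    return float(np.interp(force_pn, fm, xm))


def delta_length_curve(
    treated: ForceExtensionCurve,
    control: ForceExtensionCurve,
    force_grid: Optional[Sequence[float]] = None,
) -> DeltaLCurve:
    """ΔL(F) = treated length - control length on a force grid.

    When ``force_grid`` is omitted, the default low-force grid (0-20 pN,
    1 pN steps) is clipped to the range both curves actually cover;
    an explicit grid must be fully covered by both curves or a
    CoverageError is raised.
    """
    strict = force_grid is not None
    if force_grid is None:
        ft, _ = _monotone_envelope(treated)
        fc, _ = _monotone_envelope(control)
        lo = max(ft[0], fc[0])
        hi = min(ft[-1], fc[-1])
        grid = DEFAULT_FORCE_GRID[(DEFAULT_FORCE_GRID >= lo)
                                  & (DEFAULT_FORCE_GRID <= hi)]
    else:
        grid = np.asarray(force_grid, dtype=float)
    if grid.size < 2:
        raise CoverageError("force grid has fewer than 2 covered points")
    dl = np.empty_like(grid)
    for i, F in enumerate(grid):
        try:
            dl[i] = length_at_force(treated, F) - length_at_force(control, F)
        except ReadoutError as err:
            if strict:
                raise CoverageError(
                    f"grid point {F} pN not covered: {err}") from err
            raise
    return DeltaLCurve(force=grid, delta_l=dl, tmpyp=treated.tmpyp,
                       nacl=treated.nacl)


def fit_isotherm(
    dl: DeltaLCurve,
    c: ThermalConstants = ThermalConstants(),
    nbp: int = LAMBDA_PHAGE_BP,
) -> Tuple[IsothermParams, FitReport]:
    """Fit the multi-site isotherm to one ΔL(F) curve.

    All three parameters float; Nbp stays fixed.  K0 is optimized on a
    log10 scale within [1e2, 1e9] 1/M, the footprint within [1, 50] bp
    and Δx_eq within (0, 2] nm.  Diagnostics flag a degenerate
    (all-zero) curve and parameters pinned at their bounds.
    """
    if dl.force.size < 5:
        raise UnderdeterminedError("need >= 5 ΔL(F) points")
    if dl.tmpyp <= 0:
        raise DomainError("isotherm fit requires tmpyp > 0")
    flags = []
    if np.allclose(dl.delta_l, 0.0):
        flags.append("degenerate_all_zero")
    pars = lmfit.Parameters()
    pars.add("dx_eq", value=0.5, min=1e-4, max=2.0)
    pars.add("n", value=4.0, min=1.0, max=50.0)
    pars.add("log10_k0", value=5.5, min=2.0, max=9.0)

    F, y = dl.force, dl.delta_l

    def residual(pars):
        v = pars.valuesdict()
        p = IsothermParams(dx_eq_nm=v["dx_eq"], n=v["n"],
                           k0_per_m=10.0 ** v["log10_k0"], nbp=nbp)
        return isotherm_delta_length(F, p, dl.tmpyp, c) - y

    result = lmfit.minimize(residual, pars, method="leastsq",
                            max_nfev=20_000, xtol=1e-14, ftol=1e-14)
    v = result.params.valuesdict()
    if not fit_converged(result):
        flags.append("non_convergence")
    for name in ("dx_eq", "n", "log10_k0"):
        par = result.params[name]
        span = par.max - par.min
        if min(par.value - par.min, par.max - par.value) < 1e-6 * span:
            flags.append(f"pinned_{name}")
    fitted = IsothermParams(dx_eq_nm=v["dx_eq"], n=v["n"],
                            k0_per_m=10.0 ** v["log10_k0"], nbp=nbp)
    r = residual(result.params)
    dof = max(r.size - result.nvarys, 1)
    report = FitReport(
        residual_sd=float(np.sqrt(np.sum(r**2) / dof)),
        stderr={k: (result.params[k].stderr if result.params[k].stderr is not None
                    else float("nan")) for k in result.params},
        flags=tuple(flags),
    )
    return fitted, report


def zero_force_lengthening(
    fits: Iterable[Tuple[float, IsothermParams]],
    c: ThermalConstants = ThermalConstants(),
) -> dict:
    """ΔL at F = 0 per concentration from fitted isotherm models.

    ``fits`` is an iterable of ``(tmpyp_nM, IsothermParams)`` pairs; the
    return value maps concentration to the model's y-axis intercept in μm.
    """
    out = {}
    for conc, params in fits:
        out[float(conc)] = float(isotherm_delta_length(0.0, params, conc, c))
    return out


def fit_double_exponential(
    concentrations_nm: Sequence[float],
    delta_l_um: Sequence[float],
) -> Tuple[DoubleExpParams, FitReport]:
    """Fit the double-exponential concentration dependence of ΔL.

    Requires >= 6 distinct concentrations.  The two components are
    ordered ``c_fast <= c_slow`` after fitting; a component ratio below
    2 is flagged ``ill_conditioned``.
    """
    C = np.asarray(concentrations_nm, dtype=float)
    y = np.asarray(delta_l_um, dtype=float)
    if np.unique(C).size < 6:
        raise UnderdeterminedError("need >= 6 distinct concentrations")
    cmax = C.max()
    ymax = max(y.max(), 1e-9)
    pars = lmfit.Parameters()
    pars.add("a1", value=0.5 * ymax, min=0.0)
    pars.add("c1", value=cmax / 50.0, min=1e-6)
    pars.add("a2", value=0.5 * ymax, min=0.0)
    pars.add("c2", value=cmax / 2.0, min=1e-6)

    def residual(pars):
        v = pars.valuesdict()
        return (v["a1"] * (1.0 - np.exp(-C / v["c1"]))
                + v["a2"] * (1.0 - np.exp(-C / v["c2"])) - y)

    result = lmfit.minimize(residual, pars, method="leastsq",
                            max_nfev=20_000, xtol=1e-14, ftol=1e-14)
    v = result.params.valuesdict()
    comps = sorted([(v["c1"], v["a1"]), (v["c2"], v["a2"])])
    (c_fast, a_fast), (c_slow, a_slow) = comps
    flags = []
    if not fit_converged(result):
        flags.append("non_convergence")
    if c_slow / max(c_fast, 1e-12) < 2.0:
        flags.append("ill_conditioned")
    fitted = DoubleExpParams(a_fast_um=a_fast, c_fast_nm=c_fast,
                             a_slow_um=a_slow, c_slow_nm=c_slow)
    r = residual(result.params)
    dof = max(r.size - result.nvarys, 1)
    report = FitReport(
        residual_sd=float(np.sqrt(np.sum(r**2) / dof)),
        stderr={k: (result.params[k].stderr if result.params[k].stderr is not None
                    else float("nan")) for k in result.params},
        flags=tuple(flags),
    )
    return fitted, report
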