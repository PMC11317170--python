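"""Instantaneous apparent stiffness of a molecule from its FEC.

The apparent longitudinal stiffness is the local slope dF/dx of the
force-extension curve.  On measured data the derivative amplifies noise,
so an optional Savitzky-Golay smoothing pass (local polynomial fit of
the force trace) is applied first.  The derivative itself uses central
divided differences on the measured, generally non-uniform extension
grid with one-sided differences at the endpoints (numpy.gradient), i.e.
no resampling of the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateGridError, InvalidParameterError, WindowError
from .fec_model import ForceExtensionCurve

__all__ = [
    "StiffnessCurve",
    "StiffnessPeak",
    "smooth_force",
    "stiffness_curve",
    "stiffness_peak",
]


@dataclass(frozen=True)
class StiffnessCurve:
    extension: np.ndarray  # μm
    df_dx: np.ndarray  # pN/μm
    smoothing: str = "raw"

    def __post_init__(self):
        x = np.asarray(self.extension, dtype=float)
        k = np.asarray(self.df_dx, dtype=float)
        if x.size != k.size:
            raise InvalidParameterError("extension and dF/dx lengths differ")
        if np.any(np.diff(x) <= 0):
            raise DegenerateGridError("extension must be strictly increasing")
        object.__setattr__(self, "extension", x)
        object.__setattr__(self, "df_dx", k)


@dataclass(frozen=True)
class StiffnessPeak:
    position_um: float
    value_pn_per_um: float
    at_boundary: bool = False


def smooth_force(fec: ForceExtensionCurve, window: int = 21, order: int = 3
                 ) -> ForceExtensionCurve:
    """Savitzky-Golay smooth of the force trace (extension untouched).

    ``window`` must be odd with ``3 <= window <= n`` and ``order < window``.
    """
    n = fec.n
    if window % 2 == 0 or window < 3 or window > n:
        raise InvalidParameterError(
            f"window must be odd and within [3, {n}], got {window}"
        )
    if order >= window:
        raise InvalidParameterError(
            f"polynomial order {order} must be < window {window}"
        )
    smoothed = savgol_filter(fec.force, window_length=window, polyorder=order)
    return fec.with_force(smoothed)


def stiffness_curve(fec: ForceExtensionCurve) -> StiffnessCurve:
    """Numerical derivative dF/dx of a curve (pN/μm).

    Central differences on the interior, one-sided at the ends.  Requires
    at least 3 points and a strictly increasing extension grid.
    """
    x, f = fec.extension, fec.force
    if x.size < 3:
        raise InvalidParameterError("need >= 3 points to differentiate")
    if np.any(np.diff(x) <= 0):
        raise DegenerateGridError("duplicate or decreasing extensions")
    return StiffnessCurve(extension=x, df_dx=np.gradient(f, x), smoothing="raw")


def stiffness_peak(
    sc: StiffnessCurve,
    search_window: Optional[Tuple[float, float]] = None,
) -> StiffnessPeak:
    """Position and value of the stiffness maximum inside a window.

    Ties are broken towards the smallest extension; a maximum sitting on
    the window edge is flagged ``at_boundary``.
    """
    x, k = sc.extension, sc.df_dx
    if search_window is None:
        mask = np.ones_like(x, dtype=bool)
    else:
        lo, hi = search_window
        mask = (x >= lo) & (x <= hi)
    if not mask.any():
        raise WindowError("search window does not overlap the stiffness curve")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(k[idx])]  # argmax returns the first (leftmost) max
    at_edge = best == idx[0] or best == idx[-1]
    return StiffnessPeak(
        position_um=float(x[best]),
        value_pn_per_um=float(k[best]),
        at_boundary=bool(at_edge),
    )
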