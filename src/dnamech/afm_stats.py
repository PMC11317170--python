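"""AFM contour statistics for surface-adsorbed DNA molecules.

A traced molecule is an ordered 2-D point path (nm) with an optional
per-point topographic height.  When heights are present the molecule's
ends are defined as the outermost trace points at or above half the
maximal height along the path; the contour length is the summed segment
length of the trimmed path and the end-to-end distance the straight
span between the trimmed endpoints.

Control and treated samples are compared with Welch's unequal-variance
t-test (Welch-Satterthwaite degrees of freedom).  A summary-statistics
entry point is provided for the common case where only means, SDs and
sample sizes are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DomainError, InvalidParameterError, TrimError

__all__ = [
    "ContourTrace",
    "ContourSample",
    "ContourMeasure",
    "SampleComparison",
    "contour_length",
    "compare_samples",
    "compare_summary",
]


@dataclass(frozen=True)
class ContourTrace:
    """Ordered 2-D trace of one molecule (nm), optional heights (nm)."""

    path: np.ndarray  # (n, 2)
    height: Optional[np.ndarray] = None

    def __post_init__(self):
        p = np.asarray(self.path, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
            raise InvalidParameterError("path must be an (n>=2, 2) array")
        if not np.all(np.isfinite(p)):
            raise InvalidParameterError("path coordinates must be finite")
        h = self.height
        if h is not None:
            h = np.asarray(h, dtype=float)
            if h.size != p.shape[0]:
                raise InvalidParameterError("height length differs from path")
        object.__setattr__(self, "path", p)
        object.__setattr__(self, "height", h)


@dataclass(frozen=True)
class ContourSample:
    """Per-molecule contour lengths and end-to-end distances (nm)."""

    contour_lengths: np.ndarray
    end_to_end: np.ndarray
    label: str = ""

    def __post_init__(self):
        c = np.asarray(self.contour_lengths, dtype=float)
        r = np.asarray(self.end_to_end, dtype=float)
        if c.size != r.size:
            raise InvalidParameterError("sample array lengths differ")
        if np.any(c <= 0) or np.any(r <= 0):
            raise InvalidParameterError("sample values must be > 0")
        object.__setattr__(self, "contour_lengths", c)
        object.__setattr__(self, "end_to_end", r)

    @property
    def n(self) -> int:
        return self.contour_lengths.size


@dataclass(frozen=True)
class ContourMeasure:
    contour_nm: float
    end_to_end_nm: float


@dataclass(frozen=True)
class SampleComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    mean_difference: float  # mean_b - mean_a
    percent_change: float  # 100*(mean_b - mean_a)/mean_a
    t: float
    df: float
    p: float


def contour_length(trace: ContourTrace) -> ContourMeasure:
    """Contour length and end-to-end distance of one traced molecule.

    With heights present the path is first trimmed to the outermost
    points whose height reaches half the maximum along the trace.

    Raises
    ------
    TrimError
        If trimming leaves fewer than two points.
    """
    pts = trace.path
    if trace.height is not None:
        h = trace.height
        half = h.max() / 2.0
        keep = np.flatnonzero(h >= half)
        if keep.size < 2:
            raise TrimError("half-maximum trimming left fewer than 2 points")
        pts = pts[keep[0]:keep[-1] + 1]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return ContourMeasure(
        contour_nm=float(seg.sum()),
        end_to_end_nm=float(np.linalg.norm(pts[-1] - pts[0])),
    )


def _welch_df(var_a, n_a, var_b, n_b) -> float:
    va, vb = var_a / n_a, var_b / n_b
    denom = va**2 / (n_a - 1) + vb**2 / (n_b - 1)
    if denom == 0:
        return float(n_a + n_b - 2)
    return float((va + vb) ** 2 / denom)


def compare_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> SampleComparison:
    """Welch comparison from summary statistics (means, SDs, sizes)."""
    if n_a < 2 or n_b < 2:
        raise DomainError("each sample needs n >= 2")
    diff = mean_b - mean_a
    if sd_a == 0 and sd_b == 0:
        t = 0.0 if diff == 0 else float("inf") * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        df = float(n_a + n_b - 2)
    else:
        se = np.sqrt(sd_a**2 / n_a + sd_b**2 / n_b)
        t = diff / se
        df = _welch_df(sd_a**2, n_a, sd_b**2, n_b)
        p = 2.0 * stats.t.sf(abs(t), df)
    return SampleComparison(
        mean_a=float(mean_a), sd_a=float(sd_a), n_a=int(n_a),
        mean_b=float(mean_b), sd_b=float(sd_b), n_b=int(n_b),
        mean_difference=float(diff),
        percent_change=float(100.0 * diff / mean_a),
        t=float(t), df=float(df), p=float(p),
    )


def compare_samples(a: ContourSample, b: ContourSample) -> SampleComparison:
    """Welch comparison of the contour lengths of two raw samples.

    The sign convention is ``b - a`` (treated minus control when the
    control is passed first) and the percent change is relative to the
    first sample's mean.
    """
    if a.n < 2 or b.n < 2:
        raise DomainError("each sample needs n >= 2")
    return compare_summary(
        np.mean(a.contour_lengths), np.std(a.contour_lengths, ddof=1), a.n,
        np.mean(b.contour_lengths), np.std(b.contour_lengths, ddof=1), b.n,
    )
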