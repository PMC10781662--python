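"""The relevance function Φ(y): a shape-preserving map from target values
to [0, 1].

Imbalanced regression needs a continuous notion of which target regions
are rare-but-important.  Φ is built by monotone piecewise cubic Hermite
interpolation (pchip) through a handful of control points
(y, φ(y), φ'(y)): each interval gets the cubic

    Φ(y) = a_k + b_k (y − y_k) + c_k (y − y_k)² + d_k (y − y_k)³,

with the Hermite coefficients determined by the interval endpoints and
slopes.  Slopes are corrected by the Fritsch–Carlson ``check_slopes``
step so that wherever the control data is monotone the interpolant is
monotone too: slopes are zeroed on flat secants and sign mismatches,
and their magnitudes are projected into the circle
(b_k/δ_k)² + (b_{k+1}/δ_k)² ≤ 9 that guarantees monotonicity.

Control points are taken to sit at local extrema of the relevance, so
their derivatives default to zero.  When a derivative is left
unspecified (``None``) it is instead estimated by the standard weighted
harmonic mean of adjacent secants — the estimator used by reference
monotone-pchip implementations — whose output already lies inside the
monotonicity region and is therefore not re-projected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DegenerateInputError, DimensionError

__all__ = [
    "ControlPoint",
    "RelevanceFunction",
    "check_slopes",
    "pchip_fit",
    "evaluate_relevance",
    "default_control_points",
]


@dataclass(frozen=True)
class ControlPoint:
    """A (target value, relevance, derivative) anchor for Φ.

    ``dphi=None`` requests slope estimation; an explicit value (the
    conventional default is 0.0, control points being local extrema of
    the relevance) is honoured after monotonicity correction.
    """

    y: float
    phi: float
    dphi: float | None = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ConfigError(f"relevance must lie in [0, 1], got {self.phi}")


def check_slopes(derivatives: np.ndarray, secants: np.ndarray) -> np.ndarray:
    """Correct endpoint slopes so the Hermite interpolant is monotone
    wherever the control data is monotone (Fritsch–Carlson).

    ``derivatives`` has one entry per control point (length s) and
    ``secants`` one per interval (length s − 1).  Rules, applied in one
    sweep over intervals: a flat secant zeroes both adjacent slopes; a
    slope whose sign opposes its secant becomes 0; slope magnitudes are
    scaled so (b_k/δ_k)² + (b_{k+1}/δ_k)² ≤ 9 on every interval.
    Projection only shrinks magnitudes, so earlier intervals stay valid.
    """
    b = np.array(derivatives, dtype=float)
    d = np.asarray(secants, dtype=float)
    if b.size != d.size + 1:
        raise DimensionError(
            f"need one derivative per control point: got {b.size} derivatives "
            f"for {d.size} intervals"
        )
    for k in range(d.size):
        if d[k] == 0.0:
            b[k] = 0.0
            b[k + 1] = 0.0
            continue
        alpha = b[k] / d[k]
        beta = b[k + 1] / d[k]
        if alpha < 0.0:
            b[k] = 0.0
            alpha = 0.0
        if beta < 0.0:
            b[k + 1] = 0.0
            beta = 0.0
        r2 = alpha * alpha + beta * beta
        if r2 > 9.0:
            tau = 3.0 / np.sqrt(r2)
            b[k] = tau * alpha * d[k]
            b[k + 1] = tau * beta * d[k]
    return b


def _estimate_slopes(y: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Weighted-harmonic-mean slope estimates (shape-preserving).

    Interior slope at knot k is the weighted harmonic mean of the two
    adjacent secants when they share a sign, else 0; endpoint slopes
    use the one-sided three-point formula with monotonicity clipping.
    """
    h = np.diff(y)
    delta = np.diff(phi) / h
    s = y.size
    b = np.zeros(s)
    if s == 2:
        b[:] = delta[0]
        return b
    for k in range(1, s - 1):
        d0, d1 = delta[k - 1], delta[k]
        if d0 == 0.0 or d1 == 0.0 or np.sign(d0) != np.sign(d1):
            b[k] = 0.0
        else:
            w1 = 2.0 * h[k] + h[k - 1]
            w2 = h[k] + 2.0 * h[k - 1]
            b[k] = (w1 + w2) / (w1 / d0 + w2 / d1)
    b[0] = _edge_slope(h[0], h[1], delta[0], delta[1])
    b[-1] = _edge_slope(h[-1], h[-2], delta[-1], delta[-2])
    return b


def _edge_slope(h0: float, h1: float, d0: float, d1: float) -> float:
    d = ((2.0 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
    if np.sign(d) != np.sign(d0):
        return 0.0
    if np.sign(d0) != np.sign(d1) and abs(d) > 3.0 * abs(d0):
        return 3.0 * d0
    return d


@dataclass
class RelevanceFunction:
    """A fitted piecewise-cubic Φ with constant extension outside the
    outermost control points and output clamped to [0, 1]."""

    control_points: tuple[ControlPoint, ...]
    knots: np.ndarray  # control-point target values, strictly increasing
    a: np.ndarray  # per-interval constant terms  φ(y_k)
    b: np.ndarray  # corrected slopes at each knot (length s)
    c: np.ndarray  # per-interval quadratic coefficients
    d: np.ndarray  # per-interval cubic coefficients

    def __call__(self, y: float | np.ndarray) -> float | np.ndarray:
        return evaluate_relevance(self, y)


def pchip_fit(points: list[ControlPoint] | tuple[ControlPoint, ...]) -> RelevanceFunction:
    """Fit Φ through control points by monotone piecewise cubic Hermite
    interpolation.

    Requires at least two control points with strictly increasing
    target values.  Explicit derivatives are corrected by
    :func:`check_slopes`; fully unspecified derivatives are estimated
    (see module docstring) and used as-is.
    """
    pts = tuple(points)
    if len(pts) < 2:
        raise ConfigError(f"need at least 2 control points, got {len(pts)}")
    y = np.array([p.y for p in pts], dtype=float)
    phi = np.array([p.phi for p in pts], dtype=float)
    if np.any(np.diff(y) <= 0):
        raise ConfigError("control-point target values must be strictly increasing")

    h = np.diff(y)
    delta = np.diff(phi) / h

    if all(p.dphi is None for p in pts):
        slopes = _estimate_slopes(y, phi)
    else:
        estimated = None
        slopes = np.empty(len(pts))
        for k, p in enumerate(pts):
            if p.dphi is None:
                if estimated is None:
                    estimated = _estimate_slopes(y, phi)
                slopes[k] = estimated[k]
            else:
                slopes[k] = p.dphi
        slopes = check_slopes(slopes, delta)

    a = phi[:-1]
    c = (3.0 * delta - 2.0 * slopes[:-1] - slopes[1:]) / h
    d = (slopes[:-1] + slopes[1:] - 2.0 * delta) / h**2
    return RelevanceFunction(control_points=pts, knots=y, a=a, b=slopes, c=c, d=d)


def evaluate_relevance(
    f: RelevanceFunction, y: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate Φ(y); constant beyond the outermost control points,
    clamped to [0, 1]."""
    arr = np.asarray(y, dtype=float)
    scalar = arr.ndim == 0
    v = np.atleast_1d(arr)
    idx = np.clip(np.searchsorted(f.knots, v, side="right") - 1, 0, f.knots.size - 2)
    t = v - f.knots[idx]
    out = f.a[idx] + f.b[idx] * t + f.c[idx] * t**2 + f.d[idx] * t**3
    out = np.where(v <= f.knots[0], f.a[0], out)
    phi_last = float(f.control_points[-1].phi)
    out = np.where(v >= f.knots[-1], phi_last, out)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def default_control_points(targets: np.ndarray) -> list[ControlPoint]:
    """Boxplot-based control points for an upper-tail rare region.

    Relevance 0 at the sample minimum and median, 1 at the upper outlier
    fence Q3 + 1.5·IQR; all derivatives 0 (control points sit at local
    extrema of the relevance).  Degenerate spread (IQR = 0) falls back
    to a (min, 0) → (max, 1) ramp.
    """
    y = np.asarray(targets, dtype=float).ravel()
    if np.unique(y).size < 5:
        if np.min(y) == np.max(y):
            raise DegenerateInputError("cannot build control points from a constant target")
        return [ControlPoint(float(np.min(y)), 0.0, 0.0), ControlPoint(float(np.max(y)), 1.0, 0.0)]
    q1, med, q3 = np.quantile(y, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        return [ControlPoint(float(np.min(y)), 0.0, 0.0), ControlPoint(float(np.max(y)), 1.0, 0.0)]
    fence = float(q3 + 1.5 * iqr)
    pts = []
    ymin = float(np.min(y))
    if ymin < med:
        pts.append(ControlPoint(ymin, 0.0, 0.0))
    pts.append(ControlPoint(float(med), 0.0, 0.0))
    pts.append(ControlPoint(fence, 1.0, 0.0))
    return pts
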