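"""Function-valued characterization of intake-array shape.

An intake array can be read as a response curve: carbohydrate intake (mmol
per bee, cumulative over the trial) as a function of the diet's amino-acid
molarity.  Following the preference-function tradition in behavioural
ecology, the curve is smoothed with a cubic smoothing spline and summarized
by four traits:

* **peak** — the x at which the smoothed response is maximal;
* **height** — the response at the peak;
* **tolerance** — the width of the curve at an elevation a fixed fraction
  below the peak (the connected component containing the peak);
* **strength** — how far the response falls away from the peak on average,
  1 − mean(f)/height, in [0, 1] for non-negative curves.

Smoothing defaults to generalized cross-validation; ``lam=0`` gives the
interpolating limit.  x is the diet AA molarity by default, but any
monotone diet coordinate (e.g. mean AA intake) may be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "SmoothFunction",
    "ShapeSummary",
    "fit_smooth",
    "peak_and_height",
    "tolerance",
    "strength",
    "characterize_array",
]

_N_GRID = 1000


class InsufficientDataError(ValueError):
    """Fewer than four distinct x values — too few to characterize shape."""


@dataclass(frozen=True)
class SmoothFunction:
    """An evaluable smooth curve restricted to the observed x-range."""

    spline: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        lo, hi = self.domain
        if np.any((np.asarray(x) < lo - 1e-12) | (np.asarray(x) > hi + 1e-12)):
            raise ValueError(f"evaluation outside domain [{lo}, {hi}]")
        return self.spline(x)

    def grid(self, n: int = _N_GRID) -> tuple[np.ndarray, np.ndarray]:
        xs = np.linspace(*self.domain, n)
        return xs, np.asarray(self.spline(xs), dtype=float)


@dataclass(frozen=True)
class ShapeSummary:
    """Peak/height/tolerance/strength of one intake array."""

    peak_x: float
    height: float
    tolerance: float
    strength: float
    drop_fraction: float
    peak_at_boundary: bool
    tolerance_truncated: bool


def fit_smooth(x: Sequence[float], y: Sequence[float], lam: float | None = None) -> SmoothFunction:
    """Cubic smoothing spline through per-diet responses.

    ``lam=None`` selects the smoothing parameter by generalized
    cross-validation; ``lam=0`` interpolates.  Requires >= 4 distinct,
    strictly increasing x values; with exactly 4 points a natural
    interpolating cubic is used (too few points for cross-validated
    smoothing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(np.unique(x)) != len(x):
        raise InsufficientDataError("duplicated x values")
    if len(x) < 4:
        raise InsufficientDataError(f"need >= 4 distinct x values, got {len(x)}")
    if len(x) == 4:
        spline = CubicSpline(x, y, bc_type="natural")
    else:
        spline = make_smoothing_spline(x, y, lam=lam)
    return SmoothFunction(spline=spline, domain=(float(x[0]), float(x[-1])))


def peak_and_height(f: SmoothFunction, n_grid: int = _N_GRID) -> tuple[float, float, bool]:
    """Argmax and max of the curve over its domain.

    A dense-grid scan refined by bounded local optimization; ties (flat
    curves) break to the leftmost x.  Returns (peak_x, height, boundary_flag)
    with the flag set when the maximum sits on a domain endpoint.
    """
    xs, ys = f.grid(n_grid)
    i = int(np.argmax(ys))
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, n_grid - 1)]
    if lo < hi:
        res = optimize.minimize_scalar(
            lambda x: -float(f(x)), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        if -res.fun >= ys[i]:
            peak_x, height = float(res.x), float(-res.fun)
        else:
            peak_x, height = float(xs[i]), float(ys[i])
    else:
        peak_x, height = float(xs[i]), float(ys[i])
    # flat-curve tie-break: leftmost x at the maximal level
    at_max = np.flatnonzero(ys >= height - 1e-12 * max(1.0, abs(height)))
    if len(at_max) > 1 and np.ptp(ys[at_max]) == 0:
        peak_x = float(xs[at_max[0]])
    boundary = peak_x <= f.domain[0] + 1e-9 or peak_x >= f.domain[1] - 1e-9
    return peak_x, height, boundary


def tolerance(
    f: SmoothFunction,
    peak_x: float,
    height: float,
    drop_fraction: float = 1.0 / 3.0,
    n_grid: int = _N_GRID,
) -> tuple[float, bool]:
    """Width of the curve at elevation ``height * (1 − drop_fraction)``.

    Measured as the length of the connected superlevel component containing
    the peak; edges are sharpened by root finding.  Truncation at a domain
    end is flagged.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    threshold = height * (1.0 - drop_fraction)
    xs, ys = f.grid(n_grid)
    above = ys >= threshold - 1e-12 * max(1.0, abs(height))
    i_peak = int(np.clip(np.searchsorted(xs, peak_x), 0, n_grid - 1))
    if not above[i_peak]:  # numerical guard: snap to nearest above-threshold node
        candidates = np.flatnonzero(above)
        i_peak = int(candidates[np.argmin(np.abs(xs[candidates] - peak_x))])
    left = i_peak
    while left > 0 and above[left - 1]:
        left -= 1
    right = i_peak
    while right < n_grid - 1 and above[right + 1]:
        right += 1

    def crossing(i_out: int, i_in: int) -> float:
        g = lambda x: float(f(x)) - threshold
        a, b = xs[i_out], xs[i_in]
        if g(a) == g(b) or g(a) * g(b) > 0:
            return xs[i_out]
        return float(optimize.brentq(g, a, b, xtol=1e-12))

    truncated = False
    if left == 0:
        x_left, truncated = xs[0], True
    else:
        x_left = crossing(left - 1, left)
    if right == n_grid - 1:
        x_right, truncated = xs[-1], True
    else:
        x_right = crossing(right + 1, right)
    return float(x_right - x_left), truncated


def strength(f: SmoothFunction, height: float, n_grid: int = _N_GRID) -> float:
    """Average fall-off from the peak: 1 − mean(f)/height.

    The mean is a trapezoid average over the domain.  Zero for a flat curve;
    approaches one for a needle peak over a near-zero baseline.
    """
    if height <= 0:
        raise ValueError("strength undefined for non-positive height")
    xs, ys = f.grid(n_grid)
    mean = float(np.trapezoid(ys, xs) / (xs[-1] - xs[0]))
    return 1.0 - mean / height


def characterize_array(
    x: Sequence[float],
    y: Sequence[float],
    drop_fraction: float = 1.0 / 3.0,
    lam: float | None = None,
) -> ShapeSummary:
    """Full shape characterization of one intake array.

    ``x`` is the per-diet AA molarity (mol/L), ``y`` the per-diet mean
    cumulative carbohydrate intake (mmol per bee).
    """
    f = fit_smooth(x, y, lam=lam)
    peak_x, height, boundary = peak_and_height(f)
    width, truncated = tolerance(f, peak_x, height, drop_fraction)
    return ShapeSummary(
        peak_x=peak_x,
        height=height,
        tolerance=width,
        strength=strength(f, height),
        drop_fraction=drop_fraction,
        peak_at_boundary=boundary,
        tolerance_truncated=truncated,
    )
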