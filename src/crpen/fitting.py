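"""Parameter estimation: contour-slope fits and the two-level (D, K) solve.

Under the saturating-diffusion model the depth of a fixed intensity level
grows linearly in sqrt(t); the slopes of two such contours at distinct
levels determine both the diffusion coefficient D and the saturation
coefficient K through

    K * erfc(s_i / (2 sqrt(D))) = p_i,   i = 1, 2.

Dividing the two equations eliminates K, leaving a single monotone
equation in a = 1/(2 sqrt(D)) solved by bracketed root finding; K follows
by back-substitution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc

from .exceptions import (
    InconsistentDataError,
    InputError,
    InsufficientDataError,
    NoSolutionError,
)
from .model import PenetrationParams, fluorescence, slope_at_level
from .profiles import DepthProfile, IsoContourSeries

__all__ = [
    "SlopeFit",
    "FitReport",
    "fit_slope",
    "solve_DK",
    "profile_r_squared",
    "derived_constants",
    "fit_contours",
]


@dataclass(frozen=True)
class SlopeFit:
    """Through-origin linear fit of contour depth against sqrt(time).

    ``slope`` is in um/sqrt(s).  ``r_squared`` is 1 - SS_res/SS_tot with
    SS_tot about the mean depth (None when the depths are constant, which
    leaves R^2 undefined).  ``intercept_free_slope``/``intercept`` report
    the unconstrained fit as a diagnostic; the through-origin slope is the
    one used for parameter estimation because the model forces depth 0 at
    time 0.
    """

    level: float
    slope: float
    r_squared: float | None
    n_points: int
    intercept_free_slope: float | None = None
    intercept: float | None = None


@dataclass
class FitReport:
    """Full result of a two-contour parameter estimation."""

    params: PenetrationParams
    slope_fits: tuple[SlopeFit, SlopeFit]
    profile_r_squared: list[tuple[float, float]] = field(default_factory=list)
    bracket: tuple[float, float] = (0.0, 0.0)
    residual: float = 0.0

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "slopes": [
                {
                    "level": f.level,
                    "slope_um_per_sqrt_s": f.slope,
                    "r_squared": f.r_squared,
                    "n_points": f.n_points,
                }
                for f in self.slope_fits
            ],
            "profile_r_squared": [
                {"time_s": t, "r_squared": r} for t, r in self.profile_r_squared
            ],
            "solver": {"bracket": list(self.bracket), "residual": self.residual},
        }


def fit_slope(series: IsoContourSeries) -> SlopeFit:
    """Least-squares slope of depth = s * sqrt(t) through the origin.

    The zero intercept is model-implied (no penetration at t = 0).  The
    free-intercept fit is attached as a diagnostic only.  R^2 is computed
    about the mean of the depths so the value is comparable to ordinary
    linear-regression practice; it is None (flagged) when all depths are
    equal.
    """
    t, z = series.times, series.depths
    if t.size < 2:
        raise InsufficientDataError("need at least two contour points to fit a slope")
    if np.any(t <= 0):
        raise InputError("contour times must be positive")
    x = np.sqrt(t)
    slope = float(np.dot(x, z) / np.dot(x, x))
    ss_res = float(np.sum((z - slope * x) ** 2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - ss_res / ss_tot
    # free-intercept diagnostic
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    return SlopeFit(
        level=series.level,
        slope=slope,
        r_squared=r2,
        n_points=int(t.size),
        intercept_free_slope=float(coef[0]),
        intercept=float(coef[1]),
    )


def solve_DK(
    s1: float,
    p1: float,
    s2: float,
    p2: float,
    *,
    tol: float = 1e-12,
) -> PenetrationParams:
    """Solve the two-contour system for (D, K).

    Given contour slopes ``s1`` at level ``p1`` and ``s2`` at level ``p2``
    (um/sqrt(s)), eliminates K via ``erfc(s1*a)/erfc(s2*a) = p1/p2`` with
    ``a = 1/(2 sqrt(D))``.  The left side is strictly monotone in ``a``
    (for s1 > s2), so the root is unique and bracketed root finding is
    guaranteed to converge; then ``K = p1 / erfc(s1 * a)``.

    The deeper contour (lower level) must have the larger slope, as any
    monotone-decreasing profile requires.

    Raises
    ------
    NoSolutionError
        If the ratio equation has no sign change in the bracket.
    InconsistentDataError
        If back-substitution yields K < 1 (no saturated region can produce
        such slopes).
    """
    if not (0 < p1 < 1 and 0 < p2 < 1) or p1 == p2:
        raise InputError("levels must be distinct and in (0, 1)")
    if s1 <= 0 or s2 <= 0:
        raise InputError("slopes must be positive")
    # order so that p1 < p2 (lower level first => larger slope)
    if p1 > p2:
        s1, p1, s2, p2 = s2, p2, s1, p1
    if s1 <= s2:
        raise InputError(
            "slope ordering inconsistent with a monotone profile: the lower "
            "level must have the larger slope"
        )
    target = p1 / p2

    def ratio(a: float) -> float:
        return erfc(s1 * a) / erfc(s2 * a) - target

    a_lo = 1e-6
    a_hi = 1.0
    while erfc(s2 * a_hi) > p2 * 1e-12:
        a_hi *= 2.0
        if a_hi > 1e9:
            break
    if ratio(a_lo) * ratio(a_hi) > 0:
        raise NoSolutionError("no sign change in bracket: slopes admit no (D, K)")
    a = brentq(ratio, a_lo, a_hi, xtol=tol, rtol=4 * np.finfo(float).eps)
    K = p1 / erfc(s1 * a)
    D = 1.0 / (4.0 * a * a)
    if K < 1.0:
        raise InconsistentDataError(
            f"solve produced K={K:.4f} < 1; contour slopes are inconsistent "
            "with a saturating profile"
        )
    params = PenetrationParams(D=D, K=K)
    # self-check: forward slopes must reproduce the inputs
    for s, p in ((s1, p1), (s2, p2)):
        s_back = slope_at_level(params, p)
        if abs(s_back - s) > 1e-9 * s:
            raise NoSolutionError(
                f"forward slope {s_back} does not reproduce input {s} at level {p}"
            )
    return params


def profile_r_squared(params: PenetrationParams, measured: DepthProfile) -> float:
    """Determination coefficient of the forward model against a measured profile.

    R^2 = 1 - SS_res/SS_tot with residuals of the model evaluated at the
    measured depths/time and SS_tot about the mean measured intensity.  Can
    be negative for a bad model; reported raw, never clipped.
    """
    meas = measured.intensity
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    if ss_tot == 0:
        raise InputError("constant measured profile: R^2 undefined")
    model = fluorescence(params, measured.time, measured.depths)
    ss_res = float(np.sum((meas - model) ** 2))
    return 1.0 - ss_res / ss_tot


def derived_constants(params: PenetrationParams) -> dict[str, float]:
    """The two printed-form constants of the fitted intensity expression.

    ``two_sqrt_D`` (um/sqrt(s)) is the depth scale inside the erfc argument
    ``z / (2 sqrt(D) sqrt(t))``; ``inv_K`` is the saturation concentration
    threshold: fluorescence is saturated wherever C >= 1/K.
    """
    return {"two_sqrt_D": 2.0 * math.sqrt(params.D), "inv_K": 1.0 / params.K}


def fit_contours(
    contours: list[IsoContourSeries],
    profiles: list[DepthProfile] | None = None,
) -> FitReport:
    """Fit slopes for two contour series, solve for (D, K), and verify.

    Convenience wrapper over :func:`fit_slope`, :func:`solve_DK` and
    :func:`profile_r_squared` producing a complete :class:`FitReport`.
    """
    if len(contours) != 2:
        raise InputError("exactly two contour levels are required to determine (D, K)")
    f1, f2 = (fit_slope(c) for c in contours)
    params = solve_DK(f1.slope, f1.level, f2.slope, f2.level)
    report = FitReport(params=params, slope_fits=(f1, f2))
    if profiles:
        report.profile_r_squared = [
            (p.time, profile_r_squared(params, p)) for p in profiles
        ]
    resid = max(
        abs(slope_at_level(params, f.level) - f.slope) / f.slope for f in (f1, f2)
    )
    report.residual = resid
    return report
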