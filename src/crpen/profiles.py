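"""Depth-profile and isointensity-contour extraction from 3-D stack series.

A recording is a time series of 3-D stacks (z, y, x) with a known z
calibration and a declared surface plane.  Each stage reduces the data one
step: stack -> per-plane mean depth profile -> normalized profile ->
isointensity contour depths -> (time, depth) contour series ready for
slope fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateProfileError,
    DomainError,
    InputError,
    InsufficientDataError,
    NotYetPenetratedError,
)

__all__ = [
    "StackSeries",
    "DepthProfile",
    "IsoContourSeries",
    "FiberMaskSet",
    "mean_profile",
    "masked_profile",
    "normalize_profile",
    "contour_depth",
    "build_contours",
    "detect_surface",
]


@dataclass
class StackSeries:
    """Time series of co-registered 3-D intensity stacks.

    ``surface_index`` is the plane of the specimen surface (z = 0); planes
    above it image the buffer/immersion side and are excluded from depth
    profiles.  Depth of plane ``i`` is ``(i - surface_index) * z_step`` um.
    """

    times: np.ndarray  # seconds, strictly increasing
    stacks: list[np.ndarray]  # one (n_planes, ny, nx) array per time
    z_step: float  # um per plane
    surface_index: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.stacks) != self.times.size:
            raise InputError("one stack required per time point")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if self.z_step <= 0:
            raise InputError("z_step must be positive")
        shapes = {s.shape for s in self.stacks}
        if len(shapes) > 1:
            raise InputError(f"all stacks must share one shape, got {shapes}")
        if self.stacks:
            n_planes = self.stacks[0].shape[0]
            if not 0 <= self.surface_index < n_planes:
                raise InputError(
                    f"surface_index {self.surface_index} outside [0, {n_planes})"
                )

    @property
    def n_planes(self) -> int:
        return self.stacks[0].shape[0]

    @property
    def above_surface_planes(self) -> int:
        return self.surface_index


@dataclass
class DepthProfile:
    """Intensity versus depth below the surface at one time point.

    ``depths`` are non-negative and increasing; ``intensity`` is raw until
    :func:`normalize_profile` is applied, after which it sits in [0, 1] up
    to the noise floor with a plateau of ~1 near the surface.
    """

    time: float  # s
    depths: np.ndarray  # um, >= 0, increasing
    intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.depths.shape != self.intensity.shape:
            raise InputError("depths and intensity must have equal length")
        if self.depths.size and (np.any(self.depths < 0) or np.any(np.diff(self.depths) <= 0)):
            raise InputError("depths must be non-negative and strictly increasing")


@dataclass
class IsoContourSeries:
    """(time, depth) pairs at one fixed normalized-intensity level."""

    level: float
    times: np.ndarray  # s
    depths: np.ndarray  # um

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.times.shape != self.depths.shape:
            raise InputError("times and depths must have equal length")
        if np.any(self.depths < 0):
            raise InputError("contour depths must be non-negative")


@dataclass
class FiberMaskSet:
    """Per-fiber boolean voxel masks over (z, y, x), e.g. nerve fibers.

    In samples that are uniform only along sparse structures, depth
    profiles are averaged within each mask instead of over whole planes.
    """

    masks: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.masks:
            raise InputError("mask set must contain at least one mask")
        for m in self.masks:
            if m.dtype != bool:
                raise InputError("masks must be boolean arrays")
        if not any(m.any() for m in self.masks):
            raise InputError("all masks are empty")

    @property
    def count(self) -> int:
        return len(self.masks)


def mean_profile(series: StackSeries, t_index: int) -> DepthProfile:
    """Raw depth profile: per-plane mean over all (y, x) pixels.

    Only planes at or below the surface contribute; depth of plane ``i``
    is ``(i - surface_index) * z_step``.
    """
    stack = series.stacks[t_index]
    if stack.size == 0:
        raise InputError("empty stack")
    planes = np.arange(series.surface_index, stack.shape[0])
    intensity = stack[series.surface_index :].mean(axis=(1, 2))
    depths = (planes - series.surface_index) * series.z_step
    return DepthProfile(time=float(series.times[t_index]), depths=depths, intensity=intensity)


def masked_profile(series: StackSeries, t_index: int, masks: FiberMaskSet) -> DepthProfile:
    """Raw depth profile averaged within sparse structures.

    For each fiber mask the per-plane mean is taken over the masked pixels
    only; the per-fiber profiles are then averaged (unweighted mean across
    fibers).  Planes where no mask has pixels are omitted.
    """
    stack = series.stacks[t_index]
    if stack.shape != masks.masks[0].shape:
        raise InputError("mask shape does not match stack shape")
    n_planes = stack.shape[0]
    per_fiber = np.full((masks.count, n_planes), np.nan)
    for f, mask in enumerate(masks.masks):
        for p in range(series.surface_index, n_planes):
            sel = mask[p]
            if sel.any():
                per_fiber[f, p] = stack[p][sel].mean()
    with np.errstate(invalid="ignore"):
        combined = np.nanmean(per_fiber, axis=0)
    keep = ~np.isnan(combined)
    keep[: series.surface_index] = False
    if not keep.any():
        raise InputError("masks cover no below-surface voxels")
    planes = np.nonzero(keep)[0]
    depths = (planes - series.surface_index) * series.z_step
    return DepthProfile(time=float(series.times[t_index]), depths=depths, intensity=combined[keep])


def normalize_profile(
    profile: DepthProfile,
    background: float = 0.0,
    *,
    background_is_fraction: bool = False,
    plateau_window: float = 0.02,
    min_plateau_samples: int = 3,
) -> DepthProfile:
    """Background-subtract and plateau-normalize a raw depth profile.

    The plateau (saturated region) is estimated as the mean of the
    shallowest samples lying within ``plateau_window`` (default 2%) of the
    profile maximum, using at least ``min_plateau_samples`` samples so a
    single hot pixel cannot define the scale.  The background is then
    subtracted and the result divided by the plateau excess, so the output
    is invariant to affine rescaling of the raw intensities.

    Parameters
    ----------
    background : float
        Background fluorescence.  Interpreted on the raw intensity scale,
        or as a fraction of the estimated plateau when
        ``background_is_fraction=True`` (e.g. 0.1 for a GFP sample with 10%
        residual background).

    Raises
    ------
    DegenerateProfileError
        If the plateau estimate does not exceed the background, i.e. the
        profile has no saturated region yet.
    """
    if background < 0:
        raise InputError("background must be >= 0")
    raw = profile.intensity
    if raw.size < min_plateau_samples:
        raise InsufficientDataError("profile too short to estimate a plateau")
    top = raw.max()
    near_top = np.nonzero(raw >= (1.0 - plateau_window) * top)[0]
    if near_top.size >= min_plateau_samples:
        # the shallowest near-maximum samples: deeper candidates may sit on
        # the saturation boundary and bias the plateau low
        idx = near_top[:min_plateau_samples]
    else:
        # too few candidates (e.g. a single hot pixel): fall back to the
        # shallowest samples so one outlier cannot define the scale
        idx = np.unique(np.concatenate([near_top, np.arange(min_plateau_samples)]))
    plateau = float(raw[idx].mean())
    bg = background * plateau if background_is_fraction else background
    if plateau - bg <= 0:
        raise DegenerateProfileError(
            "plateau estimate does not exceed background: no saturated region yet"
        )
    norm = (raw - bg) / (plateau - bg)
    norm[norm < 0] = 0.0  # clip tiny negatives from noise
    return DepthProfile(
        time=profile.time, depths=profile.depths, intensity=norm, normalized=True
    )


def contour_depth(profile: DepthProfile, level: float) -> float:
    """Depth of the first downward crossing of ``level``, scanning from the surface.

    Linear interpolation between the last sample >= level and the first
    sample < level.  The first-crossing rule makes the result deterministic
    on noisy, locally non-monotone tails and matches the monotone physical
    model.

    Raises
    ------
    NotYetPenetratedError
        If the profile never reaches or never drops below ``level``.
    """
    if not 0 < level < 1:
        raise DomainError(f"contour level must be in (0, 1), got {level}")
    z, I = profile.depths, profile.intensity
    below = np.nonzero(I < level)[0]
    if below.size == 0 or below[0] == 0:
        raise NotYetPenetratedError(
            f"level {level} is not crossed downward by this profile (t={profile.time}s)"
        )
    j = below[0]  # first sample < level; sample j-1 is >= level
    i = j - 1
    if I[i] == level:
        return float(z[i])
    frac = (I[i] - level) / (I[i] - I[j])
    return float(z[i] + frac * (z[j] - z[i]))


def build_contours(
    profiles: Sequence[DepthProfile], levels: Sequence[float]
) -> list[IsoContourSeries]:
    """Isointensity-contour series (one per level) from normalized profiles.

    Time points where a level has not yet been crossed are dropped for that
    level; at least two usable points per level are required for a sqrt(t)
    slope fit.
    """
    out = []
    for level in levels:
        ts, zs = [], []
        for p in profiles:
            try:
                zs.append(contour_depth(p, level))
                ts.append(p.time)
            except NotYetPenetratedError:
                continue
        if len(ts) < 2:
            raise InsufficientDataError(
                f"level {level}: only {len(ts)} usable time point(s); need >= 2"
            )
        out.append(IsoContourSeries(level=level, times=np.asarray(ts), depths=np.asarray(zs)))
    return out


def detect_surface(stack: np.ndarray) -> int:
    """Heuristic surface plane: first plane, scanning downward, whose mean
    drops below the running plateau.

    Offered as an aid only; it is never applied silently because surface
    mislocation biases contour slopes.  Declared metadata always wins.
    """
    means = stack.mean(axis=(1, 2))
    top = means.max()
    below = np.nonzero(means < 0.98 * top)[0]
    if below.size == 0:
        return 0
    return max(int(below[0]) - 1, 0)
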