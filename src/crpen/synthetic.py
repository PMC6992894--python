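"""Synthetic 3-D stack generator with the model's exact statistical structure.

The generator is the forward model turned into an imaging simulation: each
below-surface plane's mean intensity follows the saturating erfc law for
the configured (D, K), optionally restricted to sparse fiber structures,
with a constant background floor and seeded Gaussian (read) and/or Poisson
(shot) noise on top.  Above-surface planes read as fully reactivated
(plateau value): they image the buffer side and are excluded from profile
extraction anyway.

Two stock configurations mirror the acquisition geometries the model was
developed on: a homogeneous slab imaged at 1 um z steps (50 planes, 10
above the surface) at 50/150/300/650 s, and a fiber-mode sample at 0.5 um
steps with a 0.1 background fraction at 60/300/1200/1900 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InputError
from .model import PenetrationParams, fluorescence
from .profiles import FiberMaskSet, StackSeries

__all__ = ["SyntheticSpec", "generate_stack", "generate_series", "STANDARD_SPEC", "FIBER_SPEC"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete generative description of a synthetic stack series.

    ``photon_scale`` stands in for the product of excitation intensity and
    the instrument constant: the expected photon count of a fully
    reactivated voxel.  ``background_fraction`` is the non-specific
    fluorescence floor as a fraction of that plateau. ``gaussian_sigma`` is
    read noise on the normalized scale (multiplied by ``photon_scale`` in
    counts).  A fixed ``seed`` makes output byte-identical.
    """

    params: PenetrationParams = field(
        default_factory=lambda: PenetrationParams(D=0.138, K=2.233)
    )
    times: tuple[float, ...] = (50.0, 150.0, 300.0, 650.0)
    nx: int = 64
    ny: int = 64
    n_planes: int = 50
    z_step: float = 1.0  # um
    surface_index: int = 10
    photon_scale: float = 1000.0
    background_fraction: float = 0.0
    gaussian_sigma: float = 0.02  # normalized units
    poisson: bool = False
    mode: str = "homogeneous"  # or "fibers"
    n_fibers: int = 10
    fiber_radius: int = 1  # voxels
    fiber_step: float = 1.0  # random-walk step, voxels per plane
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.n_planes) < 1:
            raise InputError("stack extents must be >= 1")
        if not 0 <= self.surface_index < self.n_planes:
            raise InputError("surface_index outside the stack")
        if self.z_step <= 0 or self.photon_scale <= 0:
            raise InputError("z_step and photon_scale must be positive")
        if not 0 <= self.background_fraction < 1:
            raise InputError("background_fraction must be in [0, 1)")
        if self.gaussian_sigma < 0:
            raise InputError("gaussian_sigma must be >= 0")
        if self.mode not in ("homogeneous", "fibers"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.mode == "fibers" and self.n_fibers < 1:
            raise InputError("fiber mode needs at least one fiber")


#: Homogeneous FITC-slab conditions: 1 um z steps, 50 planes (10 above the
#: surface), four observation times.
STANDARD_SPEC = SyntheticSpec()

#: Fiber-mode conditions: 0.5 um z steps, 0.1 background fraction, slower
#: HM20 penetration, four observation times.
FIBER_SPEC = SyntheticSpec(
    params=PenetrationParams(D=0.026, K=1.404),
    times=(60.0, 300.0, 1200.0, 1900.0),
    n_planes=50,
    z_step=0.5,
    surface_index=0,
    background_fraction=0.1,
    mode="fibers",
)


def _fiber_masks(spec: SyntheticSpec, rng: np.random.Generator) -> FiberMaskSet:
    """Seeded 3-D random-walk polylines dilated to the fiber radius.

    Each fiber starts at a random (y, x) on the surface plane and drifts
    laterally by a Gaussian step per plane, producing roughly vertical
    tubes along which the depth law is sampled.  Masks cover below-surface
    planes only.
    """
    masks = []
    yy, xx = np.mgrid[0 : spec.ny, 0 : spec.nx]
    r2 = spec.fiber_radius**2
    for _ in range(spec.n_fibers):
        mask = np.zeros((spec.n_planes, spec.ny, spec.nx), dtype=bool)
        pos = rng.uniform([0, 0], [spec.ny - 1, spec.nx - 1])
        for p in range(spec.surface_index, spec.n_planes):
            cy, cx = np.clip(pos, [0, 0], [spec.ny - 1, spec.nx - 1])
            mask[p] = (yy - cy) ** 2 + (xx - cx) ** 2 <= r2
            pos = pos + rng.normal(0.0, spec.fiber_step, size=2)
        masks.append(mask)
    return FiberMaskSet(masks=masks)


def _plane_depths(spec: SyntheticSpec) -> np.ndarray:
    return (np.arange(spec.n_planes) - spec.surface_index) * spec.z_step


def generate_stack(
    spec: SyntheticSpec,
    t: float,
    rng: np.random.Generator | None = None,
    masks: FiberMaskSet | None = None,
) -> np.ndarray | tuple[np.ndarray, FiberMaskSet]:
    """One 3-D stack (z, y, x) at time ``t`` in expected photon counts.

    Below-surface voxel means are
    ``photon_scale * (bg + (1 - bg) * fluorescence(params, t, z))``;
    above-surface planes are set to the plateau (the buffer region reads as
    fully reactivated).  In fiber mode the depth-dependent signal is
    confined to the fiber masks (background is not masked).  Poisson noise
    is applied at the photon scale, then Gaussian read noise.

    Returns the stack, and the mask set too when fiber masks were built
    here (fiber mode with no ``masks`` argument).
    """
    made_masks = False
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.mode == "fibers" and masks is None:
        masks = _fiber_masks(spec, rng)
        made_masks = True

    depths = _plane_depths(spec)
    below = depths >= 0
    signal = np.ones(spec.n_planes)  # above-surface planes sit at plateau
    signal[below] = np.asarray(
        fluorescence(spec.params, t, depths[below]), dtype=float
    )

    bg = spec.background_fraction
    stack = np.empty((spec.n_planes, spec.ny, spec.nx), dtype=float)
    stack[:] = signal[:, None, None] * (1.0 - bg) + bg
    if spec.mode == "fibers":
        fiber_any = np.zeros((spec.n_planes, spec.ny, spec.nx), dtype=bool)
        for m in masks.masks:
            fiber_any |= m
        # outside the fibers only the background floor remains
        structural = np.where(fiber_any, signal[:, None, None], 0.0)
        stack = structural * (1.0 - bg) + bg
        stack[~below] = 1.0  # buffer side: plateau everywhere
    stack *= spec.photon_scale

    if spec.poisson:
        stack = rng.poisson(stack).astype(float)
    if spec.gaussian_sigma > 0:
        stack += rng.normal(0.0, spec.gaussian_sigma * spec.photon_scale, size=stack.shape)

    return (stack, masks) if made_masks else stack


def generate_series(
    spec: SyntheticSpec,
) -> tuple[StackSeries, FiberMaskSet | None]:
    """Full time series sharing geometry and fiber masks across time points.

    Deterministic under ``spec.seed``: a single generator seeds the masks
    and then the per-time noise in sequence.
    """
    if len(spec.times) < 2:
        raise InputError("need at least two time points")
    rng = np.random.default_rng(spec.seed)
    masks = _fiber_masks(spec, rng) if spec.mode == "fibers" else None
    stacks = [generate_stack(spec, t, rng=rng, masks=masks) for t in spec.times]
    series = StackSeries(
        times=np.asarray(spec.times, dtype=float),
        stacks=stacks,
        z_step=spec.z_step,
        surface_index=spec.surface_index,
    )
    return series, masks
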