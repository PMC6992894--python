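# Methods

## Model and assumptions

Chemical reactivation (CR) of quenched fluorophores in resin is modelled
as one-dimensional semi-infinite diffusion of hydroxyl ions from the block
face, coupled to an instantaneous, saturating deprotonation response.

Assumptions, and what they imply:

- **Semi-infinite, isotropic medium.** The specimen is much thicker than
  the penetration depth over the analysis horizon, and lateral transport
  is ignored. The concentration field is then
  `C(t, z) = erfc(z / (2√(D t)))` for depth `z ≥ 0` and time `t ≥ 0`.
  Units are fixed throughout: μm, s, μm²/s; no converters are provided.
- **Constant surface concentration.** The buffer reservoir is large and
  well mixed, so `C(t, 0) = 1` for all `t > 0`. At the `t = 0, z = 0`
  corner the boundary value (1) is used: this makes the fluorescence field
  continuous for `t > 0` and matches how normalized profiles treat the
  surface.
- **Instantaneous reaction.** Deprotonation is orders of magnitude faster
  than transport, so the fluorescent (dianion) fraction is a memoryless
  function of local concentration: `min(1, K·C)` with `K ≥ 1`. `K = 1`
  means saturation occurs only exactly at the surface.
- **Intensity proportional to dianion concentration.** Excitation and
  detection constants fold into one positive scale; everything after
  normalization lives in [0, 1]. The scale (`photon_scale`) appears only
  when synthesizing photon-count images.
- **No photobleaching.** Long-horizon plateau drift is ignored; reported
  drifts in this regime are a few percent and are far below the contrast
  used by the contour extraction.

## Parameter estimation

The depth of intensity level `p` is `z_p(t) = 2√(D t)·erfcinv(p/K)`:
linear in `√t` with slope `s_p = 2√D·erfcinv(p/K)`. Slopes are fitted by
least squares **through the origin** — the model forces `z_p(0) = 0` — at
levels 0.5 and 0.9 by default (one level well inside the unsaturated tail,
one near the saturation boundary, which maximizes the contrast between the
two equations). A free-intercept fit is attached to every `SlopeFit` as a
diagnostic but never used for estimation. R² is computed about the mean
depth even for through-origin fits so values remain comparable to ordinary
regression practice; it is `None` (flagged) for constant depths.

Given slopes `s1, s2` at levels `p1 < p2`, dividing the two equations
`K·erfc(s_i/(2√D)) = p_i` eliminates `K`:

    erfc(s1·a) / erfc(s2·a) = p1/p2,   a = 1/(2√D).

The left side is strictly monotone in `a` when `s1 > s2`, so the root is
unique. It is found with `brentq` on the bracket `[1e-6, a_max]`, where
`a_max` is doubled until `erfc(s2·a_max) < p2·1e-12`; then
`K = p1/erfc(s1·a)` and `D = 1/(4a²)`. The solve self-checks by
recomputing forward slopes (must match inputs to 1e-9 relative) and
rejects results with `K < 1` as inconsistent with any saturating profile.
Published slopes are printed as 3-significant-digit roundings, so solves
from them agree with published (D, K) to ~1–2%; full-precision identity is
exercised separately on synthetic slopes (grid test over
D ∈ [0.01, 1] × K ∈ [1.05, 5], 1e-6 relative).

`erfcinv`/`erfc` come from `scipy.special`; root finding is bracketed
(`brentq`, xtol 1e-12) rather than relying on a closed-form inverse of the
ratio, which does not exist.

## Profile extraction

- **Surface location is declared metadata** (`surface_index`), as set at
  acquisition. A heuristic detector (`detect_surface`) exists but is never
  applied silently, because surface mislocation biases both slopes in the
  same direction.
- **Plateau normalization**: the saturated-region scale is the mean of the
  three shallowest samples lying within 2% of the profile maximum (falling
  back to the three shallowest samples if fewer qualify), not the global
  maximum — robust to single hot pixels, and excluding deeper candidates
  that sit on the saturation boundary. Background is subtracted before
  scaling, given either on the raw intensity scale or as a fraction of the
  plateau (0.1 is the conventional value for GFP tissue with residual
  autofluorescence; homogeneous test targets use 0). A profile whose
  plateau does not exceed the background raises a degenerate-profile
  error: there is no saturated region to normalize against yet.
- **Contour depths** use the *first* downward crossing of the level,
  scanning from the surface, with linear interpolation between the
  bracketing samples. On the model's monotone profiles this is exact to
  O(Δz²); on noisy non-monotone tails it is deterministic and matches the
  physical expectation that the front is monotone.
- **Fiber-masked profiles** average within each fiber mask per plane, then
  across fibers with an unweighted mean (the natural choice when all
  fibers report the same depth law). Planes not covered by any mask are
  omitted. Depths above the surface never enter profiles; the model domain
  is z ≥ 0.

## Finite-difference check

`fd_oracle` solves the transport equation independently of the closed
form: explicit forward-Euler/central-difference scheme, Dirichlet
conditions C(t, 0) = 1 and C(t, z_max) = 0, with the stability requirement
`D·Δt/Δz² ≤ 0.5` enforced. The far boundary defaults to `10√(D·horizon)`,
where the true semi-infinite solution is `erfc(5) ≈ 1.5e-12` — the
truncation error is negligible against grid error. At D = 0.1 μm²/s,
Δz = 0.05 μm and Δt at half the stability bound, the two solutions agree
to max-abs error below 1e-3 at t = 100 s (observed ≈ 2e-6), and the
integrated mass follows the closed-form `2√(Dt/π)` growth.

## Synthetic data generator

The generator is the forward model turned into an imaging simulation, so a
zero-noise pipeline run is an exact round trip (to contour interpolation
error). Per time point, below-surface voxel means are
`photon_scale · (bg + (1−bg)·I_f(t, z))`; above-surface planes are set to
the plateau value, since they image the buffer side, which reads as fully
reactivated (extraction excludes them regardless). Optional Poisson shot
noise acts at the photon scale, then Gaussian read noise of standard
deviation `gaussian_sigma` (normalized units; default 0.02, which puts
synthetic per-profile R² in the high-0.9s range typical of good
confocal data). One `numpy` generator seeded from `spec.seed` drives
masks and all per-time noise in sequence, making series byte-identical
under a fixed seed.

Two stock configurations mirror the acquisition geometries the model was
developed on:

- **standard**: homogeneous slab, 64×64×50 voxels, 1 μm z-step, surface at
  plane 10 (10 planes above the surface), times 50/150/300/650 s,
  D = 0.138, K = 2.233, no background;
- **fibers**: sparse-fiber mode, 0.5 μm z-step, times 60/300/1200/1900 s,
  D = 0.026, K = 1.404, background fraction 0.1.

Fibers are seeded 3-D random-walk polylines (Gaussian lateral drift per
plane) dilated to a voxel radius: roughly vertical tubes along which the
depth law is sampled, emulating structures that are uniform only along
their own axis. The generator does **not** simulate optical sectioning,
PSF blur, photobleaching, registration drift, or anatomy; passing
recovery tests therefore demonstrate correctness of the estimation chain
under the model's own noise assumptions, not robustness to real-microscope
artifacts.

## Problem sizes and numerical choices

End-to-end recovery tests use 64×64×50-voxel stacks at four time points
with σ = 0.02 — small enough to run in seconds while leaving per-plane
standard errors (~σ/64) far below the 5% recovery criterion. The
forward-inverse grid test uses a 12×12 grid over D ∈ [0.01, 1],
K ∈ [1.05, 5]. Tiny negative intensities after background subtraction are
clipped to zero; ties at a contour level resolve to the shallower sample.

## Known limitations

- Two contour levels give exactly-determined (D, K); no joint fit to the
  full (t, z) intensity surface and no uncertainty beyond slope-fit
  diagnostics.
- The saturation plateau is treated as noiseless truth for normalization;
  systematic plateau drift (bleaching) would bias K.
- Isotropic single-D transport only; anisotropic or depth-dependent
  diffusion is out of scope.
- Masks are inputs (generator- or user-provided); the package does not
  segment fibers.
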