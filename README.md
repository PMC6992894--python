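# crpen

Penetration modelling for **chemical reactivation (CR)** of quenched
fluorophores in resin-embedded specimens.

Resin embedding (GMA, LR white, Lowicryl HM20, ...) protonates and quenches
fluorophores such as GFP and FITC. Applying an alkaline buffer to the block
face restores fluorescence, but only as deep as the hydroxyl ions have
penetrated. `crpen` implements the quantitative model of that process and
the full analysis pipeline around it, for microscopists who need to know
how long to wait for a given reactivation depth — e.g. when tuning
block-face imaging of resin-embedded, fluorescently labelled tissue.

## The model

Buffer penetration is one-dimensional semi-infinite diffusion (Fick's
second law, ∂C/∂t = D ∂²C/∂z²) with the surface held at normalized
concentration 1, giving

    C(t, z) = erfc( z / (2√(D t)) ),

with diffusion coefficient *D* (μm²/s) and depth *z* (μm) below the
surface. Fluorescence saturates: the dianion (fluorescent) fraction is
`min(1, K·C)` with saturation coefficient *K* ≥ 1, so normalized intensity
is

    I_f(t, z) = 1        where C ≥ 1/K   (saturated region)
    I_f(t, z) = K·C(t,z) where C < 1/K.

The depth of any fixed intensity level *p* grows as `z_p(t) = s_p·√t` with
slope `s_p = 2√D · erfcinv(p/K)`. Measuring two such slopes at distinct
levels (conventionally 0.5 and 0.9) determines both parameters by solving

    K · erfc( s_p / (2√D) ) = p   for p = 0.5, 0.9.

The package provides:

- the forward model, isointensity depths, and CR-thickness curves
  (`crpen.model`), plus an explicit finite-difference solver used as an
  independent numerical check;
- depth-profile and contour extraction from time series of 3-D stacks,
  including fiber-masked averaging and plateau/background normalization
  (`crpen.profiles`);
- slope fitting, the two-contour (D, K) solve, and model-vs-data R²
  verification (`crpen.fitting`);
- a synthetic stack generator with the model's exact statistical structure
  (`crpen.synthetic`), so the whole chain is testable without microscope
  data;
- TIFF/CSV/JSON I/O and a thin CLI (`crpen simulate|extract|fit|predict|verify`).

## Worked example

Solving the two-contour system with measured slopes 0.642 μm/√s (level
0.5) and 0.441 μm/√s (level 0.9) — the FITC standard sample — and with
0.210/0.106 for an HM20-embedded GFP mouse brain
(`python examples/02_fit_published_slopes.py`):

```
FITC standard sample:
  contour slopes: 0.642 um/sqrt(s) at level 0.5, 0.441 at level 0.9
  D = 0.140 um^2/s   K = 2.227
  intensity expression constants: 2*sqrt(D) = 0.747, 1/K = 0.45
  -> fluorescence saturates wherever C(t,z) >= 0.45

HM20 GFP mouse brain:
  contour slopes: 0.21 um/sqrt(s) at level 0.5, 0.106 at level 0.9
  D = 0.026 um^2/s   K = 1.403
  intensity expression constants: 2*sqrt(D) = 0.322, 1/K = 0.71
```

*D* is the buffer's diffusion coefficient in the resin; *K* controls how
deep the fluorescence stays saturated (down to where C falls to 1/K).
The other examples simulate and refit a noisy synthetic stack series
(`03_synthetic_pipeline.py`, parameter recovery to ~0.1% at 2% voxel
noise) and tabulate predicted reactivation thickness for three resins
(`04_resin_predictions.py`: GMA fastest, HM20 slowest, depth ∝ √t).

Or from the shell:

```sh
crpen simulate --preset standard --seed 3 --out scratch/stacks
crpen fit --in scratch/stacks --out scratch/fit.json
crpen predict --preset GMA --levels 0.5 --out scratch/gma.csv
```

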