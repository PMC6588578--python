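# slayer-assembly

Quantitative image- and track-analysis tools for studying how a
bacterial **S-layer** — the crystalline 2D protein lattice coating the
cell surface — assembles on a living cell.  The package implements the
five measurements used to establish that S-layer growth is driven by
self-assembly of surface-diffusing monomers at crystal edges and lattice
defects, rather than by localized secretion:

1. **Binary cell profiles** (`slayer.profile`): two-color
   super-resolution cell images are registered to the transmitted-light
   gradient, rotated horizontal, and reduced to 40-bin binary profiles of
   S-layer presence along the normalized cell axis (upper and lower cell
   halves separately).  Across a population each bin is a binomial
   observation k / (2·n_cells), summarized with a Wilson score 95%
   interval — this is what shows new S-layer appearing preferentially at
   the poles and division plane.
2. **Punctum molecule counting** (`slayer.puncta`): spots ≥ 10 background
   SDs are fitted with asymmetric 2D Gaussians; integrated photons are
   converted to molecule numbers via
   `molecules = (photons / μ) · bleach_correction / labeling_efficiency`,
   with μ the single-molecule photon yield measured in vitro.
3. **Bound/unbound classification** (`slayer.mobility`): the RMSD of a
   track's positions from the window mean over a 1 s (20-frame) sliding
   window separates immobile (crystal-bound) from diffusing molecules.
   The threshold is mean + 2σ of a Gaussian fitted to the lowest-RMSD
   mode of the pooled histogram (field-calibrated default **57.3 nm**);
   proximity to a nucleation seed is d_NS < **300 nm**.  Co-occupancy
   fractions of (near, bound) categories quantify that molecules stop
   diffusing almost exclusively at existing crystal patches.
4. **Diffusion estimation** (`slayer.msd`): pooled 3D MSD fitted over
   the first 4 lags with the motion-blur- and localization-error-aware
   model

   MSD₃D(τ) = 6D·(τ − τ_E/3) + 2(s₁² + s₂² + s₃²)

   with exposure τ_E = 50 ms and per-axis errors s = (93, 93, 91) nm,
   giving the apparent surface diffusivity D ≈ 0.077 μm²/s.
5. **Surface Gaussian curvature** (`slayer.curvature`): per-vertex
   angle-deficit curvature K = (2π − Σθ)/A on cell-surface triangle
   meshes, satisfying discrete Gauss–Bonnet (ΣKA = 4π) exactly; |K|
   concentrates at the poles, where lattice defects — and new S-layer —
   accumulate.

No experimental data ships with the package; `slayer.synthetic`
generates every input with known ground truth (Brownian tracks with
camera blur and seed-capture kinetics, two-color STED-like cell renders,
spherocylinder meshes), so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from slayer.synthetic import TrackSimConfig, simulate_tracks
from slayer.msd import MsdModel, msd_pipeline

cfg = TrackSimConfig(diffusion_coefficient=0.077, rng_seed=1)  # study conditions
tracks = simulate_tracks(cfg)                  # 30 tracks x 500 frames, 20 fps
model = MsdModel(tau_E=0.05, s_xyz=(93.0, 93.0, 91.0), n_fit_lags=4)
curve, fit = msd_pipeline(tracks, model, frame_interval=cfg.frame_interval)
print(f"MSD(50 ms) = {curve.msd[0]:.4f} um^2")
print(f"D = {fit.D:.4f} +/- {fit.stderr:.4f} um^2/s")
```

prints

```
MSD(50 ms) = 0.0661 um^2
D = 0.0780 +/- 0.0005 um^2/s
```

i.e. the first-lag MSD is dominated by the static localization-error
offset 2Σs² ≈ 0.0512 μm² plus the blur-corrected diffusive term, and the
4-lag fit recovers the generator's diffusivity to ~1%.

The numbered scripts under `analysis/` run the same computations as
narrative steps (simulate → profiles → puncta → mobility → MSD →
curvature), writing their tables under `results/`.

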