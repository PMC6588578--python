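# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, module by module.

## Synthetic data: what it emulates, and what it does not

All analyses are exercised on generated data with known ground truth.
The generators emulate the *observables* of the corresponding
experiments, not the instruments.

**Brownian tracks** (`synthetic.simulate_tracks`).  Free diffusion with
coefficient D (default 0.077 μm²/s, the tracking-derived surface
diffusivity of the S-layer monomer) sampled by a camera running at 20
frames/s with a 50 ms exposure.  Motion blur is modeled by averaging
`n_substeps_per_exposure = 10` intra-exposure positions; as the substep
count grows this converges to the continuous exposure average whose MSD
signature is the −τ_E/3 term of the diffusion model, and 10 substeps put
the residual discretization bias well below the statistical error of a
30×500-frame experiment (the zero-noise recovery test bounds total bias
at < 5%).  Localization error is independent Gaussian noise per axis
(defaults 93/93/91 nm, the calibrated 3D localization precisions).
Binding is first-order capture: within `capture_radius` (150 nm) of an
immobile seed a molecule binds with rate `on_rate` and unbinds with
`off_rate`; bound molecules are perfectly immobile.  This is the
simplest kinetics consistent with capture at crystal edges; real
molecules presumably wiggle within the lattice at the nanometre scale,
which is far below the localization error and irrelevant to the RMSD
classifier.  2D experiments are simulated in the image plane (projected
coordinates), not on the curved membrane: the downstream 2D analyses
operate on projections anyway, and on-surface geodesic diffusion is out
of scope.  Per-frame ground truth (blurred true position, bound state by
majority over the exposure) rides along on each track.

**Cell images** (`synthetic.simulate_cell_image`).  A projected
spherocylinder (default body 2 μm × radius 400 nm, optional centerline
bend and stalk) rendered at 20 nm/px (STED-like).  The transmitted-light
channel peaks on the centerline and steps to zero at the membrane edge,
which is placed half an outline-band width (100 nm) inside the outer
label surface: per-column intensity maxima then track the medial axis,
and the transmitted gradient peaks at the centre of the 200 nm outline
band, making the two outline definitions (fluorescence-threshold-based
and gradient-based) consistent, as they are in real data.  Fluorescence
channels place individual emitters (default 100 photons each) according
to a label pattern — uniform over the outline band, polar-enriched,
crack-like transverse features, or explicit puncta with molecule counts
— convolve with a Gaussian PSF (60/80 nm FWHM per channel) and apply
Poisson noise over a uniform background.  Total expected photons equal
n_emitters × photons/molecule + background × n_pixels exactly, which the
photon-bookkeeping tests rely on.  Not modeled: EM gain and read noise,
depletion-beam photophysics, out-of-focus light.  Consequently the
tests demonstrate algorithmic correctness on faithful geometry and
photon statistics, not robustness to every camera artifact.

**Meshes** (`synthetic.make_spherocylinder_mesh`).  Spherocylinders are
built as explicit surfaces of revolution (pole fans + latitude rings +
evenly spaced body rings) rather than from a split sphere, so that the
developable body carries vertices and the axial curvature profile has no
empty bins.  Watertightness is enforced; `body_length=0` degenerates to
a sphere.

## Binary cell profiles

Pipeline per cell: register → orient → axis fit → outline → binarize →
project.

* **Registration** uses normalized cross-correlation (overlap-normalized
  via a padded template search, ±10 px) between channel intensity and
  the transmitted-light gradient magnitude.  Plain unnormalized
  correlation with mean subtraction is biased ~1 px toward zero shift by
  the varying overlap area; the normalized form removes this.  For a
  long thin cell the correlation is sharp across the axis but shallow
  along it, so along-axis registration is accurate to about ±1 px — the
  relevant guarantee, verified by test, is that *changes* in drift are
  recovered exactly.
* **Orientation**: the radon-transform projection angle of maximal
  variance gives the long axis (cells at angle a peak at θ = 90° + a);
  near-isotropic objects (max variance < 1.2× the median over angles)
  are rejected.  Mirroring puts the declared stalk side on the left;
  stalk side arrives as metadata because swarmer/stalked classification
  was manual in the source workflow and automating it is a non-goal.
* **Axis fit**: a 2nd-order polynomial through per-column ridge
  positions of the transmitted channel.  Columns are kept when their
  maximum exceeds 0.75× the median in-cell column maximum (this drops
  the dim, geometrically ambiguous cap-edge columns), and the ridge row
  is the intensity-weighted centroid of pixels within 70% of the column
  maximum — a subpixel refinement of "maximum-intensity pixel" that
  removes the half-pixel bias of a plain argmax.  Cells longer than
  6 μm (the division-inhibited, filamentous regime; no principled
  cutoff exists, this one sits midway between normal ~3 μm cells and
  ≥10 μm filaments) switch to a smoothing spline.  The axis is returned
  as a 1000-point polyline with normalized arc length.
* **Outline band** (200 nm): `complete_layer` mode thresholds (Otsu) the
  max-normalized sum of the fluorescence channels, fills holes, and
  subtracts the erosion by the band width — valid when the S-layer
  covers the cell.  `incomplete_layer` mode finds the maximum of the
  transmitted gradient along normals cast from the axis (plus endpoint
  fans to cover the pole caps) and expands that ridge to the full width
  — valid when fluorescence may be absent anywhere.  On fully labeled
  synthetic cells the two masks agree with Jaccard > 0.7.
* **Binarization**: Gaussian smooth at σ = 0.9 px, then a per-cell Otsu
  threshold computed inside the dilated outline band (parameter-free and
  reproducible; a fixed threshold or quantile can be supplied).  Empty
  results are legitimate — unlabeled cells exist in de novo assembly
  experiments.
* **Projection**: each positive pixel maps to the nearest axis-polyline
  point; bins are half-open [i/40, (i+1)/40) with the last bin closed;
  the upper/lower split is by sign of the row offset from the axis, with
  on-axis pixels assigned to upper (deterministic tie-break; "upper"
  means smaller row index, 0-based row-major images).
* **Population fractions**: per bin, k positive half-profiles out of
  n = 2 × n_cells; 95% Wilson score intervals (via statsmodels), clipped
  to [0, 1] against floating-point underflow.

## Punctum counting

Detection: background mean and SD are estimated robustly
(median / 1.4826·MAD) from a user-supplied off-cell region; connected
groups of pixels above mean + 10 SD yield one candidate per local
maximum.  Fitting: axis-aligned elliptical ("asymmetric") Gaussian with
local offset by nonlinear least squares; no rotation term is fitted —
with no evidence for preferentially oriented puncta the extra parameter
only destabilizes small-window fits.  Integrated photons are the
analytic integral 2πAσxσy of the fitted peak, offset excluded; whether
the source workflow excluded the offset is unknowable from its
description, so this choice is documented rather than asserted.
In-focus selection (manual in the source workflow) is a σ-range filter:
fits outside [0.5×, 2×] the nominal PSF σ are rejected.  Calibration: μ
is the median integrated photon count of isolated single molecules in
depleted (STED) mode — median rather than mean to resist rare
double-emitters — and the photobleaching correction is the ratio of
molecule counts detected in confocal vs depleted images of identical
fields (≥ 10 molecules required).  Counts are corrected as
photons/μ × bleach / labeling_efficiency, with labeling efficiency
(0.5–0.9 in practice) supplied by the user from spectroscopy.

## Mobility classification

Sliding RMSD uses a 20-frame (1 s at 20 frames/s) window: RMSD =
√(mean |r − r̄|²) over the window, assigned to the window's **centre**
frame (the placement is not dictated by the definition; centring
minimizes lag bias at state transitions).  Classification is strict:
bound iff RMSD < threshold; RMSD exactly at threshold is unbound.  The
default threshold is 57.3 nm (= mean + 2σ of the immobile mode in the
calibrated 2D experiment); `calibrate_threshold` re-derives a threshold
from pooled RMSD values by isolating the lowest mode below the first
significant anti-mode of a kernel density estimate (modes under 5% of
the peak density are ignored as tail noise) and least-squares fitting a
Gaussian to the Freedman–Diaconis histogram of that subpopulation.  When
the density is unimodal the fit simply uses all bins — a truncated
half-histogram fit adds variance without benefit.  Seed positions come
from symmetric 2D Gaussian fits per frame; seeds whose positional SD
over time exceeds 2× the localization precision are flagged
non-stationary, and seeds closer than one PSF FWHM are flagged
overlapping.  d_NS is the per-frame Euclidean distance to the nearest
seed; proximity is strict d_NS < 300 nm, mirroring the strict binding
inequality.  Co-occupancy fractions {near∧unbound, near∧bound,
bound∧¬near} are fractions of frames where both series are defined and
sum with the "neither" remainder to exactly 1.

Track linking (used when input arrives as a localization table) is
greedy nearest-neighbour: per frame, candidate pairs within `max_step`
are accepted in order of increasing distance with ties broken by lower
localization index; gaps up to `max_gap` frames are bridged; unmatched
localizations start new tracks.  No probabilistic or global-optimal
linker is attempted — at single-molecule densities greedy matching
agrees with the optimal assignment (tested against a Hungarian oracle).

## MSD and diffusion

Per track, the time-averaged MSD uses all overlapping frame pairs at
each lag (pairing by frame index, so detection gaps drop pairs rather
than corrupting them).  Pooling weights each track's lag by its pair
count, which is identical to averaging the flat list of squared
displacements — the most literal reading of "pooling".  The SEM is that
of the pooled squared displacements; because overlapping pairs are
correlated it understates the true uncertainty, so accuracy claims rest
on ground-truth recovery tests, not on SEM coverage.  The fit of
MSD = 6D(τ − τ_E/3) + 2Σsᵢ² over the first 4 lags (first lag = one
frame interval, 50 ms) holds τ_E and sᵢ fixed at their calibrated
values, leaving D as the single linear parameter — solved in closed form
as a weighted regression (weights 1/SEM²) and verified against an
iterative least-squares route.  A `fit_offset` flag estimates the offset
jointly for users without error calibration.  Negative fitted D (possible
in noise) is returned with a warning flag rather than clipped.

## Surface curvature

Per-vertex angle deficit K = (2π − Σ incident angles)/A with barycentric
vertex area (one third of incident triangle areas); boundary vertices of
non-closed meshes use π.  This estimator was chosen over quadric-fitting
estimators because it satisfies discrete Gauss–Bonnet *exactly*
(ΣK·A = 2πχ), which gives every closed mesh a machine-precision
invariant test for free; a Meyer-style mixed Voronoi area is available
via `area_scheme="mixed"` for users who prefer lower per-vertex variance
on irregular meshes (at the cost of the exact invariant).  The tests
also verify rigid-motion invariance, 1/λ² scaling, refinement
convergence on spheres, and agreement with trimesh's independently
implemented vertex defects.  The axial |K| profile uses the same 40-bin
equi-length convention as the image profiles so the two can be compared
bin for bin.  Point-cloud-to-mesh reconstruction is out of scope; meshes
arrive ready-made (fixtures come from the generator).

## Problem sizes and determinism

Default analysis sizes — 30 tracks × 500 frames for diffusion, 15 × 400
for the capture experiment, 8–10 cells per population profile, ~60
rendered puncta, ~1300-vertex meshes — are chosen so each analysis
completes in seconds while keeping Monte-Carlo errors comfortably inside
the tested tolerances (e.g. the 10-seed median D lands within ~1% of
truth against a 15% acceptance band).  All generators take explicit
integer seeds and are bit-reproducible; the acceptance script derives
every internal seed from its single `--seed` argument.

## Known limitations

* The binarization threshold rule and the normalized-sum definition for
  the outer boundary are not uniquely determined by the source
  workflow's description; both are configurable, and population-profile
  claims are reproduced qualitatively (shape), not numerically.
* Along-axis image registration is accurate to ±1 px for straight
  cells (shallow correlation along the long axis); drift *changes* are
  exact.
* The SEM of pooled MSD ignores pair correlation (see above).
* The RMSD-threshold calibration assumes the immobile mode is the lowest
  mode and resolvable; when it is not, calibration raises and the
  57.3 nm default (or a manual threshold) must be used.
* Simulated 2D diffusion ignores membrane curvature; simulated images
  ignore camera gain/read noise and depth effects.
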