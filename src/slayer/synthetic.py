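"""Synthetic observables with known ground truth.

This module generates the three kinds of data the analysis pipeline
consumes, each with the ground truth needed to test the downstream stages:

* Brownian single-molecule trajectories on a membrane, with optional
  first-order capture at immobile nucleation seeds, finite camera exposure
  (motion blur) and per-axis Gaussian localization error;
* two-color STED-like cell images (transmitted light + up to two
  fluorescence channels) with configurable surface-label patterns and
  Poisson photon noise;
* spherocylinder (capsule) surface meshes with analytically known Gaussian
  curvature.

Units: lengths in nm, times in s, diffusion coefficients in um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .tracks import Track

UM2_TO_NM2 = 1.0e6


# --------------------------------------------------------------------------
# Brownian trajectories
# --------------------------------------------------------------------------

@dataclass
class BindingConfig:
    """First-order capture kinetics at immobile nucleation seeds.

    A molecule within ``capture_radius`` (nm) of a seed binds with rate
    ``on_rate`` (1/s); a bound molecule is immobile and unbinds with rate
    ``off_rate`` (1/s).  ``off_rate = 0`` makes the bound state absorbing.
    """

    seed_positions: np.ndarray  # (n_seeds, d) nm
    capture_radius: float = 150.0
    on_rate: float = 50.0
    off_rate: float = 0.0

    def __post_init__(self) -> None:
        self.seed_positions = np.atleast_2d(
            np.asarray(self.seed_positions, dtype=float))
        if self.seed_positions.shape[0] == 0:
            raise ValueError("binding.seed_positions must be non-empty")
        for name in ("capture_radius", "on_rate", "off_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"binding.{name} must be finite and >= 0")


@dataclass
class TrackSimConfig:
    """Camera-sampled Brownian motion with motion blur and binding.

    The camera integrates for ``exposure_time`` (tau_E) out of each
    ``frame_interval``; the reported position per frame is the mean of
    ``n_substeps_per_exposure`` intra-exposure positions (converging to the
    continuous-exposure average responsible for the tau_E/3 term of the MSD
    model), plus independent Gaussian localization error per axis.
    """

    diffusion_coefficient: float = 0.077   # um^2/s
    frame_interval: float = 0.05           # s  (20 frames/s)
    exposure_time: float = 0.05            # s  (tau_E)
    n_substeps_per_exposure: int = 10
    localization_error_xyz: tuple = (93.0, 93.0, 91.0)  # nm, (s1, s2, s3)
    n_tracks: int = 30
    n_frames_per_track: int = 500
    dimensionality: int = 3
    binding: BindingConfig | None = None
    start_box_nm: float = 2000.0  # tracks start uniform in [-box/2, box/2]^d
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diffusion_coefficient", "frame_interval",
                     "exposure_time"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if not (0.0 < self.exposure_time <= self.frame_interval):
            raise ValueError(
                "exposure_time must satisfy 0 < exposure_time <= "
                "frame_interval")
        if self.n_substeps_per_exposure < 1:
            raise ValueError("n_substeps_per_exposure must be >= 1")
        err = np.asarray(self.localization_error_xyz, dtype=float)
        if not np.all(np.isfinite(err)) or np.any(err < 0):
            raise ValueError(
                "localization_error_xyz must be finite and >= 0")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")


def simulate_tracks(config: TrackSimConfig) -> list[Track]:
    """Simulate camera-sampled Brownian tracks with ground truth.

    Each returned :class:`~slayer.tracks.Track` carries the *observed*
    positions (blur-averaged + localization noise); ground truth is
    attached as ``track.true_positions`` (blur-averaged, noise-free) and
    ``track.true_state`` (bound flag per frame, majority state over the
    exposure).
    """
    rng = np.random.default_rng(config.rng_seed)
    d = config.dimensionality
    D_nm2 = config.diffusion_coefficient * UM2_TO_NM2  # nm^2/s
    n_sub = config.n_substeps_per_exposure
    dt_sub = config.exposure_time / n_sub
    dt_gap = config.frame_interval - config.exposure_time
    sigma_sub = np.sqrt(2.0 * D_nm2 * dt_sub)
    sigma_gap = np.sqrt(2.0 * D_nm2 * dt_gap) if dt_gap > 0 else 0.0
    err = np.asarray(config.localization_error_xyz, dtype=float)[:d]

    binding = config.binding
    if binding is not None:
        seeds = binding.seed_positions[:, :d]
        seed_tree = cKDTree(seeds)
        p_on = 1.0 - np.exp(-binding.on_rate * dt_sub)
        p_off = 1.0 - np.exp(-binding.off_rate * dt_sub)

    if binding is None:
        # free diffusion has no state dependence: vectorize whole tracks
        n_f = config.n_frames_per_track
        tracks = []
        for tid in range(config.n_tracks):
            start = rng.uniform(-config.start_box_nm / 2.0,
                                config.start_box_nm / 2.0, size=d)
            n_step = n_sub + (1 if dt_gap > 0 else 0)
            sigmas = np.full(n_step, sigma_sub)
            if dt_gap > 0:
                sigmas[-1] = sigma_gap
            inc = sigmas[None, :, None] * rng.standard_normal(
                (n_f, n_step, d))
            pos_sub = start + np.cumsum(
                inc.reshape(n_f * n_step, d), axis=0).reshape(
                n_f, n_step, d)
            truth = pos_sub[:, :n_sub, :].mean(axis=1)
            obs = truth + err * rng.standard_normal((n_f, d))
            frames = np.arange(n_f)
            tr = Track(tid, frames, frames * config.frame_interval, obs,
                       err.copy(),
                       true_state=np.zeros(n_f, dtype=bool))
            tr.true_positions = truth
            tracks.append(tr)
        return tracks

    tracks: list[Track] = []
    for tid in range(config.n_tracks):
        pos = rng.uniform(-config.start_box_nm / 2.0,
                          config.start_box_nm / 2.0, size=d)
        bound = False
        obs = np.empty((config.n_frames_per_track, d))
        truth = np.empty_like(obs)
        state = np.empty(config.n_frames_per_track, dtype=bool)
        for f in range(config.n_frames_per_track):
            sub_pos = np.empty((n_sub, d))
            n_bound_sub = 0
            for k in range(n_sub):
                if binding is not None:
                    if bound:
                        if p_off > 0 and rng.random() < p_off:
                            bound = False
                    else:
                        dist, _ = seed_tree.query(pos)
                        if dist < binding.capture_radius and \
                                rng.random() < p_on:
                            bound = True
                if not bound:
                    pos = pos + sigma_sub * rng.standard_normal(d)
                sub_pos[k] = pos
                n_bound_sub += bound
            truth[f] = sub_pos.mean(axis=0)
            state[f] = n_bound_sub * 2 >= n_sub
            obs[f] = truth[f] + err * rng.standard_normal(d)
            if dt_gap > 0 and not bound:
                pos = pos + sigma_gap * rng.standard_normal(d)
        frames = np.arange(config.n_frames_per_track)
        tr = Track(tid, frames, frames * config.frame_interval, obs,
                   err.copy(), true_state=state)
        tr.true_positions = truth  # ground truth rides along
        tracks.append(tr)
    return tracks


# --------------------------------------------------------------------------
# Cell images
# --------------------------------------------------------------------------

@dataclass
class LabelPattern:
    """Where surface-label molecules sit on the projected cell outline."""

    kind: str = "uniform"  # uniform | polar_enriched | crack_features | puncta
    n_molecules: int = 2000
    polar_fraction: float = 0.8        # polar_enriched: fraction in caps
    n_cracks: int = 3                  # crack_features
    puncta: list = field(default_factory=list)  # [(x_nm, y_nm, n_molecules)]

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "polar_enriched", "crack_features",
                             "puncta"):
            raise ValueError(f"unknown label pattern kind {self.kind!r}")


@dataclass
class CellGeometry:
    """Projected spherocylinder: body plus optional bend and stalk (nm)."""

    body_length: float = 2000.0        # cylindrical section length
    body_radius: float = 400.0
    centerline_curvature: float = 0.0  # 1/nm; 0 = straight rod
    stalk_length: float = 0.0
    stalk_radius: float = 60.0


@dataclass
class ImageSimConfig:
    """STED-like two-color cell image with Poisson photon statistics."""

    pixel_size: float = 20.0                      # nm (20 STED, 100 confocal)
    psf_fwhm_per_channel: tuple = (60.0, 80.0)    # nm
    photons_per_molecule_mean: float = 100.0
    background_mean: float = 0.5                  # photons/pixel
    cell_geometry: CellGeometry = field(default_factory=CellGeometry)
    channel_patterns: tuple = (LabelPattern(),)   # one or two channels
    margin: float = 500.0                         # nm of empty border
    transmitted_peak: float = 200.0               # photons at the centerline
    outline_band: float = 200.0                   # nm label band thickness
    add_poisson_noise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if any(f <= 0 for f in self.psf_fwhm_per_channel):
            raise ValueError("psf_fwhm_per_channel must be > 0")
        if self.photons_per_molecule_mean < 0 or self.background_mean < 0:
            raise ValueError("photon means must be >= 0")
        if not 1 <= len(self.channel_patterns) <= 2:
            raise ValueError("one or two channel_patterns required")


@dataclass
class SimulatedCellImage:
    """Rendered channels plus ground truth for one synthetic cell."""

    transmitted: np.ndarray            # photons/px (noisy if configured)
    channels: list                     # list of noisy photon images
    expected_channels: list            # noise-free expectation per channel
    label_masks: list                  # boolean emitter-region mask/channel
    emitter_positions: list            # (n, 2) nm per channel (x, y)
    punctum_truth: list                # per channel: [(x, y, n_molecules)]
    silhouette: np.ndarray             # boolean cell-body mask
    centerline: np.ndarray             # (m, 2) nm dense centerline samples
    pixel_size: float
    config: ImageSimConfig


def _centerline_points(geom: CellGeometry, n: int = 512) -> np.ndarray:
    """Dense (x, y) nm samples of the body centerline, centred at origin."""
    L = geom.body_length
    s = np.linspace(-L / 2.0, L / 2.0, n)
    if abs(geom.centerline_curvature) < 1e-12 or L == 0:
        return np.column_stack([s, np.zeros_like(s)])
    R = 1.0 / geom.centerline_curvature
    theta = s / R
    x = R * np.sin(theta)
    y = R * (1.0 - np.cos(theta))
    return np.column_stack([x, y - y.mean()])


def _grid_nm(shape, pixel_size, origin):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx * pixel_size + origin[0], yy * pixel_size + origin[1])


def simulate_cell_image(config: ImageSimConfig) -> SimulatedCellImage:
    """Render transmitted-light + fluorescence channels for one cell.

    The transmitted channel has a parabolic cross-section profile (maximal
    at the centerline, dropping to zero at the cell edge) so that the
    per-column intensity maximum tracks the medial axis and the intensity
    gradient peaks at the cell boundary, as the profile pipeline assumes.
    Fluorescence channels are rendered as point emitters placed according
    to the channel's :class:`LabelPattern`, convolved with a Gaussian PSF,
    plus uniform background, then Poisson-sampled.
    """
    rng = np.random.default_rng(config.rng_seed)
    geom = config.cell_geometry
    px = config.pixel_size

    cl = _centerline_points(geom)
    # stalk: thin rod extending from the left pole along -x
    left_pole = cl[0]
    if geom.stalk_length > 0:
        sx = np.linspace(left_pole[0] - geom.body_radius -
                         geom.stalk_length, left_pole[0], 64)
        stalk = np.column_stack([sx, np.full_like(sx, left_pole[1])])
    else:
        stalk = np.empty((0, 2))

    all_pts = np.vstack([cl, stalk]) if len(stalk) else cl
    lo = all_pts.min(axis=0) - geom.body_radius - config.margin
    hi = all_pts.max(axis=0) + geom.body_radius + config.margin
    shape = (int(np.ceil((hi[1] - lo[1]) / px)),
             int(np.ceil((hi[0] - lo[0]) / px)))
    gx, gy = _grid_nm(shape, px, lo)

    tree = cKDTree(cl)
    d_body, idx_body = tree.query(np.column_stack([gx.ravel(), gy.ravel()]))
    d_body = d_body.reshape(shape)
    silhouette = d_body <= geom.body_radius

    # transmitted-light edge (the cell membrane) sits half an outline band
    # inside the outer label surface; intensity peaks on the centerline and
    # steps down to zero at the membrane, so per-column maxima track the
    # medial axis and the gradient peaks sharply at the boundary
    r_t = geom.body_radius - config.outline_band / 2.0
    trans = np.where(
        d_body <= r_t,
        config.transmitted_peak * (1.0 - 0.5 * (d_body / r_t) ** 2), 0.0)
    if len(stalk):
        d_stalk = cKDTree(stalk).query(
            np.column_stack([gx.ravel(), gy.ravel()]))[0].reshape(shape)
        trans = np.maximum(trans, np.where(
            d_stalk <= geom.stalk_radius,
            0.6 * config.transmitted_peak *
            (1.0 - 0.5 * (d_stalk / geom.stalk_radius) ** 2), 0.0))
    trans = gaussian_filter(trans, 1.0) + 5.0  # slight blur + camera offset

    band = config.outline_band
    boundary_mask = (d_body <= geom.body_radius) & \
                    (d_body >= geom.body_radius - band)

    channels, expected, masks, emit_xy, punct_truth = [], [], [], [], []
    for ch, pattern in enumerate(config.channel_patterns):
        fwhm = config.psf_fwhm_per_channel[
            min(ch, len(config.psf_fwhm_per_channel) - 1)]
        sigma_px = fwhm / 2.3548 / px
        positions, per_photons, truth = _place_emitters(
            pattern, cl, geom, config, rng)
        density = np.zeros(shape)
        if len(positions):
            ix = np.clip(((positions[:, 0] - lo[0]) / px).round().astype(int),
                         0, shape[1] - 1)
            iy = np.clip(((positions[:, 1] - lo[1]) / px).round().astype(int),
                         0, shape[0] - 1)
            np.add.at(density, (iy, ix), per_photons)
        exp_img = gaussian_filter(density, sigma_px) + config.background_mean
        mask = np.zeros(shape, dtype=bool)
        if len(positions):
            mask[iy, ix] = True
        if pattern.kind == "uniform":
            mask = boundary_mask.copy()
        img = (rng.poisson(exp_img).astype(float)
               if config.add_poisson_noise else exp_img.copy())
        channels.append(img)
        expected.append(exp_img)
        masks.append(mask)
        emit_xy.append(positions - lo)  # nm, image frame (origin at px 0,0)
        punct_truth.append([(x - lo[0], y - lo[1], n) for x, y, n in truth])

    if config.add_poisson_noise:
        trans = rng.poisson(trans).astype(float)

    return SimulatedCellImage(
        transmitted=trans, channels=channels, expected_channels=expected,
        label_masks=masks, emitter_positions=emit_xy,
        punctum_truth=punct_truth, silhouette=silhouette,
        centerline=cl - lo, pixel_size=px, config=config)


def _place_emitters(pattern, cl, geom, config, rng):
    """Return (positions_nm, photons_per_emitter, punctum_truth)."""
    ppm = config.photons_per_molecule_mean
    band = config.outline_band
    tree = cKDTree(cl)
    lo_box = cl.min(axis=0) - geom.body_radius
    hi_box = cl.max(axis=0) + geom.body_radius

    def on_outline(n, arc_range=None):
        """Uniform emitters in the projected outline band (caps included).

        Rejection sampling over the band region {r - band <= d(p,
        centerline) <= r}; ``arc_range`` restricts to points whose nearest
        centerline sample lies in that normalized index range.
        """
        m = len(cl)
        out = np.empty((0, 2))
        while len(out) < n:
            cand = rng.uniform(lo_box, hi_box, size=(max(4 * n, 256), 2))
            d, idx = tree.query(cand)
            keep = (d <= geom.body_radius) & \
                   (d >= geom.body_radius - band)
            if arc_range is not None:
                frac = idx / (m - 1)
                keep &= (frac >= arc_range[0]) & (frac <= arc_range[1])
            out = np.vstack([out, cand[keep]])
        return out[:n]

    truth: list[tuple] = []
    if pattern.kind == "uniform":
        pos = on_outline(pattern.n_molecules)
        photons = np.full(len(pos), ppm)
    elif pattern.kind == "polar_enriched":
        n_polar = int(round(pattern.polar_fraction * pattern.n_molecules))
        n_body = pattern.n_molecules - n_polar
        # caps = outer 10% of arc length each end, plus true cap arcs
        cap_frac = 0.08
        half = n_polar // 2
        p1 = on_outline(half, (0.0, cap_frac))
        p2 = on_outline(n_polar - half, (1.0 - cap_frac, 1.0))
        pb = on_outline(n_body)
        pos = np.vstack([p1, p2, pb])
        photons = np.full(len(pos), ppm)
    elif pattern.kind == "crack_features":
        # short transverse segments across the body + polar caps
        per_crack = pattern.n_molecules // max(pattern.n_cracks, 1)
        chunks = []
        for _ in range(pattern.n_cracks):
            s = rng.uniform(0.2, 0.8)
            c = cl[int(s * (len(cl) - 1))]
            t = np.linspace(-geom.body_radius, geom.body_radius, per_crack)
            jitter = rng.normal(0, 10.0, size=(per_crack, 2))
            chunks.append(np.column_stack([np.full(per_crack, c[0]),
                                           c[1] + t]) + jitter)
        pos = np.vstack(chunks) if chunks else np.empty((0, 2))
        photons = np.full(len(pos), ppm)
    else:  # puncta
        chunks, photons_l = [], []
        half_w = (np.ptp(cl[:, 0]) / 2.0 + geom.body_radius +
                  config.margin)
        for (x, y, n) in pattern.puncta:
            if abs(x) > half_w or abs(y) > half_w:
                raise ValueError(
                    f"punctum center ({x}, {y}) nm outside the image")
            chunks.append(np.array([[x, y]]))
            photons_l.append(n * ppm)
            truth.append((x, y, n))
        pos = (np.vstack(chunks) if chunks else np.empty((0, 2)))
        photons = np.asarray(photons_l, dtype=float)
    return pos, photons, truth


# --------------------------------------------------------------------------
# Spherocylinder meshes
# --------------------------------------------------------------------------

def make_spherocylinder_mesh(body_length: float, radius: float,
                             subdivisions: int = 24) -> trimesh.Trimesh:
    """Closed spherocylinder mesh, long axis along x, centred at origin.

    Built as a surface of revolution: two hemispherical caps of the given
    radius joined by a cylindrical body sampled with evenly spaced rings,
    so vertices cover the developable body as well as the caps.
    ``subdivisions`` sets the number of points around the circumference
    (and scales the meridian sampling).  ``body_length = 0`` degenerates
    to a sphere.  The result is watertight and genus-0 (V - E + F = 2).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if subdivisions < 4:
        raise ValueError("subdivisions must be >= 4 to close the surface")
    if body_length < 0:
        raise ValueError("body_length must be >= 0")

    n_around = int(subdivisions)
    n_cap = max(subdivisions // 4, 3)          # latitude rings per cap
    # meridian profile: (x, distance from axis), poles excluded
    phis = np.linspace(0.0, np.pi / 2.0, n_cap + 1)[1:]
    left = [(-body_length / 2.0 - radius * np.cos(p), radius * np.sin(p))
            for p in phis]
    if body_length > 0:
        ring_arc = radius * (np.pi / 2.0) / n_cap
        n_body = max(int(np.ceil(body_length / ring_arc)) - 1, 0)
        xs = np.linspace(-body_length / 2.0, body_length / 2.0,
                         n_body + 2)[1:-1]
        body = [(x, radius) for x in xs]
    else:
        body = []
    right = [(body_length / 2.0 + radius * np.cos(p), radius * np.sin(p))
             for p in phis[::-1]]
    profile = left + body + right

    theta = np.linspace(0.0, 2.0 * np.pi, n_around, endpoint=False)
    verts = [np.array([-body_length / 2.0 - radius, 0.0, 0.0])]
    for (x, r) in profile:
        ring = np.column_stack([np.full(n_around, x),
                                r * np.cos(theta), r * np.sin(theta)])
        verts.append(ring)
    verts.append(np.array([body_length / 2.0 + radius, 0.0, 0.0]))
    vertices = np.vstack([verts[0][None]] + verts[1:-1] +
                         [verts[-1][None]])

    faces = []
    n_rings = len(profile)
    first = 1                                   # index of first ring vertex
    last_pole = 1 + n_rings * n_around
    for j in range(n_around):                   # left pole fan
        a = first + j
        b = first + (j + 1) % n_around
        faces.append([0, b, a])
    for i in range(n_rings - 1):                # quad strips
        r0 = first + i * n_around
        r1 = first + (i + 1) * n_around
        for j in range(n_around):
            a, b = r0 + j, r0 + (j + 1) % n_around
            c, d = r1 + j, r1 + (j + 1) % n_around
            faces.append([a, b, c])
            faces.append([b, d, c])
    top = first + (n_rings - 1) * n_around
    for j in range(n_around):                   # right pole fan
        a = top + j
        b = top + (j + 1) % n_around
        faces.append([last_pole, a, b])

    mesh = trimesh.Trimesh(vertices, np.asarray(faces), process=False)
    mesh.fix_normals()
    if not mesh.is_watertight:
        raise ValueError("subdivisions too small to close the surface")
    return mesh
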