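"""Bound/unbound classification of single-molecule tracks.

A molecule bound to an S-layer crystal patch is immobile up to the
localization precision, so the root-mean-squared deviation (RMSD) of its
positions from the window mean over a 1 s (20-frame) sliding window is
small; a diffusing molecule's RMSD is large.  A binding threshold is
calibrated as 2 sigma above the mean of a Gaussian fitted to the
lowest-RMSD mode of the pooled RMSD histogram (the mode set by
localization precision); the field-calibrated default is 57.3 nm.
Per-frame bound flags are combined with the distance to the nearest
nucleation seed (d_NS, proximity < 300 nm) into co-occupancy fractions of
time spent near-and-unbound, near-and-bound, and bound-but-not-near.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats
from scipy.spatial import cKDTree

from .tracks import Track

#: default binding threshold (nm): 2 sigma above the immobile-mode mean
BINDING_THRESHOLD_NM = 57.3
#: default crystal-patch proximity threshold on d_NS (nm)
PROXIMITY_NM = 300.0
#: RMSD window: 20 frames = 1 s at 20 frames/s
RMSD_WINDOW_FRAMES = 20


# --------------------------------------------------------------------------
# Track linking
# --------------------------------------------------------------------------

def link_localizations(localizations, max_step: float,
                       max_gap: int = 0) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Candidate (active track, localization) pairs in each frame are accepted
    in order of increasing distance (ties broken by lower localization
    index); links longer than ``max_step`` nm are rejected and detection
    gaps up to ``max_gap`` frames are bridged.  Unlinked localizations seed
    new tracks, so every input row ends up in exactly one track.

    ``localizations`` is a DataFrame with columns frame, t_s, x_nm, y_nm
    [, z_nm] (as written by the simulator).
    """
    df = localizations.sort_values(["frame"]).reset_index(drop=True)
    has_z = "z_nm" in df.columns and not df["z_nm"].isna().all()
    cols = ["x_nm", "y_nm"] + (["z_nm"] if has_z else [])

    active: list[dict] = []   # {'last_pos','last_frame','rows'}
    done: list[dict] = []
    for f, g in df.groupby("frame", sort=True):
        pts = g[cols].to_numpy(float)
        rows = list(g.index)
        # retire tracks that can no longer be extended
        still = []
        for tr in active:
            if f - tr["last_frame"] > max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        # all candidate pairs within max_step, greedy by (distance, index)
        pairs = []
        for ti, tr in enumerate(active):
            d = np.linalg.norm(pts - tr["last_pos"], axis=1)
            for li in range(len(rows)):
                if d[li] <= max_step:
                    pairs.append((d[li], li, ti))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_t, used_l = set(), set()
        for d, li, ti in pairs:
            if ti in used_t or li in used_l:
                continue
            used_t.add(ti)
            used_l.add(li)
            active[ti]["rows"].append(rows[li])
            active[ti]["last_pos"] = pts[li]
            active[ti]["last_frame"] = f
        for li in range(len(rows)):
            if li not in used_l:
                active.append({"last_pos": pts[li], "last_frame": f,
                               "rows": [rows[li]]})
    done.extend(active)
    done.sort(key=lambda tr: tr["rows"][0])

    tracks = []
    for tid, tr in enumerate(done):
        g = df.loc[tr["rows"]].sort_values("frame")
        unc = np.zeros(len(cols))
        for i, c in enumerate(("sx_nm", "sy_nm", "sz_nm")[:len(cols)]):
            if c in g:
                unc[i] = float(np.nan_to_num(g[c].iloc[0]))
        tracks.append(Track(tid, g["frame"].to_numpy(int),
                            g["t_s"].to_numpy(float),
                            g[cols].to_numpy(float), unc))
    return tracks


# --------------------------------------------------------------------------
# Sliding-window RMSD and classification
# --------------------------------------------------------------------------

def sliding_rmsd(track: Track, window: int = RMSD_WINDOW_FRAMES):
    """RMSD from the window-mean position over a sliding window.

    For every run of ``window`` consecutive localizations the RMSD is
    sqrt(mean |r - r_bar|^2) over the window, assigned to the window's
    centre frame (index ``i + window // 2`` for the window starting at
    ``i``).  Tracks shorter than the window yield empty arrays.

    Returns ``(frames, rmsd)`` arrays.
    """
    n = len(track)
    if window < 2:
        raise ValueError("window must be >= 2 frames")
    if n < window:
        return np.empty(0, dtype=int), np.empty(0)
    pos = track.positions
    # cumulative sums give O(n) windowed moments
    c1 = np.vstack([np.zeros(pos.shape[1]), np.cumsum(pos, axis=0)])
    c2 = np.concatenate([[0.0], np.cumsum(np.sum(pos ** 2, axis=1))])
    i = np.arange(n - window + 1)
    wsum = c1[i + window] - c1[i]          # (m, d)
    wsq = c2[i + window] - c2[i]           # (m,)
    mean_sq = np.sum(wsum ** 2, axis=1) / window ** 2
    msd_from_mean = wsq / window - mean_sq
    rmsd = np.sqrt(np.maximum(msd_from_mean, 0.0))
    centers = track.frames[i + window // 2]
    return centers, rmsd


@dataclass
class ThresholdCalibration:
    """Binding threshold = mean + 2 sigma of the lowest-RMSD mode."""

    fitted_mean: float     # nm
    fitted_sigma: float    # nm
    threshold: float       # nm
    n_values: int = 0
    cutoff: float | None = None   # KDE anti-mode used to isolate the mode

    @classmethod
    def paper_default(cls) -> "ThresholdCalibration":
        """Field-calibrated default threshold (57.3 nm, 2D tracking)."""
        return cls(fitted_mean=np.nan, fitted_sigma=np.nan,
                   threshold=BINDING_THRESHOLD_NM)


def calibrate_threshold(rmsd_values,
                        min_values: int = 500) -> ThresholdCalibration:
    """Fit a Gaussian to the lowest-RMSD population; threshold = mu + 2 sigma.

    The immobile population is isolated as the values below the first
    anti-mode (valley) of a kernel-density estimate of the pooled RMSD
    values; a Gaussian is then fitted by least squares to the
    Freedman-Diaconis histogram of bins below that cutoff (all bins when
    the density is unimodal).  Raises ``ValueError`` when the low-RMSD
    mode cannot be resolved, in which case a manual threshold (e.g. the
    57.3 nm default) should be supplied.
    """
    vals = np.asarray(rmsd_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < min_values:
        raise ValueError(
            f"need >= {min_values} pooled RMSD values, got {vals.size}")

    kde = stats.gaussian_kde(vals)
    grid = np.linspace(vals.min(), vals.max(), 512)
    dens = kde(grid)
    minima = signal.argrelmin(dens)[0]
    maxima = signal.argrelmax(dens)[0]
    # ignore negligible tail bumps when looking for the first mode and the
    # valley separating it from the mobile population
    maxima = maxima[dens[maxima] >= 0.05 * dens.max()]
    cutoff = None
    if minima.size and maxima.size:
        after = minima[minima > maxima[0]]
        for m in after:
            if dens[m] < 0.9 * dens[maxima[0]]:
                cutoff = float(grid[m])
                break

    # histogram of the low-mode population only, so the Gaussian fit has
    # full resolution there regardless of the mobile population's tail
    sub = vals[vals < cutoff] if cutoff is not None else vals
    if sub.size < 50:
        raise ValueError("no resolvable low-RMSD mode; supply a manual "
                         "threshold (e.g. ThresholdCalibration.paper_default)")
    counts, edges = np.histogram(sub, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    sel = np.ones_like(centers, dtype=bool)
    if sel.sum() < 5:
        raise ValueError("no resolvable low-RMSD mode; supply a manual "
                         "threshold (e.g. ThresholdCalibration.paper_default)")
    p0 = (counts.max(), float(np.median(sub)), float(sub.std() or 1.0))

    def gauss(x, a, mu, sig):
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    try:
        popt, _ = optimize.curve_fit(gauss, centers[sel], counts[sel],
                                     p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise ValueError("no resolvable low-RMSD mode; supply a manual "
                         "threshold") from exc
    mu, sig = float(popt[1]), float(abs(popt[2]))
    if sig <= 0 or not np.isfinite(mu):
        raise ValueError("degenerate Gaussian fit; supply a manual threshold")
    return ThresholdCalibration(fitted_mean=mu, fitted_sigma=sig,
                                threshold=mu + 2.0 * sig,
                                n_values=vals.size, cutoff=cutoff)


def classify_bound(rmsd, threshold: float = BINDING_THRESHOLD_NM):
    """Bound iff RMSD < threshold (strict); RMSD >= threshold is unbound."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return np.asarray(rmsd, dtype=float) < threshold


# --------------------------------------------------------------------------
# Nucleation seeds
# --------------------------------------------------------------------------

@dataclass
class Seed:
    x_nm: float
    y_nm: float
    sigma_nm: float
    stationary: bool = True
    overlapping: bool = False


def _fit_symmetric_gaussian(window, x0, y0, pixel_size):
    """Symmetric 2D Gaussian fit; returns (x_nm, y_nm, sigma_nm)."""
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]

    def model(_, a, cx, cy, sig, off):
        return (a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) /
                           (2 * sig ** 2)) + off).ravel()

    a0 = float(window.max() - window.min())
    p0 = (a0, w / 2.0, h / 2.0, max(w / 6.0, 1.0), float(window.min()))
    popt, _ = optimize.curve_fit(model, None, window.ravel(), p0=p0,
                                 maxfev=10000)
    cx, cy, sig = popt[1], popt[2], abs(popt[3])
    return ((x0 + cx) * pixel_size, (y0 + cy) * pixel_size,
            sig * pixel_size)


def locate_seeds(stack, pixel_size: float, psf_fwhm_nm: float,
                 localization_precision_nm: float = 20.0,
                 detection_nsigma: float = 10.0) -> list[Seed]:
    """Locate stationary nucleation seeds in a seed-channel image (stack).

    Each seed is fitted per frame with a symmetric 2D Gaussian; the
    reported position is the temporal mean.  A seed whose positional SD
    over time exceeds twice the localization precision is flagged
    non-stationary; seeds closer than one PSF FWHM are flagged overlapping.
    A single 2D image is treated as a 1-frame stack.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    ref = stack.mean(axis=0)
    med = np.median(ref)
    mad = np.median(np.abs(ref - med)) * 1.4826
    if mad == 0:
        mad = max(ref.std(), 1e-12)
    thr = med + detection_nsigma * mad
    from skimage.feature import peak_local_max
    min_d = max(int(round(psf_fwhm_nm / pixel_size)), 1)
    peaks = peak_local_max(ref, min_distance=min_d, threshold_abs=thr)
    if peaks.size == 0:
        raise ValueError("no seed signal above threshold")

    half = max(int(round(1.5 * psf_fwhm_nm / pixel_size)), 3)
    seeds = []
    for (py, px_) in peaks:
        y0, y1 = max(py - half, 0), min(py + half + 1, ref.shape[0])
        x0, x1 = max(px_ - half, 0), min(px_ + half + 1, ref.shape[1])
        per_frame = []
        for frame in stack:
            try:
                per_frame.append(_fit_symmetric_gaussian(
                    frame[y0:y1, x0:x1], x0, y0, pixel_size))
            except RuntimeError:
                continue
        if not per_frame:
            continue
        arr = np.asarray(per_frame)
        x_nm, y_nm, sig = arr[:, 0].mean(), arr[:, 1].mean(), arr[:, 2].mean()
        sd = float(np.hypot(arr[:, 0].std(), arr[:, 1].std())) \
            if len(arr) > 1 else 0.0
        seeds.append(Seed(float(x_nm), float(y_nm), float(sig),
                          stationary=sd < 2.0 * localization_precision_nm))
    pos = np.array([[s.x_nm, s.y_nm] for s in seeds])
    if len(seeds) > 1:
        dmat = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(dmat, np.inf)
        for i, s in enumerate(seeds):
            if dmat[i].min() < psf_fwhm_nm:
                s.overlapping = True
    return seeds


def distance_to_nearest_seed(track: Track, seeds) -> np.ndarray:
    """Per-frame Euclidean distance (nm) to the closest seed (xy plane)."""
    if len(seeds) and isinstance(seeds[0], Seed):
        pts = np.asarray([[s.x_nm, s.y_nm] for s in seeds], dtype=float)
    else:
        pts = np.atleast_2d(np.asarray(seeds, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("at least one seed required")
    tree = cKDTree(pts)
    d, _ = tree.query(track.positions[:, :2])
    return d


# --------------------------------------------------------------------------
# Co-occupancy
# --------------------------------------------------------------------------

@dataclass
class CooccupancySummary:
    """Fractions of classified time in each binding/proximity category."""

    total_time: float          # s
    frac_near_unbound: float
    frac_near_bound: float
    frac_bound_not_near: float

    @property
    def frac_neither(self) -> float:
        return 1.0 - (self.frac_near_unbound + self.frac_near_bound +
                      self.frac_bound_not_near)


def cooccupancy(bound, d_ns, frame_interval: float,
                proximity: float = PROXIMITY_NM) -> CooccupancySummary:
    """Fractions of time near a crystal patch and/or bound.

    ``near`` means d_NS < proximity (strict, matching the strict binding
    inequality).  Fractions are of the total classified time (frames where
    both series are defined); the three categories plus "neither" sum to 1.
    """
    bound = np.asarray(bound, dtype=bool)
    d_ns = np.asarray(d_ns, dtype=float)
    if bound.shape != d_ns.shape:
        raise ValueError("bound and d_ns series must be frame-aligned")
    ok = np.isfinite(d_ns)
    if not ok.any():
        raise ValueError("no frames with both series defined")
    bound, d_ns = bound[ok], d_ns[ok]
    near = d_ns < proximity
    n = bound.size
    return CooccupancySummary(
        total_time=n * frame_interval,
        frac_near_unbound=float(np.sum(near & ~bound)) / n,
        frac_near_bound=float(np.sum(near & bound)) / n,
        frac_bound_not_near=float(np.sum(bound & ~near)) / n)


@dataclass
class MobilitySeries:
    """Per-frame mobility classification for one track (RMSD-defined frames)."""

    frames: np.ndarray
    rmsd: np.ndarray       # nm
    bound: np.ndarray
    d_ns: np.ndarray       # nm
    near_seed: np.ndarray


def analyze_track(track: Track, seeds, threshold: float = BINDING_THRESHOLD_NM,
                  proximity: float = PROXIMITY_NM,
                  window: int = RMSD_WINDOW_FRAMES) -> MobilitySeries:
    """Full per-track mobility analysis: RMSD, bound flags, d_NS, proximity."""
    frames, rmsd = sliding_rmsd(track, window)
    bound = classify_bound(rmsd, threshold)
    d_all = distance_to_nearest_seed(track, seeds)
    idx = {f: i for i, f in enumerate(track.frames)}
    d_ns = np.array([d_all[idx[f]] for f in frames])
    return MobilitySeries(frames, rmsd, bound, d_ns, d_ns < proximity)
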