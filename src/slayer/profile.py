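"""Binary cell-profile analysis of two-color super-resolution cell images.

Each cell image (transmitted light + up to two fluorescence channels) is
reduced to four 40-bin binary profiles: the fluorescence channels are
registered to the transmitted-light gradient, the cell is rotated
horizontal (stalk left), a medial axis is fitted to the transmitted
channel, a 200 nm wide outline band is built around the cell boundary,
each channel is smoothed (sigma = 0.9 px) and thresholded inside the
band, and every positive pixel is projected onto the normalized cell axis
into 40 equi-length bins, split into upper and lower cell halves — a
single positive pixel makes its bin positive.  Across a population of
cells each bin is then a binomial observation (k positive half-profiles
out of n = 2 x n_cells), summarized as a fraction with a Wilson score 95%
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion
from skimage.transform import radon, rotate
from statsmodels.stats.proportion import proportion_confint

N_BINS_DEFAULT = 40
OUTLINE_WIDTH_NM = 200.0
SMOOTH_SIGMA_PX = 0.9
#: cell length above which the axis uses a smoothing spline (filamentous
#: cells, e.g. division-inhibited) instead of a 2nd-order polynomial
SPLINE_LENGTH_NM = 6000.0


@dataclass
class CellRecord:
    """One pre-cropped cell: transmitted light + 1-2 fluorescence channels."""

    transmitted: np.ndarray
    channel_a: np.ndarray
    channel_b: np.ndarray | None = None
    pixel_size: float = 20.0                 # nm
    stalk_side: str = "unknown"              # left | right | unknown
    orientation_applied: float = 0.0         # degrees, cumulative
    mirrored: bool = False
    shifts_applied: dict = field(default_factory=dict)
    axis: "CellAxis | None" = None
    outline_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, ch in (("channel_a", self.channel_a),
                         ("channel_b", self.channel_b)):
            if ch is not None and ch.shape != self.transmitted.shape:
                raise ValueError(f"{name} shape differs from transmitted")
        if self.stalk_side not in ("left", "right", "unknown"):
            raise ValueError("stalk_side must be left/right/unknown")

    @property
    def channels(self) -> list:
        return [c for c in (self.channel_a, self.channel_b) if c is not None]


@dataclass
class CellAxis:
    """Medial axis of an oriented cell, arc-length parameterized on [0,1]."""

    model_kind: str                    # poly2 | smoothing_spline
    coefficients: np.ndarray           # polyfit coeffs or spline knots repr
    x_range: tuple                     # (x_min, x_max) in px
    samples: np.ndarray                # (m, 2) densely sampled (x, y) px
    arclength: np.ndarray              # (m,) normalized arc length in [0,1]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arclength) < 0):
            raise ValueError("arc-length parameterization must be monotone")


# --------------------------------------------------------------------------
# Registration
# --------------------------------------------------------------------------

def register_channels(record: CellRecord,
                      max_shift: int = 10) -> CellRecord:
    """Translate fluorescence channels onto the transmitted-light gradient.

    Scan-drift correction: each channel is translated by the integer-pixel
    shift maximizing the normalized cross-correlation between its
    intensity and the gradient magnitude of the transmitted image,
    searched over +/- ``max_shift`` px (overlap-normalized, so the search
    is unbiased toward small shifts).  A correlation peak on the border of
    the search window marks the registration unreliable (recorded in
    ``shifts_applied``).
    """
    from skimage.feature import match_template

    grad = _gradient_magnitude(record.transmitted)
    padded = np.pad(grad, max_shift)
    for name in ("channel_a", "channel_b"):
        ch = getattr(record, name)
        if ch is None:
            continue
        ncc = match_template(padded, np.asarray(ch, dtype=float))
        peak = np.unravel_index(np.argmax(ncc), ncc.shape)
        shift = (int(peak[0]) - max_shift, int(peak[1]) - max_shift)
        unreliable = any(p in (0, s - 1) for p, s in zip(peak, ncc.shape))
        shifted = ndimage.shift(ch, shift, order=0, cval=0.0)
        setattr(record, name, shifted)
        record.shifts_applied[name] = {"shift": shift,
                                       "unreliable": bool(unreliable)}
    return record


def _gradient_magnitude(img) -> np.ndarray:
    gy, gx = np.gradient(np.asarray(img, dtype=float))
    return np.hypot(gx, gy)


# --------------------------------------------------------------------------
# Orientation
# --------------------------------------------------------------------------

def orient_cell(record: CellRecord, stalk_side: str | None = None,
                min_anisotropy: float = 1.2) -> CellRecord:
    """Rotate the cell horizontal (radon transform), stalk to the left.

    The long-axis angle is the radon projection angle of maximal variance;
    the image is rotated so that axis is horizontal, then mirrored when
    the declared stalk side is ``right``.  A nearly isotropic object (no
    dominant projection angle) raises ``ValueError``.
    """
    side = stalk_side or record.stalk_side
    img = np.asarray(record.transmitted, dtype=float)
    thetas = np.arange(0.0, 180.0, 1.0)
    sino = radon(img, theta=thetas, circle=False)
    variances = sino.var(axis=0)
    best = int(np.argmax(variances))
    if variances[best] < min_anisotropy * np.median(variances):
        raise ValueError("no dominant orientation: object is nearly "
                         "isotropic")
    # a horizontal cell peaks at theta = 90; a cell at angle a (CCW from
    # horizontal) peaks at theta = 90 + a, so rotating by (90 - theta)
    # makes the axis horizontal
    rot_deg = 90.0 - thetas[best]
    for name in ("transmitted", "channel_a", "channel_b"):
        ch = getattr(record, name)
        if ch is None:
            continue
        out = rotate(ch, rot_deg, resize=False, preserve_range=True,
                     order=1, cval=0.0)
        setattr(record, name, out)
    record.orientation_applied += rot_deg
    if side == "right":
        for name in ("transmitted", "channel_a", "channel_b"):
            ch = getattr(record, name)
            if ch is not None:
                setattr(record, name, np.fliplr(ch))
        record.mirrored = not record.mirrored
        record.stalk_side = "left"
    elif side == "left":
        record.stalk_side = "left"
    return record


# --------------------------------------------------------------------------
# Axis fit
# --------------------------------------------------------------------------

def fit_cell_axis(record: CellRecord, n_samples: int = 1000,
                  spline_length_nm: float = SPLINE_LENGTH_NM,
                  min_columns: int = 6) -> CellAxis:
    """Fit the medial axis through per-column transmitted-light maxima.

    For every image column where the cell is present (column max above
    half the Otsu threshold) the row of maximal transmitted intensity is
    taken; a 2nd-order polynomial is least-squares fitted through these
    points (a smoothing spline instead for cells longer than
    ``spline_length_nm``, the filamentous regime).  The axis is returned
    densely sampled with a normalized arc-length parameterization.
    """
    img = np.asarray(record.transmitted, dtype=float)
    col_max = img.max(axis=0)
    rough = np.where(col_max > 0.5 * threshold_otsu(img))[0]
    if rough.size < min_columns:
        raise ValueError(
            f"only {rough.size} usable columns (need >= {min_columns})")
    # keep columns where the ridge is strong (drops dim cap-edge columns)
    cols = np.where(col_max > 0.75 * np.median(col_max[rough]))[0]
    if cols.size < min_columns:
        cols = rough
    # sub-pixel ridge row: intensity-weighted centroid of near-maximal px
    rows = np.empty(cols.size)
    for i, c in enumerate(cols):
        col = img[:, c]
        base = 0.7 * col[np.argmax(col)]
        sel = np.nonzero(col >= base)[0]
        w = col[sel] - base
        rows[i] = (sel * w).sum() / w.sum() if w.sum() > 0 else np.argmax(col)

    length_nm = (cols.max() - cols.min()) * record.pixel_size
    xs = np.linspace(cols.min(), cols.max(), n_samples)
    if length_nm > spline_length_nm:
        from scipy.interpolate import UnivariateSpline
        order = np.argsort(cols)
        spl = UnivariateSpline(cols[order], rows[order],
                               s=len(cols) * 2.0, k=3)
        ys = spl(xs)
        kind, coeffs = "smoothing_spline", np.asarray(spl.get_coeffs())
    else:
        coeffs = np.polyfit(cols, rows, 2)
        ys = np.polyval(coeffs, xs)
        kind = "poly2"

    seg = np.hypot(np.diff(xs), np.diff(ys))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s /= s[-1]
    axis = CellAxis(model_kind=kind, coefficients=np.asarray(coeffs),
                    x_range=(float(cols.min()), float(cols.max())),
                    samples=np.column_stack([xs, ys]), arclength=s)
    record.axis = axis
    return axis


# --------------------------------------------------------------------------
# Outline band
# --------------------------------------------------------------------------

def make_outline(record: CellRecord, mode: str = "complete_layer",
                 width_nm: float = OUTLINE_WIDTH_NM) -> np.ndarray:
    """200 nm wide band mask following the cell boundary.

    ``complete_layer``: the outer boundary is the Otsu threshold of the
    max-normalized sum of the fluorescence channels (valid when the
    S-layer covers the cell); the band is that region minus its erosion
    by the band width.  ``incomplete_layer``: the band centre is the
    maximum of the transmitted-light gradient along normals to the cell
    axis, expanded to the full width (valid when fluorescence may be
    absent anywhere).
    """
    width_px = max(int(round(width_nm / record.pixel_size)), 1)
    if mode == "complete_layer":
        norm = np.zeros_like(np.asarray(record.channel_a, dtype=float))
        for ch in record.channels:
            m = float(np.max(ch))
            if m > 0:
                norm = norm + np.asarray(ch, dtype=float) / m
        if norm.max() <= 0:
            raise ValueError("empty boundary: no fluorescence signal")
        region = norm > threshold_otsu(norm)
        region = ndimage.binary_fill_holes(region)
        if not region.any():
            raise ValueError("empty boundary after thresholding")
        inner = erosion(region, disk(width_px))
        mask = region & ~inner
    elif mode == "incomplete_layer":
        if record.axis is None:
            fit_cell_axis(record)
        center = _gradient_ridge(record)
        if not center.any():
            raise ValueError("empty boundary: no transmitted-light "
                             "gradient ridge found")
        dist = ndimage.distance_transform_edt(~center)
        mask = dist <= width_px / 2.0
    else:
        raise ValueError(f"unknown outline mode {mode!r}")
    record.outline_mask = mask
    return mask


def _gradient_ridge(record: CellRecord) -> np.ndarray:
    """Boundary centre: per-axis-normal maximum of the transmitted gradient.

    Rays are cast from every other axis sample along both normals, plus
    fans from the two axis endpoints so the pole caps are covered.
    """
    grad = ndimage.gaussian_filter(
        _gradient_magnitude(record.transmitted), 1.0)
    H, W = grad.shape
    ridge = np.zeros((H, W), dtype=bool)
    samples = record.axis.samples
    tang = np.gradient(samples, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    ts = np.arange(1.0, max(H, W))

    def mark_ray(p, direction):
        xs = p[0] + ts * direction[0]
        ys = p[1] + ts * direction[1]
        ok = (xs >= 0) & (xs < W) & (ys >= 0) & (ys < H)
        if not ok.any():
            return
        xi = xs[ok].astype(int)
        yi = ys[ok].astype(int)
        vals = grad[yi, xi]
        j = int(np.argmax(vals))
        if vals[j] > 0:
            ridge[yi[j], xi[j]] = True

    for p, nrm in zip(samples[::2], normals[::2]):
        mark_ray(p, nrm)
        mark_ray(p, -nrm)
    # endpoint fans cover the hemispherical caps
    for end, outward in ((samples[0], -tang[0]), (samples[-1], tang[-1])):
        base = np.arctan2(outward[1], outward[0])
        for ang in base + np.linspace(-np.pi / 2, np.pi / 2, 60):
            mark_ray(end, (np.cos(ang), np.sin(ang)))
    return ridge


# --------------------------------------------------------------------------
# Binarization and projection
# --------------------------------------------------------------------------

def binarize_layer(channel, outline_mask, smooth_sigma: float =
                   SMOOTH_SIGMA_PX, threshold: float | None = None,
                   quantile: float | None = None) -> np.ndarray:
    """Smooth (sigma = 0.9 px), threshold, intersect with the outline band.

    The default threshold is per-cell Otsu computed on the smoothed
    intensities inside a dilated outline band; a fixed ``threshold`` or a
    ``quantile`` of the in-band intensities may override it.  An empty
    result is legitimate (unlabeled cells exist in de novo experiments).
    """
    img = ndimage.gaussian_filter(np.asarray(channel, dtype=float),
                                  smooth_sigma)
    if threshold is None:
        region = dilation(outline_mask, disk(3))
        vals = img[region]
        if quantile is not None:
            threshold = float(np.quantile(vals, quantile))
        elif vals.size == 0 or vals.max() == vals.min():
            return np.zeros_like(outline_mask)
        else:
            threshold = float(threshold_otsu(vals))
    return (img > threshold) & outline_mask


@dataclass
class BinaryProfile:
    """Per-bin S-layer presence for the upper and lower cell half."""

    upper: np.ndarray
    lower: np.ndarray
    channel: str = "a"

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=bool)
        self.lower = np.asarray(self.lower, dtype=bool)
        if self.upper.shape != self.lower.shape:
            raise ValueError("upper/lower length mismatch")

    @property
    def n_bins(self) -> int:
        return self.upper.size


def project_profile(layer_mask, axis: CellAxis,
                    n_bins: int = N_BINS_DEFAULT,
                    channel: str = "a") -> BinaryProfile:
    """Project positive pixels onto the axis into equi-length binary bins.

    Each positive pixel is assigned the normalized arc length of the
    nearest point on the densely sampled axis polyline, binned half-open
    ``[i/n, (i+1)/n)`` (last bin closed), and assigned to the upper or
    lower half by the sign of its row offset from the axis (pixels exactly
    on the axis count as upper; "upper" = smaller row index).  One
    positive pixel makes its bin positive.
    """
    ys, xs = np.nonzero(np.asarray(layer_mask, dtype=bool))
    upper = np.zeros(n_bins, dtype=bool)
    lower = np.zeros(n_bins, dtype=bool)
    if xs.size == 0:
        return BinaryProfile(upper, lower, channel)
    tree = cKDTree(axis.samples)
    _, idx = tree.query(np.column_stack([xs, ys]))
    s = axis.arclength[idx]
    bins = np.minimum((s * n_bins).astype(int), n_bins - 1)
    axis_y = axis.samples[idx, 1]
    is_upper = ys <= axis_y          # smaller row index = upper; ties upper
    np.logical_or.at(upper, bins[is_upper], True)
    np.logical_or.at(lower, bins[~is_upper], True)
    return BinaryProfile(upper, lower, channel)


# --------------------------------------------------------------------------
# Population summary
# --------------------------------------------------------------------------

@dataclass
class PopulationProfile:
    """Per-bin fraction of positive half-profiles with Wilson 95% CI."""

    n_cells: int
    fraction: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    @property
    def n_half_profiles(self) -> int:
        return 2 * self.n_cells


def population_fraction(profiles: list[BinaryProfile],
                        alpha: float = 0.05) -> PopulationProfile:
    """Combine upper+lower half-profiles into per-bin binomial fractions.

    Per bin, k = number of positive half-profiles out of n = 2 x n_cells;
    the 95% interval is the Wilson score interval, which keeps good
    coverage at small n and fractions near 0 or 1.
    """
    if not profiles:
        raise ValueError("empty profile collection")
    n_bins = profiles[0].n_bins
    if any(p.n_bins != n_bins for p in profiles):
        raise ValueError("profiles disagree on n_bins")
    halves = np.vstack([[p.upper, p.lower] for p in profiles]
                       ).reshape(-1, n_bins)
    k = halves.sum(axis=0)
    n = halves.shape[0]
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return PopulationProfile(n_cells=len(profiles), fraction=k / n,
                             ci_low=np.clip(np.asarray(lo), 0.0, 1.0),
                             ci_high=np.clip(np.asarray(hi), 0.0, 1.0))


# --------------------------------------------------------------------------
# End-to-end per-cell pipeline
# --------------------------------------------------------------------------

def profile_cell(record: CellRecord, mode: str = "complete_layer",
                 n_bins: int = N_BINS_DEFAULT,
                 orient: bool = True) -> dict:
    """Run register -> orient -> axis -> outline -> binarize -> project.

    Returns ``{"a": BinaryProfile, "b": BinaryProfile | None}``.
    """
    register_channels(record)
    if orient:
        orient_cell(record)
    fit_cell_axis(record)
    outline = make_outline(record, mode=mode)
    out = {}
    for name, ch in (("a", record.channel_a), ("b", record.channel_b)):
        if ch is None:
            out[name] = None
            continue
        mask = binarize_layer(ch, outline)
        out[name] = project_profile(mask, record.axis, n_bins, channel=name)
    return out
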