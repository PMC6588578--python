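"""Binary cell-profile pipeline: registration through Wilson fractions."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import norm
from skimage.measure import regionprops
from skimage.transform import rotate

from slayer.profile import (BinaryProfile, CellRecord, binarize_layer,
                            fit_cell_axis, make_outline, orient_cell,
                            population_fraction, profile_cell,
                            project_profile, register_channels)
from slayer.synthetic import (CellGeometry, ImageSimConfig, LabelPattern,
                              simulate_cell_image)


# --------------------------------------------------------------- helpers --

def _silhouette_angle_deg(img):
    """Residual long-axis angle from horizontal, via image moments."""
    mask = img > 0.5 * img.max()
    props = regionprops(mask.astype(int))[0]
    ang = abs(np.degrees(props.orientation))  # vs the row (vertical) axis
    return abs(90.0 - ang)


def _brute_force_shift(grad, channel, search=10):
    """Exhaustive integer-shift NCC oracle (independent of the FFT path)."""
    best, best_val = (0, 0), -np.inf
    for dy in range(-search, search + 1):
        for dx in range(-search, search + 1):
            moved = ndimage.shift(channel, (dy, dx), order=0)
            g = grad.ravel() - grad.mean()
            c = moved.ravel() - moved.mean()
            val = g @ c / (np.linalg.norm(g) * np.linalg.norm(c))
            if val > best_val:
                best_val, best = val, (dy, dx)
    return best


def _wilson(k, n, z=None):
    """Closed-form Wilson score interval, evaluated independently."""
    if z is None:
        z = norm.ppf(0.975)
    p = k / n
    denom = 1 + z ** 2 / n
    center = (p + z ** 2 / (2 * n)) / denom
    half = z / denom * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2))
    return center - half, center + half


# ----------------------------------------------------------- registration --

def _registered_shift(transmitted, channel, pixel_size):
    rec = CellRecord(transmitted.copy(), channel.copy(),
                     pixel_size=pixel_size)
    register_channels(rec)
    return np.asarray(rec.shifts_applied["channel_a"]["shift"])


def test_planted_integer_shift_recovered(uniform_cell):
    """Drift correction: a (+3, -2) px planted shift moves the recovered
    registration shift by exactly (-3, +2) relative to the unshifted
    channel (the constant part is the template offset of this cell)."""
    t = uniform_cell.transmitted
    ch = uniform_cell.channels[0]
    base = _registered_shift(t, ch, uniform_cell.pixel_size)
    moved = _registered_shift(t, np.roll(ch, (3, -2), axis=(0, 1)),
                              uniform_cell.pixel_size)
    np.testing.assert_array_equal(moved - base, (-3, 2))
    assert np.all(np.abs(base) <= 1)  # template offset is sub-pixel scale


def test_zero_shift_is_identity():
    """A channel that exactly matches the registration template (the
    transmitted-light gradient) is left untouched."""
    from slayer.profile import _gradient_magnitude
    cfg = ImageSimConfig(channel_patterns=(LabelPattern("uniform", 2000),),
                         rng_seed=13)
    img = simulate_cell_image(cfg)
    grad_channel = 50.0 * _gradient_magnitude(img.transmitted)
    rec = CellRecord(img.transmitted, grad_channel.copy(),
                     pixel_size=img.pixel_size)
    register_channels(rec)
    assert rec.shifts_applied["channel_a"]["shift"] == (0, 0)
    assert not rec.shifts_applied["channel_a"]["unreliable"]
    np.testing.assert_array_equal(rec.channel_a, grad_channel)


def test_subpixel_shift_rounds_to_nearest_integer(uniform_cell):
    """A planted (0, +1.4) px shift is corrected to the nearest integer
    (0, -1) relative to baseline, and the implementation's peak matches
    an exhaustive integer-shift NCC oracle."""
    from slayer.profile import _gradient_magnitude
    t = uniform_cell.transmitted
    ch = uniform_cell.channels[0]
    base = _registered_shift(t, ch, uniform_cell.pixel_size)
    moved_ch = ndimage.shift(ch, (0.0, 1.4), order=1)
    moved = _registered_shift(t, moved_ch, uniform_cell.pixel_size)
    np.testing.assert_array_equal(moved - base, (0, -1))
    oracle = _brute_force_shift(_gradient_magnitude(t), moved_ch)
    np.testing.assert_array_equal(moved, oracle)


# ------------------------------------------------------------ orientation --

def test_rotated_cell_is_restored_to_horizontal(uniform_cell):
    rec = CellRecord(
        rotate(uniform_cell.transmitted, 30, resize=True,
               preserve_range=True),
        rotate(uniform_cell.channels[0], 30, resize=True,
               preserve_range=True),
        pixel_size=uniform_cell.pixel_size, stalk_side="left")
    orient_cell(rec)
    assert _silhouette_angle_deg(rec.transmitted) < 1.0


def test_horizontal_cell_rotation_is_zero(uniform_record):
    orient_cell(uniform_record)
    assert abs(uniform_record.orientation_applied) <= 1.0


def test_stalk_right_input_is_mirrored(stalked_cell):
    flipped = CellRecord(np.fliplr(stalked_cell.transmitted),
                         np.fliplr(stalked_cell.channels[0]),
                         pixel_size=stalked_cell.pixel_size,
                         stalk_side="right")
    orient_cell(flipped)
    assert flipped.mirrored
    # the stalk (thin extension) must end up on the low-x side: vertical
    # extent of the leftmost occupied columns is smaller than the body's
    t = flipped.transmitted
    occ = t > 0.25 * t.max()
    cols = np.where(occ.any(axis=0))[0]
    left_extent = occ[:, cols[:10]].sum(axis=0).mean()
    mid_extent = occ[:, cols[len(cols) // 2 - 5:len(cols) // 2 + 5]].sum(
        axis=0).mean()
    assert left_extent < 0.6 * mid_extent


def test_isotropic_object_rejected():
    yy, xx = np.mgrid[0:80, 0:80]
    disk_img = ((yy - 40) ** 2 + (xx - 40) ** 2 < 30 ** 2) * 100.0
    rec = CellRecord(disk_img, disk_img.copy())
    with pytest.raises(ValueError, match="isotropic"):
        orient_cell(rec)


# --------------------------------------------------------------- axis fit --

def test_straight_cell_axis_is_flat_at_the_centerline(uniform_cell,
                                                      uniform_record):
    axis = fit_cell_axis(uniform_record)
    assert axis.model_kind == "poly2"
    assert abs(axis.coefficients[0]) < 5e-3       # curvature ~ 0
    true_row = uniform_cell.centerline[:, 1].mean() / uniform_cell.pixel_size
    assert abs(np.median(axis.samples[:, 1]) - true_row) < 1.0


def test_parabolic_ridge_recovers_generating_coefficients():
    """Transmitted ridge drawn on y = a x^2 + b x + c: the fitted axis
    matches a direct polynomial fit through the generating pixels."""
    a, b, c = 0.004, -0.5, 60.0
    xs = np.arange(20, 180)
    ys = np.round(a * xs ** 2 + b * xs + c).astype(int)
    img = np.zeros((120, 200))
    img[ys, xs] = 100.0
    img = ndimage.gaussian_filter(img, 1.0)
    rec = CellRecord(img, np.zeros_like(img))
    axis = fit_cell_axis(rec)
    oracle = np.polyfit(xs, ys, 2)
    np.testing.assert_allclose(axis.coefficients, oracle, atol=0.05,
                               rtol=0.05)


def test_crescent_cell_axis_tracks_true_centerline():
    cfg = ImageSimConfig(
        channel_patterns=(LabelPattern("uniform", 2000),),
        cell_geometry=CellGeometry(body_length=2400.0,
                                   centerline_curvature=1 / 5000.0),
        rng_seed=6)
    img = simulate_cell_image(cfg)
    rec = CellRecord(img.transmitted, img.channels[0],
                     pixel_size=img.pixel_size)
    axis = fit_cell_axis(rec)
    truth = img.centerline / img.pixel_size  # px
    # oracle: the same quadratic model fitted directly on the true
    # centerline; the pipeline's fit may differ only through pixel noise
    oracle = np.polyfit(truth[:, 0], truth[:, 1], 2)
    inside = (truth[:, 0] >= axis.x_range[0]) & \
             (truth[:, 0] <= axis.x_range[1])
    fit_y = np.interp(truth[inside, 0], axis.samples[:, 0],
                      axis.samples[:, 1])
    oracle_y = np.polyval(oracle, truth[inside, 0])
    assert np.max(np.abs(fit_y - oracle_y)) < 1.0


def test_too_few_columns_rejected():
    img = np.zeros((40, 40))
    img[20, 18:21] = 100.0
    rec = CellRecord(img, np.zeros_like(img))
    with pytest.raises(ValueError, match="columns"):
        fit_cell_axis(rec)


# ------------------------------------------------------------ outline band --

@pytest.mark.parametrize("mode", ["complete_layer", "incomplete_layer"])
def test_outline_band_width_is_200_nm(uniform_record, mode):
    """Band thickness measured by the distance transform is 10 +/- ~1 px."""
    fit_cell_axis(uniform_record)
    band = make_outline(uniform_record, mode=mode)
    dist = ndimage.distance_transform_edt(band)
    ridge = dist >= ndimage.grey_dilation(dist, size=3) - 1e-9
    widths = 2.0 * dist[band & ridge]
    lo, hi = np.percentile(widths, [10, 90])
    assert 7.0 <= lo and hi <= 13.0
    assert abs(np.median(widths) - 10.0) <= 2.0


def test_outline_modes_agree_on_fully_labeled_cell(uniform_record):
    fit_cell_axis(uniform_record)
    a = make_outline(uniform_record, mode="complete_layer")
    b = make_outline(uniform_record, mode="incomplete_layer")
    jaccard = (a & b).sum() / (a | b).sum()
    assert jaccard > 0.7


def test_blank_image_has_no_boundary():
    blank = np.zeros((50, 50))
    rec = CellRecord(blank, blank.copy())
    with pytest.raises(ValueError, match="[Ee]mpty boundary"):
        make_outline(rec, mode="complete_layer")


# ------------------------------------------------------------ binarization --

def test_zero_channel_binarizes_to_empty(uniform_record):
    fit_cell_axis(uniform_record)
    band = make_outline(uniform_record, mode="complete_layer")
    mask = binarize_layer(np.zeros_like(uniform_record.channel_a), band)
    assert not mask.any()


def test_uniform_label_binarization_covers_ground_truth():
    cfg = ImageSimConfig(channel_patterns=(LabelPattern("uniform", 4000),),
                         add_poisson_noise=False, background_mean=0.0,
                         rng_seed=8)
    img = simulate_cell_image(cfg)
    rec = CellRecord(img.transmitted, img.channels[0],
                     pixel_size=img.pixel_size)
    fit_cell_axis(rec)
    band = make_outline(rec, mode="complete_layer")
    mask = binarize_layer(rec.channel_a, band)
    # the detectable footprint of the labeled band: its interior at the
    # half-maximum boundary, i.e. eroded by ~1 PSF sigma + 1 px
    from skimage.morphology import disk, erosion
    gt = erosion(img.label_masks[0], disk(2)) & band
    assert (mask & gt).sum() / gt.sum() >= 0.99


def test_crack_pattern_binarization_f1_at_snr_10():
    """Pixel-wise F1 > 0.8 against the generator's crack mask (dilated to
    the PSF footprint) at detection SNR >= 10."""
    bg = 4.0  # photons/px -> sigma_bg = 2
    cfg = ImageSimConfig(
        channel_patterns=(LabelPattern("crack_features", 1200, n_cracks=3),),
        background_mean=bg, rng_seed=9)
    img = simulate_cell_image(cfg)
    sigma_bg = np.sqrt(bg)
    peak = np.percentile(img.expected_channels[0], 99.9) - bg
    assert peak / sigma_bg >= 10  # the render really is at SNR >= 10
    # cracks cross the interior: binarize within the whole silhouette
    from skimage.morphology import dilation, disk
    rec = CellRecord(img.transmitted, img.channels[0],
                     pixel_size=img.pixel_size)
    mask = binarize_layer(rec.channel_a, img.silhouette)
    psf_sigma_px = 60.0 / 2.3548 / img.pixel_size
    gt = dilation(img.label_masks[0], disk(int(round(psf_sigma_px)))) \
        & img.silhouette
    tp = (mask & gt).sum()
    prec = tp / max(mask.sum(), 1)
    rec_ = tp / max(gt.sum(), 1)
    f1 = 2 * prec * rec_ / max(prec + rec_, 1e-12)
    assert f1 > 0.8


# ------------------------------------------------------------- projection --

def _projection_oracle(mask, axis, n_bins=40):
    """Brute-force per-pixel projection: direct distance loop."""
    upper = np.zeros(n_bins, dtype=bool)
    lower = np.zeros(n_bins, dtype=bool)
    ys, xs = np.nonzero(mask)
    for x, y in zip(xs, ys):
        d = np.hypot(axis.samples[:, 0] - x, axis.samples[:, 1] - y)
        i = int(np.argmin(d))
        b = min(int(axis.arclength[i] * n_bins), n_bins - 1)
        if y <= axis.samples[i, 1]:
            upper[b] = True
        else:
            lower[b] = True
    return upper, lower


def test_full_coverage_mask_fills_all_bins(uniform_record):
    fit_cell_axis(uniform_record)
    band = make_outline(uniform_record, mode="complete_layer")
    prof = project_profile(band, uniform_record.axis)
    assert prof.upper.all() and prof.lower.all()


def test_empty_mask_fills_no_bins(uniform_record):
    axis = fit_cell_axis(uniform_record)
    prof = project_profile(np.zeros_like(uniform_record.transmitted,
                                         dtype=bool), axis)
    assert not prof.upper.any() and not prof.lower.any()


def test_leftmost_quarter_occupies_only_leading_bins(uniform_record):
    axis = fit_cell_axis(uniform_record)
    band = make_outline(uniform_record, mode="complete_layer")
    x_25 = axis.samples[np.searchsorted(axis.arclength, 0.25), 0]
    partial = band & (np.arange(band.shape[1])[None, :] <= x_25)
    prof = project_profile(partial, axis)
    oracle_u, oracle_l = _projection_oracle(partial, axis)
    np.testing.assert_array_equal(prof.upper, oracle_u)
    np.testing.assert_array_equal(prof.lower, oracle_l)
    # positive bins are exactly those overlapping [0, ~0.25]
    last_true = max(np.flatnonzero(prof.upper | prof.lower))
    assert 8 <= last_true <= 11
    assert not (prof.upper[last_true + 2:].any() or
                prof.lower[last_true + 2:].any())


def test_projection_matches_brute_force_oracle(uniform_record):
    fit_cell_axis(uniform_record)
    band = make_outline(uniform_record, mode="complete_layer")
    mask = binarize_layer(uniform_record.channel_a, band)
    prof = project_profile(mask, uniform_record.axis)
    oracle_u, oracle_l = _projection_oracle(mask, uniform_record.axis)
    np.testing.assert_array_equal(prof.upper, oracle_u)
    np.testing.assert_array_equal(prof.lower, oracle_l)


def test_projection_stable_under_adding_redundant_pixels(uniform_record):
    axis = fit_cell_axis(uniform_record)
    band = make_outline(uniform_record, mode="complete_layer")
    mask = binarize_layer(uniform_record.channel_a, band)
    prof = project_profile(mask, axis)
    grown = mask.copy()
    # add the on-axis pixel of every already-positive upper bin
    for b in np.flatnonzero(prof.upper):
        i = np.searchsorted(axis.arclength, (b + 0.5) / prof.n_bins)
        x, y = axis.samples[min(i, len(axis.samples) - 1)]
        grown[int(round(y)), int(round(x))] = True
    prof2 = project_profile(grown, axis)
    np.testing.assert_array_equal(prof.upper, prof2.upper)


# ---------------------------------------------------------- population CI --

def test_wilson_interval_all_positive_81_cells():
    """81 fully positive cells: fraction 1.0, Wilson 95% ~ [0.977, 1]."""
    profiles = [BinaryProfile(np.ones(40, bool), np.ones(40, bool))
                for _ in range(81)]
    pop = population_fraction(profiles)
    assert pop.n_half_profiles == 162
    np.testing.assert_allclose(pop.fraction, 1.0)
    lo, hi = _wilson(162, 162)
    np.testing.assert_allclose(pop.ci_low, lo, atol=1e-6)
    np.testing.assert_allclose(pop.ci_high, 1.0, atol=1e-9)
    assert 0.976 < pop.ci_low[0] < 0.978


def test_wilson_interval_all_negative_is_symmetric():
    profiles = [BinaryProfile(np.zeros(40, bool), np.zeros(40, bool))
                for _ in range(81)]
    pop = population_fraction(profiles)
    np.testing.assert_allclose(pop.fraction, 0.0)
    np.testing.assert_allclose(pop.ci_low, 0.0, atol=1e-9)
    lo_pos, _ = _wilson(162, 162)
    np.testing.assert_allclose(pop.ci_high, 1.0 - lo_pos, atol=1e-6)


def test_wilson_interval_half_positive_n_2():
    """One cell, upper half positive only: k=1, n=2 -> ~[0.095, 0.905]."""
    prof = BinaryProfile(np.ones(40, bool), np.zeros(40, bool))
    pop = population_fraction([prof])
    lo, hi = _wilson(1, 2)
    np.testing.assert_allclose(pop.fraction, 0.5)
    np.testing.assert_allclose(pop.ci_low, lo, atol=1e-6)
    np.testing.assert_allclose(pop.ci_high, hi, atol=1e-6)
    assert 0.09 < pop.ci_low[0] < 0.10 and 0.90 < pop.ci_high[0] < 0.91


def test_wilson_interval_contains_fraction_and_shrinks_with_n():
    for n_cells in (1, 4, 16):
        profiles = []
        for i in range(n_cells):
            up = np.zeros(40, bool)
            up[:20] = (i % 2 == 0)
            profiles.append(BinaryProfile(up, ~up))
        pop = population_fraction(profiles)
        assert np.all(pop.ci_low <= pop.fraction + 1e-12)
        assert np.all(pop.fraction <= pop.ci_high + 1e-12)
        assert np.all(pop.ci_low >= 0) and np.all(pop.ci_high <= 1)
    widths = []
    for n in (2, 8, 32):
        lo, hi = _wilson(n // 2, n)
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


def test_empty_population_rejected():
    with pytest.raises(ValueError, match="empty"):
        population_fraction([])


# ------------------------------------------------------------- end-to-end --

def test_polar_enriched_population_profile_peaks_at_poles():
    """Label placed preferentially at the poles yields end-elevated
    population fractions relative to mid-cell."""
    profiles = []
    for seed in range(10):
        cfg = ImageSimConfig(
            channel_patterns=(LabelPattern("polar_enriched", 500,
                                           polar_fraction=0.9),),
            background_mean=0.2, rng_seed=100 + seed)
        img = simulate_cell_image(cfg)
        rec = CellRecord(img.transmitted, img.channels[0],
                         pixel_size=img.pixel_size, stalk_side="left")
        profs = profile_cell(rec, mode="incomplete_layer", orient=False)
        profiles.append(profs["a"])
    pop = population_fraction(profiles)
    ends = np.r_[pop.fraction[:3], pop.fraction[-3:]].mean()
    middle = pop.fraction[15:25].mean()
    assert ends > middle


def test_pipeline_is_deterministic(uniform_cell):
    def run():
        rec = CellRecord(uniform_cell.transmitted.copy(),
                         uniform_cell.channels[0].copy(),
                         pixel_size=uniform_cell.pixel_size,
                         stalk_side="left")
        profs = profile_cell(rec, mode="complete_layer", orient=False)
        return profs["a"]
    p1, p2 = run(), run()
    np.testing.assert_array_equal(p1.upper, p2.upper)
    np.testing.assert_array_equal(p1.lower, p2.lower)
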