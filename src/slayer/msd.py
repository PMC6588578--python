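"""Mean-squared-displacement analysis and motion-blur-corrected diffusion fit.

The apparent diffusion coefficient of a membrane-anchored molecule is
estimated by pooling per-track 3D MSD curves and fitting, over the first
few time lags, the camera-aware model

    MSD_3D(tau) = 6 D (tau - tau_E / 3) + 2 (s1^2 + s2^2 + s3^2)

where ``tau`` is the time lag, ``tau_E`` the camera exposure time (the
tau_E/3 term corrects for motion blur under continuous exposure) and
``s_i`` the per-axis localization error contributing a constant offset.
With ``tau_E`` and ``s_i`` calibrated, D is the only free parameter and
the fit is an exactly linear weighted regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracks import Track

NM2_TO_UM2 = 1.0e-6


@dataclass
class TrackMsd:
    """Per-track MSD moments, kept as sums so pooling is exact."""

    lags: np.ndarray        # frame lags (integers >= 1)
    n_pairs: np.ndarray     # displacement pairs per lag
    sum_d2: np.ndarray      # sum of squared displacements (nm^2)
    sum_d4: np.ndarray      # sum of (squared displacement)^2 (nm^4)

    @property
    def msd(self) -> np.ndarray:
        """Mean squared displacement per lag (nm^2)."""
        return self.sum_d2 / self.n_pairs


@dataclass
class MsdCurve:
    """Pooled MSD versus time lag, in the units used for reporting."""

    lags: np.ndarray        # s, strictly increasing
    msd: np.ndarray         # um^2
    sem: np.ndarray         # um^2, SEM of the pooled squared displacements
    n_pairs: np.ndarray


@dataclass
class MsdModel:
    """Fixed acquisition parameters of the diffusion model."""

    tau_E: float = 0.05                       # s, camera exposure
    s_xyz: tuple = (93.0, 93.0, 91.0)         # nm per axis
    n_fit_lags: int = 4

    def __post_init__(self) -> None:
        if self.tau_E <= 0:
            raise ValueError("tau_E must be > 0")
        if self.n_fit_lags < 2:
            raise ValueError("n_fit_lags must be >= 2")

    @property
    def offset_um2(self) -> float:
        """Static localization-error offset 2*(s1^2+s2^2+s3^2) in um^2."""
        s = np.asarray(self.s_xyz, dtype=float)
        return 2.0 * float(np.sum(s ** 2)) * NM2_TO_UM2

    def evaluate(self, lags_s: np.ndarray, D: float) -> np.ndarray:
        """Model MSD (um^2) at the given time lags for diffusivity D."""
        lags_s = np.asarray(lags_s, dtype=float)
        return 6.0 * D * (lags_s - self.tau_E / 3.0) + self.offset_um2


@dataclass
class DiffusionFit:
    D: float                 # um^2/s
    stderr: float            # um^2/s
    offset_um2: float
    negative_D: bool = False
    n_lags_used: int = 0
    fitted_offset: float | None = None


def compute_msd(track: Track, max_lag: int) -> TrackMsd:
    """Time-averaged MSD of one track over frame lags 1..max_lag.

    All overlapping frame pairs ``(i, i + lag)`` are used; pairs broken by
    detection gaps are skipped (pairing is by frame index, not row index).
    """
    if len(track) < 2:
        raise ValueError("track must have >= 2 localizations")
    frames = track.frames
    pos = track.positions
    lags = np.arange(1, max_lag + 1)
    n = np.zeros(max_lag, dtype=int)
    s2 = np.zeros(max_lag)
    s4 = np.zeros(max_lag)
    index_of = {f: i for i, f in enumerate(frames)}
    for li, lag in enumerate(lags):
        src, dst = [], []
        for i, f in enumerate(frames):
            j = index_of.get(f + lag)
            if j is not None:
                src.append(i)
                dst.append(j)
        if not src:
            continue
        d2 = np.sum((pos[dst] - pos[src]) ** 2, axis=1)
        n[li] = d2.size
        s2[li] = d2.sum()
        s4[li] = (d2 ** 2).sum()
    return TrackMsd(lags, n, s2, s4)


def pool_msd(per_track: list[TrackMsd], frame_interval: float) -> MsdCurve:
    """Pool per-track MSDs, weighting each lag by its pair count.

    Equivalent to averaging the flat list of squared displacements across
    all tracks; the SEM is that of the pooled squared displacements.  Lags
    with no pairs in any track are omitted.
    """
    if not per_track:
        raise ValueError("no tracks to pool")
    max_lag = max(t.lags.max() for t in per_track)
    n = np.zeros(max_lag)
    s2 = np.zeros(max_lag)
    s4 = np.zeros(max_lag)
    for t in per_track:
        idx = t.lags - 1
        n[idx] += t.n_pairs
        s2[idx] += t.sum_d2
        s4[idx] += t.sum_d4
    defined = n > 0
    lags = (np.arange(1, max_lag + 1)[defined]) * frame_interval
    mean = s2[defined] / n[defined]
    var = np.maximum(s4[defined] / n[defined] - mean ** 2, 0.0)
    sem = np.sqrt(var / n[defined])
    return MsdCurve(lags=lags, msd=mean * NM2_TO_UM2,
                    sem=sem * NM2_TO_UM2,
                    n_pairs=n[defined].astype(int))


def fit_diffusion(curve: MsdCurve, model: MsdModel,
                  fit_offset: bool = False) -> DiffusionFit:
    """Weighted least-squares fit of the blur-corrected diffusion model.

    By default the localization-error offset is fixed from the calibrated
    ``model.s_xyz`` and D is the only free parameter, so the solution is
    the closed-form weighted regression slope of ``MSD - offset`` on
    ``6 (tau - tau_E / 3)``.  With ``fit_offset=True`` the offset is
    estimated jointly (for uncalibrated data).  Weights are 1/SEM^2 where
    SEM is available and positive, otherwise uniform.
    """
    k = model.n_fit_lags
    if curve.lags.size < k:
        raise ValueError(
            f"curve has {curve.lags.size} lags; need >= {k}")
    tau = curve.lags[:k]
    y = curve.msd[:k]
    sem = curve.sem[:k]
    w = np.where(sem > 0, 1.0 / np.maximum(sem, 1e-300) ** 2, np.nan)
    if np.any(~np.isfinite(w)):
        w = np.ones_like(y)
    x = 6.0 * (tau - model.tau_E / 3.0)

    if fit_offset:
        # weighted linear regression y = D*x + c
        W = np.diag(w)
        A = np.column_stack([x, np.ones_like(x)])
        cov = np.linalg.inv(A.T @ W @ A)
        beta = cov @ (A.T @ W @ y)
        D, c = float(beta[0]), float(beta[1])
        stderr = float(np.sqrt(cov[0, 0]))
        fit = DiffusionFit(D, stderr, model.offset_um2,
                           n_lags_used=k, fitted_offset=c)
    else:
        yc = y - model.offset_um2
        denom = float(np.sum(w * x * x))
        D = float(np.sum(w * x * yc) / denom)
        stderr = float(np.sqrt(1.0 / denom)) if np.all(sem > 0) else float(
            np.sqrt(np.sum(w * (yc - D * x) ** 2) / max(k - 1, 1) / denom))
        fit = DiffusionFit(D, stderr, model.offset_um2, n_lags_used=k)
    if fit.D < 0:
        warnings.warn("fitted diffusion coefficient is negative "
                      "(possible in noise)", stacklevel=2)
        fit.negative_D = True
    return fit


def msd_pipeline(tracks: list[Track], model: MsdModel,
                 frame_interval: float,
                 max_lag: int | None = None) -> tuple[MsdCurve, DiffusionFit]:
    """Convenience: per-track MSDs -> pooled curve -> diffusion fit."""
    if max_lag is None:
        max_lag = max(model.n_fit_lags * 3, 10)
    per_track = [compute_msd(t, max_lag) for t in tracks if len(t) >= 2]
    curve = pool_msd(per_track, frame_interval)
    return curve, fit_diffusion(curve, model)
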