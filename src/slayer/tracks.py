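"""Single-molecule track container and CSV round-trip.

A :class:`Track` is the time-ordered sequence of localizations of one
molecule: frame indices, times in seconds, positions in nanometres (2D or
3D), and per-axis localization uncertainties in nanometres.  Tracks are the
substrate of the sliding-window RMSD mobility analysis, the
distance-to-seed analysis, and the MSD diffusion estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order for track tables on disk
TRACK_COLUMNS = [
    "track_id", "frame", "t_s",
    "x_nm", "y_nm", "z_nm",
    "sx_nm", "sy_nm", "sz_nm",
    "true_state",
]


@dataclass
class Track:
    """Time-ordered localizations of a single molecule.

    Parameters
    ----------
    track_id:
        Integer identifier, unique within a collection.
    frames:
        Strictly increasing camera frame indices (gaps allowed).
    times:
        Acquisition times in seconds, same length as ``frames``.
    positions:
        ``(n, d)`` array of positions in nm, ``d`` in {2, 3}.
    uncertainties:
        Per-axis localization error (1 sigma, nm): scalar per axis,
        shape ``(d,)``, applied to every frame.
    true_state:
        Optional ground-truth bound flags per frame (simulation only).
    """

    track_id: int
    frames: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    uncertainties: np.ndarray = field(default=None)  # type: ignore[assignment]
    true_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] != self.frames.shape[0]:
            raise ValueError("positions and frames length mismatch")
        if self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be 2D or 3D")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.uncertainties is None:
            self.uncertainties = np.zeros(self.ndim)
        self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        if self.true_state is not None:
            self.true_state = np.asarray(self.true_state, dtype=bool)

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    def __len__(self) -> int:
        return self.frames.shape[0]


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Flatten a collection of tracks into one long-format table (nm / s)."""
    rows = []
    for tr in tracks:
        n = len(tr)
        d = tr.ndim
        block = {
            "track_id": np.full(n, tr.track_id),
            "frame": tr.frames,
            "t_s": tr.times,
            "x_nm": tr.positions[:, 0],
            "y_nm": tr.positions[:, 1],
            "z_nm": tr.positions[:, 2] if d == 3 else np.full(n, np.nan),
            "sx_nm": np.full(n, tr.uncertainties[0]),
            "sy_nm": np.full(n, tr.uncertainties[1]),
            "sz_nm": np.full(n, tr.uncertainties[2] if d == 3 else np.nan),
            "true_state": (tr.true_state if tr.true_state is not None
                           else np.full(n, False)),
        }
        rows.append(pd.DataFrame(block))
    if not rows:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]


def dataframe_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Inverse of :func:`tracks_to_dataframe`; drops all-NaN z columns."""
    out: list[Track] = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        has_z = "z_nm" in g and not g["z_nm"].isna().all()
        cols = ["x_nm", "y_nm"] + (["z_nm"] if has_z else [])
        pos = g[cols].to_numpy(float)
        unc = [float(g["sx_nm"].iloc[0]), float(g["sy_nm"].iloc[0])]
        if has_z:
            unc.append(float(g["sz_nm"].iloc[0]))
        state = (g["true_state"].to_numpy(bool)
                 if "true_state" in g else None)
        out.append(Track(int(tid), g["frame"].to_numpy(int),
                         g["t_s"].to_numpy(float), pos,
                         np.asarray(unc), state))
    return out


def write_tracks_csv(tracks: list[Track], path) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def read_tracks_csv(path) -> list[Track]:
    return dataframe_to_tracks(pd.read_csv(path))
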