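"""Bound/unbound classification of the seed-capture tracking data.

Reads the 2D capture simulation from 01, computes sliding-window RMSD
per track, calibrates the binding threshold from the pooled RMSD
histogram (and compares with the 57.3 nm default), and summarizes
co-occupancy of binding and seed proximity.  Writes
results/mobility_summary.json and a per-frame table.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from slayer.mobility import (BINDING_THRESHOLD_NM, analyze_track,
                             calibrate_threshold, cooccupancy,
                             sliding_rmsd)
from slayer.tracks import read_tracks_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tracks = read_tracks_csv(ROOT / "data" / "tracks_2d_capture.csv")
    seeds = pd.read_csv(ROOT / "data" / "seeds.csv")[
        ["x_nm", "y_nm"]].to_numpy()

    pooled = np.concatenate([sliding_rmsd(t)[1] for t in tracks])
    cal = calibrate_threshold(pooled)
    print(f"{pooled.size} pooled RMSD values; low-mode Gaussian "
          f"{cal.fitted_mean:.1f} +/- {cal.fitted_sigma:.1f} nm -> "
          f"threshold {cal.threshold:.1f} nm "
          f"(field default {BINDING_THRESHOLD_NM} nm)")

    rows, bound_all, dns_all = [], [], []
    for tr in tracks:
        ms = analyze_track(tr, seeds, threshold=cal.threshold)
        for i, f in enumerate(ms.frames):
            rows.append({"track_id": tr.track_id, "frame": int(f),
                         "rmsd_nm": ms.rmsd[i],
                         "bound": bool(ms.bound[i]),
                         "d_ns_nm": ms.d_ns[i],
                         "near": bool(ms.near_seed[i])})
        bound_all.append(ms.bound)
        dns_all.append(ms.d_ns)
    pd.DataFrame(rows).to_csv(ROOT / "mobility_frames.csv", index=False)

    s = cooccupancy(np.concatenate(bound_all), np.concatenate(dns_all),
                    frame_interval=0.05)
    summary = {
        "threshold_nm": cal.threshold,
        "total_time_s": s.total_time,
        "frac_near_unbound": s.frac_near_unbound,
        "frac_near_bound": s.frac_near_bound,
        "frac_bound_not_near": s.frac_bound_not_near,
    }
    (ROOT / "mobility_summary.json").write_text(
        json.dumps(summary, indent=2))
    print(f"co-occupancy over {s.total_time:.0f} s: near&unbound "
          f"{s.frac_near_unbound:.2f}, near&bound {s.frac_near_bound:.2f},"
          f" bound-not-near {s.frac_bound_not_near:.3f} "
          "(binding happens essentially only at seeds)")


if __name__ == "__main__":
    main()
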