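"""Pooled 3D MSD and the motion-blur-corrected diffusion estimate.

Reads the 3D tracking simulation from 01, pools per-track MSDs, fits
MSD = 6D(tau - tau_E/3) + 2(s1^2+s2^2+s3^2) over the first 4 lags with
the calibrated offsets fixed, and writes results/msd_curve.csv and
results/msd_fit.json.  The recovered D should match the generator's
0.077 um^2/s.
"""

import json
from pathlib import Path

import pandas as pd

from slayer.msd import MsdModel, msd_pipeline
from slayer.tracks import read_tracks_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tracks = read_tracks_csv(ROOT / "data" / "tracks_3d.csv")
    model = MsdModel(tau_E=0.05, s_xyz=(93.0, 93.0, 91.0), n_fit_lags=4)
    curve, fit = msd_pipeline(tracks, model, frame_interval=0.05,
                              max_lag=12)
    pd.DataFrame({"lag_s": curve.lags, "msd_um2": curve.msd,
                  "sem_um2": curve.sem, "n_pairs": curve.n_pairs}
                 ).to_csv(ROOT / "msd_curve.csv", index=False)
    (ROOT / "msd_fit.json").write_text(json.dumps(
        {"D_um2_per_s": fit.D, "stderr": fit.stderr,
         "offset_um2": fit.offset_um2, "n_lags": fit.n_lags_used},
        indent=2))
    print(f"pooled MSD over {len(tracks)} tracks; MSD(50 ms) = "
          f"{curve.msd[0]:.4f} um^2")
    print(f"D = {fit.D:.4f} +/- {fit.stderr:.4f} um^2/s "
          "(generator truth 0.0770)")


if __name__ == "__main__":
    main()
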