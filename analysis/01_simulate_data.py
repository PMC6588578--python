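"""Generate the synthetic datasets used by the downstream analyses.

Writes to results/data/: 3D tracking CSV at the study conditions
(30 tracks x 500 frames, 20 frames/s, 50 ms exposure, 93/93/91 nm
errors), a 2D seed-capture tracking CSV with its seed table, a directory
of two-color cell TIFFs (uniform / polar / crack label patterns), and a
spherocylinder surface mesh.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from slayer.io import write_cell_tiff
from slayer.profile import CellRecord
from slayer.synthetic import (BindingConfig, CellGeometry, ImageSimConfig,
                              LabelPattern, TrackSimConfig,
                              make_spherocylinder_mesh, simulate_cell_image,
                              simulate_tracks)
from slayer.tracks import write_tracks_csv

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1


def main() -> None:
    # 3D free-diffusion tracks at the tracking-experiment conditions
    cfg3d = TrackSimConfig(diffusion_coefficient=0.077, rng_seed=SEED)
    write_tracks_csv(simulate_tracks(cfg3d), OUT / "tracks_3d.csv")
    print(f"tracks_3d.csv: {cfg3d.n_tracks} tracks x "
          f"{cfg3d.n_frames_per_track} frames, D = "
          f"{cfg3d.diffusion_coefficient} um^2/s")

    # 2D tracks with capture at immobile nucleation seeds
    seeds = np.array([[0.0, 0.0], [1800.0, 200.0], [-1600.0, -400.0]])
    cfg2d = TrackSimConfig(
        diffusion_coefficient=0.05, dimensionality=2,
        localization_error_xyz=(25.0, 25.0, 0.0),
        binding=BindingConfig(seeds, capture_radius=150.0, on_rate=100.0,
                              off_rate=0.05),
        n_tracks=15, n_frames_per_track=400, start_box_nm=3500.0,
        rng_seed=SEED + 1)
    write_tracks_csv(simulate_tracks(cfg2d), OUT / "tracks_2d_capture.csv")
    pd.DataFrame({"seed_id": range(len(seeds)), "x_nm": seeds[:, 0],
                  "y_nm": seeds[:, 1]}).to_csv(OUT / "seeds.csv",
                                               index=False)
    print(f"tracks_2d_capture.csv: {cfg2d.n_tracks} tracks with "
          f"{len(seeds)} seeds")

    # two-color style cell images, one directory per label pattern
    patterns = {
        "uniform": LabelPattern("uniform", 3000),
        "polar": LabelPattern("polar_enriched", 600, polar_fraction=0.9),
        "cracks": LabelPattern("crack_features", 1200, n_cracks=3),
    }
    for name, pattern in patterns.items():
        d = OUT / f"cells_{name}"
        d.mkdir(exist_ok=True)
        for k in range(8):
            img = simulate_cell_image(ImageSimConfig(
                channel_patterns=(pattern,), background_mean=0.2,
                rng_seed=SEED * 100 + k))
            rec = CellRecord(img.transmitted, img.channels[0],
                             pixel_size=img.pixel_size, stalk_side="left")
            write_cell_tiff(rec, d / f"cell_{k:02d}.tif")
        print(f"cells_{name}/: 8 cells")

    # predivisional-scale spherocylinder surface
    mesh = make_spherocylinder_mesh(2000.0, 400.0, subdivisions=32)
    mesh.export(OUT / "spherocylinder.ply")
    (OUT / "mesh_info.json").write_text(json.dumps(
        {"V": len(mesh.vertices), "F": len(mesh.faces),
         "euler": int(mesh.euler_number)}))
    print(f"spherocylinder.ply: V={len(mesh.vertices)} "
          f"F={len(mesh.faces)} chi={mesh.euler_number}")


if __name__ == "__main__":
    main()
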