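"""Gaussian curvature map and axial |K| profile of the cell surface.

Loads the spherocylinder mesh from 01, computes per-vertex angle-deficit
Gaussian curvature (checking the discrete Gauss-Bonnet total), and bins
|K| along the long axis with the same 40-bin convention as the image
profiles.  Writes results/curvature_vertices.csv and
results/curvature_profile.csv.  |K| concentrates at the poles — the
regions where the axial S-layer profiles show preferential incorporation.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from slayer.curvature import (curvature_profile, gaussian_curvature,
                              load_mesh)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    mesh = gaussian_curvature(load_mesh(ROOT / "data" /
                                        "spherocylinder.ply"))
    print(f"mesh: V={len(mesh.vertices)}, chi={mesh.euler_characteristic};"
          f" total curvature / 4pi = "
          f"{mesh.total_curvature / (4 * np.pi):.12f}")
    pd.DataFrame({
        "vertex": np.arange(len(mesh.vertices)),
        "x_nm": mesh.vertices[:, 0], "y_nm": mesh.vertices[:, 1],
        "z_nm": mesh.vertices[:, 2], "K_per_nm2": mesh.K,
        "absK_per_nm2": np.abs(mesh.K), "area_nm2": mesh.vertex_area,
    }).to_csv(ROOT / "curvature_vertices.csv", index=False)
    prof = curvature_profile(mesh, axis=(1, 0, 0), n_bins=40)
    pd.DataFrame({"bin": np.arange(40), "mean_absK_per_nm2": prof}
                 ).to_csv(ROOT / "curvature_profile.csv", index=False)
    r = 400.0
    caps = np.nanmean(np.r_[prof[:3], prof[-3:]]) * r ** 2
    mid = np.nanmean(prof[15:25]) * r ** 2
    print(f"|K| r^2: caps {caps:.3f} (sphere value 1), body {mid:.4f} "
          "(developable ~ 0) -> curvature concentrates at the poles")


if __name__ == "__main__":
    main()
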