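"""Output writers: VTK legacy fields, particle/metrics CSV, run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_fields_vtk",
    "write_particles_csv",
    "write_particles_vtk",
    "write_metrics_csv",
    "write_manifest",
]


def write_fields_vtk(path, grid, state):
    """Cell fields (u_z, u_r, p, phi) as a legacy ASCII structured grid.

    The (r, z) plane is written as a one-cell-thick 3D structured grid so any
    VTK reader can open it; axisymmetric data are in the meridional plane.
    """
    nr, nz = grid.nr, grid.nz
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("rbcdem fields (r-z plane)\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nz + 1} {nr + 1} 1\n")
        fh.write(f"POINTS {(nz + 1) * (nr + 1)} float\n")
        for i in range(nr + 1):
            for j in range(nz + 1):
                fh.write(f"{j * grid.dz:.9e} {i * grid.dr:.9e} 0.0\n")
        fh.write(f"CELL_DATA {nr * nz}\n")
        u_zc = 0.5 * (state.u_z + np.roll(state.u_z, -1, axis=1))
        u_rc = 0.5 * (state.u_r[1:] + state.u_r[:-1])
        for name, arr in (("u_z", u_zc), ("u_r", u_rc), ("p", state.p), ("phi", state.phi)):
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(-1), fmt="%.9e")
        fh.write("SCALARS solid_mask int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, grid.solid_mask.astype(int).reshape(-1), fmt="%d")
    return path


def write_particles_csv(path, particles):
    """Particle snapshot: id, position, velocity, cached closure state."""
    df = pd.DataFrame({
        "id": np.arange(len(particles)),
        "x": particles.pos[:, 0], "y": particles.pos[:, 1], "z": particles.pos[:, 2],
        "vx": particles.vel[:, 0], "vy": particles.vel[:, 1], "vz": particles.vel[:, 2],
        "d_p": particles.d_p,
        "DI": particles.DI, "C_d": particles.C_d, "C_l": particles.C_l,
    })
    df.to_csv(path, index=False)
    return Path(path)


def write_particles_vtk(path, particles):
    """Particles as legacy ASCII poly-data points with a DI scalar."""
    n = len(particles)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nrbcdem particles\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        np.savetxt(fh, particles.pos, fmt="%.9e")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in (("DI", particles.DI), ("C_d", particles.C_d),
                          ("C_l", particles.C_l), ("d_p", particles.d_p)):
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.9e")
    return path


def write_metrics_csv(path, samples: pd.DataFrame, summary: dict | None = None,
                      plasma_flux: float | None = None, pries=None):
    """Flux time series with derived metric columns; the run summary goes into
    commented header lines.

    With ``plasma_flux`` (and optionally a Pries reference), instantaneous
    Ht_d / mu_rel columns and the reference values are appended per row.
    """
    df = samples.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["Ht_d"] = np.where(df["Q_blood"] > 0, df["Q_RBCs"] / df["Q_blood"], np.nan)
        if plasma_flux is not None:
            df["mu_rel"] = np.where(df["Q_blood"] > 0, plasma_flux / df["Q_blood"], np.nan)
    if pries is not None:
        df["Ht_d_pries"] = pries.Ht_d_ref
        df["mu_rel_pries"] = pries.mu_rel_ref
    path = Path(path)
    with path.open("w") as fh:
        if summary:
            for k, v in summary.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    return path


def write_manifest(path, cfg, extras: dict | None = None):
    """Echo the resolved configuration (and any run metadata) as JSON."""
    payload = {"config": cfg.to_dict()}
    if extras:
        payload.update(extras)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    return path
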