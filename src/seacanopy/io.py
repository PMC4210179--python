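"""Scene, radiance and result import/export.

Meshes travel as OBJ or PLY (via trimesh) with a sidecar CSV mapping facet
index -> role, material id and plant id; radiance snapshots as (zenith bin x
band) CSV matrices; H^A_sat surfaces as long-format CSV; isoclines as
GeoJSON-style polyline JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .bands import DirectionalRadiance, SpectralBands, ZenithGrid
from .morphology import CanopyScene
from .saturation import HAsatSurface


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".facets.csv")


def export_scene(scene: CanopyScene, path) -> Path:
    """Write a scene mesh (OBJ/PLY by extension) plus its facet-table sidecar."""
    path = Path(path)
    mesh = trimesh.Trimesh(vertices=scene.vertices, faces=scene.faces,
                           process=False)
    mesh.export(path)
    pd.DataFrame({
        "facet": np.arange(scene.n_facets),
        "role": scene.role.astype(int),
        "material": scene.material.astype(int),
        "plant": scene.plant_id.astype(int),
    }).to_csv(_sidecar_path(path), index=False)
    return path


def import_scene(path, tile=(0.2, 0.2)) -> CanopyScene:
    """Load a mesh and its sidecar facet table back into a scene."""
    path = Path(path)
    mesh = trimesh.load(path, process=False, force="mesh")
    table = pd.read_csv(_sidecar_path(path))
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if len(table) != faces.shape[0]:
        raise ValueError("sidecar facet table does not match mesh")
    return CanopyScene(
        tile_x=tile[0], tile_y=tile[1],
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=faces,
        role=table["role"].to_numpy(dtype=np.int8),
        material=table["material"].to_numpy(dtype=np.int16),
        plant_id=table["plant"].to_numpy(dtype=np.int32),
        plants=[],
    )


def export_radiance(rad: DirectionalRadiance, path) -> Path:
    """Radiance snapshot as a (zenith bin x band) CSV matrix."""
    path = Path(path)
    df = pd.DataFrame(rad.radiance,
                      index=[f"zen_{c:.2f}" for c in rad.zgrid.centres],
                      columns=[f"{c:.0f}nm" for c in rad.bands.centres])
    df.to_csv(path)
    return path


def import_radiance(path, bands: SpectralBands | None = None,
                    zgrid: ZenithGrid | None = None) -> DirectionalRadiance:
    df = pd.read_csv(path, index_col=0)
    bands = bands or SpectralBands()
    zgrid = zgrid or ZenithGrid(df.shape[0])
    return DirectionalRadiance(bands, zgrid, df.to_numpy(dtype=float))


def export_surface(surface: HAsatSurface, path) -> Path:
    """Long-format CSV: lai, shading, ek, wave_mode, hasat, sd."""
    path = Path(path)
    rows = []
    for i, lai in enumerate(surface.lai_values):
        for j, sh in enumerate(surface.shading_values):
            rows.append({
                "lai": lai, "shading": sh, "ek": surface.ek.value,
                "wave_mode": surface.wave_mode,
                "hasat": surface.values[i, j],
                "sd": surface.sd[i, j] if surface.sd is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def import_surface(path) -> HAsatSurface:
    from .saturation import Ek
    df = pd.read_csv(path)
    lais = np.sort(df["lai"].unique())
    shs = np.sort(df["shading"].unique())
    piv = df.pivot(index="lai", columns="shading", values="hasat")
    sd = df.pivot(index="lai", columns="shading", values="sd")
    return HAsatSurface(lai_values=lais, shading_values=shs,
                        values=piv.loc[lais, shs].to_numpy(),
                        ek=Ek(float(df["ek"].iloc[0])),
                        wave_mode=str(df["wave_mode"].iloc[0]),
                        sd=sd.loc[lais, shs].to_numpy())


def export_solution(sol, path) -> Path:
    """Per-facet incident irradiances as CSV plus the energy ledger as JSON.

    One row per (facet, face) with the band irradiances (W m^-2 nm^-1) and
    the face's incident PAR; the ledger goes to ``<path>.ledger.json``.
    """
    from .bands import to_par_array

    path = Path(path)
    scene = sol.scene
    areas = scene.facet_areas()
    rows = []
    for face in (0, 1):
        spec = sol.incident[:, face, :]
        par = to_par_array(spec * sol.bands.widths, sol.bands)
        for i in range(scene.n_facets):
            row = {"facet": i, "role": int(scene.role[i]),
                   "area_m2": areas[i], "face": face, "par": par[i]}
            row.update({f"E_{c:.0f}nm": spec[i, b]
                        for b, c in enumerate(sol.bands.centres)})
            rows.append(row)
    pd.DataFrame(rows).sort_values(["facet", "face"]).to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".ledger.json"), "w") as fh:
        json.dump({**sol.ledger, "iterations": sol.iterations,
                   "residual": sol.residual, "converged": sol.converged}, fh)
    return path


def export_isoclines(isoclines: dict[float, list[np.ndarray]], path) -> Path:
    """Isocline polylines as GeoJSON-style JSON in (LAI, shading) space."""
    path = Path(path)
    features = []
    for level, polys in isoclines.items():
        for poly in polys:
            features.append({
                "type": "Feature",
                "properties": {"hasat": level},
                "geometry": {"type": "LineString",
                             "coordinates": np.asarray(poly).tolist()},
            })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path
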