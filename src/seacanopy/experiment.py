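"""Factorial modelling-experiment driver, fixtures and configuration.

Enumerates and executes the LAI x canopy-structure x shading x hour design
(5 x 15 x 9 x 12 = 8100 runs at the default design), with seeded synthetic
plant fixtures standing in for field-sampled morphometrics.  Two exact model
properties keep the computation desk-scale: shading is a spectrally neutral
multiplier on the boundary radiance and the whole optical chain is linear in
that boundary condition, so all shading levels (and all E_k thresholds)
derive from the single unshaded solve of each (LAI, structure, hour) cell;
and the azimuthally averaged radiance is symmetric about solar noon, so only
the unique morning zeniths need solving.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import itertools
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .bands import SpectralBands, ZenithGrid
from .dynamics import WaveForcing, extract_snapshots, simulate_motion
from .lightfield import (Site, WaterIOPs, diurnal_zeniths, top_of_canopy_radiance)
from .materials import MaterialLibrary
from .morphology import (ROLE_LEAF, ROLE_SUBSTRATE, CanopyScene, PlantParams,
                         assemble_canopy, build_scene, facetize)
from .radiosity import (Tracer, energy_audit, leaf_field, solve_canopy,
                        substrate_transmittance)
from .saturation import (Ek, HAsatSurface, SaturationSeries,
                         build_hasat_surface, hasat, wave_average)

MATERIAL_OPAQUE = 3

DEFAULT_LAI_TREATMENTS = (1.27, 1.94, 3.15, 5.00, 7.65)
DEFAULT_SHADING_PERCENT = (0, 10, 25, 40, 50, 60, 70, 85, 95)
DEFAULT_EK_VALUES = (45.0, 50.0, 55.0)
N_STRUCTURES = 15  # 1 upright + 14 movement snapshots


@dataclass(frozen=True)
class Resolution:
    """Numerical resolution bundle for the optical solver."""

    max_facet_area: float = 5e-5   # m^2; ~0.5 cm^2 leaf facets
    n_az: int = 8                  # azimuth samples per zenith ring
    n_scatter: int = 32            # exchange-factor rays per facet face
    n_zenith: int = 18             # zenith bins over the hemisphere
    tol: float = 1e-4
    max_iters: int = 20


DEFAULT_RESOLUTION = Resolution()
REDUCED_RESOLUTION = Resolution(max_facet_area=2e-4, n_az=8, n_scatter=16)


@dataclass(frozen=True)
class RunSpec:
    """One factorial cell: (LAI treatment, structure, shading %, hour index)."""

    lai: float
    structure: int      # 0 = upright (low wave); 1..14 = movement snapshots
    shading: float      # percent
    hour: int           # 1..12


@dataclass
class ExperimentConfig:
    site: Site = field(default_factory=Site)
    lai_treatments: tuple = DEFAULT_LAI_TREATMENTS
    shading_percent: tuple = DEFAULT_SHADING_PERCENT
    ek_values: tuple = DEFAULT_EK_VALUES
    n_hours: int = 12
    structures: tuple = tuple(range(N_STRUCTURES))
    wave: WaveForcing = field(default_factory=WaveForcing.high)
    resolution: Resolution = DEFAULT_RESOLUTION
    use_diurnal_symmetry: bool = True
    master_seed: int = 0

    def to_yaml(self, path) -> None:
        d = {
            "site": {"latitude": self.site.latitude,
                     "longitude": self.site.longitude,
                     "date": self.site.date.isoformat(),
                     "depth": self.site.depth},
            "lai_treatments": list(self.lai_treatments),
            "shading_percent": list(self.shading_percent),
            "ek_values": list(self.ek_values),
            "n_hours": self.n_hours,
            "structures": list(self.structures),
            "wave": {"amplitude": self.wave.amplitude,
                     "period": self.wave.period,
                     "drag_coefficient": self.wave.drag_coefficient,
                     "mode": self.wave.mode},
            "resolution": dataclasses.asdict(self.resolution),
            "use_diurnal_symmetry": self.use_diurnal_symmetry,
            "master_seed": self.master_seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        site = Site(latitude=d["site"]["latitude"],
                    longitude=d["site"]["longitude"],
                    date=_dt.date.fromisoformat(d["site"]["date"]),
                    depth=d["site"]["depth"])
        wave = WaveForcing(amplitude=d["wave"]["amplitude"],
                           period=d["wave"]["period"],
                           drag_coefficient=d["wave"]["drag_coefficient"],
                           mode=d["wave"]["mode"])
        return cls(site=site,
                   lai_treatments=tuple(d["lai_treatments"]),
                   shading_percent=tuple(d["shading_percent"]),
                   ek_values=tuple(d["ek_values"]),
                   n_hours=d["n_hours"],
                   structures=tuple(d["structures"]),
                   wave=wave,
                   resolution=Resolution(**d["resolution"]),
                   use_diurnal_symmetry=d["use_diurnal_symmetry"],
                   master_seed=d["master_seed"])


def derive_seed(master_seed: int, *fields) -> int:
    """Stable per-run seed from the master seed and RunSpec fields."""
    key = "|".join(str(f) for f in (master_seed,) + fields)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def enumerate_runs(config: ExperimentConfig) -> list[RunSpec]:
    """Cartesian product of the design axes in (lai, structure, shading, hour) order."""
    axes = (config.lai_treatments, config.structures,
            config.shading_percent, range(1, config.n_hours + 1))
    if any(len(list(a)) == 0 for a in axes):
        raise ValueError("empty design axis")
    return [RunSpec(lai=l, structure=s, shading=sh, hour=h)
            for l, s, sh, h in itertools.product(*axes)]


# ---------------------------------------------------------------------------
# Toy and fixture scenes
# ---------------------------------------------------------------------------

def scene_from_facets(vertices, faces, role, tile=(0.2, 0.2),
                      material=None) -> CanopyScene:
    """Raw facets plus a substrate quad as a scene (fixture plumbing)."""
    base = build_scene([], tile)
    v = np.concatenate([base.vertices, np.asarray(vertices, dtype=float)])
    f = np.concatenate([base.faces,
                        np.asarray(faces, dtype=np.int64) + base.vertices.shape[0]])
    r = np.concatenate([base.role, np.asarray(role, dtype=np.int8)])
    m = (np.concatenate([base.material, np.asarray(material, dtype=np.int16)])
         if material is not None else r.astype(np.int16))
    pid = np.concatenate([base.plant_id,
                          np.zeros(len(faces), dtype=np.int32)])
    return CanopyScene(tile_x=tile[0], tile_y=tile[1], vertices=v, faces=f,
                       role=r, material=m, plant_id=pid, plants=[])


def substrate_only_scene(tile=(0.2, 0.2)) -> CanopyScene:
    return build_scene([], tile)


def single_leaf_scene(leaf_area: float = 1e-3, height: float = 0.1,
                      tile=(0.2, 0.2)) -> CanopyScene:
    """One horizontal square leaf of given one-sided area at mid-canopy."""
    s = np.sqrt(leaf_area)
    cx, cy = tile[0] / 2, tile[1] / 2
    v = np.array([[cx - s / 2, cy - s / 2, height],
                  [cx + s / 2, cy - s / 2, height],
                  [cx + s / 2, cy + s / 2, height],
                  [cx - s / 2, cy + s / 2, height]])
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return scene_from_facets(v, f, np.full(2, ROLE_LEAF), tile)


def opaque_slab_scene(height: float = 0.2, tile=(0.2, 0.2)) -> CanopyScene:
    """Horizontal opaque slab covering the whole (periodic) tile."""
    tx, ty = tile
    v = np.array([[0, 0, height], [tx, 0, height],
                  [tx, ty, height], [0, ty, height]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return scene_from_facets(v, f, np.full(2, ROLE_LEAF), tile,
                             material=np.full(2, MATERIAL_OPAQUE))


def random_facet_scene(n: int = 50, seed: int = 0,
                       tile=(0.2, 0.2)) -> CanopyScene:
    """n randomly placed/oriented leaf triangles (path-tracer oracle scene)."""
    rng = np.random.default_rng(seed)
    verts = []
    faces = []
    for i in range(n):
        c = rng.uniform([0.02, 0.02, 0.03], [tile[0] - 0.02, tile[1] - 0.02, 0.15])
        size = rng.uniform(0.008, 0.016)
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        a = a / np.linalg.norm(a) * size
        b = b / np.linalg.norm(b) * size
        verts.extend([c, c + a, c + b])
        faces.append([3 * i, 3 * i + 1, 3 * i + 2])
    return scene_from_facets(np.asarray(verts), np.asarray(faces),
                             np.full(n, ROLE_LEAF), tile)


@dataclass
class Fixtures:
    plant_params: list[PlantParams]
    canopies: dict[float, CanopyScene]
    toys: dict[str, CanopyScene]


def make_plant_pool(seed: int, n: int = 10,
                    leaf_inclination=(67.0, 86.0)) -> list[PlantParams]:
    """Ten seeded plant-parameter variants emulating field-sampled plants."""
    rng = np.random.default_rng(seed)
    pool = []
    for _ in range(n):
        h = rng.uniform(0.32, 0.58)
        pool.append(PlantParams(
            stem_height=(h * 0.95, h * 1.05),
            n_internodes=int(rng.integers(6, 11)),
            branches_per_node=(2.0, 3.5),
            branch_length=(0.04, 0.10),
            leaves_per_cluster=(2.0, 4.0),
            leaf_length=(float(rng.uniform(0.045, 0.06)),
                         float(rng.uniform(0.08, 0.11))),
            leaf_width=(0.006, 0.010),
            leaf_inclination=leaf_inclination,
            stem_diameter=0.002,
            seed=int(rng.integers(2**31)),
        ))
    return pool


def make_fixtures(seed: int = 0,
                  lai_treatments=DEFAULT_LAI_TREATMENTS) -> Fixtures:
    """Seeded synthetic plant pool, the five design canopies and toy scenes."""
    pool = make_plant_pool(seed)
    canopies = {
        lai: assemble_canopy(pool, target_lai=lai,
                             seed=derive_seed(seed, "canopy", lai))
        for lai in lai_treatments
    }
    toys = {
        "substrate_only": substrate_only_scene(),
        "single_leaf": single_leaf_scene(),
        "opaque_slab": opaque_slab_scene(),
        "random_facets": random_facet_scene(seed=derive_seed(seed, "random50")),
    }
    return Fixtures(plant_params=pool, canopies=canopies, toys=toys)


def default_materials(bands: SpectralBands | None = None) -> MaterialLibrary:
    """Default material library plus the opaque fixture material."""
    bands = bands or SpectralBands()
    lib = MaterialLibrary.default(bands)
    lib.add(MATERIAL_OPAQUE, np.full(bands.n, 0.1), np.zeros(bands.n))
    return lib


# ---------------------------------------------------------------------------
# Diurnal machinery
# ---------------------------------------------------------------------------

def diurnal_boundary(site: Site, iops: WaterIOPs, n_hours: int = 12,
                     zgrid: ZenithGrid | None = None,
                     bands: SpectralBands | None = None):
    """Hour centres, zeniths and (cached) unique boundary radiances.

    Returns (hours, zeniths, radiance list per hour, unique-hour indices):
    zeniths are exactly symmetric about solar noon, so mirrored hours share
    one computed radiance.
    """
    bands = bands or SpectralBands()
    zgrid = zgrid or ZenithGrid()
    hours, zens = diurnal_zeniths(site.latitude, site.date, n_hours)
    cache: dict[float, object] = {}
    rads = []
    unique_idx = []
    for i, z in enumerate(zens):
        key = round(float(z), 9)
        if key not in cache:
            cache[key] = top_of_canopy_radiance(site, z, iops, bands, zgrid)
            unique_idx.append(i)
        rads.append(cache[key])
    return hours, zens, rads, unique_idx


def diurnal_leaf_par(scene: CanopyScene, site: Site, iops: WaterIOPs,
                     resolution: Resolution = DEFAULT_RESOLUTION,
                     seed: int = 0, n_hours: int = 12,
                     materials: MaterialLibrary | None = None,
                     use_symmetry: bool = True):
    """Unshaded per-leaf PAR and top-of-canopy PAR for every diurnal hour.

    Returns (hours, list of per-leaf PAR arrays, leaf areas, toc PAR array).
    With ``use_symmetry`` mirrored hours reuse the computed morning solve
    (exact: their boundary radiances are identical).
    """
    bands = SpectralBands()
    zgrid = ZenithGrid(resolution.n_zenith)
    materials = materials or default_materials(bands)
    if not scene.is_facetized:
        scene = facetize(scene, resolution.max_facet_area)
    tracer = Tracer(scene)
    hours, zens, rads, _ = diurnal_boundary(site, iops, n_hours, zgrid, bands)
    cache: dict[float, tuple] = {}
    par_by_hour = []
    toc = np.empty(len(hours))
    areas = None
    for i, (z, rad) in enumerate(zip(zens, rads)):
        key = round(float(z), 9) if use_symmetry else float(i)
        if key not in cache:
            sol = solve_canopy(scene, rad, materials, iops, seed=seed,
                               n_az=resolution.n_az,
                               n_scatter=resolution.n_scatter,
                               tol=resolution.tol,
                               max_iters=resolution.max_iters,
                               tracer=tracer)
            fld = leaf_field(sol)
            cache[key] = (fld.par, fld.areas, fld.toc_par)
        par_by_hour.append(cache[key][0])
        areas = cache[key][1]
        toc[i] = cache[key][2]
    return hours, par_by_hour, areas, toc


def saturation_series(par_by_hour, areas, toc_par, hours,
                      ek: Ek, shading_fraction: float = 0.0) -> SaturationSeries:
    """Saturation series for one shading level from the unshaded solve.

    Exploits linearity: shading by s scales every leaf PAR by (1-s), so the
    saturated fraction equals thresholding the unshaded field at Ek/(1-s).
    """
    total = areas.sum()
    thresh = ek.value / (1.0 - shading_fraction)
    frac = np.array([100.0 * areas[par >= thresh].sum() / total
                     for par in par_by_hour])
    return SaturationSeries(hours=hours, sat_fraction=frac,
                            toc_par=toc_par * (1.0 - shading_fraction))


def structure_scenes(scene: CanopyScene, structures, wave: WaveForcing,
                     n_snapshots: int = 14) -> dict[int, CanopyScene]:
    """Map structure indices to scenes (0 upright, 1..n movement snapshots)."""
    out = {}
    snaps = None
    for s in structures:
        if s == 0:
            out[0] = scene
        else:
            if snaps is None:
                traj = simulate_motion(scene, wave)
                snaps = extract_snapshots(traj, n_snapshots)
            out[s] = snaps[s - 1]
    return out


def compute_hasat_surface(
    canopies: dict[float, CanopyScene],
    site: Site,
    iops: WaterIOPs,
    shading_percent=DEFAULT_SHADING_PERCENT,
    ek: Ek = Ek(50.0),
    wave_mode: str = "low",
    wave: WaveForcing | None = None,
    n_snapshots: int = 14,
    resolution: Resolution = REDUCED_RESOLUTION,
    seed: int = 0,
    n_hours: int = 12,
    use_symmetry: bool = True,
    monotone_tol: float = 1e-9,
) -> HAsatSurface:
    """H^A_sat over the LAI x shading grid for one E_k and wave mode."""
    results: dict[tuple[float, float], float] = {}
    sds: dict[tuple[float, float], float] = {}
    for lai, scene in canopies.items():
        if wave_mode == "low":
            scenes = [scene]
        else:
            wave = wave or WaveForcing.high()
            traj = simulate_motion(scene, wave)
            scenes = extract_snapshots(traj, n_snapshots)
        per_structure: dict[float, list[float]] = {s: [] for s in shading_percent}
        for k, sc in enumerate(scenes):
            run_seed = derive_seed(seed, "surface", lai, k)
            hours, par_by_hour, areas, toc = diurnal_leaf_par(
                sc, site, iops, resolution, run_seed, n_hours,
                use_symmetry=use_symmetry)
            for sh in shading_percent:
                series = saturation_series(par_by_hour, areas, toc, hours,
                                           ek, sh / 100.0)
                per_structure[sh].append(hasat(series))
        for sh in shading_percent:
            mean, sd = wave_average(per_structure[sh])
            results[(lai, float(sh))] = mean
            sds[(lai, float(sh))] = sd
    return build_hasat_surface(results, list(canopies.keys()),
                               [float(s) for s in shading_percent],
                               ek, wave_mode=wave_mode, sd=sds,
                               monotone_tol=monotone_tol)


# ---------------------------------------------------------------------------
# Validation computations (energy audit, transmittance-vs-LAI)
# ---------------------------------------------------------------------------

def noon_zenith(site: Site) -> float:
    """Air solar zenith at the diurnal hour-centre closest to solar noon."""
    _, zens = diurnal_zeniths(site.latitude, site.date, 12)
    return float(zens.min())


def audit_subset(seed: int = 0,
                 lai_treatments=DEFAULT_LAI_TREATMENTS,
                 n_structures: int = 3,
                 resolution: Resolution = DEFAULT_RESOLUTION,
                 site: Site | None = None) -> pd.DataFrame:
    """Energy audits over a representative run subset (water absorption zero).

    For each LAI treatment: the upright structure plus movement snapshots to
    a total of ``n_structures`` structures, audited at the midday boundary
    radiance.  Returns a DataFrame of closure errors (fractions).
    """
    site = site or Site()
    bands = SpectralBands()
    zgrid = ZenithGrid(resolution.n_zenith)
    iops = WaterIOPs.reference(bands, depth=site.depth)
    rad = top_of_canopy_radiance(site, noon_zenith(site), iops, bands, zgrid)
    materials = default_materials(bands)
    fx = make_fixtures(seed, lai_treatments)
    rows = []
    for lai, scene in fx.canopies.items():
        scenes = [("upright", scene)]
        if n_structures > 1:
            traj = simulate_motion(scene, WaveForcing.high())
            snaps = extract_snapshots(traj, 14)
            pick = np.linspace(0, 13, n_structures - 1).astype(int)
            scenes += [(f"snapshot_{k}", snaps[k]) for k in pick]
        for name, sc in scenes:
            fsc = facetize(sc, resolution.max_facet_area)
            closure, _ = energy_audit(
                fsc, materials, rad,
                seed=derive_seed(seed, "audit", lai, name),
                n_az=resolution.n_az, n_scatter=resolution.n_scatter)
            rows.append({"lai": lai, "structure": name,
                         "closure_error": closure})
    return pd.DataFrame(rows)


def transmittance_validation(seed: int = 0, n_points: int = 25,
                             lai_min: float = 0.3, lai_max: float = 8.0,
                             resolution: Resolution = REDUCED_RESOLUTION,
                             site: Site | None = None,
                             leaf_inclination=None) -> pd.DataFrame:
    """Substrate transmittance vs LAI across fixture canopies at midday.

    Upright (low wave) structures at the hour closest to midday, mirroring
    the canopy-optical-model validation protocol.
    """
    site = site or Site()
    bands = SpectralBands()
    zgrid = ZenithGrid(resolution.n_zenith)
    iops = WaterIOPs.reference(bands, depth=site.depth)
    rad = top_of_canopy_radiance(site, noon_zenith(site), iops, bands, zgrid)
    materials = default_materials(bands)
    pool = (make_plant_pool(seed) if leaf_inclination is None
            else make_plant_pool(seed, leaf_inclination=leaf_inclination))
    rows = []
    for lai in np.linspace(lai_min, lai_max, n_points):
        sc = assemble_canopy(pool, target_lai=float(lai),
                             seed=derive_seed(seed, "valcanopy", round(lai, 4)))
        fsc = facetize(sc, resolution.max_facet_area)
        sol = solve_canopy(fsc, rad, materials, iops,
                           seed=derive_seed(seed, "valrun", round(lai, 4)),
                           n_az=resolution.n_az,
                           n_scatter=resolution.n_scatter)
        rows.append({"lai": fsc.lai,
                     "transmittance_pct": substrate_transmittance(sol)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full factorial driver
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Execute the factorial design; one row per enumerated run.

    Deterministic for a fixed master seed (per-run seeds derived by a stable
    hash of the RunSpec).  Individual structure failures are recorded in the
    ``error`` column and the remainder completes.
    """
    runs = enumerate_runs(config)
    bands = SpectralBands()
    iops = WaterIOPs.reference(bands, depth=config.site.depth)
    materials = default_materials(bands)
    fx = make_fixtures(config.master_seed, config.lai_treatments)
    res = config.resolution

    rows: list[dict] = []
    for lai in config.lai_treatments:
        base = fx.canopies[lai]
        try:
            scenes = structure_scenes(base, config.structures, config.wave)
        except Exception as exc:  # pragma: no cover - defensive
            for r in runs:
                if r.lai == lai:
                    rows.append({**dataclasses.asdict(r), "error": str(exc)})
            continue
        for s, sc in scenes.items():
            run_seed = derive_seed(config.master_seed, lai, s)
            try:
                hours, par_by_hour, areas, toc = diurnal_leaf_par(
                    sc, config.site, iops, res, run_seed, config.n_hours,
                    materials, use_symmetry=config.use_diurnal_symmetry)
            except Exception as exc:
                for r in runs:
                    if r.lai == lai and r.structure == s:
                        rows.append({**dataclasses.asdict(r), "error": str(exc)})
                continue
            total = areas.sum()
            for sh in config.shading_percent:
                fac = 1.0 - sh / 100.0
                for h in range(1, config.n_hours + 1):
                    par = par_by_hour[h - 1]
                    row = {"lai": lai, "structure": s, "shading": float(sh),
                           "hour": h, "toc_par": toc[h - 1] * fac,
                           "error": ""}
                    for ek in config.ek_values:
                        row[f"sat{int(ek)}"] = float(
                            100.0 * areas[par >= ek / fac].sum() / total)
                    rows.append(row)
    df = pd.DataFrame(rows)
    order = ["lai", "structure", "shading", "hour"]
    return df.sort_values(order).reset_index(drop=True)
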