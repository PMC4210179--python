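"""Geometric-optics radiative transfer within the periodic canopy.

Stage 1 (direct illumination): the azimuthally uniform top-of-canopy radiance
is integrated over the downward hemisphere at every facet centroid, with
occlusion resolved by ray casting against the periodically wrapped scene and
within-canopy water absorption exp(-a * pathlength) applied along each ray.

Stage 2 (multiple scattering): all surfaces are two-sided Lambertian
reflector/transmitters.  Facet-to-facet exchange factors are estimated by
seeded cosine-weighted Monte-Carlo rays from both faces of every facet, and
the Lambertian inter-reflection/transmission equilibrium is found by Jacobi
gathering sweeps; a face's exitant radiosity is rho * (same-face incident) +
tau * (opposite-face incident).

The energy audit runs the same machinery with water absorption forced to
zero and checks top-of-canopy incident power against exitant-to-sky plus
surface-absorbed power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import curve_fit

from ._ray import Tracer
from .bands import DirectionalRadiance, SpectralBands, to_par_array
from .lightfield import WaterIOPs
from .materials import MaterialLibrary
from .morphology import ROLE_LEAF, ROLE_SUBSTRATE, CanopyScene


@dataclass
class RadiositySolution:
    """Per-facet, per-face incident spectral irradiance after scattering."""

    scene: CanopyScene
    bands: SpectralBands
    incident: np.ndarray          # (n_facets, 2, n_bands) W m^-2 nm^-1
    radiosity: np.ndarray         # (n_facets, 2, n_bands) W m^-2 nm^-1 exitant
    toc_band_irradiance: np.ndarray  # (n_bands,) W m^-2 nm^-1 planar downwelling
    iterations: int
    residual: float
    converged: bool
    ledger: dict = field(default_factory=dict)


@dataclass
class LeafIrradianceField:
    """Total (both faces) incident PAR per leaf facet."""

    areas: np.ndarray             # (n_leaf,) m^2
    par: np.ndarray               # (n_leaf,) umol quanta m^-2 s^-1
    spectral: np.ndarray          # (n_leaf, n_bands) W m^-2 nm^-1, both faces
    toc_par: float                # top-of-canopy planar downwelling PAR

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def hemisphere_directions(zgrid, n_az: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upward quadrature directions, their solid angles and zenith-bin ids.

    Directions sit at each ring's irradiance-weighted mean zenith so the
    cosine-weighted sum over a ring is exact for a horizontal facet.
    """
    theta = np.radians(zgrid.eff_zenith)
    phi = (np.arange(n_az) + 0.5) / n_az * 2.0 * np.pi
    dirs = np.empty((zgrid.n_bins * n_az, 3))
    omega = np.empty(zgrid.n_bins * n_az)
    bin_id = np.empty(zgrid.n_bins * n_az, dtype=np.int64)
    k = 0
    for b in range(zgrid.n_bins):
        st, ct = math.sin(theta[b]), math.cos(theta[b])
        for p in phi:
            dirs[k] = (st * math.cos(p), st * math.sin(p), ct)
            omega[k] = zgrid.ring_omega[b] / n_az
            bin_id[k] = b
            k += 1
    return dirs, omega, bin_id


def direct_illumination(
    scene: CanopyScene,
    rad: DirectionalRadiance,
    iops: WaterIOPs | None = None,
    n_az: int = 8,
    tracer: Tracer | None = None,
) -> tuple[np.ndarray, Tracer]:
    """First-order incident irradiance per facet face.

    Returns ``(first_order, tracer)`` where ``first_order`` has shape
    (n_facets, 2, n_bands) in W m^-2 nm^-1; face 0 is the facet-normal side.
    Linear in ``rad``.
    """
    if not scene.is_facetized:
        raise ValueError("scene must be facetized before illumination")
    tracer = tracer or Tracer(scene)
    zgrid, bands = rad.zgrid, rad.bands
    dirs, omega, bin_id = hemisphere_directions(zgrid, n_az)
    # directions in zero-radiance zenith bins contribute nothing; skip them
    active = rad.radiance.max(axis=1)[bin_id] > 0.0
    dirs, omega, bin_id = dirs[active], omega[active], bin_id[active]
    phases = tracer.azimuth_phases()
    vis = tracer.visibility(dirs, phases).astype(np.float64)  # (m, k)

    # the kernel rotates each facet's directions about z by its phase;
    # rotating the normal the opposite way gives the matching cosines
    c, s = np.cos(phases), np.sin(phases)
    n = tracer.normals
    n_rot = np.column_stack([c * n[:, 0] + s * n[:, 1],
                             -s * n[:, 0] + c * n[:, 1],
                             n[:, 2]])
    cosa = n_rot @ dirs.T                                     # (m, k) signed
    z = tracer.centroids[:, 2]
    path = (tracer.z_top - z)[:, None] / dirs[:, 2][None, :]  # (m, k)

    a = (iops.absorption if iops is not None else np.zeros(bands.n))
    L = rad.radiance[bin_id]                                  # (k, nb)

    m = tracer.v0.shape[0]
    first = np.zeros((m, 2, bands.n))
    chunk = 512
    for s in range(0, m, chunk):
        e = min(s + chunk, m)
        att = np.exp(-path[s:e, :, None] * a[None, None, :])  # (c, k, nb)
        w = vis[s:e] * omega[None, :]
        up = w * np.maximum(cosa[s:e], 0.0)
        dn = w * np.maximum(-cosa[s:e], 0.0)
        first[s:e, 0] = np.einsum("ck,ckb,kb->cb", up, att, L)
        first[s:e, 1] = np.einsum("ck,ckb,kb->cb", dn, att, L)
    return first, tracer


def solve_scattering(
    scene: CanopyScene,
    materials: MaterialLibrary,
    first_order: np.ndarray,
    rad: DirectionalRadiance,
    iops: WaterIOPs | None = None,
    tol: float = 1e-4,
    max_iters: int = 20,
    seed: int = 0,
    n_scatter: int = 32,
    tracer: Tracer | None = None,
) -> RadiositySolution:
    """Jacobi gathering over Monte-Carlo exchange factors.

    Iterates E = E_first + M B(E) with B = rho*E_same + tau*E_opposite until
    the relative change in total surface-absorbed power is below ``tol`` or
    ``max_iters`` sweeps; the solution is linear in ``first_order``.
    """
    tracer = tracer or Tracer(scene)
    bands = materials.bands
    m = scene.n_facets
    rho, tau = materials.arrays_for(scene.material)           # (m, nb)
    if np.any(rho + tau > 1.0 + 1e-12):
        raise ValueError("materials must satisfy rho + tau <= 1")
    areas = tracer.areas
    widths = bands.widths
    a = (iops.absorption if iops is not None else np.zeros(bands.n))

    black = bool(np.all(rho == 0) and np.all(tau == 0))
    dst, dst_face, dist = (None, None, None)
    mats: list[sp.csr_matrix] = []
    sky_w = np.zeros(2 * m)
    if not black:
        dst, dst_face, dist = tracer.scatter_rays(n_scatter, seed)
        src_face_idx = np.repeat(np.arange(2 * m), n_scatter)
        hit = dst >= 0
        rows = dst[hit] * 2 + dst_face[hit]
        cols = src_face_idx[hit]
        src_facet = cols // 2
        dst_facet = dst[hit]
        base_w = areas[src_facet] / (n_scatter * areas[dst_facet])
        d_hit = dist[hit]
        uniform_a = bool(np.all(a == a[0]))
        n_mats = 1 if uniform_a else bands.n
        for b in range(n_mats):
            data = base_w * np.exp(-a[b] * d_hit)
            mats.append(sp.csr_matrix(
                (data, (rows, cols)), shape=(2 * m, 2 * m)))
        sky = dst == -1
        # sky escape weighted by water attenuation on the mean sky path
        sky_att = np.exp(-a.mean() * dist[sky])
        np.add.at(sky_w, src_face_idx[sky], sky_att / n_scatter)

    E = first_order.copy()                                    # (m, 2, nb)
    absorbtance = np.clip(1.0 - rho - tau, 0.0, None)

    def absorbed_power(Einc):
        per_face = (Einc * absorbtance[:, None, :]).sum(axis=1)  # (m, nb)
        return float(((per_face * widths) * areas[:, None]).sum())

    def incident_power(Einc):
        return float(((Einc.sum(axis=1) * widths) * areas[:, None]).sum())

    sky_power = 0.0
    it = 0
    # convergence is tracked on total incident power (robust even for
    # zero-absorptance materials, where absorbed power is identically 0)
    prev = incident_power(E)
    residual = 0.0
    converged = black
    if not black:
        for it in range(1, max_iters + 1):
            B0 = rho * E[:, 0, :] + tau * E[:, 1, :]
            B1 = rho * E[:, 1, :] + tau * E[:, 0, :]
            Bfaces = np.empty((2 * m, bands.n))
            Bfaces[0::2] = B0
            Bfaces[1::2] = B1
            if len(mats) == 1:
                scat = mats[0] @ Bfaces
            else:
                scat = np.column_stack(
                    [mats[b] @ Bfaces[:, b] for b in range(bands.n)])
            E = first_order.copy()
            E[:, 0, :] += scat[0::2]
            E[:, 1, :] += scat[1::2]
            cur = incident_power(E)
            residual = abs(cur - prev) / max(abs(cur), 1e-300)
            prev = cur
            if residual < tol:
                converged = True
                break
        # exitant to sky at the converged radiosity
        B0 = rho * E[:, 0, :] + tau * E[:, 1, :]
        B1 = rho * E[:, 1, :] + tau * E[:, 0, :]
        p0 = (B0 * widths).sum(axis=1) * areas
        p1 = (B1 * widths).sum(axis=1) * areas
        sky_power = float((p0 * sky_w[0::2]).sum() + (p1 * sky_w[1::2]).sum())

    B0 = rho * E[:, 0, :] + tau * E[:, 1, :]
    B1 = rho * E[:, 1, :] + tau * E[:, 0, :]
    radiosity = np.stack([B0, B1], axis=1)

    toc = rad.planar_irradiance()
    tile_area = scene.tile_x * scene.tile_y
    e_in = float((toc * widths).sum() * tile_area)
    e_abs = absorbed_power(E)
    ledger = {
        "incident": e_in,
        "exitant_to_sky": sky_power,
        "absorbed_by_surfaces": e_abs,
        "absorbed_by_water": e_in - sky_power - e_abs,
    }
    return RadiositySolution(
        scene=scene,
        bands=bands,
        incident=E,
        radiosity=radiosity,
        toc_band_irradiance=toc,
        iterations=it if not black else 1,
        residual=residual,
        converged=converged,
        ledger=ledger,
    )


def solve_canopy(
    scene: CanopyScene,
    rad: DirectionalRadiance,
    materials: MaterialLibrary | None = None,
    iops: WaterIOPs | None = None,
    seed: int = 0,
    n_az: int = 8,
    n_scatter: int = 32,
    tol: float = 1e-4,
    max_iters: int = 20,
    tracer: Tracer | None = None,
) -> RadiositySolution:
    """Direct illumination followed by the multiple-scattering solve."""
    materials = materials or MaterialLibrary.default(rad.bands)
    tracer = tracer or Tracer(scene)
    first, tracer = direct_illumination(scene, rad, iops, n_az=n_az, tracer=tracer)
    return solve_scattering(scene, materials, first, rad, iops,
                            tol=tol, max_iters=max_iters, seed=seed,
                            n_scatter=n_scatter, tracer=tracer)


def leaf_field(sol: RadiositySolution) -> LeafIrradianceField:
    """Reduce a solution to per-leaf-facet incident PAR (both faces summed)."""
    scene = sol.scene
    leaf = scene.role == ROLE_LEAF
    if not leaf.any():
        raise ValueError("scene has no leaf facets")
    areas = scene.facet_areas()[leaf]
    spectral = sol.incident[leaf].sum(axis=1)                 # (n_leaf, nb)
    par = to_par_array(spectral * sol.bands.widths, sol.bands)
    toc_par = to_par_array(sol.toc_band_irradiance * sol.bands.widths, sol.bands)
    return LeafIrradianceField(areas=areas, par=par, spectral=spectral,
                               toc_par=float(toc_par))


def energy_audit(
    scene: CanopyScene,
    materials: MaterialLibrary,
    rad: DirectionalRadiance,
    seed: int = 0,
    n_az: int = 8,
    n_scatter: int = 32,
) -> tuple[float, RadiositySolution]:
    """Energy-conservation closure with within-canopy water absorption zero.

    Returns (closure error fraction, solution): |E_in - E_sky - E_absorbed|
    / E_in integrated over all bands and the tile.
    """
    sol = solve_canopy(scene, rad, materials, iops=None, seed=seed,
                       n_az=n_az, n_scatter=n_scatter)
    led = sol.ledger
    closure = abs(led["incident"] - led["exitant_to_sky"]
                  - led["absorbed_by_surfaces"]) / led["incident"]
    return float(closure), sol


def substrate_transmittance(sol: RadiositySolution) -> float:
    """Percent of top-of-canopy downwelling PAR incident on the substrate."""
    scene = sol.scene
    sub = scene.role == ROLE_SUBSTRATE
    if not sub.any():
        raise ValueError("scene has no substrate facets")
    toc_par = to_par_array(sol.toc_band_irradiance * sol.bands.widths, sol.bands)
    if toc_par <= 0:
        raise ValueError("zero incident top-of-canopy irradiance")
    areas = sol.scene.facet_areas()[sub]
    spec = sol.incident[sub, 0, :]                            # up face
    mean_spec = (spec * areas[:, None]).sum(axis=0) / areas.sum()
    sub_par = to_par_array(mean_spec * sol.bands.widths, sol.bands)
    return float(100.0 * sub_par / toc_par)


def fit_exponential_transmittance(points) -> tuple[float, float]:
    """Least-squares fit of y = 100 exp(-b LAI) to (LAI, percent) points.

    Returns (b, r^2 of the points against the fitted curve).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (LAI, percent) points")
    lai, y = pts[:, 0], pts[:, 1]
    if np.any(lai < 0):
        raise ValueError("LAI must be >= 0")
    (b,), _ = curve_fit(lambda x, b: 100.0 * np.exp(-b * x), lai, y, p0=[0.3])
    pred = 100.0 * np.exp(-b * lai)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(b), r2
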