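"""Numba ray-casting kernels over a horizontally periodic triangle scene.

The canopy tile tessellates the horizontal plane, so rays are traced through
an infinite periodic repetition of the tile.  Triangles are binned into a 2D
uniform grid over the base tile (entries carry the tile-shift that brings the
triangle copy into the base domain) and rays walk world cells with a 2D DDA;
a world cell maps to its base cell plus a world tile offset.  Intersection is
Moller-Trumbore with a 1e-7 m epsilon; self-intersection is excluded by facet
id.  Rays terminate on the first hit, on escaping above the scene top, or on
a step cap (near-horizontal rays in near-empty scenes).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 1e-7
_MAX_STEPS = 4000


@njit(cache=True)
def _rand01(state):
    """splitmix64 -> uniform in [0, 1)."""
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _trace(ox, oy, oz, dx, dy, dz, skip,
           v0, e1, e2,
           nx, ny, hx, hy, tile_x, tile_y,
           cell_start, cell_tri, cell_sx, cell_sy,
           z_top):
    """Trace one ray; returns (hit_tri, t). hit_tri -1 = sky, -2 = lost."""
    big = 1e30
    if dz > 1e-12:
        t_end = (z_top - oz) / dz
    elif dz < -1e-12:
        t_end = (-1e-4 - oz) / dz
    else:
        t_end = big

    best_t = big
    best_i = -1

    jx = int(math.floor(ox / hx))
    jy = int(math.floor(oy / hy))
    if dx > 1e-15:
        step_x, dt_x = 1, hx / dx
        t_next_x = ((jx + 1) * hx - ox) / dx
    elif dx < -1e-15:
        step_x, dt_x = -1, -hx / dx
        t_next_x = (jx * hx - ox) / dx
    else:
        step_x, dt_x, t_next_x = 0, big, big
    if dy > 1e-15:
        step_y, dt_y = 1, hy / dy
        t_next_y = ((jy + 1) * hy - oy) / dy
    elif dy < -1e-15:
        step_y, dt_y = -1, -hy / dy
        t_next_y = (jy * hy - oy) / dy
    else:
        step_y, dt_y, t_next_y = 0, big, big

    steps = 0
    while steps < _MAX_STEPS:
        steps += 1
        t_exit = t_next_x if t_next_x < t_next_y else t_next_y
        if t_end < t_exit:
            t_exit = t_end
        bx = jx % nx
        by = jy % ny
        wx = (jx - bx) // nx * tile_x
        wy = (jy - by) // ny * tile_y
        c = by * nx + bx
        for e in range(cell_start[c], cell_start[c + 1]):
            i = cell_tri[e]
            if i == skip:
                continue
            sx = cell_sx[e] + wx
            sy = cell_sy[e] + wy
            # Moller-Trumbore against triangle translated by (sx, sy, 0)
            e1x, e1y, e1z = e1[i, 0], e1[i, 1], e1[i, 2]
            e2x, e2y, e2z = e2[i, 0], e2[i, 1], e2[i, 2]
            px = dy * e2z - dz * e2y
            py = dz * e2x - dx * e2z
            pz = dx * e2y - dy * e2x
            det = e1x * px + e1y * py + e1z * pz
            if -1e-14 < det < 1e-14:
                continue
            inv = 1.0 / det
            tx = ox - (v0[i, 0] + sx)
            ty = oy - (v0[i, 1] + sy)
            tz = oz - v0[i, 2]
            u = (tx * px + ty * py + tz * pz) * inv
            if u < -1e-9 or u > 1.0 + 1e-9:
                continue
            qx = ty * e1z - tz * e1y
            qy = tz * e1x - tx * e1z
            qz = tx * e1y - ty * e1x
            v = (dx * qx + dy * qy + dz * qz) * inv
            if v < -1e-9 or u + v > 1.0 + 1e-9:
                continue
            t = (e2x * qx + e2y * qy + e2z * qz) * inv
            if _EPS < t < best_t:
                best_t = t
                best_i = i
        if best_t <= t_exit:
            return best_i, best_t
        if t_exit >= t_end:
            break
        if t_next_x <= t_next_y:
            jx += step_x
            t_next_x += dt_x
        else:
            jy += step_y
            t_next_y += dt_y

    if best_i >= 0:
        return best_i, best_t
    if dz > 1e-12:
        return -1, t_end  # escaped to sky; t is path length to z_top
    return -2, 0.0


@njit(cache=True)
def _visibility_kernel(cent, dirs, phase,
                       v0, e1, e2,
                       nx, ny, hx, hy, tile_x, tile_y,
                       cell_start, cell_tri, cell_sx, cell_sy,
                       z_top):
    """Sky visibility of each facet centroid along each upward direction.

    Each facet's direction set is rotated about z by its own azimuth phase,
    decorrelating the azimuthal quadrature across facets (shared azimuth
    samples alias against the anisotropic canopy and bias the energy sum).
    """
    m = cent.shape[0]
    k = dirs.shape[0]
    vis = np.zeros((m, k), dtype=np.float32)
    pts = np.empty((3, 3))
    for f in range(m):
        cph = math.cos(phase[f])
        sph = math.sin(phase[f])
        # sample points: midpoints between centroid and each vertex, so a
        # partially occluded (or interpenetrating) facet counts fractionally
        for s in range(3):
            if s == 0:
                px, py, pz = v0[f, 0], v0[f, 1], v0[f, 2]
            elif s == 1:
                px = v0[f, 0] + e1[f, 0]
                py = v0[f, 1] + e1[f, 1]
                pz = v0[f, 2] + e1[f, 2]
            else:
                px = v0[f, 0] + e2[f, 0]
                py = v0[f, 1] + e2[f, 1]
                pz = v0[f, 2] + e2[f, 2]
            pts[s, 0] = 0.5 * (cent[f, 0] + px)
            pts[s, 1] = 0.5 * (cent[f, 1] + py)
            pts[s, 2] = 0.5 * (cent[f, 2] + pz)
        for j in range(k):
            ux, uy, dz = dirs[j, 0], dirs[j, 1], dirs[j, 2]
            dx = cph * ux - sph * uy
            dy = sph * ux + cph * uy
            n_open = 0
            for s in range(3):
                hit, _ = _trace(pts[s, 0] + 1e-6 * dx,
                                pts[s, 1] + 1e-6 * dy,
                                pts[s, 2] + 1e-6 * dz,
                                dx, dy, dz, f,
                                v0, e1, e2, nx, ny, hx, hy, tile_x, tile_y,
                                cell_start, cell_tri, cell_sx, cell_sy, z_top)
                if hit == -1:
                    n_open += 1
            vis[f, j] = n_open / 3.0
    return vis


@njit(cache=True)
def _scatter_kernel(cent, normal, n_rays, seed,
                    v0, e1, e2,
                    nx, ny, hx, hy, tile_x, tile_y,
                    cell_start, cell_tri, cell_sx, cell_sy,
                    z_top):
    """Cosine-weighted exchange-factor rays from both faces of every facet.

    Returns per-ray destination facet (-1 sky, -2 lost), destination face
    (0 = normal side), and path length.  Ray r of face (f, s) is slot
    (f*2+s)*n_rays + r; the RNG stream is seeded per face so results are
    independent of facet chunking.
    """
    m = cent.shape[0]
    total = m * 2 * n_rays
    dst = np.full(total, -2, dtype=np.int64)
    dst_face = np.zeros(total, dtype=np.uint8)
    dist = np.zeros(total)
    for f in range(m):
        nxv, nyv, nzv = normal[f, 0], normal[f, 1], normal[f, 2]
        # tangent frame
        if abs(nzv) < 0.9:
            t1x, t1y, t1z = -nyv, nxv, 0.0
        else:
            t1x, t1y, t1z = 1.0, 0.0, 0.0
        t1n = math.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
        t1x, t1y, t1z = t1x / t1n, t1y / t1n, t1z / t1n
        # orthogonalise against n
        d0 = t1x * nxv + t1y * nyv + t1z * nzv
        t1x -= d0 * nxv
        t1y -= d0 * nyv
        t1z -= d0 * nzv
        t1n = math.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
        t1x, t1y, t1z = t1x / t1n, t1y / t1n, t1z / t1n
        t2x = nyv * t1z - nzv * t1y
        t2y = nzv * t1x - nxv * t1z
        t2z = nxv * t1y - nyv * t1x
        for s in range(2):
            sgn = 1.0 if s == 0 else -1.0
            state = np.uint64(seed) ^ (np.uint64(f * 2 + s) *
                                       np.uint64(0xD1B54A32D192ED03))
            for r in range(n_rays):
                state, u1 = _rand01(state)
                state, u2 = _rand01(state)
                sr = math.sqrt(u1)
                phi = 2.0 * math.pi * u2
                lx = sr * math.cos(phi)
                ly = sr * math.sin(phi)
                lz = math.sqrt(1.0 - u1)
                dx = t1x * lx + t2x * ly + sgn * nxv * lz
                dy = t1y * lx + t2y * ly + sgn * nyv * lz
                dz = t1z * lx + t2z * ly + sgn * nzv * lz
                hit, t = _trace(cent[f, 0] + 1e-6 * dx,
                                cent[f, 1] + 1e-6 * dy,
                                cent[f, 2] + 1e-6 * dz,
                                dx, dy, dz, f,
                                v0, e1, e2, nx, ny, hx, hy, tile_x, tile_y,
                                cell_start, cell_tri, cell_sx, cell_sy, z_top)
                k = (f * 2 + s) * n_rays + r
                if hit >= 0:
                    dst[k] = hit
                    dn = (dx * normal[hit, 0] + dy * normal[hit, 1]
                          + dz * normal[hit, 2])
                    dst_face[k] = 0 if dn < 0.0 else 1
                    dist[k] = t
                elif hit == -1:
                    dst[k] = -1
                    dist[k] = t
    return dst, dst_face, dist


class Tracer:
    """Periodic-grid ray tracer bound to one facetized scene."""

    def __init__(self, scene, n_cells: int = 24):
        v = scene.vertices
        f = scene.faces
        self.scene = scene
        self.v0 = np.ascontiguousarray(v[f[:, 0]], dtype=np.float64)
        self.e1 = np.ascontiguousarray(v[f[:, 1]] - v[f[:, 0]], dtype=np.float64)
        self.e2 = np.ascontiguousarray(v[f[:, 2]] - v[f[:, 0]], dtype=np.float64)
        self.normals = scene.facet_normals()
        self.centroids = scene.centroids()
        self.areas = scene.facet_areas()
        self.z_top = scene.z_top
        self.tile_x, self.tile_y = scene.tile_x, scene.tile_y
        self.nx = self.ny = n_cells
        self.hx = self.tile_x / self.nx
        self.hy = self.tile_y / self.ny
        self._build_grid(v, f)

    def _build_grid(self, v, f):
        nx, ny, hx, hy = self.nx, self.ny, self.hx, self.hy
        tx, ty = self.tile_x, self.tile_y
        cells: list[list[tuple[int, float, float]]] = [
            [] for _ in range(nx * ny)
        ]
        tri = v[f]
        mins = tri.min(axis=1)
        maxs = tri.max(axis=1)
        pad = 1e-9
        for i in range(f.shape[0]):
            ix0 = int(math.floor((mins[i, 0] - pad) / hx))
            ix1 = int(math.floor((maxs[i, 0] + pad) / hx))
            iy0 = int(math.floor((mins[i, 1] - pad) / hy))
            iy1 = int(math.floor((maxs[i, 1] + pad) / hy))
            for ix in range(ix0, ix1 + 1):
                bx = ix % nx
                sx = -((ix - bx) // nx) * tx
                for iy in range(iy0, iy1 + 1):
                    by = iy % ny
                    sy = -((iy - by) // ny) * ty
                    cells[by * nx + bx].append((i, sx, sy))
        counts = np.array([len(c) for c in cells], dtype=np.int64)
        self.cell_start = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        total = int(counts.sum())
        self.cell_tri = np.empty(total, dtype=np.int64)
        self.cell_sx = np.empty(total)
        self.cell_sy = np.empty(total)
        k = 0
        for c in cells:
            for (i, sx, sy) in c:
                self.cell_tri[k] = i
                self.cell_sx[k] = sx
                self.cell_sy[k] = sy
                k += 1

    def _args(self):
        return (self.v0, self.e1, self.e2,
                self.nx, self.ny, self.hx, self.hy, self.tile_x, self.tile_y,
                self.cell_start, self.cell_tri, self.cell_sx, self.cell_sy,
                self.z_top)

    def azimuth_phases(self) -> np.ndarray:
        """Deterministic per-facet azimuth rotation for the quadrature."""
        m = self.v0.shape[0]
        golden = 2.0 * math.pi * 0.6180339887498949
        return np.mod(np.arange(m) * golden, 2.0 * math.pi)

    def visibility(self, dirs: np.ndarray,
                   phases: np.ndarray | None = None) -> np.ndarray:
        """(n_facets, n_dirs) sky visibility along (per-facet rotated) dirs."""
        dirs = np.ascontiguousarray(dirs, dtype=np.float64)
        if phases is None:
            phases = np.zeros(self.v0.shape[0])
        return _visibility_kernel(self.centroids, dirs, phases, *self._args())

    def scatter_rays(self, n_rays: int, seed: int):
        """Exchange-factor samples from both faces of every facet."""
        return _scatter_kernel(self.centroids, self.normals,
                               n_rays, seed, *self._args())

    def trace_one(self, origin, direction, skip=-1):
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        return _trace(o[0], o[1], o[2], d[0], d[1], d[2], skip, *self._args())
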