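"""Independent brute-force oracles used by the test suite.

The forward path tracer below deliberately shares no machinery with the
package's radiosity solver: photons are sampled from the boundary radiance
over the tile (one spectral band per photon), intersected against every
triangle by brute force over 3x3 periodic images, and bounced with
Lambertian reflect/transmit splitting until negligible or escaped.  It
estimates total surface-absorbed power with a Monte-Carlo standard error.
"""

from __future__ import annotations

import numpy as np


def _intersect_brute(origin, direction, v0, e1, e2, skip, tile):
    """Nearest triangle hit with 3x3 periodic images; returns (idx, t)."""
    best_t, best_i = np.inf, -1
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            shift = np.array([sx * tile[0], sy * tile[1], 0.0])
            p = np.cross(direction, e2)
            det = np.einsum("ij,ij->i", e1, p)
            ok = np.abs(det) > 1e-14
            inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
            tv = origin - (v0 + shift)
            u = np.einsum("ij,ij->i", tv, p) * inv
            q = np.cross(tv, e1)
            vv = np.einsum("j,ij->i", direction, q) * inv
            t = np.einsum("ij,ij->i", e2, q) * inv
            cand = ok & (u >= -1e-9) & (vv >= -1e-9) & (u + vv <= 1 + 1e-9) & (t > 1e-7)
            if skip >= 0:
                cand[skip] = False
            if np.any(cand):
                idx = np.argmin(np.where(cand, t, np.inf))
                if t[idx] < best_t:
                    best_t, best_i = t[idx], int(idx)
    return best_i, best_t


def path_trace_absorbed(scene, rad, materials, n_photons=4000, seed=123,
                        max_bounces=20):
    """Total surface-absorbed power (W per tile) with its MC standard error.

    Each photon carries one spectral band (drawn from the band/zenith power
    distribution of the boundary radiance) and a scalar weight; Lambertian
    interactions deposit the absorbed fraction and continue with the
    scattered fraction, choosing reflect vs transmit by their band ratio.
    """
    rng = np.random.default_rng(seed)
    v = scene.vertices
    f = scene.faces
    v0 = v[f[:, 0]]
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    normals = np.cross(e1, e2)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    tile = (scene.tile_x, scene.tile_y)
    z_top = scene.z_top
    bands = materials.bands
    rho, tau = materials.arrays_for(scene.material)

    # joint (zenith ring, band) power distribution of the boundary radiance
    w = rad.zgrid.cos_weight[:, None] * rad.radiance * bands.widths[None, :]
    total_power = w.sum() * tile[0] * tile[1]
    p_joint = (w / w.sum()).ravel()
    edges = np.radians(rad.zgrid.edges)

    absorbed_samples = np.zeros(n_photons)
    for n in range(n_photons):
        k = rng.choice(p_joint.size, p=p_joint)
        b, band = divmod(k, bands.n)
        c2a, c2b = np.cos(edges[b]) ** 2, np.cos(edges[b + 1]) ** 2
        ct = np.sqrt(rng.uniform(c2b, c2a))  # cosine-weighted within ring
        st = np.sqrt(1 - ct * ct)
        ph = rng.uniform(0, 2 * np.pi)
        d = np.array([st * np.cos(ph), st * np.sin(ph), -ct])
        o = np.array([rng.uniform(0, tile[0]), rng.uniform(0, tile[1]), z_top])
        weight = total_power
        absorbed = 0.0
        cur = -1
        for _ in range(max_bounces):
            # march tile-by-tile: the 3x3 images only cover one tile of
            # horizontal travel, so near-grazing rays advance the origin
            hit = -1
            for _march in range(600):
                o[0] %= tile[0]
                o[1] %= tile[1]
                hit, t = _intersect_brute(o, d, v0, e1, e2, cur, tile)
                if hit >= 0:
                    horiz = max(abs(d[0]), abs(d[1]), 1e-12)
                    if t * horiz > min(tile):  # hit found beyond one tile of
                        hit = -1               # travel: advance and re-check
                    else:
                        break
                if d[2] >= 0 and o[2] + min(tile) / max(abs(d[0]), abs(d[1]), 1e-12) * d[2] > z_top:
                    break  # escapes upward before the next tile
                t_adv = min(tile) / max(abs(d[0]), abs(d[1]), 1e-12)
                o = o + t_adv * d
                cur = -1
                if o[2] > z_top + 1.0 or o[2] < -1.0:
                    break
            if hit < 0:
                break  # escaped to sky
            o = o + t * d
            cur = hit
            r, tr = rho[hit, band], tau[hit, band]
            absorbed += weight * (1.0 - r - tr)
            weight *= r + tr
            if weight < 1e-9 * total_power:
                break
            n_hat = normals[hit]
            if np.dot(d, n_hat) > 0:
                n_hat = -n_hat
            transmit = rng.uniform() < tr / (r + tr)
            axis = -n_hat if transmit else n_hat
            t1 = np.cross(axis, [1.0, 0.0, 0.0])
            if np.linalg.norm(t1) < 1e-6:
                t1 = np.cross(axis, [0.0, 1.0, 0.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(axis, t1)
            u1, u2 = rng.uniform(), rng.uniform()
            sr = np.sqrt(u1)
            d = (t1 * sr * np.cos(2 * np.pi * u2)
                 + t2 * sr * np.sin(2 * np.pi * u2)
                 + axis * np.sqrt(1 - u1))
        absorbed_samples[n] = absorbed
    mean = absorbed_samples.mean()
    se = absorbed_samples.std(ddof=1) / np.sqrt(n_photons)
    return mean, se
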