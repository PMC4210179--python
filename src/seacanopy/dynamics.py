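"""Mass-spring flexing of plant skeletons under oscillatory wave forcing.

Plants are point-mass chains (stem, branches, leaf midribs) treated as
neutrally buoyant cloth-like structures.  The integrator is semi-implicit
(symplectic) Euler with Gauss-Seidel distance-constraint relaxation over the
structural edges plus grandparent-child bending constraints; anchored base
nodes are pinned.  Forcing is a horizontal body force F(t) = A sin(2 pi t /
period) on every point mass with linear drag -c v — the simplest model that
produces the characteristic forward-and-backward canopy sway.  With zero
amplitude the upright rest pose is an exact fixed point.

Snapshots extracted at evenly spaced phases of the final forcing period are
re-skinned into canopy scenes: each mesh vertex follows its skeleton edge by
the minimal rotation taking the rest edge direction to the current one, so
leaf segments move rigidly and leaf area is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .morphology import (CanopyScene, PlacedPlant, PlantMesh, build_scene)


@dataclass(frozen=True)
class WaveForcing:
    """Oscillatory horizontal body forcing applied to every point mass."""

    amplitude: float = 0.0        # N per point mass
    period: float = 3.0           # s
    direction: tuple[float, float] = (1.0, 0.0)
    drag_coefficient: float = 0.08  # N s m^-1 per point mass
    mode: str = "low"

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.mode not in ("low", "high"):
            raise ValueError("mode must be 'low' or 'high'")
        if self.mode == "low" and self.amplitude != 0:
            raise ValueError("low wave mode means zero amplitude")
        n = math.hypot(*self.direction)
        if n == 0:
            raise ValueError("direction must be a nonzero horizontal vector")
        object.__setattr__(self, "direction",
                           (self.direction[0] / n, self.direction[1] / n))

    @classmethod
    def high(cls, amplitude: float = 1.2e-2, period: float = 3.0) -> "WaveForcing":
        """Default 'high' wave action: vigorous forward/backward sway."""
        return cls(amplitude=amplitude, period=period, mode="high")

    @classmethod
    def low(cls) -> "WaveForcing":
        return cls(amplitude=0.0, mode="low")


@dataclass
class Trajectory:
    """Stored skeleton positions through the simulated interval."""

    times: np.ndarray             # (T,)
    positions: np.ndarray         # (T, n_nodes, 3) all plants concatenated
    node_slices: list[slice]
    scene: CanopyScene
    forcing: WaveForcing
    spin_up: float                # s of discarded transient

    @property
    def period(self) -> float:
        return self.forcing.period

    def kinetic_energy(self) -> np.ndarray:
        """Per-recorded-frame kinetic energy (J) from finite differences."""
        if self.times.size < 2:
            return np.zeros(self.times.size)
        dt = np.gradient(self.times)
        v = np.gradient(self.positions, axis=0) / dt[:, None, None]
        masses = np.concatenate([pp.mesh.skeleton.masses
                                 for pp in self.scene.plants])
        return 0.5 * (masses[None, :] * (v ** 2).sum(axis=2)).sum(axis=1)

    def max_edge_strain(self) -> float:
        """Maximum relative edge-length deviation over the trajectory."""
        worst = 0.0
        for pp, sl in zip(self.scene.plants, self.node_slices):
            sk = pp.mesh.skeleton
            p = self.positions[:, sl, :]
            d = p[:, sk.edges[:, 1], :] - p[:, sk.edges[:, 0], :]
            ln = np.linalg.norm(d, axis=2)
            worst = max(worst, float(np.abs(ln / sk.rest_lengths - 1.0).max()))
        return worst


@njit(cache=True)
def _integrate(x, inv_mass, edges, rest, bends, bend_rest, anchored,
               fdir, amp, period, drag, mass, dt, n_steps,
               record_idx, out):
    n = x.shape[0]
    v = np.zeros((n, 3))
    rec = 0
    for step in range(n_steps):
        t = step * dt
        f = amp * math.sin(2.0 * math.pi * t / period)
        fx = f * fdir[0]
        fy = f * fdir[1]
        # semi-implicit Euler
        for i in range(n):
            if anchored[i]:
                continue
            ax = (fx - drag * v[i, 0]) / mass
            ay = (fy - drag * v[i, 1]) / mass
            az = (-drag * v[i, 2]) / mass
            v[i, 0] += ax * dt
            v[i, 1] += ay * dt
            v[i, 2] += az * dt
        x_prev = x.copy()
        for i in range(n):
            if not anchored[i]:
                x[i, 0] += v[i, 0] * dt
                x[i, 1] += v[i, 1] * dt
                x[i, 2] += v[i, 2] * dt
        # Gauss-Seidel constraint relaxation
        for _ in range(8):
            for e in range(edges.shape[0]):
                a = edges[e, 0]
                b = edges[e, 1]
                dx = x[b, 0] - x[a, 0]
                dy = x[b, 1] - x[a, 1]
                dz = x[b, 2] - x[a, 2]
                ln = math.sqrt(dx * dx + dy * dy + dz * dz)
                if ln < 1e-12:
                    continue
                wa = 0.0 if anchored[a] else inv_mass[a]
                wb = 0.0 if anchored[b] else inv_mass[b]
                ws = wa + wb
                if ws == 0.0:
                    continue
                corr = (ln - rest[e]) / ln / ws
                x[a, 0] += wa * corr * dx
                x[a, 1] += wa * corr * dy
                x[a, 2] += wa * corr * dz
                x[b, 0] -= wb * corr * dx
                x[b, 1] -= wb * corr * dy
                x[b, 2] -= wb * corr * dz
            for e in range(bends.shape[0]):
                a = bends[e, 0]
                b = bends[e, 1]
                dx = x[b, 0] - x[a, 0]
                dy = x[b, 1] - x[a, 1]
                dz = x[b, 2] - x[a, 2]
                ln = math.sqrt(dx * dx + dy * dy + dz * dz)
                if ln < 1e-12:
                    continue
                wa = 0.0 if anchored[a] else inv_mass[a]
                wb = 0.0 if anchored[b] else inv_mass[b]
                ws = wa + wb
                if ws == 0.0:
                    continue
                # bending stiffness 0.5: soft angular springs at joints
                corr = 0.5 * (ln - bend_rest[e]) / ln / ws
                x[a, 0] += wa * corr * dx
                x[a, 1] += wa * corr * dy
                x[a, 2] += wa * corr * dz
                x[b, 0] -= wb * corr * dx
                x[b, 1] -= wb * corr * dy
                x[b, 2] -= wb * corr * dz
        # velocity correction from projected positions
        for i in range(n):
            if not anchored[i]:
                v[i, 0] = (x[i, 0] - x_prev[i, 0]) / dt
                v[i, 1] = (x[i, 1] - x_prev[i, 1]) / dt
                v[i, 2] = (x[i, 2] - x_prev[i, 2]) / dt
        if rec < record_idx.shape[0] and step == record_idx[rec]:
            out[rec] = x
            rec += 1
    return rec


def simulate_motion(
    scene: CanopyScene,
    forcing: WaveForcing,
    duration: float | None = None,
    dt: float = 2e-3,
    spin_up_periods: float = 2.0,
    n_record: int = 64,
) -> Trajectory:
    """Simulate plant skeleton motion; deterministic for fixed inputs.

    ``duration`` defaults to spin-up plus one forcing period; the recorded
    samples cover the final period.  Raises on numerical blow-up with the
    first bad step in the message.
    """
    if not scene.plants:
        raise ValueError("scene has no plants to simulate")
    spin_up = spin_up_periods * forcing.period
    if duration is None:
        duration = spin_up + forcing.period
    if duration < spin_up + forcing.period:
        raise ValueError("duration must cover spin-up plus one period")

    nodes = []
    inv_mass = []
    edges = []
    rests = []
    bends = []
    bend_rests = []
    anchored = []
    slices = []
    off = 0
    for pp in scene.plants:
        sk = pp.mesh.skeleton
        n = sk.nodes.shape[0]
        nodes.append(sk.nodes.copy())
        inv_mass.append(1.0 / sk.masses)
        edges.append(sk.edges + off)
        rests.append(sk.rest_lengths)
        if sk.bend_pairs.size:
            bends.append(sk.bend_pairs + off)
            bend_rests.append(sk.bend_rest)
        anchored.append(sk.anchored)
        slices.append(slice(off, off + n))
        off += n

    x = np.concatenate(nodes).astype(np.float64)
    inv_mass = np.concatenate(inv_mass)
    edges_arr = np.concatenate(edges).astype(np.int64)
    rest_arr = np.concatenate(rests)
    bends_arr = (np.concatenate(bends).astype(np.int64)
                 if bends else np.zeros((0, 2), dtype=np.int64))
    bend_rest_arr = np.concatenate(bend_rests) if bend_rests else np.zeros(0)
    anch = np.concatenate(anchored)

    n_steps = int(round(duration / dt))
    first_rec_t = duration - forcing.period
    rec_times = first_rec_t + np.arange(n_record) / n_record * forcing.period
    record_idx = np.clip(np.round(rec_times / dt).astype(np.int64), 0, n_steps - 1)
    record_idx = np.unique(record_idx)
    out = np.zeros((record_idx.size, x.shape[0], 3))

    mass = float(scene.plants[0].mesh.skeleton.masses[0])
    fdir = np.array(forcing.direction)
    _integrate(x, inv_mass, edges_arr, rest_arr, bends_arr, bend_rest_arr,
               anch, fdir, forcing.amplitude, forcing.period,
               forcing.drag_coefficient, mass, dt, n_steps, record_idx, out)

    if not np.all(np.isfinite(out)):
        bad = int(np.argwhere(~np.isfinite(out).all(axis=(1, 2)))[0, 0])
        raise FloatingPointError(
            f"dynamics blow-up: non-finite positions at stored step {bad}")

    return Trajectory(
        times=record_idx * dt,
        positions=out,
        node_slices=slices,
        scene=scene,
        forcing=forcing,
        spin_up=spin_up,
    )


def _rotation_between(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u to unit vector w."""
    c = float(np.dot(u, w))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    axis = np.cross(u, w)
    s = np.linalg.norm(axis)
    if s < 1e-12:  # antiparallel: rotate pi about any perpendicular
        p = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, p)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis /= s
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def reskin_plant(mesh: PlantMesh, new_nodes: np.ndarray) -> PlantMesh:
    """Rebuild mesh vertices from deformed skeleton node positions."""
    sk = mesh.skeleton
    n_edges = sk.edges.shape[0]
    rots = np.empty((n_edges, 3, 3))
    for e in range(n_edges):
        a, b = sk.edges[e]
        u = sk.nodes[b] - sk.nodes[a]
        w = new_nodes[b] - new_nodes[a]
        un, wn = np.linalg.norm(u), np.linalg.norm(w)
        rots[e] = _rotation_between(u / un, w / wn) if un > 0 and wn > 0 else np.eye(3)
    anchors = new_nodes[sk.edges[mesh.bind_edge, 0]]
    verts = anchors + np.einsum("vij,vj->vi", rots[mesh.bind_edge], mesh.bind_offset)
    new_sk = dataclasses_replace_skeleton(sk, new_nodes)
    return PlantMesh(vertices=verts, faces=mesh.faces, role=mesh.role,
                     skeleton=new_sk, bind_edge=mesh.bind_edge,
                     bind_offset=mesh.bind_offset)


def dataclasses_replace_skeleton(sk, new_nodes):
    from .morphology import Skeleton
    return Skeleton(nodes=np.asarray(new_nodes), masses=sk.masses,
                    edges=sk.edges, rest_lengths=sk.rest_lengths,
                    bend_pairs=sk.bend_pairs, bend_rest=sk.bend_rest,
                    anchored=sk.anchored)


def extract_snapshots(traj: Trajectory, n: int) -> list[CanopyScene]:
    """``n`` re-skinned scenes at evenly spaced phases of the final period."""
    if n < 1:
        raise ValueError("need at least one snapshot")
    phases = traj.times[0] + np.arange(n) / n * traj.period
    scenes = []
    for ph in phases:
        idx = int(np.argmin(np.abs(traj.times - ph)))
        placed = []
        for pp, sl in zip(traj.scene.plants, traj.node_slices):
            new_nodes = traj.positions[idx, sl, :]
            placed.append(PlacedPlant(mesh=reskin_plant(pp.mesh, new_nodes),
                                      position=pp.position))
        scenes.append(build_scene(placed, (traj.scene.tile_x, traj.scene.tile_y)))
    return scenes
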