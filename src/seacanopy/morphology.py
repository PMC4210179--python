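"""Parametric *Amphibolis*-like plant meshes and periodic-tile canopies.

Plants are built as a vertical stem of internodes carrying branches at the
upper nodes, each branch (and the stem tip) ending in a cluster of strap
leaves.  Leaves are zero-thickness two-sided rectangular strips triangulated
along a midrib; stems and branches are thin ribbons that act as optical
occluders but do not count toward LAI.  Every mesh carries a point-mass
skeleton (stem, branches, leaf midribs) used by the dynamics module, and
every mesh vertex is bound to a skeleton edge so flexed skeletons can be
re-skinned.

Scenes are a 20 cm x 20 cm substrate tile that is treated as periodic in x
and y by the optical solver, so a single tile represents a horizontally
uniform canopy of the same LAI.  LAI is one-sided leaf area per substrate
area (stems excluded).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np

ROLE_SUBSTRATE = 0
ROLE_STEM = 1
ROLE_LEAF = 2
ROLE_NAMES = {ROLE_SUBSTRATE: "substrate", ROLE_STEM: "stem", ROLE_LEAF: "leaf"}

Dist = float | tuple[float, float]


def _sample(d: Dist, rng: np.random.Generator) -> float:
    if isinstance(d, (tuple, list)):
        lo, hi = float(d[0]), float(d[1])
        return float(rng.uniform(lo, hi))
    return float(d)


def _dist_bounds(d: Dist) -> tuple[float, float]:
    if isinstance(d, (tuple, list)):
        return float(d[0]), float(d[1])
    return float(d), float(d)


@dataclass(frozen=True)
class PlantParams:
    """Morphometric parameter distributions for one plant archetype.

    Lengths in metres, angles in degrees from horizontal.  Each distribution
    is either a scalar or a (low, high) uniform range.
    """

    stem_height: Dist = (0.35, 0.55)
    n_internodes: int = 8
    branches_per_node: Dist = (1.0, 3.0)
    branch_length: Dist = (0.04, 0.10)
    leaves_per_cluster: Dist = (2.0, 3.0)
    leaf_length: Dist = (0.04, 0.09)
    leaf_width: Dist = (0.006, 0.010)
    leaf_inclination: Dist = (67.0, 86.0)
    stem_diameter: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stem_height", "branch_length", "leaf_length", "leaf_width"):
            lo, hi = _dist_bounds(getattr(self, name))
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name}: must be positive and finite")
        for name in ("branches_per_node", "leaves_per_cluster"):
            lo, hi = _dist_bounds(getattr(self, name))
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0 or hi < lo:
                raise ValueError(f"invalid {name}: counts must be >= 0")
        lo, hi = _dist_bounds(self.leaf_inclination)
        if not (0.0 <= lo <= hi <= 90.0):
            raise ValueError("invalid leaf_inclination: must lie in [0, 90] deg")
        if not np.isfinite(self.stem_diameter) or self.stem_diameter <= 0:
            raise ValueError("invalid stem_diameter: must be positive and finite")
        if self.n_internodes < 1:
            raise ValueError("invalid n_internodes: must be >= 1")


@dataclass
class Skeleton:
    """Point-mass graph driving the dynamics module."""

    nodes: np.ndarray          # (n, 3) rest positions, m
    masses: np.ndarray         # (n,) kg
    edges: np.ndarray          # (e, 2) int
    rest_lengths: np.ndarray   # (e,)
    bend_pairs: np.ndarray     # (b, 2) int, grandparent-child distance constraints
    bend_rest: np.ndarray      # (b,)
    anchored: np.ndarray       # (n,) bool


@dataclass
class PlantMesh:
    """Triangle mesh of one plant with its skeleton and skinning binds."""

    vertices: np.ndarray       # (v, 3)
    faces: np.ndarray          # (f, 3) int
    role: np.ndarray           # (f,) int8
    skeleton: Skeleton
    bind_edge: np.ndarray      # (v,) int, skeleton edge each vertex follows
    bind_offset: np.ndarray    # (v, 3) rest offset from the edge's first node

    def facet_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    @property
    def leaf_area(self) -> float:
        return float(self.facet_areas()[self.role == ROLE_LEAF].sum())

    def scale_leaf_width(self, factor: float) -> None:
        """Uniformly scale leaf strip widths (area scales by the same factor)."""
        leaf_verts = np.unique(self.faces[self.role == ROLE_LEAF])
        for vi in leaf_verts:
            e = self.bind_edge[vi]
            a, b = self.skeleton.edges[e]
            u = self.skeleton.nodes[b] - self.skeleton.nodes[a]
            u = u / np.linalg.norm(u)
            off = self.bind_offset[vi]
            along = np.dot(off, u) * u
            perp = off - along
            self.bind_offset[vi] = along + factor * perp
            self.vertices[vi] = self.skeleton.nodes[a] + self.bind_offset[vi]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _strip_perp(direction: np.ndarray) -> np.ndarray:
    z = np.array([0.0, 0.0, 1.0])
    p = np.cross(direction, z)
    n = np.linalg.norm(p)
    if n < 1e-8:
        p = np.cross(direction, np.array([1.0, 0.0, 0.0]))
        n = np.linalg.norm(p)
    return p / n


class _MeshBuilder:
    def __init__(self) -> None:
        self.verts: list[np.ndarray] = []
        self.faces: list[tuple[int, int, int]] = []
        self.role: list[int] = []
        self.bind_edge: list[int] = []
        self.bind_offset: list[np.ndarray] = []

    def add_strip_segment(
        self,
        n0: np.ndarray,
        n1: np.ndarray,
        half_width: float,
        role: int,
        edge_id: int,
        perp: np.ndarray,
    ) -> None:
        base = len(self.verts)
        quad = [n0 - half_width * perp, n0 + half_width * perp,
                n1 - half_width * perp, n1 + half_width * perp]
        for q in quad:
            self.verts.append(q)
            self.bind_edge.append(edge_id)
            self.bind_offset.append(q - n0)
        self.faces.append((base, base + 2, base + 1))
        self.faces.append((base + 1, base + 2, base + 3))
        self.role.extend([role, role])


def generate_plant(params: PlantParams) -> PlantMesh:
    """Generate one plant mesh deterministically from its parameter set."""
    rng = np.random.default_rng(params.seed)

    nodes: list[np.ndarray] = []
    parent: list[int] = []

    def add_node(p: np.ndarray, par: int) -> int:
        nodes.append(np.asarray(p, dtype=float))
        parent.append(par)
        return len(nodes) - 1

    h = _sample(params.stem_height, rng)
    n_int = params.n_internodes
    seg = np.full(n_int, h / n_int)
    seg *= 1.0 + rng.uniform(-0.1, 0.1, n_int)
    seg *= h / seg.sum()
    z = np.concatenate([[0.0], np.cumsum(seg)])

    stem_ids = [add_node(np.array([0.0, 0.0, zz]), -1 if k == 0 else k - 1)
                for k, zz in enumerate(z)]

    cluster_nodes: list[tuple[int, float]] = []  # (node id, preferred azimuth)
    # branches cluster on the upper stem: terminal leaf tufts over bare stem
    for k in range(1, n_int + 1):
        if z[k] < 0.6 * h:
            continue
        nb = int(round(_sample(params.branches_per_node, rng)))
        for _ in range(nb):
            az = rng.uniform(0.0, 2.0 * math.pi)
            el = math.radians(rng.uniform(15.0, 45.0))  # from vertical
            d = np.array([math.sin(el) * math.cos(az),
                          math.sin(el) * math.sin(az),
                          math.cos(el)])
            lb = _sample(params.branch_length, rng)
            b1 = add_node(nodes[stem_ids[k]] + d * lb / 2.0, stem_ids[k])
            b2 = add_node(nodes[stem_ids[k]] + d * lb, b1)
            cluster_nodes.append((b2, az))
    cluster_nodes.append((stem_ids[-1], rng.uniform(0.0, 2.0 * math.pi)))

    builder = _MeshBuilder()
    edges: list[tuple[int, int]] = []

    def add_edge(a: int, b: int) -> int:
        edges.append((a, b))
        return len(edges) - 1

    # stem + branch skeleton edges with ribbon facets
    ribbon_perp_az = rng.uniform(0.0, 2.0 * math.pi)
    for i, par in enumerate(parent):
        if par < 0:
            continue
        eid = add_edge(par, i)
        d = _unit(nodes[i] - nodes[par])
        perp = _strip_perp(d)
        c, s = math.cos(ribbon_perp_az), math.sin(ribbon_perp_az)
        axis = d
        # rotate perp about the edge axis for a stable but varied ribbon facing
        perp = (perp * c + np.cross(axis, perp) * s
                + axis * np.dot(axis, perp) * (1 - c))
        perp = _unit(perp)
        # branches are slimmer than the main stem
        half_w = params.stem_diameter / (2.0 if i in stem_ids else 3.0)
        builder.add_strip_segment(nodes[par], nodes[i], half_w,
                                  ROLE_STEM, eid, perp)

    # leaves
    n_midrib = 3
    for cn, base_az in cluster_nodes:
        nl = int(round(_sample(params.leaves_per_cluster, rng)))
        for _ in range(nl):
            ll = _sample(params.leaf_length, rng)
            lw = _sample(params.leaf_width, rng)
            inc = math.radians(_sample(params.leaf_inclination, rng))
            az = base_az + math.radians(rng.uniform(-45.0, 45.0))
            d = np.array([math.cos(inc) * math.cos(az),
                          math.cos(inc) * math.sin(az),
                          math.sin(inc)])
            perp = _strip_perp(d)
            prev = cn
            for k in range(n_midrib):
                p = nodes[cn] + d * ll * (k + 1) / n_midrib
                nid = add_node(p, prev)
                eid = add_edge(prev, nid)
                builder.add_strip_segment(nodes[prev], p, lw / 2.0,
                                          ROLE_LEAF, eid, perp)
                prev = nid

    node_arr = np.asarray(nodes)
    edge_arr = np.asarray(edges, dtype=np.int64)
    rest = np.linalg.norm(node_arr[edge_arr[:, 1]] - node_arr[edge_arr[:, 0]], axis=1)

    bend_pairs = []
    for i, par in enumerate(parent):
        if par >= 0 and parent[par] >= 0:
            bend_pairs.append((parent[par], i))
    bend_arr = (np.asarray(bend_pairs, dtype=np.int64)
                if bend_pairs else np.zeros((0, 2), dtype=np.int64))
    bend_rest = (np.linalg.norm(node_arr[bend_arr[:, 1]] - node_arr[bend_arr[:, 0]], axis=1)
                 if len(bend_pairs) else np.zeros(0))

    anchored = np.zeros(len(nodes), dtype=bool)
    anchored[stem_ids[0]] = True
    anchored[stem_ids[1]] = True

    skel = Skeleton(
        nodes=node_arr,
        masses=np.full(len(nodes), 1e-3),
        edges=edge_arr,
        rest_lengths=rest,
        bend_pairs=bend_arr,
        bend_rest=bend_rest,
        anchored=anchored,
    )
    return PlantMesh(
        vertices=np.asarray(builder.verts),
        faces=np.asarray(builder.faces, dtype=np.int64),
        role=np.asarray(builder.role, dtype=np.int8),
        skeleton=skel,
        bind_edge=np.asarray(builder.bind_edge, dtype=np.int64),
        bind_offset=np.asarray(builder.bind_offset),
    )


def prune_trailing_leaves(mesh: PlantMesh, area_to_remove: float) -> PlantMesh:
    """Remove whole leaves from the end of a plant until ~``area_to_remove``
    leaf area is gone (leaves are appended last during generation, in groups
    of facets per leaf).  Unbound vertices are left in place; only facet
    arrays shrink."""
    if area_to_remove <= 0:
        return mesh
    areas = mesh.facet_areas()
    leaf_idx = np.flatnonzero(mesh.role == ROLE_LEAF)
    keep = np.ones(mesh.faces.shape[0], dtype=bool)
    removed = 0.0
    # drop trailing leaf facets in segment pairs until close to the target
    for fi in leaf_idx[::-1]:
        if removed + areas[fi] > area_to_remove + 1e-12:
            # stop once the next removal would overshoot the requested area
            break
        keep[fi] = False
        removed += areas[fi]
    return PlantMesh(
        vertices=mesh.vertices,
        faces=mesh.faces[keep],
        role=mesh.role[keep],
        skeleton=mesh.skeleton,
        bind_edge=mesh.bind_edge,
        bind_offset=mesh.bind_offset,
    )


@dataclass
class PlacedPlant:
    mesh: PlantMesh
    position: np.ndarray  # (2,) stem base in tile coordinates


@dataclass
class CanopyScene:
    """Triangle-facet scene on a periodic substrate tile."""

    tile_x: float
    tile_y: float
    vertices: np.ndarray
    faces: np.ndarray
    role: np.ndarray          # (f,) int8
    material: np.ndarray      # (f,) int16 (defaults: role id)
    plant_id: np.ndarray      # (f,) int32, -1 for substrate
    plants: list[PlacedPlant] = field(default_factory=list)
    max_leaf_facet_area: float | None = None

    def facet_areas(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    def facet_normals(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def leaf_area(self) -> float:
        return float(self.facet_areas()[self.role == ROLE_LEAF].sum())

    @property
    def lai(self) -> float:
        return self.leaf_area / (self.tile_x * self.tile_y)

    @property
    def z_top(self) -> float:
        return float(self.vertices[:, 2].max()) + 1e-3

    @property
    def is_facetized(self) -> bool:
        return self.max_leaf_facet_area is not None

    @property
    def n_facets(self) -> int:
        return self.faces.shape[0]


def _substrate_arrays(tile_x: float, tile_y: float):
    v = np.array([[0, 0, 0], [tile_x, 0, 0], [tile_x, tile_y, 0], [0, tile_y, 0]],
                 dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3]], dtype=np.int64)
    return v, f


def build_scene(
    placed: list[PlacedPlant], tile: tuple[float, float] = (0.2, 0.2)
) -> CanopyScene:
    """Assemble placed plants plus a substrate quad into one scene."""
    tx, ty = tile
    if tx <= 0 or ty <= 0:
        raise ValueError("tile dimensions must be positive")
    verts = []
    faces = []
    role = []
    plant_ids = []
    sv, sf = _substrate_arrays(tx, ty)
    verts.append(sv)
    faces.append(sf)
    role.append(np.full(2, ROLE_SUBSTRATE, dtype=np.int8))
    plant_ids.append(np.full(2, -1, dtype=np.int32))
    off = sv.shape[0]
    for pid, pp in enumerate(placed):
        x, y = pp.position
        if not (0.0 <= x < tx and 0.0 <= y < ty):
            raise ValueError("plant stem base outside the half-open tile")
        v = pp.mesh.vertices + np.array([x, y, 0.0])
        verts.append(v)
        faces.append(pp.mesh.faces + off)
        role.append(pp.mesh.role)
        plant_ids.append(np.full(pp.mesh.faces.shape[0], pid, dtype=np.int32))
        off += v.shape[0]
    role_arr = np.concatenate(role)
    return CanopyScene(
        tile_x=tx,
        tile_y=ty,
        vertices=np.concatenate(verts),
        faces=np.concatenate(faces),
        role=role_arr,
        material=role_arr.astype(np.int16),
        plant_id=np.concatenate(plant_ids),
        plants=list(placed),
    )


def compute_lai(scene: CanopyScene) -> float:
    """One-sided leaf facet area per substrate tile area."""
    return scene.lai


def _place_positions(
    n: int, tile: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Seeded uniform placement with a minimum periodic stem spacing."""
    tx, ty = tile
    spacing = 0.4 * math.sqrt(tx * ty / max(n, 1))
    pts: list[np.ndarray] = []
    while len(pts) < n:
        placed_this_round = False
        for _ in range(200):
            p = rng.uniform([0, 0], [tx, ty])
            ok = True
            for q in pts:
                d = np.abs(p - q)
                d = np.minimum(d, [tx, ty] - d)  # periodic distance
                if np.hypot(*d) < spacing:
                    ok = False
                    break
            if ok:
                pts.append(p)
                placed_this_round = True
                break
        if not placed_this_round:
            spacing *= 0.8
    return np.asarray(pts)


def assemble_canopy(
    plant_pool: list[PlantParams],
    tile: tuple[float, float] = (0.2, 0.2),
    target_lai: float = 0.0,
    seed: int = 0,
) -> CanopyScene:
    """Assemble a canopy of target LAI by varying plant choice and count.

    Plants are drawn from the pool with derived seeds until the summed leaf
    area brackets the target; the final residual is absorbed by a uniform
    leaf-width scaling of at most 5%.  The returned scene's LAI is within
    +/-2% of the target.
    """
    if target_lai < 0:
        raise ValueError("target_lai must be >= 0")
    tx, ty = tile
    rng = np.random.default_rng(seed)
    if target_lai == 0.0:
        return build_scene([], tile)
    if not plant_pool:
        raise ValueError("cannot reach positive LAI with an empty plant pool")

    target_area = target_lai * tx * ty

    def draw() -> PlantMesh:
        params = plant_pool[int(rng.integers(len(plant_pool)))]
        return generate_plant(replace(params, seed=int(rng.integers(2**31))))

    meshes: list[PlantMesh] = []
    area = 0.0
    for _ in range(2000):
        if area >= target_area:
            break
        m = draw()
        if m.leaf_area <= 0:
            if all(mm.leaf_area <= 0 for mm in meshes) and len(meshes) > 3 * len(plant_pool):
                raise ValueError("plant pool yields no leaf area; target LAI unreachable")
            meshes.append(m)
            continue
        meshes.append(m)
        area += m.leaf_area
    if area < target_area * 0.95:
        raise ValueError("plant pool cannot reach target LAI")

    f = target_area / area
    if f < 0.95:
        # overshoot too large: prune trailing leaves off the last plant
        last = meshes[-1]
        excess = area - target_area
        pruned = prune_trailing_leaves(last, excess)
        area += pruned.leaf_area - last.leaf_area
        meshes[-1] = pruned
        f = target_area / area

    for m in meshes:
        if m.leaf_area > 0:
            m.scale_leaf_width(f)

    n = len(meshes)
    pos = _place_positions(n, tile, rng)
    placed = [PlacedPlant(mesh=m, position=p) for m, p in zip(meshes, pos)]
    scene = build_scene(placed, tile)
    if target_lai > 0 and abs(scene.lai - target_lai) / target_lai > 0.02:
        raise ValueError(
            f"assembled LAI {scene.lai:.4f} misses target {target_lai} by >2%"
        )
    return scene


def facetize(scene: CanopyScene, max_facet_area: float = 5e-5) -> CanopyScene:
    """Refine facets until every leaf facet area is <= ``max_facet_area``.

    Stems and substrate are refined to a coarser bound (8x the leaf bound);
    longest-edge bisection preserves total area per role exactly.
    """
    if max_facet_area <= 0:
        raise ValueError("max_facet_area must be positive")
    coarse = 8.0 * max_facet_area
    v = scene.vertices
    out_v: list[np.ndarray] = []
    out_f: list[tuple[int, int, int]] = []
    out_role: list[int] = []
    out_mat: list[int] = []
    out_pid: list[int] = []

    for fi in range(scene.faces.shape[0]):
        tri = v[scene.faces[fi]]
        limit = max_facet_area if scene.role[fi] == ROLE_LEAF else coarse
        stack = [tri]
        while stack:
            t = stack.pop()
            e1, e2 = t[1] - t[0], t[2] - t[0]
            area = 0.5 * np.linalg.norm(np.cross(e1, e2))
            if area <= limit:
                base = len(out_v)
                out_v.extend(t)
                out_f.append((base, base + 1, base + 2))
                out_role.append(int(scene.role[fi]))
                out_mat.append(int(scene.material[fi]))
                out_pid.append(int(scene.plant_id[fi]))
                continue
            # split the longest edge at its midpoint
            lens = [np.linalg.norm(t[1] - t[0]),
                    np.linalg.norm(t[2] - t[1]),
                    np.linalg.norm(t[0] - t[2])]
            k = int(np.argmax(lens))
            a, b, c = t[k], t[(k + 1) % 3], t[(k + 2) % 3]
            mid = 0.5 * (a + b)
            stack.append(np.array([a, mid, c]))
            stack.append(np.array([mid, b, c]))

    return CanopyScene(
        tile_x=scene.tile_x,
        tile_y=scene.tile_y,
        vertices=np.asarray(out_v),
        faces=np.asarray(out_f, dtype=np.int64),
        role=np.asarray(out_role, dtype=np.int8),
        material=np.asarray(out_mat, dtype=np.int16),
        plant_id=np.asarray(out_pid, dtype=np.int32),
        plants=scene.plants,
        max_leaf_facet_area=max_facet_area,
    )


def merge_scenes(a: CanopyScene, b: CanopyScene) -> CanopyScene:
    """Union of the plants of two scenes on the same tile (one substrate)."""
    if (a.tile_x, a.tile_y) != (b.tile_x, b.tile_y):
        raise ValueError("scenes must share the same tile")
    return build_scene(list(a.plants) + list(b.plants), (a.tile_x, a.tile_y))
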