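"""Uniform point sets and Voronoi tessellations on S^2 and S^3.

The direction part of the translation grid lives on the 2-sphere and is
generated by iterative midpoint subdivision of an inscribed icosahedron
(12, 42, 162, ... points).  The orientation grid lives on the quaternion
3-sphere and is generated by subdividing an inscribed 4-cube (tesseract;
16, 80, 544, ... points before removing antipodal duplicates).  Arbitrary
sizes are reached by pruning the next-larger grid.

Voronoi tessellations use the angular (arc-length) metric.  On S^3 the
tessellation is built on the antipodally doubled set {+q, -q} so that the
cells of canonical quaternions are not artificially cut at the equator of
the upper half-sphere.  Borders between S^3 cells are spherical polygons on
a great 2-sphere; their areas follow from the spherical-excess formula
after an SVD rotation that annihilates the fourth coordinate.  Cell volumes
on S^3 are estimated by Monte-Carlo assignment of uniform samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, SphericalVoronoi

from gridbind.rotations import canonicalize, random_unit_quaternions

__all__ = [
    "SphereGrid",
    "SphereVoronoi",
    "HypersphereGrid",
    "HypersphereVoronoi",
    "icosahedral_grid",
    "tesseract_grid",
    "prune_to_size",
    "spherical_voronoi",
    "spherical_polygon_area",
    "polygon_interior_angles",
    "hypersphere_voronoi",
    "hyper_border_area",
    "hyper_cell_volume",
]

_DEDUP_TOL = 1e-10

# ---------------------------------------------------------------------------
# grid containers


@dataclass
class SphereGrid:
    """Point set on the unit 2-sphere with per-point subdivision level."""

    points: np.ndarray  # (n, 3) unit vectors
    levels: np.ndarray  # (n,) generation at which each point appeared

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.levels = np.asarray(self.levels, dtype=int)
        norms = np.linalg.norm(self.points, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("sphere grid points must be unit vectors")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class HypersphereGrid:
    """Canonical unit quaternions on the upper half of S^3.

    ``doubled`` stacks the canonical set with its antipodes; the Voronoi
    tessellation is always built on that doubled set.
    """

    quaternions: np.ndarray  # (N_o, 4) canonical representatives
    levels: np.ndarray
    pre_truncation: np.ndarray | None = None  # full +/- set before truncation

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        self.levels = np.asarray(self.levels, dtype=int)

    def __len__(self) -> int:
        return len(self.quaternions)

    @property
    def doubled(self) -> np.ndarray:
        return np.vstack([self.quaternions, -self.quaternions])


@dataclass
class SphereVoronoi:
    """Spherical Voronoi tessellation of a :class:`SphereGrid` at radius R."""

    grid: SphereGrid
    radius: float
    vertices: np.ndarray  # (m, 3) on the unit sphere
    regions: list  # per cell, ordered loop of vertex indices
    areas: np.ndarray  # (n,) cell areas at radius R
    adjacency: list  # [(i, j), ...] with i < j
    shared_vertices: dict  # (i, j) -> vertex index array

    def neighbors(self, i: int) -> list:
        out = []
        for a, b in self.adjacency:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


@dataclass
class HypersphereVoronoi:
    """Voronoi tessellation of S^3 on the doubled quaternion set.

    Adjacency, border areas and volumes are reported between *canonical*
    cells (rotations): contributions of the two antipodal copies are
    accumulated, so a border area is the full interface through which one
    rotation cell exchanges with another.
    """

    grid: HypersphereGrid
    vertices: np.ndarray  # (m, 4) Voronoi vertices, unit 4-vectors
    regions: list  # per doubled point, vertex index list (unordered)
    adjacency: list  # canonical pairs [(i, j), ...], i < j
    border_areas: dict  # (i, j) -> area on the unit 3-sphere
    volumes: np.ndarray = field(default=None)  # (N_o,) per canonical cell
    volumes_doubled: np.ndarray = field(default=None)  # (2 N_o,)


# ---------------------------------------------------------------------------
# S^2: icosahedral subdivision


def _icosahedron_vertices() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts += [(0, a, b), (a, b, 0), (b, 0, a)]
    verts = np.array(verts, dtype=float)
    return verts / np.linalg.norm(verts, axis=1, keepdims=True)


def _dedup_rows(points: np.ndarray, tol: float = _DEDUP_TOL) -> np.ndarray:
    """Indices of unique rows (first occurrence wins), tolerance on coords."""
    keep: list[int] = []
    for i, p in enumerate(points):
        if not any(np.linalg.norm(p - points[k]) < tol for k in keep):
            keep.append(i)
    return np.array(keep, dtype=int)


def icosahedral_grid(level: int) -> SphereGrid:
    """Icosahedral geodesic grid on S^2.

    Level 0 is the 12 vertices of an icosahedron inscribed in the unit
    sphere.  Each further level inserts the midpoints of all edges of the
    current triangulation and projects them back onto the sphere, so the
    sizes run 12, 42, 162, ...
    """
    if level < 0:
        raise ValueError("subdivision level must be non-negative")
    if level > 6:
        raise ValueError("subdivision level capped at 6")
    points = _icosahedron_vertices()
    levels = np.zeros(len(points), dtype=int)
    for lev in range(1, level + 1):
        hull = ConvexHull(points)
        edges = set()
        for simplex in hull.simplices:
            for a, b in ((0, 1), (1, 2), (0, 2)):
                i, j = sorted((simplex[a], simplex[b]))
                edges.add((i, j))
        mids = np.array([points[i] + points[j] for i, j in sorted(edges)])
        mids /= np.linalg.norm(mids, axis=1, keepdims=True)
        points = np.vstack([points, mids])
        levels = np.concatenate([levels, np.full(len(mids), lev)])
        keep = _dedup_rows(points)
        points, levels = points[keep], levels[keep]
    return SphereGrid(points, levels)


# ---------------------------------------------------------------------------
# S^3: tesseract subdivision


def _tesseract_lattice(level: int) -> np.ndarray:
    """Boundary lattice points of the 4-cube [-1/2, 1/2]^4 at a given level."""
    axis = np.linspace(-0.5, 0.5, 2**level + 1)
    pts = np.array(np.meshgrid(axis, axis, axis, axis, indexing="ij"))
    pts = pts.reshape(4, -1).T
    on_boundary = np.max(np.abs(pts), axis=1) > 0.5 - 1e-12
    return pts[on_boundary]


def tesseract_grid(level: int) -> HypersphereGrid:
    """Quaternion grid on S^3 from iterative subdivision of a tesseract.

    Level 0 projects the 16 vertices (+-1/2, +-1/2, +-1/2, +-1/2) onto the
    3-sphere.  Each level halves the edge length of the hypercubic boundary
    complex, adding points along edges, faces and cell centers, projects to
    S^3 and removes duplicate directions.  The returned grid keeps only
    canonical (upper-half) representatives; the full projected point set is
    available as ``pre_truncation``.
    """
    if level < 0:
        raise ValueError("subdivision level must be non-negative")
    if level > 4:
        raise ValueError("subdivision level capped at 4")
    all_points = None
    all_levels = None
    for lev in range(level + 1):
        lattice = _tesseract_lattice(lev)
        lattice /= np.linalg.norm(lattice, axis=1, keepdims=True)
        if all_points is None:
            all_points, all_levels = lattice, np.zeros(len(lattice), dtype=int)
        else:
            all_points = np.vstack([all_points, lattice])
            all_levels = np.concatenate(
                [all_levels, np.full(len(lattice), lev, dtype=int)]
            )
    # first occurrence wins, so points inherit the lowest level they occur at
    keep = _dedup_rows(all_points)
    pre, levels = all_points[keep], all_levels[keep]
    canon = canonicalize(pre)
    is_canon = np.all(np.abs(canon - pre) < 1e-12, axis=1)
    return HypersphereGrid(pre[is_canon], levels[is_canon], pre_truncation=pre)


# ---------------------------------------------------------------------------
# pruning


def _pairwise_angular(points: np.ndarray, quaternion: bool) -> np.ndarray:
    dots = np.clip(points @ points.T, -1.0, 1.0)
    if quaternion:
        dots = np.abs(dots)
    d = np.arccos(dots)
    np.fill_diagonal(d, np.inf)
    return d


def prune_to_size(grid, n: int):
    """Deterministically remove points until exactly ``n`` remain.

    Iteratively drops the point with the smallest nearest-neighbor distance
    in the retained set, always preferring points of the highest generation
    level still present (polytope vertices are removed last).  Ties are
    broken by lexicographic coordinate order.  Works for both sphere and
    hypersphere grids; for quaternions the rotational metric is used.
    """
    if isinstance(grid, HypersphereGrid):
        pts, quaternion = grid.quaternions, True
    elif isinstance(grid, SphereGrid):
        pts, quaternion = grid.points, False
    else:
        raise TypeError(f"cannot prune object of type {type(grid)!r}")
    if n > len(pts):
        raise ValueError(f"cannot prune grid of size {len(pts)} to {n} points")
    if n < 1:
        raise ValueError("target size must be positive")
    levels = grid.levels.copy()
    alive = np.ones(len(pts), dtype=bool)
    dist = _pairwise_angular(pts, quaternion)
    while alive.sum() > n:
        idx = np.flatnonzero(alive)
        max_level = levels[idx].max()
        cand = idx[levels[idx] == max_level]
        nn = dist[np.ix_(cand, idx)].min(axis=1)
        best = nn.min()
        tied = cand[nn <= best + 1e-12]
        if len(tied) > 1:  # lexicographic tie-break for determinism
            order = np.lexsort(pts[tied].T[::-1])
            victim = tied[order[0]]
        else:
            victim = tied[0]
        alive[victim] = False
    keep = np.flatnonzero(alive)
    if quaternion:
        return HypersphereGrid(pts[keep], levels[keep])
    return SphereGrid(pts[keep], levels[keep])


def grid_with_n_points(n: int, kind: str):
    """Smallest subdivision grid with >= n points, pruned to exactly n.

    ``kind`` is "sphere" (S^2 directions) or "hypersphere" (canonical
    quaternions).
    """
    if kind == "sphere":
        for level in range(7):
            g = icosahedral_grid(level)
            if len(g) >= n:
                return prune_to_size(g, n)
    elif kind == "hypersphere":
        for level in range(5):
            g = tesseract_grid(level)
            if len(g) >= n:
                return prune_to_size(g, n)
    else:
        raise ValueError(f"unknown grid kind {kind!r}")
    raise ValueError(f"no supported subdivision level reaches {n} points")


# ---------------------------------------------------------------------------
# spherical polygon areas


def polygon_interior_angles(loop: np.ndarray) -> np.ndarray:
    """Interior angles of a convex spherical polygon given its ordered
    vertex loop (unit 3-vectors)."""
    loop = np.asarray(loop, dtype=float)
    n = len(loop)
    angles = np.empty(n)
    for i in range(n):
        v = loop[i]
        for k, w in enumerate((loop[i - 1], loop[(i + 1) % n])):
            t = w - np.dot(w, v) * v
            t /= np.linalg.norm(t)
            if k == 0:
                t_prev = t
            else:
                t_next = t
        angles[i] = np.arccos(np.clip(np.dot(t_prev, t_next), -1.0, 1.0))
    return angles


def spherical_polygon_area(interior_angles, radius: float = 1.0) -> float:
    """Area of an n-sided spherical polygon from its interior angles.

    Spherical excess: ``(sum(alpha_i) - (n - 2) pi) R^2``.  Also covers the
    two-sided lune (n = 2).
    """
    angles = np.asarray(interior_angles, dtype=float)
    n = len(angles)
    if n < 2:
        raise ValueError("a spherical polygon needs at least 2 angles")
    if np.any(angles <= 0) or np.any(angles >= 2 * np.pi):
        raise ValueError("interior angles must lie in (0, 2 pi)")
    area = (angles.sum() - (n - 2) * np.pi) * radius**2
    if area <= 0:
        raise ValueError("inconsistent interior angles: non-positive area")
    return float(area)


# ---------------------------------------------------------------------------
# S^2 Voronoi


def spherical_voronoi(grid: SphereGrid, radius: float = 1.0) -> SphereVoronoi:
    """Spherical Voronoi tessellation of a direction grid at a radius.

    One cell per grid point; cell areas follow the spherical-excess formula
    applied to the ordered Voronoi vertex loop; two cells are adjacent when
    they share a Voronoi edge (two vertices).
    """
    if len(grid) < 4:
        raise ValueError("need at least 4 points for a spherical Voronoi diagram")
    try:
        sv = SphericalVoronoi(grid.points, radius=1.0)
    except Exception as exc:  # qhull degeneracies (coplanar input etc.)
        raise ValueError(f"degenerate point set for spherical Voronoi: {exc}")
    sv.sort_vertices_of_regions()
    vertices, regions = _merge_close_vertices(sv.vertices, sv.regions)
    areas = np.array(
        [
            spherical_polygon_area(
                polygon_interior_angles(vertices[loop]), radius
            )
            for loop in regions
        ]
    )
    adjacency, shared = _adjacency_from_regions(regions, min_shared=2)
    return SphereVoronoi(
        grid=grid,
        radius=radius,
        vertices=vertices,
        regions=regions,
        areas=areas,
        adjacency=adjacency,
        shared_vertices=shared,
    )


def _merge_close_vertices(vertices, regions, tol=1e-8):
    """Merge Voronoi vertices that coincide within ``tol``.

    Qhull triangulates non-simplicial facets, which produces repeated
    circumcenters for symmetric grids; shared-vertex counting needs the
    deduplicated set.
    """
    vertices = np.asarray(vertices, dtype=float)
    order = np.lexsort(vertices.T[::-1])
    remap = np.empty(len(vertices), dtype=int)
    unique: list[int] = []
    for idx in order:
        v = vertices[idx]
        found = None
        for u in reversed(unique):  # sorted order: duplicates are nearby
            if np.linalg.norm(v - vertices[u]) < tol:
                found = u
                break
            if abs(v[0] - vertices[u][0]) > tol:
                break
        if found is None:
            unique.append(idx)
            remap[idx] = idx
        else:
            remap[idx] = found
    new_ids = {old: new for new, old in enumerate(sorted(set(remap)))}
    new_vertices = vertices[sorted(set(remap))]
    new_regions = []
    for loop in regions:
        seen: list[int] = []
        for v in loop:
            nid = new_ids[remap[v]]
            if nid not in seen:
                seen.append(nid)
        new_regions.append(seen)
    return new_vertices, new_regions


def _adjacency_from_regions(regions, min_shared):
    vert_to_cells: dict[int, list[int]] = {}
    for cell, loop in enumerate(regions):
        for v in loop:
            vert_to_cells.setdefault(v, []).append(cell)
    pair_shared: dict[tuple[int, int], list[int]] = {}
    for v, cells in vert_to_cells.items():
        for a_i in range(len(cells)):
            for b_i in range(a_i + 1, len(cells)):
                key = tuple(sorted((cells[a_i], cells[b_i])))
                pair_shared.setdefault(key, []).append(v)
    adjacency = []
    shared = {}
    for key, verts in sorted(pair_shared.items()):
        if len(verts) >= min_shared:
            adjacency.append(key)
            shared[key] = np.array(sorted(verts), dtype=int)
    return adjacency, shared


# ---------------------------------------------------------------------------
# S^3 Voronoi


def hyper_border_area(shared_vertices: np.ndarray) -> float:
    """Area of the border polygon between two adjacent S^3 Voronoi cells.

    The shared Voronoi vertices are equidistant from both cell centers and
    hence lie on the intersection of S^3 with a hyperplane through the
    origin: a great 2-sphere.  An SVD of the vertex matrix yields the 4-D
    rotation that maps that 2-sphere onto the coordinate hyperplane q3 = 0;
    the rotated vertices are then ordinary unit 3-vectors bounding a
    spherical polygon whose area follows from the spherical excess.  Of the
    two complementary polygons the smaller one is the border.
    """
    v4 = np.atleast_2d(np.asarray(shared_vertices, dtype=float))
    if v4.shape[0] < 3:
        raise ValueError("need at least 3 shared vertices for a border polygon")
    if v4.shape[1] != 4:
        raise ValueError("vertices must be 4-dimensional")
    _, svals, wt = np.linalg.svd(v4, full_matrices=True)
    if len(svals) == 4 and svals[3] > 1e-8:
        raise ValueError(
            "shared vertices are not co-spherical (spread along the fourth "
            f"singular direction: {svals[3]:.2e})"
        )
    v3 = (v4 @ wt.T)[:, :3]
    v3 /= np.linalg.norm(v3, axis=1, keepdims=True)
    loop = _order_loop(v3)
    area = spherical_polygon_area(polygon_interior_angles(loop), radius=1.0)
    return float(min(area, 4 * np.pi - area))


def _order_loop(points3: np.ndarray) -> np.ndarray:
    """Order points of a convex spherical polygon along its boundary."""
    center = points3.mean(axis=0)
    nrm = np.linalg.norm(center)
    if nrm < 1e-12:  # hemisphere-spanning polygon: use plane normal instead
        # all points satisfy n . p ~ const; take normal of best-fit plane
        _, _, vt = np.linalg.svd(points3 - points3.mean(axis=0))
        center = vt[2]
    else:
        center /= nrm
    ref = points3[0] - np.dot(points3[0], center) * center
    ref /= np.linalg.norm(ref)
    ref2 = np.cross(center, ref)
    ang = np.arctan2(points3 @ ref2, points3 @ ref)
    return points3[np.argsort(ang)]


def hypersphere_voronoi(
    grid: HypersphereGrid,
    n_samples: int = 5000,
    seed: int = 0,
) -> HypersphereVoronoi:
    """Voronoi tessellation of the orientation grid on S^3.

    Built on the antipodally doubled set so that no rotation cell is cut by
    the truncation to the upper half-sphere.  Two rotations are adjacent
    when any of their antipodal cell copies share at least three Voronoi
    vertices; border areas accumulate the contributions of both copies.
    Volumes are Monte-Carlo estimates (see :func:`hyper_cell_volume`).
    """
    doubled = grid.doubled
    n_o = len(grid)
    if n_o == 1:
        # single rotation cell: the two antipodal copies split S^3 evenly
        return HypersphereVoronoi(
            grid=grid,
            vertices=np.empty((0, 4)),
            regions=[[], []],
            adjacency=[],
            border_areas={},
            volumes=np.array([np.pi**2]),
            volumes_doubled=np.array([np.pi**2, np.pi**2]),
        )
    if len(doubled) < 5:
        raise ValueError("need at least 5 points on the doubled set")
    try:
        sv = SphericalVoronoi(doubled, radius=1.0)
    except Exception as exc:
        raise ValueError(f"degenerate quaternion set for S^3 Voronoi: {exc}")
    vertices, regions = _merge_close_vertices(sv.vertices, sv.regions)
    pairs, shared = _adjacency_from_regions(regions, min_shared=3)

    border: dict[tuple[int, int], float] = {}
    for (a, b) in pairs:
        ca, cb = a % n_o, b % n_o
        if ca == cb:
            continue  # a cell facing its own antipodal copy is not a transition
        key = (min(ca, cb), max(ca, cb))
        area = hyper_border_area(vertices[shared[(a, b)]])
        border[key] = border.get(key, 0.0) + area
    # each canonical pair is seen twice (the two antipodal copies of the
    # interface are congruent): halve the accumulated area
    border = {k: v / 2.0 for k, v in border.items()}
    adjacency = sorted(border)
    result = HypersphereVoronoi(
        grid=grid,
        vertices=vertices,
        regions=regions,
        adjacency=adjacency,
        border_areas=border,
    )
    hyper_cell_volume(result, n_samples=n_samples, seed=seed)
    return result


def hyper_cell_volume(
    voronoi: HypersphereVoronoi,
    n_samples: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo volumes of the S^3 Voronoi cells.

    Uniform samples on S^3 (normalized Gaussian 4-vectors) are assigned to
    the nearest center of the doubled set; each doubled-set cell volume is
    its sample fraction times the total hypersurface 2 pi^2.  The canonical
    cell volume is the average of its two (congruent) antipodal copies.
    Updates ``voronoi.volumes`` / ``voronoi.volumes_doubled`` in place and
    returns the canonical volumes.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 Monte-Carlo samples")
    rng = np.random.default_rng(seed)
    doubled = voronoi.grid.doubled
    n_cells = len(doubled)
    samples = random_unit_quaternions(n_samples, rng)
    owner = np.argmax(samples @ doubled.T, axis=1)  # max dot = min arc
    counts = np.bincount(owner, minlength=n_cells)
    if np.any(counts == 0):
        warnings.warn(
            f"{int((counts == 0).sum())} S^3 cells received no Monte-Carlo "
            "samples; their volumes are zero",
            stacklevel=2,
        )
    volumes_doubled = counts / n_samples * 2 * np.pi**2
    n_o = len(voronoi.grid)
    volumes = 0.5 * (volumes_doubled[:n_o] + volumes_doubled[n_o:])
    voronoi.volumes_doubled = volumes_doubled
    voronoi.volumes = volumes
    return volumes
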