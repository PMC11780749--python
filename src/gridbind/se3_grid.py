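"""Radial, translational and full SE(3) grid geometry.

The translation grid is the product of an equidistant radial grid and a
uniform direction grid on S^2; its Voronoi cells are spherical-shell
sectors.  The full configuration grid is the product of the translation
grid with the quaternion orientation grid.  For every pair of adjacent
cells the center-to-center distance ``h`` and interface area ``S`` are
computed, and for every cell its volume ``V`` — the three geometric
ingredients of the square-root-approximation rate formula.

Adjacency on the product grid requires the two cells to coincide in one
subgrid and be adjacent in the other; there are therefore pure translation
moves and pure rotation moves.  The dimensionless weight ``alpha`` sets the
metric scale of the rotation subspace relative to translation (default 1):
rotational distances scale with alpha, rotational border areas with
alpha^2, and rotational cell volumes with alpha^3.

Units: nm for lengths, radians for angles; rotational distances and areas
are dimensionless (unit 3-sphere) times powers of alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gridbind.rotations import rotational_distance
from gridbind.sphere_grids import (
    HypersphereVoronoi,
    SphereGrid,
    SphereVoronoi,
    grid_with_n_points,
    hypersphere_voronoi,
    spherical_voronoi,
)

__all__ = [
    "RadialGrid",
    "TranslationGrid",
    "SE3Grid",
    "build_radial_grid",
    "build_translation_grid",
    "build_se3_grid",
    "angular_distance",
]


# ---------------------------------------------------------------------------
# radial grid


@dataclass
class RadialGrid:
    """Equidistant radii ``r_i`` with cell boundaries ``R_i``.

    Boundaries sit at midpoints between neighboring radii; the innermost
    boundary is 0 and the outermost extends half a spacing beyond the last
    radius, so every cell has the same radial thickness.
    """

    radii: np.ndarray  # (N_r,) cell-center radii, nm
    boundaries: np.ndarray  # (N_r + 1,) with boundaries[0] == 0

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def spacing(self) -> float:
        if len(self.radii) == 1:
            return float(self.radii[0])
        return float(self.radii[1] - self.radii[0])


def build_radial_grid(r_min: float, r_max: float, n_r: int) -> RadialGrid:
    """``n_r`` radii equally spaced between ``r_min`` and ``r_max`` [nm]."""
    if n_r < 1:
        raise ValueError("need at least one radial grid point")
    if not (0 < r_min <= r_max):
        raise ValueError("require 0 < r_min <= r_max")
    if n_r == 1:
        if not np.isclose(r_min, r_max):
            raise ValueError("a single radial point requires r_min == r_max")
        radii = np.array([r_min])
        # degenerate-spacing rule: treat the radius itself as the spacing
        boundaries = np.array([0.0, 1.5 * r_min])
    else:
        if r_min == r_max:
            raise ValueError("r_min must be strictly smaller than r_max")
        radii = np.linspace(r_min, r_max, n_r)
        spacing = radii[1] - radii[0]
        boundaries = np.concatenate(
            [[0.0], 0.5 * (radii[:-1] + radii[1:]), [radii[-1] + spacing / 2]]
        )
    return RadialGrid(radii, boundaries)


def radial_distance(grid: RadialGrid, i: int, k: int) -> float:
    """Distance between adjacent radial layers: ``|r_k - r_i|`` [nm]."""
    if abs(i - k) != 1:
        raise ValueError("radial distance is defined for adjacent layers only")
    return float(abs(grid.radii[k] - grid.radii[i]))


def angular_distance(t_i: np.ndarray, t_k: np.ndarray) -> float:
    """Arc-length distance between two translation points at equal radius.

    ``r * beta`` [nm] where beta is the angle between the two direction
    vectors.
    """
    t_i = np.asarray(t_i, dtype=float)
    t_k = np.asarray(t_k, dtype=float)
    r_i, r_k = np.linalg.norm(t_i), np.linalg.norm(t_k)
    if not np.isclose(r_i, r_k, rtol=1e-9, atol=1e-12):
        raise ValueError("angular distance requires equal radii")
    beta = np.arccos(np.clip(np.dot(t_i, t_k) / (r_i * r_k), -1.0, 1.0))
    return float(r_i * beta)


# ---------------------------------------------------------------------------
# translation grid


@dataclass
class TranslationGrid:
    """Product of a radial grid and a direction grid on S^2.

    Cells are indexed ``(radial layer i, direction s)`` with flat index
    ``i * N_s + s``.  ``edges`` lists adjacent flat-index pairs with
    center-to-center distance ``h`` [nm] and interface area ``S`` [nm^2];
    ``volumes`` holds the cell volumes [nm^3].
    """

    radial: RadialGrid
    directions: SphereVoronoi  # at unit radius
    points: np.ndarray  # (N_r * N_s, 3) Cartesian cell centers, nm
    volumes: np.ndarray
    edges: np.ndarray  # (E, 2) int
    h: np.ndarray  # (E,) nm
    S: np.ndarray  # (E,) nm^2
    edge_kind: np.ndarray  # (E,) "radial" or "angular"

    @property
    def n_r(self) -> int:
        return len(self.radial)

    @property
    def n_s(self) -> int:
        return len(self.directions.grid)

    def __len__(self) -> int:
        return len(self.points)


def side_face_area(beta: float, r_inner: float, r_outer: float) -> float:
    """Interface between angular neighbors: circular-sector difference.

    ``(beta / 2) (R_outer^2 - R_inner^2)`` with beta the sector angle [rad].
    """
    if beta <= 0:
        raise ValueError("sector angle must be positive")
    return float(0.5 * beta * (r_outer**2 - r_inner**2))


def build_translation_grid(
    radial: RadialGrid,
    directions: SphereGrid,
    side_angle: str = "center",
) -> TranslationGrid:
    """Assemble the translation grid and its geometric parameters.

    ``side_angle`` picks the sector angle of the side-face formula:
    ``"center"`` uses the angle between the two cell-center directions,
    ``"voronoi_edge"`` uses the arc length of the shared Voronoi edge
    (geometrically exact for irregular direction cells).
    """
    if side_angle not in ("center", "voronoi_edge"):
        raise ValueError(f"unknown side_angle mode {side_angle!r}")
    if len(directions) == 1:
        # single direction cell covering the whole sphere
        voronoi = SphereVoronoi(
            grid=directions,
            radius=1.0,
            vertices=np.empty((0, 3)),
            regions=[[]],
            areas=np.array([4 * np.pi]),
            adjacency=[],
            shared_vertices={},
        )
    else:
        voronoi = spherical_voronoi(directions, radius=1.0)
    n_r, n_s = len(radial), len(directions)
    unit_areas = voronoi.areas  # steradians at R = 1
    radii, bounds = radial.radii, radial.boundaries

    points = (radii[:, None, None] * directions.points[None, :, :]).reshape(-1, 3)
    volumes = (
        (unit_areas[None, :] / 3.0) * (bounds[1:, None] ** 3 - bounds[:-1, None] ** 3)
    ).reshape(-1)

    edges, h_list, s_list, kinds = [], [], [], []
    # radial moves: same direction, neighboring layers; the face sits at the
    # boundary radius between the layers
    for i in range(n_r - 1):
        for s in range(n_s):
            edges.append((i * n_s + s, (i + 1) * n_s + s))
            h_list.append(radii[i + 1] - radii[i])
            s_list.append(unit_areas[s] * bounds[i + 1] ** 2)
            kinds.append("radial")
    # angular moves: same layer, adjacent directions
    for (s1, s2) in voronoi.adjacency:
        d1, d2 = directions.points[s1], directions.points[s2]
        beta_center = np.arccos(np.clip(np.dot(d1, d2), -1.0, 1.0))
        if side_angle == "center":
            beta = beta_center
        else:
            shared = voronoi.shared_vertices[(s1, s2)]
            v = voronoi.vertices[shared]
            # arc between the two outermost shared vertices
            dots = np.clip(v @ v.T, -1, 1)
            beta = float(np.arccos(dots.min()))
        for i in range(n_r):
            edges.append((i * n_s + s1, i * n_s + s2))
            h_list.append(radii[i] * beta_center)
            s_list.append(side_face_area(beta, bounds[i], bounds[i + 1]))
            kinds.append("angular")

    return TranslationGrid(
        radial=radial,
        directions=voronoi,
        points=points,
        volumes=volumes,
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        h=np.array(h_list),
        S=np.array(s_list),
        edge_kind=np.array(kinds),
    )


# ---------------------------------------------------------------------------
# full SE(3) grid


@dataclass
class SE3Grid:
    """Product grid over translations and orientations.

    Cells are indexed ``(translation t, orientation o)`` with flat index
    ``t * N_o + o`` and ``t = i * N_s + s``.  ``edges`` carries both move
    types; ``edge_kind`` distinguishes ``"translation"`` from
    ``"rotation"``.
    """

    translation: TranslationGrid
    orientation: HypersphereVoronoi
    alpha: float
    edges: np.ndarray  # (E, 2)
    h: np.ndarray
    S: np.ndarray
    volumes: np.ndarray  # (N_d,)
    edge_kind: np.ndarray

    @property
    def n_r(self) -> int:
        return self.translation.n_r

    @property
    def n_s(self) -> int:
        return self.translation.n_s

    @property
    def n_o(self) -> int:
        return len(self.orientation.grid)

    @property
    def n_cells(self) -> int:
        return len(self.translation) * self.n_o

    def __len__(self) -> int:
        return self.n_cells

    def flat_index(self, i_r: int, i_s: int, i_o: int) -> int:
        return (i_r * self.n_s + i_s) * self.n_o + i_o

    def unravel(self, flat):
        """(radial, direction, orientation) indices of flat cell indices."""
        flat = np.asarray(flat)
        i_o = flat % self.n_o
        t = flat // self.n_o
        return t // self.n_s, t % self.n_s, i_o

    @property
    def quaternions(self) -> np.ndarray:
        return self.orientation.grid.quaternions

    def cell_center(self, flat: int):
        """(Cartesian translation [nm], quaternion) of a cell center."""
        i_o = flat % self.n_o
        t = flat // self.n_o
        return self.translation.points[t], self.quaternions[i_o]

    @property
    def translation_centers(self) -> np.ndarray:
        """Cartesian translation of every cell, shape (N_d, 3)."""
        return np.repeat(self.translation.points, self.n_o, axis=0)

    @property
    def spherical_centers(self) -> np.ndarray:
        """(r, theta, phi) of every cell center, shape (N_d, 3)."""
        xyz = self.translation_centers
        r = np.linalg.norm(xyz, axis=1)
        theta = np.arccos(np.clip(xyz[:, 2] / r, -1, 1))
        phi = np.mod(np.arctan2(xyz[:, 1], xyz[:, 0]), 2 * np.pi)
        return np.column_stack([r, theta, phi])


def build_se3_grid(
    r_min: float,
    r_max: float,
    n_r: int,
    n_s: int,
    n_o: int,
    alpha: float = 1.0,
    mc_samples: int = 5000,
    seed: int = 0,
    side_angle: str = "center",
) -> SE3Grid:
    """Build the full configuration grid with its geometric parameters.

    Direction and orientation grids are polytope-subdivision grids pruned
    to exactly ``n_s`` / ``n_o`` points.  ``mc_samples`` and ``seed``
    control the Monte-Carlo estimate of the orientation cell volumes.
    """
    radial = build_radial_grid(r_min, r_max, n_r)
    directions = grid_with_n_points(n_s, "sphere")
    trans = build_translation_grid(radial, directions, side_angle=side_angle)
    orient_grid = grid_with_n_points(n_o, "hypersphere")
    orient = hypersphere_voronoi(orient_grid, n_samples=mc_samples, seed=seed)
    return combine_grids(trans, orient, alpha=alpha)


def combine_grids(
    trans: TranslationGrid,
    orient: HypersphereVoronoi,
    alpha: float = 1.0,
) -> SE3Grid:
    """Product of a translation grid and an orientation tessellation."""
    n_t, n_o = len(trans), len(orient.grid)
    v_rot = alpha**3 * orient.volumes
    quats = orient.grid.quaternions

    volumes = (trans.volumes[:, None] * v_rot[None, :]).reshape(-1)

    # translation moves: same orientation, adjacent translations
    e_t = len(trans.edges)
    t_edges = trans.edges[:, :, None] * n_o + np.arange(n_o)[None, None, :]
    t_edges = t_edges.transpose(0, 2, 1).reshape(-1, 2)
    t_h = np.repeat(trans.h, n_o)
    t_s = (trans.S[:, None] * v_rot[None, :]).reshape(-1)

    # rotation moves: same translation, adjacent orientations
    r_pairs = np.array(orient.adjacency, dtype=int).reshape(-1, 2)
    r_h_rot = np.array(
        [alpha * rotational_distance(quats[a], quats[b]) for a, b in r_pairs]
    )
    r_s_rot = np.array(
        [alpha**2 * orient.border_areas[tuple(p)] for p in r_pairs]
    )
    base = np.arange(n_t)[:, None, None] * n_o
    r_edges = (base + r_pairs[None, :, :]).reshape(-1, 2)
    r_h = np.tile(r_h_rot, n_t)
    r_s = (trans.volumes[:, None] * r_s_rot[None, :]).reshape(-1)

    edges = np.vstack([t_edges, r_edges])
    h = np.concatenate([t_h, r_h])
    s = np.concatenate([t_s, r_s])
    kind = np.concatenate(
        [
            np.repeat("translation", e_t * n_o),
            np.repeat("rotation", len(r_pairs) * n_t),
        ]
    )
    if np.any(h <= 0) or np.any(s <= 0) or np.any(volumes <= 0):
        raise ValueError("grid geometry contains non-positive h, S or V")
    return SE3Grid(
        translation=trans,
        orientation=orient,
        alpha=alpha,
        edges=edges,
        h=h,
        S=s,
        volumes=volumes,
        edge_kind=kind,
    )


@dataclass
class GridGeometry:
    """Bare grid geometry: enough to assemble a rate matrix.

    Useful for custom discretizations (1-D chains, externally computed
    tessellations): only adjacency ``edges`` with per-edge ``h`` and ``S``
    plus per-cell ``volumes`` are required.
    """

    edges: np.ndarray  # (E, 2) int
    h: np.ndarray
    S: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.h = np.asarray(self.h, dtype=float).reshape(-1)
        self.S = np.asarray(self.S, dtype=float).reshape(-1)
        self.volumes = np.asarray(self.volumes, dtype=float).reshape(-1)

    @property
    def n_cells(self) -> int:
        return len(self.volumes)


def chain_geometry(n: int, spacing: float = 1.0) -> GridGeometry:
    """Uniform 1-D chain with reflecting ends: h = a, S = 1, V = a.

    With a flat potential the SqRA rates reduce to the classic
    finite-difference Laplacian D/a^2 whose reflecting-boundary spectrum
    is known in closed form — a convenient analytic reference.
    """
    if n < 2:
        raise ValueError("chain needs at least two cells")
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return GridGeometry(
        edges=edges,
        h=np.full(n - 1, spacing),
        S=np.ones(n - 1),
        volumes=np.full(n, spacing),
    )


# ---------------------------------------------------------------------------
# plain-text export


def export_cells(grid: SE3Grid, path: str) -> None:
    """Write the cell table: index, r, theta, phi, q0..q3, V (TSV)."""
    sph = grid.spherical_centers
    quats = np.tile(grid.quaternions, (len(grid.translation), 1))
    with open(path, "w") as fh:
        fh.write("index\tr\ttheta\tphi\tq0\tq1\tq2\tq3\tvolume\n")
        for i in range(grid.n_cells):
            r, th, ph = sph[i]
            q = quats[i]
            fh.write(
                f"{i}\t{r:.10g}\t{th:.10g}\t{ph:.10g}\t"
                f"{q[0]:.10g}\t{q[1]:.10g}\t{q[2]:.10g}\t{q[3]:.10g}\t"
                f"{grid.volumes[i]:.10g}\n"
            )


def export_edges(grid: SE3Grid, path: str) -> None:
    """Write the adjacency table: index_a, index_b, h, S (TSV)."""
    with open(path, "w") as fh:
        fh.write("index_a\tindex_b\th\tS\n")
        for (a, b), h, s in zip(grid.edges, grid.h, grid.S):
            fh.write(f"{a}\t{b}\t{h:.10g}\t{s:.10g}\n")
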