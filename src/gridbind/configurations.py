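"""Rigid-body structures, frame alignment, grid placement and file I/O.

Molecule A defines the coordinate system: its center of mass sits at the
origin and its principal axes of inertia align with the coordinate axes.
Molecule B is treated as a rigid body whose pose is a point of the SE(3)
grid: its reference coordinates are first rotated by ``R(q)`` and then
translated by the Cartesian image of the spherical grid point
``(r, theta, phi)`` (physics convention: theta polar from +z, phi azimuth
from +x).  A pseudotrajectory is the systematic enumeration of one such
pose per grid cell — generated, not simulated.

Coordinates are stored in nm.  File I/O (XYZ, multi-model PDB, GRO) is
delegated to MDAnalysis; XYZ and PDB files are in Angstrom on disk, GRO in
nm, with conversion applied on read/write.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace

import numpy as np

from gridbind.rotations import to_rotation_matrix

__all__ = [
    "RigidMolecule",
    "Pose",
    "PseudoTrajectory",
    "center_of_mass",
    "inertia_tensor",
    "align_principal_frame",
    "spherical_to_cartesian",
    "place",
    "generate_pseudotrajectory",
    "read_structure",
    "write_structure",
    "write_trajectory",
    "read_trajectory",
]

_NM_PER_ANGSTROM = 0.1


class ParseError(ValueError):
    """Raised for malformed structure files."""


@dataclass
class RigidMolecule:
    """A rigid molecule: names, coordinates [nm], masses [u] and optional
    nonbonded parameters (charge [e], LJ sigma [nm], LJ epsilon [kJ/mol])."""

    names: list
    coords: np.ndarray  # (n, 3) nm
    masses: np.ndarray  # (n,) u
    charges: np.ndarray | None = None
    sigmas: np.ndarray | None = None
    epsilons: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        if len(self.coords) == 0:
            raise ValueError("molecule needs at least one atom")
        if len(self.masses) != len(self.coords):
            raise ValueError("masses and coordinates disagree in length")
        if self.masses.sum() <= 0:
            raise ValueError("total mass must be positive")
        for attr in ("charges", "sigmas", "epsilons"):
            val = getattr(self, attr)
            if val is not None:
                setattr(self, attr, np.asarray(val, dtype=float).reshape(-1))

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def with_coords(self, coords: np.ndarray) -> "RigidMolecule":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Pose:
    """Molecule B's Cartesian coordinates [nm] at one grid cell."""

    cell_index: int
    coords: np.ndarray


@dataclass
class PseudoTrajectory:
    """One pose of molecule B per grid cell, in flat-index order.

    ``frames[i]`` is the coordinate array of molecule B at cell ``i``;
    molecule A is identical in every frame.
    """

    molecule_a: RigidMolecule
    molecule_b: RigidMolecule  # reference configuration
    frames: np.ndarray  # (N_d, n_atoms_B, 3) nm

    def __len__(self) -> int:
        return len(self.frames)

    def pose(self, i: int) -> Pose:
        return Pose(cell_index=i, coords=self.frames[i])


# ---------------------------------------------------------------------------
# mass-weighted geometry


def center_of_mass(molecule: RigidMolecule) -> np.ndarray:
    """Mass-weighted mean position [nm]."""
    return molecule.masses @ molecule.coords / molecule.total_mass


def inertia_tensor(molecule: RigidMolecule) -> np.ndarray:
    """Inertia tensor about the center of mass [u nm^2]."""
    r = molecule.coords - center_of_mass(molecule)
    m = molecule.masses
    r2 = np.einsum("i,ij,ij->", m, r, r)
    return r2 * np.eye(3) - np.einsum("i,ij,ik->jk", m, r, r)


def align_principal_frame(molecule: RigidMolecule) -> RigidMolecule:
    """Shift the COM to the origin and rotate onto the principal axes.

    Axes are ordered by ascending moment of inertia.  The sign of the
    first two axes is fixed by a molecule-intrinsic rule — the
    mass-weighted third moment (skewness) of the coordinates along the
    axis is made positive, falling back to the coordinate sign of the
    atom farthest along the axis when the skewness vanishes — and the
    third axis is their cross product (right-handed frame).  Intrinsic
    sign rules make the result invariant under any rigid pre-rotation of
    the input.  Nearly degenerate moments (symmetric tops, linear
    molecules) trigger a warning because the in-plane axes are then only
    defined up to the numerical tie-break.
    """
    centered = molecule.coords - center_of_mass(molecule)
    inertia = inertia_tensor(molecule.with_coords(centered))
    moments, axes = np.linalg.eigh(inertia)  # ascending
    scale = max(moments[-1], 1e-30)
    if len(molecule) > 1 and np.min(np.diff(moments)) < 1e-9 * scale:
        warnings.warn(
            "near-degenerate principal moments of inertia; the principal "
            "frame is fixed only by the deterministic sign convention",
            stacklevel=2,
        )
    m = molecule.masses
    for k in range(2):
        x = centered @ axes[:, k]
        skew = float(m @ x**3)
        if abs(skew) > 1e-12 * max(float(np.abs(x).max()) ** 3 * m.sum(), 1e-30):
            sign = np.sign(skew)
        else:
            j = int(np.argmax(np.abs(x)))
            sign = np.sign(x[j]) if abs(x[j]) > 1e-12 else 1.0
        axes[:, k] *= sign
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return molecule.with_coords(centered @ axes)


# ---------------------------------------------------------------------------
# placement


def spherical_to_cartesian(r: float, theta: float, phi: float) -> np.ndarray:
    """(r, theta, phi) [nm, rad, rad] -> Cartesian [nm], theta polar from +z."""
    st = np.sin(theta)
    return np.array([r * st * np.cos(phi), r * st * np.sin(phi), r * np.cos(theta)])


def place(molecule_b: RigidMolecule, t, q: np.ndarray) -> np.ndarray:
    """Coordinates of molecule B rotated by ``R(q)`` then translated to ``t``.

    ``t`` is a spherical triple ``(r, theta, phi)``; use
    :func:`place_cartesian` for a Cartesian target.  The molecule must be
    in its reference configuration (COM at the origin).
    """
    t_cart = spherical_to_cartesian(*t)
    return place_cartesian(molecule_b, t_cart, q)


def place_cartesian(
    molecule_b: RigidMolecule, t_cart: np.ndarray, q: np.ndarray
) -> np.ndarray:
    com = center_of_mass(molecule_b)
    if np.linalg.norm(com) > 1e-9:
        raise ValueError(
            "molecule B must be in its reference configuration (COM at origin)"
        )
    rot = to_rotation_matrix(q)
    return molecule_b.coords @ rot.T + np.asarray(t_cart, dtype=float)


def generate_pseudotrajectory(grid, molecule_a, molecule_b) -> PseudoTrajectory:
    """Place molecule B at every cell of an SE(3) grid.

    Molecule A is aligned to its principal frame and molecule B to its own
    principal frame (the reference rotation); frames follow the grid's flat
    cell-index order.
    """
    mol_a = align_principal_frame(molecule_a)
    mol_b = align_principal_frame(molecule_b)
    rots = np.array([to_rotation_matrix(q) for q in grid.quaternions])
    # (N_o, n_atoms, 3): all rotated copies of B
    rotated = np.einsum("oij,aj->oai", rots, mol_b.coords)
    trans = grid.translation.points  # (N_t, 3)
    n_t, n_o = len(trans), len(rots)
    frames = (
        rotated[None, :, :, :] + trans[:, None, None, :]
    ).reshape(n_t * n_o, len(mol_b), 3)
    return PseudoTrajectory(molecule_a=mol_a, molecule_b=mol_b, frames=frames)


# ---------------------------------------------------------------------------
# structure I/O (MDAnalysis back end)


def _universe_from(names, coords_nm):
    import MDAnalysis as mda

    u = mda.Universe.empty(len(names), trajectory=True)
    elements = [_element_of(n) for n in names]
    u.add_TopologyAttr("names", list(names))
    u.add_TopologyAttr("elements", elements)
    u.add_TopologyAttr("resnames", ["MOL"])
    u.atoms.positions = np.asarray(coords_nm, dtype=float) / _NM_PER_ANGSTROM
    return u


_TWO_LETTER = ("Cl", "Br", "Na", "Mg", "Ca", "Zn", "Fe")


def _element_of(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    if len(stripped) > 1 and stripped[:2].capitalize() in _TWO_LETTER:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_structure(path: str) -> RigidMolecule:
    """Read a molecule from XYZ, PDB or GRO into nm coordinates.

    Masses are taken from the file's (inferred) elements.  Nonbonded
    parameters are not part of these formats and stay unset.
    """
    import MDAnalysis as mda

    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise ParseError(f"empty structure file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise ParseError(f"no atoms in {path}")
    coords = u.atoms.positions * _NM_PER_ANGSTROM
    names = list(u.atoms.names)
    masses = np.asarray(u.atoms.masses, dtype=float)
    return RigidMolecule(names=names, coords=coords, masses=masses)


def write_structure(molecule: RigidMolecule, path: str) -> None:
    """Write a molecule to XYZ, PDB or GRO (format from the extension)."""
    u = _universe_from(molecule.names, molecule.coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def write_trajectory(
    trajectory,
    path: str,
    molecule_a: RigidMolecule | None = None,
    molecule_b: RigidMolecule | None = None,
) -> None:
    """Write frames of the two-molecule system to a multi-frame XYZ or
    multi-model PDB file.

    Each frame contains molecule A (fixed) followed by molecule B at its
    per-frame coordinates.  Accepts a :class:`PseudoTrajectory` or a raw
    ``(n_frames, n_atoms_B, 3)`` array plus both molecules.
    """
    import MDAnalysis as mda

    if isinstance(trajectory, PseudoTrajectory):
        mol_a, mol_b = trajectory.molecule_a, trajectory.molecule_b
        frames = trajectory.frames
    else:
        if molecule_a is None or molecule_b is None:
            raise ValueError("raw frame arrays need molecule_a and molecule_b")
        mol_a, mol_b = molecule_a, molecule_b
        frames = np.asarray(trajectory, dtype=float)
    names = list(mol_a.names) + list(mol_b.names)
    u = _universe_from(names, np.vstack([mol_a.coords, frames[0]]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=len(names), multiframe=True) as writer:
            for frame in frames:
                u.atoms.positions = (
                    np.vstack([mol_a.coords, frame]) / _NM_PER_ANGSTROM
                )
                writer.write(u.atoms)


def read_trajectory(path: str, n_atoms_a: int) -> tuple:
    """Read a two-molecule trajectory; returns (coords_a, frames_b) in nm.

    ``coords_a`` is (n_frames, n_atoms_a, 3); ``frames_b`` the remaining
    atoms per frame.
    """
    import MDAnalysis as mda

    if not os.path.exists(path) or os.path.getsize(path) == 0:
        raise ParseError(f"missing or empty trajectory file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
        if len(u.atoms) <= n_atoms_a:
            raise ParseError(
                f"trajectory has {len(u.atoms)} atoms, "
                f"expected more than {n_atoms_a}"
            )
        coords_a, coords_b = [], []
        for _ in u.trajectory:
            pos = u.atoms.positions * _NM_PER_ANGSTROM
            coords_a.append(pos[:n_atoms_a].copy())
            coords_b.append(pos[n_atoms_a:].copy())
    return np.array(coords_a), np.array(coords_b)
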