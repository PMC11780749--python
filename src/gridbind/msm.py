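"""Markov state models estimated from trajectories on the SE(3) grid.

Each trajectory frame of the two-molecule system is assigned to a grid
cell by a three-step nearest-center lookup after aligning the frame to
molecule A's principal frame: (1) nearest radial layer for the
center-of-mass distance, (2) nearest direction-grid point for the
center-of-mass direction, (3) nearest orientation-grid quaternion for
molecule B's rotation.  Frames beyond the outer grid boundary are either
pushed into the outermost radial layer (``"assign_outer"``) or left
unassigned (``"omit"``); transition counts touching an unassigned frame
are dropped.

Counting uses a sliding window at lag ``tau`` frames; detailed balance is
enforced by symmetrizing the count matrix; the transition matrix is the
row-normalized symmetrized count matrix over the visited states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.transform import Rotation

from gridbind.configurations import (
    RigidMolecule,
    align_principal_frame,
    center_of_mass,
)
from gridbind.rotations import canonicalize

__all__ = [
    "UNASSIGNED",
    "DiscreteTrajectory",
    "CountMatrix",
    "assign",
    "count_matrix",
    "enforce_detailed_balance",
    "transition_matrix",
    "msm_implied_timescales",
    "sample_markov_chain",
]

#: sentinel for frames outside the grid in "omit" mode
UNASSIGNED = -1


@dataclass
class DiscreteTrajectory:
    """Per-frame cell indices (or :data:`UNASSIGNED`) at a frame interval."""

    indices: np.ndarray
    frame_interval: float = 1.0  # ps

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int).reshape(-1)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class CountMatrix:
    """Sparse transition counts at a lag, over all grid cells."""

    counts: sp.csr_matrix
    lag_frames: int
    lag_ps: float

    @property
    def total(self) -> float:
        return float(self.counts.sum())


# ---------------------------------------------------------------------------
# trajectory assignment


def _kabsch(reference: np.ndarray, moved: np.ndarray, weights: np.ndarray):
    """Rotation carrying ``reference`` onto ``moved`` (both centered)."""
    rot, _ = Rotation.align_vectors(moved, reference, weights=weights)
    return rot


def assign(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    molecule_a: RigidMolecule,
    molecule_b: RigidMolecule,
    grid,
    mode: str = "assign_outer",
    frame_interval: float = 1.0,
) -> DiscreteTrajectory:
    """Assign trajectory frames to grid cells.

    ``coords_a`` / ``coords_b`` are per-frame coordinate arrays
    ``(n_frames, n_atoms, 3)`` [nm] of the two molecules in any common lab
    frame.  ``mode`` controls frames whose center-of-mass distance exceeds
    the outer grid boundary: ``"assign_outer"`` books them into the
    outermost radial layer (closest direction and orientation still
    apply); ``"omit"`` marks them :data:`UNASSIGNED`.
    """
    if mode not in ("assign_outer", "omit"):
        raise ValueError(f"unknown boundary mode {mode!r}")
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if coords_a.ndim == 2:
        coords_a = coords_a[None]
    if coords_b.ndim == 2:
        coords_b = coords_b[None]
    n_frames = len(coords_b)
    if len(coords_a) not in (1, n_frames):
        raise ValueError("molecule A coordinates must match the frame count")
    ref_a = align_principal_frame(molecule_a)
    ref_b = align_principal_frame(molecule_b)
    if coords_a.shape[1] != len(ref_a) or coords_b.shape[1] != len(ref_b):
        raise ValueError("frame atom counts do not match the molecules")

    radial = grid.translation.radial
    directions = grid.translation.directions.grid.points  # (N_s, 3)
    quats = grid.quaternions  # (N_o, 4)
    n_o, n_s = grid.n_o, grid.n_s
    outer_boundary = radial.boundaries[-1]
    m_a, m_b = ref_a.masses, ref_b.masses

    indices = np.empty(n_frames, dtype=int)
    for f in range(n_frames):
        frame_a = coords_a[0] if len(coords_a) == 1 else coords_a[f]
        com_a = m_a @ frame_a / m_a.sum()
        # rotation of the lab frame relative to A's principal frame
        rot_a = _kabsch(ref_a.coords, frame_a - com_a, m_a)
        to_ref = rot_a.inv()
        b_local = to_ref.apply(coords_b[f] - com_a)
        com_b = m_b @ b_local / m_b.sum()
        r = np.linalg.norm(com_b)
        if r > outer_boundary and mode == "omit":
            indices[f] = UNASSIGNED
            continue
        i_r = int(np.argmin(np.abs(radial.radii - r)))
        direction = com_b / r if r > 0 else np.array([0.0, 0.0, 1.0])
        i_s = int(np.argmax(directions @ direction))
        rot_b = _kabsch(ref_b.coords, b_local - com_b, m_b)
        q = _quat_scalar_first(rot_b)
        i_o = int(np.argmax(np.abs(quats @ q)))
        indices[f] = (i_r * n_s + i_s) * n_o + i_o
    return DiscreteTrajectory(indices=indices, frame_interval=frame_interval)


def _quat_scalar_first(rot: Rotation) -> np.ndarray:
    x, y, z, w = rot.as_quat()
    return canonicalize(np.array([w, x, y, z]))


# ---------------------------------------------------------------------------
# count and transition matrices


def count_matrix(
    dtraj: DiscreteTrajectory | np.ndarray,
    lag_frames: int,
    n_states: int | None = None,
) -> CountMatrix:
    """Sliding-window transition counts ``C_ab = #{t: s(t)=a, s(t+lag)=b}``.

    Pairs in which either end is :data:`UNASSIGNED` are dropped.
    """
    if isinstance(dtraj, DiscreteTrajectory):
        s = dtraj.indices
        interval = dtraj.frame_interval
    else:
        s = np.asarray(dtraj, dtype=int).reshape(-1)
        interval = 1.0
    if lag_frames < 1:
        raise ValueError("lag must be at least one frame")
    if lag_frames >= len(s):
        raise ValueError("lag exceeds the trajectory length")
    a, b = s[:-lag_frames], s[lag_frames:]
    keep = (a != UNASSIGNED) & (b != UNASSIGNED)
    a, b = a[keep], b[keep]
    if n_states is None:
        n_states = int(s.max()) + 1 if len(s) else 0
    counts = sp.coo_matrix(
        (np.ones(len(a)), (a, b)), shape=(n_states, n_states)
    ).tocsr()
    return CountMatrix(
        counts=counts, lag_frames=lag_frames, lag_ps=lag_frames * interval
    )


def enforce_detailed_balance(count: CountMatrix) -> CountMatrix:
    """Symmetrize the count matrix: ``C <- (C + C^T) / 2``."""
    sym = (count.counts + count.counts.T) * 0.5
    return CountMatrix(
        counts=sym.tocsr(), lag_frames=count.lag_frames, lag_ps=count.lag_ps
    )


def transition_matrix(count: CountMatrix):
    """Row-normalized transition matrix over the visited states.

    States with zero total counts are removed; the returned ``state_map``
    gives the original grid cell index of each retained MSM state.
    """
    c = count.counts.tocsr()
    row_sums = np.asarray(c.sum(axis=1)).ravel()
    col_sums = np.asarray(c.sum(axis=0)).ravel()
    active = np.flatnonzero(row_sums + col_sums > 0)
    if len(active) == 0:
        raise ValueError("empty count matrix")
    sub = c[active][:, active]
    sub_rows = np.asarray(sub.sum(axis=1)).ravel()
    if np.any(sub_rows == 0):
        # states seen only as targets at the trajectory end: drop them too
        keep = sub_rows > 0
        active = active[keep]
        sub = c[active][:, active]
        sub_rows = np.asarray(sub.sum(axis=1)).ravel()
    t = sp.diags(1.0 / sub_rows) @ sub
    return t.tocsr(), active


def msm_implied_timescales(
    t_matrix, lag_ps: float, k: int = 5
) -> np.ndarray:
    """Implied timescales ``-lag / ln(lambda_i)`` [ps], slowest first.

    The stationary eigenvalue (lambda_0 = 1) is excluded; eigenvalues at
    or above 1 within round-off map to ``+inf``; non-positive eigenvalues
    are dropped (no real timescale).
    """
    dense = t_matrix.toarray() if sp.issparse(t_matrix) else np.asarray(t_matrix)
    ev = np.linalg.eigvals(dense)
    ev = np.real(ev[np.abs(np.imag(ev)) < 1e-10])
    ev = np.sort(ev)[::-1]
    ev = ev[1 : k + 1]  # drop lambda_0
    out = []
    for lam in ev:
        if lam >= 1.0 - 1e-12:
            out.append(np.inf)
        elif lam > 0:
            out.append(-lag_ps / np.log(lam))
    return np.array(out)


def write_discrete_trajectory(dtraj: DiscreteTrajectory, path: str) -> None:
    """Single-column text dump; unassigned frames as the sentinel value."""
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_ps: {dtraj.frame_interval}\n")
        for idx in dtraj.indices:
            fh.write(f"{idx}\n")


def read_discrete_trajectory(path: str) -> DiscreteTrajectory:
    interval = 1.0
    indices = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "frame_interval_ps:" in line:
                    interval = float(line.split(":")[1])
                continue
            if line:
                indices.append(int(line))
    return DiscreteTrajectory(np.array(indices, dtype=int), interval)


def write_sparse_matrix(matrix, path: str) -> None:
    """Coordinate-format text dump (row, col, value) of a sparse matrix."""
    coo = sp.coo_matrix(matrix)
    with open(path, "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{v:.12g}\n")


def sample_markov_chain(
    t_matrix, n_steps: int, seed: int = 0, start: int | None = None
) -> np.ndarray:
    """Exact sampling of a state sequence from a transition matrix."""
    dense = t_matrix.toarray() if sp.issparse(t_matrix) else np.asarray(t_matrix)
    n = dense.shape[0]
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(dense, axis=1)
    states = np.empty(n_steps, dtype=int)
    states[0] = start if start is not None else rng.integers(n)
    draws = rng.random(n_steps)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cdf[states[t - 1]], draws[t])
    return states
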