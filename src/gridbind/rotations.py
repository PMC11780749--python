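"""Quaternion algebra for the orientation grid.

Unit quaternions ``q = (q0, q1, q2, q3)`` (scalar-first) parametrize the
rotation group SO(3) with a double cover: ``q`` and ``-q`` describe the same
rotation.  To obtain a one-to-one parametrization the package always works
with the *canonical* (upper-half-hypersphere) representative, whose first
nonzero component is positive.  Rotations are active: coordinates transform
as ``x' = R(q) @ x``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "canonicalize",
    "is_canonical",
    "to_rotation_matrix",
    "rotational_distance",
    "random_unit_quaternions",
]

#: components smaller than this are treated as zero by the canonical rule
_ZERO_TOL = 1e-12
#: tolerance on |q| - 1 before a quaternion is rejected as non-unit
_UNIT_TOL = 1e-9


def _check_unit(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"quaternion must have 4 components, got shape {q.shape}")
    norm = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norm - 1.0) > _UNIT_TOL):
        raise ValueError("quaternion is not unit-norm within tolerance 1e-9")
    # renormalize to remove accumulated round-off
    return q / norm[..., np.newaxis]


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Return the canonical (upper-half-hypersphere) representative of ``q``.

    Out of the antipodal pair ``{q, -q}`` the representative whose first
    component of magnitude above 1e-12 is positive is selected: quaternions
    with ``q0 > 0`` are kept; for ``q0 = 0`` those with ``q1 > 0``, and so on
    through the fourth component.  Idempotent, and ``R(canonicalize(q)) ==
    R(q)`` because the rotation is insensitive to the overall sign.

    Accepts a single quaternion ``(4,)`` or a batch ``(n, 4)``.
    """
    q = _check_unit(q)
    single = q.ndim == 1
    qb = np.atleast_2d(q).copy()
    sign = np.zeros(len(qb))
    for comp in range(4):
        undecided = sign == 0
        if not np.any(undecided):
            break
        col = qb[undecided, comp]
        s = np.where(np.abs(col) > _ZERO_TOL, np.sign(col), 0.0)
        sign[undecided] = s
    if np.any(sign == 0):
        raise ValueError("zero quaternion cannot be canonicalized")
    qb *= sign[:, np.newaxis]
    return qb[0] if single else qb


def is_canonical(q: np.ndarray) -> bool:
    """True if ``q`` already is its canonical representative."""
    q = np.asarray(q, dtype=float)
    return bool(np.allclose(canonicalize(q), q, atol=1e-12))


def to_rotation_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix ``R(q)`` of a unit quaternion (scalar-first).

    The result is orthogonal with determinant +1 and satisfies
    ``R(q) = R(-q)``.
    """
    q0, q1, q2, q3 = _check_unit(q)
    return np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
            ],
        ]
    )


def rotational_distance(q1: np.ndarray, q2: np.ndarray) -> float:
    """Distance between two rotations, in radians, on the quaternion sphere.

    The angle between the unit 4-vectors, folded for the double cover:
    ``min(arccos<q1, q2>, arccos<q1, -q2>)``.  The result lies in
    [0, pi/2], is symmetric, and is invariant under negating either argument.
    """
    q1 = _check_unit(q1)
    q2 = _check_unit(q2)
    dot = np.clip(np.abs(np.dot(q1, q2)), -1.0, 1.0)
    return float(np.arccos(dot))


def rotational_distance_matrix(qs1: np.ndarray, qs2: np.ndarray) -> np.ndarray:
    """Pairwise rotational distances between two stacks of unit quaternions."""
    qs1 = np.atleast_2d(np.asarray(qs1, dtype=float))
    qs2 = np.atleast_2d(np.asarray(qs2, dtype=float))
    dots = np.clip(np.abs(qs1 @ qs2.T), -1.0, 1.0)
    return np.arccos(dots)


def random_unit_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` quaternions uniform on S^3 (normalized 4-D Gaussian draws)."""
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)
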