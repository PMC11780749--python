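"""Per-cell effective potential of the rigid two-molecule system.

Within the rigid-body approximation the effective potential of a grid cell
is simply the intermolecular potential energy of the two molecules with B
placed at the cell center — one energy evaluation per cell.  The built-in
evaluator sums pairwise Coulomb and Lennard-Jones terms over all
intermolecular atom pairs (Lorentz–Berthelot combining, no cutoff by
default).  Any other engine can stand in through the callable hook of
:func:`evaluate_grid` or by importing a plain-text energy table.

Units: kJ/mol for energies, nm for distances, elementary charges for
partial charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "EnergyTable",
    "pairwise_nonbonded",
    "evaluate_grid",
    "cap_energy_difference",
    "read_energy_table",
    "write_energy_table",
    "COULOMB_CONSTANT",
]

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2 (MD unit system)
COULOMB_CONSTANT = 138.935458

#: default cap on pairwise energy differences [kJ/mol]; larger differences
#: correspond to transition rates that are numerically zero
DEFAULT_ENERGY_CAP = 500.0


@dataclass
class EnergyTable:
    """Per-cell effective potential V_eff [kJ/mol], flat cell-index order.

    ``+inf`` is the sentinel for steric clashes (zero interatomic
    distance); all rates into and out of such a cell fall into the
    capped-zero regime.
    """

    energies: np.ndarray
    potential: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float).reshape(-1)
        if np.any(np.isnan(self.energies)):
            raise ValueError("energy table contains NaN")

    def __len__(self) -> int:
        return len(self.energies)


def _lj_params(mol):
    sig = mol.sigmas if mol.sigmas is not None else np.zeros(len(mol))
    eps = mol.epsilons if mol.epsilons is not None else np.zeros(len(mol))
    chg = mol.charges if mol.charges is not None else np.zeros(len(mol))
    return chg, sig, eps


def pairwise_nonbonded(
    molecule_a,
    coords_b: np.ndarray,
    molecule_b=None,
    cutoff: float | None = None,
) -> float:
    """Intermolecular Coulomb + Lennard-Jones energy [kJ/mol].

    ``coords_b`` are molecule B's coordinates for this pose [nm];
    ``molecule_b`` supplies B's charges and LJ parameters (defaults to
    ``molecule_a``'s parameter source being required on both).  Mixing is
    Lorentz–Berthelot: sigma_ij = (sigma_i + sigma_j)/2, eps_ij =
    sqrt(eps_i eps_j).  A coincident atom pair returns ``+inf``.
    """
    if molecule_b is None:
        raise ValueError("molecule_b (parameter source for coords_b) is required")
    qa, sa, ea = _lj_params(molecule_a)
    qb, sb, eb = _lj_params(molecule_b)
    r = cdist(molecule_a.coords, np.asarray(coords_b, dtype=float))
    if np.any(r == 0):
        return float("inf")
    qq = np.outer(qa, qb)
    sig = 0.5 * (sa[:, None] + sb[None, :])
    eps = np.sqrt(np.outer(ea, eb))
    if cutoff is not None:
        mask = r <= cutoff
    else:
        mask = np.ones_like(r, dtype=bool)
    coul = COULOMB_CONSTANT * qq / r
    with np.errstate(divide="ignore"):
        sr6 = np.where(sig > 0, (sig / r) ** 6, 0.0)
    lj = 4.0 * eps * (sr6**2 - sr6)
    return float(((coul + lj) * mask).sum())


def evaluate_grid(grid, molecule_a, molecule_b, potential=None) -> EnergyTable:
    """Evaluate one energy per grid cell, in flat-index order.

    ``potential`` is any callable ``(molecule_a, coords_b, molecule_b) ->
    kJ/mol`` — the hook through which external engines or QM energies can
    replace the built-in evaluator.  The default is the vectorized
    Coulomb + Lennard-Jones evaluator.
    """
    from gridbind.configurations import generate_pseudotrajectory

    traj = generate_pseudotrajectory(grid, molecule_a, molecule_b)
    if potential is None:
        energies = _nonbonded_vectorized(traj.molecule_a, traj.molecule_b, traj.frames)
        name = "coulomb+lj"
    else:
        energies = np.array(
            [potential(traj.molecule_a, frame, traj.molecule_b) for frame in traj.frames]
        )
        name = getattr(potential, "__name__", "custom")
    return EnergyTable(energies=energies, potential=name)


def _nonbonded_vectorized(mol_a, mol_b, frames: np.ndarray) -> np.ndarray:
    """Coulomb + LJ energies for a whole stack of poses at once."""
    qa, sa, ea = _lj_params(mol_a)
    qb, sb, eb = _lj_params(mol_b)
    diff = frames[:, None, :, :] - mol_a.coords[None, :, None, :]
    r = np.linalg.norm(diff, axis=-1)  # (n_frames, n_a, n_b)
    qq = np.outer(qa, qb)[None]
    sig = 0.5 * (sa[:, None] + sb[None, :])[None]
    eps = np.sqrt(np.outer(ea, eb))[None]
    with np.errstate(divide="ignore", invalid="ignore"):
        coul = COULOMB_CONSTANT * qq / r
        sr6 = np.where(sig > 0, (sig / r) ** 6, 0.0)
        lj = 4.0 * eps * (sr6**2 - sr6)
        total = (coul + lj).sum(axis=(1, 2))
    total[np.any(r == 0, axis=(1, 2))] = np.inf
    return total


def cap_energy_difference(delta_v, cap: float = DEFAULT_ENERGY_CAP):
    """Clip an energy difference to ``[-cap, +cap]`` kJ/mol.

    Differences at the cap correspond to rates that are numerically zero;
    capping avoids overflow in the Boltzmann factor.  Works element-wise.
    """
    return np.clip(delta_v, -cap, cap)


def write_energy_table(table: EnergyTable, path: str) -> None:
    """Write a TSV energy table: cell_index, energy [kJ/mol]."""
    with open(path, "w") as fh:
        fh.write(f"# potential: {table.potential}\n")
        fh.write("cell_index\tenergy_kJ_mol\n")
        for i, e in enumerate(table.energies):
            fh.write(f"{i}\t{e:.10g}\n")


def read_energy_table(path: str, n_cells: int | None = None) -> EnergyTable:
    """Read a TSV energy table (cell_index, energy) written by any engine.

    Rows may come in any order; the index column defines the cell.  If
    ``n_cells`` is given the table length is validated against it.
    """
    idx, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("cell_index"):
                continue
            parts = line.split()
            try:
                idx.append(int(parts[0]))
                vals.append(float(parts[1]))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed energy row") from exc
    if not idx:
        raise ValueError(f"{path}: empty energy table")
    n = max(idx) + 1
    if n_cells is not None and n != n_cells:
        raise ValueError(
            f"energy table covers {n} cells but the grid has {n_cells}"
        )
    energies = np.full(n, np.nan)
    energies[idx] = vals
    if np.any(np.isnan(energies)):
        raise ValueError(f"{path}: missing cell indices in energy table")
    return EnergyTable(energies=energies, potential="external")
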