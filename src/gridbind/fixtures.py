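"""Built-in rigid molecules so the whole pipeline runs with no downloads.

``water_like`` is a rigid three-site water: O–H bond 0.09572 nm, H–O–H
angle 104.52 deg, charges (-0.834, +0.417, +0.417) e and Lennard-Jones
parameters on the oxygen only (sigma = 0.31506 nm, epsilon = 0.63627
kJ/mol) — the standard three-site water constants.  ``dipole_pair`` is a
two-site dumbbell carrying opposite charges and LJ spheres on both sites.
``random_rigid`` draws a reproducible random rigid cluster for stress
tests.
"""

from __future__ import annotations

import numpy as np

from gridbind.configurations import RigidMolecule

__all__ = ["make_fixture", "water_like", "dipole_pair", "random_rigid"]


def water_like() -> RigidMolecule:
    """Rigid three-site water (net charge zero)."""
    bond = 0.09572  # nm
    angle = np.deg2rad(104.52)
    h1 = bond * np.array([np.sin(angle / 2), 0.0, np.cos(angle / 2)])
    h2 = bond * np.array([-np.sin(angle / 2), 0.0, np.cos(angle / 2)])
    return RigidMolecule(
        names=["O", "H1", "H2"],
        coords=np.array([[0.0, 0.0, 0.0], h1, h2]),
        masses=np.array([15.999, 1.008, 1.008]),
        charges=np.array([-0.834, 0.417, 0.417]),
        sigmas=np.array([0.31506, 0.0, 0.0]),
        epsilons=np.array([0.63627, 0.0, 0.0]),
    )


def dipole_pair() -> RigidMolecule:
    """Two-site dumbbell: +-0.5 e separated by 0.2 nm, LJ on both sites."""
    return RigidMolecule(
        names=["P", "N"],
        coords=np.array([[0.0, 0.0, 0.1], [0.0, 0.0, -0.1]]),
        masses=np.array([20.0, 20.0]),
        charges=np.array([0.5, -0.5]),
        sigmas=np.array([0.3, 0.3]),
        epsilons=np.array([0.5, 0.5]),
    )


def random_rigid(seed: int = 0, n_atoms: int = 5) -> RigidMolecule:
    """Random rigid cluster with random nonbonded parameters (seeded)."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=0.1, size=(n_atoms, 3))
    charges = rng.normal(scale=0.3, size=n_atoms)
    charges -= charges.mean()  # neutral overall
    return RigidMolecule(
        names=[f"X{i}" for i in range(n_atoms)],
        coords=coords,
        masses=rng.uniform(1.0, 16.0, size=n_atoms),
        charges=charges,
        sigmas=rng.uniform(0.25, 0.35, size=n_atoms),
        epsilons=rng.uniform(0.1, 1.0, size=n_atoms),
    )


def make_fixture(name: str, seed: int = 0) -> RigidMolecule:
    """Fixture molecule by name: water_like, dipole_pair or random_rigid."""
    if name == "water_like":
        return water_like()
    if name == "dipole_pair":
        return dipole_pair()
    if name == "random_rigid":
        return random_rigid(seed=seed)
    raise ValueError(f"unknown fixture {name!r}")
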