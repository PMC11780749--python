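"""End-to-end pipeline and metastable-state analysis.

The dominant eigenvectors of the rate matrix span the slow subspace of
the dynamics; k-means clustering in that subspace partitions the grid
cells into metastable sets.  Clustering uses the probability-weighted
(left) form phi_i = diag(pi) psi_i: weighting by the stationary
distribution collapses the vast low-probability background of a uniform
configuration-space grid onto a single point in eigenvector space, so it
collects into one large cluster while the binding minima and transition
regions split off as small clusters.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("gridbind")

__all__ = [
    "ClusterResult",
    "cluster_eigenvectors",
    "top_populated_cells",
    "run_pipeline",
    "PIPELINE_DEFAULTS",
]


@dataclass
class ClusterResult:
    """k-means partition of grid cells in eigenvector space."""

    labels: np.ndarray  # (N_d,) cluster label per cell
    populations: np.ndarray  # (k,) cells per cluster
    representatives: np.ndarray  # (k,) one cell index per cluster
    inertia: float

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    @property
    def largest_fraction(self) -> float:
        return float(self.populations.max() / self.populations.sum())


def cluster_eigenvectors(
    psi: np.ndarray,
    k: int = 12,
    seed: int = 0,
    n_init: int = 10,
    pi: np.ndarray | None = None,
) -> ClusterResult:
    """k-means clustering of grid cells in the space of right eigenvectors.

    ``psi`` is an ``(N_d, m)`` matrix whose columns are the dominant right
    eigenvectors (m >= 2; the constant stationary eigenvector merely
    shifts all points and is harmless).  Deterministic for a given seed.
    Representatives are the most probable member cells when ``pi`` is
    given, otherwise the members closest to the cluster centroids.
    """
    from sklearn.cluster import KMeans

    psi = np.asarray(psi, dtype=float)
    if psi.ndim != 2 or psi.shape[1] < 2:
        raise ValueError("need at least two eigenvector columns")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(psi)
    populations = np.bincount(labels, minlength=k)
    reps = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:
            reps[c] = -1
            continue
        if pi is not None:
            reps[c] = members[np.argmax(pi[members])]
        else:
            dist = np.linalg.norm(psi[members] - km.cluster_centers_[c], axis=1)
            reps[c] = members[np.argmin(dist)]
    return ClusterResult(
        labels=labels,
        populations=populations,
        representatives=reps,
        inertia=float(km.inertia_),
    )


def top_populated_cells(values: np.ndarray, n: int = 30, sign: str = "positive"):
    """Cell indices with the ``n`` most positive / most negative / largest-
    magnitude entries of a stationary distribution or eigenvector.

    Ties are broken by cell index (lower index first).
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    if sign == "positive":
        key = -values
    elif sign == "negative":
        key = values
    elif sign == "absolute":
        key = -np.abs(values)
    else:
        raise ValueError(f"unknown sign criterion {sign!r}")
    order = np.lexsort((np.arange(len(values)), key))
    return order[:n]


# ---------------------------------------------------------------------------
# pipeline

PIPELINE_DEFAULTS: dict = {
    "r_min": 0.2,  # nm
    "r_max": 0.4,  # nm
    "n_r": 10,
    "n_s": 80,
    "n_o": 80,
    "alpha": 1.0,
    "temperature": 300.0,  # K
    "tau_c": 0.1,  # ps
    "mass": None,  # u; default: total mass of molecule B
    "diffusion": None,  # nm^2/ps; overrides tau_c/mass when set
    "energy_cap": 500.0,  # kJ/mol
    "n_eigenvectors": 6,
    "k_clusters": 12,
    "mc_samples": 5000,
    "seed": 0,
    "molecule_a": "water_like",
    "molecule_b": "water_like",
    "energy_table": None,  # path to an external per-cell energy TSV
    "side_angle": "center",
    "outdir": None,
}


@dataclass
class PipelineResult:
    """Everything the pipeline produced, ready for inspection or export."""

    config: dict
    grid: object
    trajectory: object
    energies: object
    rate_matrix: object
    spectrum: object
    clusters: ClusterResult
    timings: dict = field(default_factory=dict)


def _load_molecule(spec, seed):
    from gridbind.configurations import read_structure
    from gridbind.fixtures import make_fixture

    if spec in ("water_like", "dipole_pair", "random_rigid"):
        return make_fixture(spec, seed=seed)
    return read_structure(spec)


def run_pipeline(config: dict | None = None, **overrides) -> PipelineResult:
    """Grid -> geometry -> pseudotrajectory -> energies -> rate matrix ->
    spectrum -> clusters, with plain-text artifacts when ``outdir`` is set.

    The configuration is validated before any computation; every random
    stage derives its seed from ``config["seed"]``, so reruns with the
    same configuration are bit-reproducible.
    """
    from gridbind.configurations import generate_pseudotrajectory
    from gridbind.energy import evaluate_grid, read_energy_table
    from gridbind.se3_grid import build_se3_grid, export_cells, export_edges
    from gridbind.sqra import SqRAParams, build_rate_matrix, eigendecompose

    cfg = dict(PIPELINE_DEFAULTS)
    cfg.update(config or {})
    cfg.update(overrides)
    unknown = set(cfg) - set(PIPELINE_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("n_r", "n_s", "n_o"):
        if int(cfg[key]) < 1:
            raise ValueError(f"{key} must be a positive integer")
    if not (0 < cfg["r_min"] <= cfg["r_max"]):
        raise ValueError("require 0 < r_min <= r_max")

    timings: dict = {}

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0
                logger.info("stage=%s wall_s=%.2f", name, timings[name])

        return _Timer()

    mol_a = _load_molecule(cfg["molecule_a"], cfg["seed"])
    mol_b = _load_molecule(cfg["molecule_b"], cfg["seed"] + 1)

    with _stage("grid"):
        grid = build_se3_grid(
            cfg["r_min"],
            cfg["r_max"],
            int(cfg["n_r"]),
            int(cfg["n_s"]),
            int(cfg["n_o"]),
            alpha=cfg["alpha"],
            mc_samples=int(cfg["mc_samples"]),
            seed=int(cfg["seed"]),
            side_angle=cfg["side_angle"],
        )
    with _stage("pseudotrajectory"):
        traj = generate_pseudotrajectory(grid, mol_a, mol_b)
    with _stage("energies"):
        if cfg["energy_table"] is not None:
            energies = read_energy_table(cfg["energy_table"], n_cells=grid.n_cells)
        else:
            energies = evaluate_grid(grid, mol_a, mol_b)
    mass = cfg["mass"] if cfg["mass"] is not None else traj.molecule_b.total_mass
    params = SqRAParams(
        temperature=cfg["temperature"],
        diffusion=cfg["diffusion"],
        tau_c=cfg["tau_c"] if cfg["diffusion"] is None else None,
        mass=mass if cfg["diffusion"] is None else None,
        energy_cap=cfg["energy_cap"],
    )
    with _stage("rate_matrix"):
        rate = build_rate_matrix(grid, energies, params)
    with _stage("spectrum"):
        spectrum = eigendecompose(rate, k=int(cfg["n_eigenvectors"]))
    with _stage("clusters"):
        phi = spectrum.phi[:, : int(cfg["n_eigenvectors"])]
        phi = phi / np.linalg.norm(phi, axis=0, keepdims=True)
        clusters = cluster_eigenvectors(
            phi,
            k=int(cfg["k_clusters"]),
            seed=int(cfg["seed"]),
            pi=spectrum.pi,
        )

    if cfg["outdir"] is not None:
        import os

        from gridbind.energy import write_energy_table
        from gridbind.sqra import export_rate_matrix

        out = cfg["outdir"]
        os.makedirs(out, exist_ok=True)
        with _stage("export"):
            export_cells(grid, os.path.join(out, "cells.tsv"))
            export_edges(grid, os.path.join(out, "edges.tsv"))
            write_energy_table(energies, os.path.join(out, "energies.tsv"))
            export_rate_matrix(rate, os.path.join(out, "rate_matrix.tsv"))
            _export_spectrum(spectrum, os.path.join(out, "spectrum.tsv"))
            _export_clusters(clusters, os.path.join(out, "clusters.tsv"))
    return PipelineResult(
        config=cfg,
        grid=grid,
        trajectory=traj,
        energies=energies,
        rate_matrix=rate,
        spectrum=spectrum,
        clusters=clusters,
        timings=timings,
    )


def _export_spectrum(spectrum, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("index\tkappa_per_ps\timplied_timescale_ps\n")
        for i, kap in enumerate(spectrum.kappa):
            its = -1.0 / kap if kap < -1e-15 else float("inf")
            fh.write(f"{i}\t{kap:.12g}\t{its:.12g}\n")


def _export_clusters(clusters: ClusterResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cell_index\tcluster\n")
        for i, lab in enumerate(clusters.labels):
            fh.write(f"{i}\t{lab}\n")
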