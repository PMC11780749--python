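"""Square-root-approximation rate matrix and its spectral analysis.

For overdamped isotropic diffusion with diffusion constant D, the
discretized Fokker–Planck generator on a Voronoi grid has the pairwise
rates

    Q_ab = D * S_ab / (h_ab * V_a) * sqrt(pi_b / pi_a)
         = D * S_ab / (h_ab * V_a) * exp(-(V_b - V_a) / (2 kB T))

between adjacent cells a ~ b, where h is the center-to-center distance, S
the interface area, V_a the cell volume and V_a/V_b the cell energies in
the Boltzmann factor.  The diagonal makes row sums vanish.  The square
root of the Boltzmann ratio enforces detailed balance with respect to the
stationary distribution pi_a ∝ V_a exp(-V_eff(x_a) / kB T), so the
spectrum is real and the generator can be symmetrized by the similarity
transform diag(pi)^{1/2} Q diag(pi)^{-1/2}.

The rate matrix relates to a Markov-state-model transition matrix through
P(tau) = exp(Q tau): identical eigenvectors, eigenvalues linked by
lambda_i = exp(kappa_i tau), implied timescales t_i = -1/kappa_i =
-tau/ln(lambda_i).

Units: nm, ps, kJ/mol, K.  Energy differences are capped (default
500 kJ/mol) before exponentiation; rates across such interfaces are
numerically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from gridbind.energy import DEFAULT_ENERGY_CAP, EnergyTable, cap_energy_difference

__all__ = [
    "BOLTZMANN_KJ_MOL_K",
    "SqRAParams",
    "RateMatrix",
    "Spectrum",
    "build_rate_matrix",
    "stationary_distribution",
    "eigendecompose",
    "rate_to_transition",
    "implied_timescales",
    "export_rate_matrix",
]

#: Boltzmann (gas) constant in kJ / (mol K)
BOLTZMANN_KJ_MOL_K = 0.00831446

#: dense eigensolver below this size, sparse Lanczos above
_DENSE_LIMIT = 2000

#: sparse-LU shift-invert below this size, preconditioned CG above
_LU_LIMIT = 25000


@dataclass
class SqRAParams:
    """Physical parameters of the rate model.

    Either give the diffusion constant ``diffusion`` [nm^2/ps] directly or
    give a friction coupling time ``tau_c`` [ps] and effective mass
    ``mass`` [u], from which ``D = kB T tau_c / M``.  A single scalar D
    drives both translational and rotational moves (isotropic-diffusion
    assumption).
    """

    temperature: float = 300.0  # K
    diffusion: float | None = None  # nm^2 / ps
    tau_c: float | None = None  # ps
    mass: float | None = None  # u
    energy_cap: float = DEFAULT_ENERGY_CAP  # kJ/mol

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.diffusion is None:
            if self.tau_c is None or self.mass is None:
                raise ValueError(
                    "give either diffusion or both tau_c and mass"
                )
            self.diffusion = (
                BOLTZMANN_KJ_MOL_K * self.temperature * self.tau_c / self.mass
            )
        if self.diffusion <= 0:
            raise ValueError("diffusion constant must be positive")

    @property
    def kbt(self) -> float:
        return BOLTZMANN_KJ_MOL_K * self.temperature


@dataclass
class Spectrum:
    """Leading eigenpairs of a reversible rate matrix.

    Eigenvalues ``kappa`` [1/ps] are sorted descending (kappa_0 = 0
    first).  Right eigenvectors ``psi`` (columns) are normalized so that
    ``psi_i^T diag(pi) psi_j = delta_ij``; left eigenvectors are
    ``phi_i = diag(pi) psi_i``.
    """

    kappa: np.ndarray
    psi: np.ndarray  # (n, k) right eigenvectors, columns
    pi: np.ndarray

    @property
    def phi(self) -> np.ndarray:
        return self.pi[:, None] * self.psi


@dataclass
class RateMatrix:
    """Sparse SqRA generator with zero row sums and detailed balance."""

    Q: sp.csr_matrix  # 1/ps
    pi: np.ndarray  # stationary distribution, sums to 1
    params: SqRAParams | None = None
    spectrum: Spectrum | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return self.Q.shape[0]


def build_rate_matrix(grid, energies: EnergyTable, params: SqRAParams) -> RateMatrix:
    """Assemble the SqRA rate matrix from grid geometry and cell energies.

    The numerical guard against overflowing Boltzmann factors clips cell
    energies at (minimum finite energy + ``params.energy_cap``) before
    differencing — clash sentinels (``+inf``) land exactly at the clipped
    maximum.  Every pairwise difference is then within the cap, uphill
    rates across a full-cap interface are ~e^-100 (numerically zero), and,
    unlike capping the differences themselves, the generator stays exactly
    reversible with respect to the clipped Boltzmann distribution.  The
    stationary distribution is evaluated in closed form from volumes and
    clipped energies.
    """
    n = grid.n_cells
    if len(energies) != n:
        raise ValueError(
            f"energy table has {len(energies)} entries, grid has {n} cells"
        )
    v_raw = energies.energies
    finite = np.isfinite(v_raw)
    if not np.any(finite):
        raise ValueError("all cell energies are infinite")
    v_eff = np.minimum(v_raw, v_raw[finite].min() + params.energy_cap)
    edges = grid.edges
    a, b = edges[:, 0], edges[:, 1]
    dv = cap_energy_difference(v_eff[b] - v_eff[a], params.energy_cap)
    geom = params.diffusion * grid.S / grid.h
    two_kbt = 2.0 * params.kbt
    rate_ab = geom / grid.volumes[a] * np.exp(-dv / two_kbt)
    rate_ba = geom / grid.volumes[b] * np.exp(dv / two_kbt)

    rows = np.concatenate([a, b])
    cols = np.concatenate([b, a])
    vals = np.concatenate([rate_ab, rate_ba])
    q = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    q.setdiag(-np.asarray(q.sum(axis=1)).ravel())
    pi = _analytic_stationary(grid.volumes, v_eff, params.kbt)
    return RateMatrix(Q=q.tocsr(), pi=pi, params=params)


def _analytic_stationary(volumes, v_eff, kbt) -> np.ndarray:
    # subtract the minimum finite energy before exponentiating
    finite = np.isfinite(v_eff)
    if not np.any(finite):
        raise ValueError("all cell energies are infinite")
    shifted = v_eff - v_eff[finite].min()
    w = np.where(finite, volumes * np.exp(-shifted / kbt), 0.0)
    return w / w.sum()


def stationary_distribution(rate: RateMatrix | sp.spmatrix, method: str = "auto"):
    """Stationary distribution pi with pi Q = 0 and sum(pi) = 1.

    ``method="analytic"`` returns the closed form stored on a
    :class:`RateMatrix`; ``"nullspace"`` solves for the null vector of Q^T
    (dense, for matrices below a few thousand cells); ``"auto"`` prefers
    the analytic form when available.
    """
    if isinstance(rate, RateMatrix):
        if method in ("auto", "analytic"):
            return rate.pi
        q = rate.Q
    else:
        if method == "analytic":
            raise ValueError("analytic stationary distribution needs a RateMatrix")
        q = rate
    n = q.shape[0]
    if n > _DENSE_LIMIT:
        raise ValueError(
            "null-space solve is dense-only; use the analytic form for "
            f"matrices larger than {_DENSE_LIMIT}"
        )
    dense = q.toarray() if sp.issparse(q) else np.asarray(q, dtype=float)
    w, vl = scipy.linalg.eig(dense.T)
    i0 = np.argmin(np.abs(w))
    pi = np.real(vl[:, i0])
    pi = np.abs(pi)
    return pi / pi.sum()


def detailed_balance_residual(rate: RateMatrix) -> float:
    """max |pi_a Q_ab - pi_b Q_ba| relative to max |pi_a Q_ab| (off-diag)."""
    q = rate.Q.tocoo()
    off = q.row != q.col
    flux = sp.coo_matrix(
        (rate.pi[q.row[off]] * q.data[off], (q.row[off], q.col[off])),
        shape=rate.Q.shape,
    ).tocsr()
    diff = flux - flux.T
    num = np.abs(diff.data).max() if diff.nnz else 0.0
    den = np.abs(flux.data).max() if flux.nnz else 1.0
    return float(num / den)


def _shift_invert_operator(q_sym: sp.csr_matrix, sigma: float):
    """Accurate applications of (Q_sym - sigma I)^-1 for huge-range spectra.

    The shifted matrix is symmetrically equilibrated to unit diagonal
    before factorization / iteration: with rate scales spanning tens of
    orders of magnitude (energy-capped Boltzmann factors), an
    unequilibrated solve loses the slow subspace to round-off.  Below
    ``_LU_LIMIT`` cells a sparse LU of the scaled matrix is cheap; above,
    a Jacobi-preconditioned conjugate gradient on the (negated, SPD)
    system is used instead, whose effective condition number is that of
    the equilibrated operator.
    """
    n = q_sym.shape[0]
    a = (q_sym - sigma * sp.eye(n)).tocsc()
    d = np.sqrt(-a.diagonal())
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("shifted symmetrized generator is not negative-diagonal")
    d_inv = 1.0 / d
    if n <= _LU_LIMIT:
        scaled = (sp.diags(d_inv) @ a @ sp.diags(d_inv)).tocsc()
        lu = spla.splu(
            scaled,
            permc_spec="MMD_AT_PLUS_A",
            options=dict(SymmetricMode=True, DiagPivotThresh=0.001),
        )

        def solve(b):
            return d_inv * lu.solve(b * d_inv)

    else:
        spd = (-a).tocsr()
        jacobi = spla.LinearOperator((n, n), matvec=lambda b: (d_inv**2) * b)

        def solve(b):
            x, info = spla.cg(
                spd, -b, rtol=1e-12, atol=0.0, maxiter=50000, M=jacobi
            )
            if info != 0:
                raise RuntimeError(
                    f"inner CG failed to converge (info={info})"
                )
            return x

    return spla.LinearOperator((n, n), matvec=solve)


def eigendecompose(
    rate: RateMatrix,
    k: int = 6,
    tol: float = 0.0,
    balance_tol: float = 1e-8,
) -> Spectrum:
    """Leading eigenpairs of the rate matrix (kappa closest to zero).

    The computation runs on the symmetric similarity transform
    ``diag(pi)^{1/2} Q diag(pi)^{-1/2}`` for numerical stability, which
    requires detailed balance; a residual above ``balance_tol`` raises.
    Small well-conditioned matrices are solved densely; otherwise a
    shift-invert Lanczos iteration with equilibrated solves extracts the
    slow end of the spectrum, which for energy-capped systems lies tens
    of orders of magnitude below the fastest escape rates.  The result is
    cached on ``rate.spectrum``.
    """
    resid = detailed_balance_residual(rate)
    if resid > balance_tol:
        raise ValueError(
            f"rate matrix violates detailed balance (residual {resid:.2e})"
        )
    pi = rate.pi
    sqrt_pi = np.sqrt(pi)
    inv_sqrt = 1.0 / sqrt_pi
    n = rate.n_cells
    k = min(k, n - 1)
    q_sym = sp.diags(sqrt_pi) @ rate.Q @ sp.diags(inv_sqrt)
    q_sym = (0.5 * (q_sym + q_sym.T)).tocsr()  # remove round-off asymmetry
    diag = -q_sym.diagonal()
    dynamic_range = diag.max() / max(diag[diag > 0].min(), 1e-300)
    if n <= k + 2 or (n <= _DENSE_LIMIT and dynamic_range < 1e8):
        w, y = scipy.linalg.eigh(q_sym.toarray())
        w, y = w[::-1][: k + 1], y[:, ::-1][:, : k + 1]
    else:
        # shift slightly above 0 (all kappa <= 0): the slow spectrum is
        # separated from the fast escape rates by the inverse transform
        sigma = 1e-10 * max(diag[diag > 0].min(), 1e-20)
        sigma = min(sigma, 1e-10)
        op = _shift_invert_operator(q_sym, sigma)
        w, y = spla.eigsh(
            q_sym,
            k=k + 1,
            sigma=sigma,
            which="LM",
            OPinv=op,
            v0=sqrt_pi,
            tol=tol,
        )
        order = np.argsort(w)[::-1]
        w, y = w[order], y[:, order]
    psi = inv_sqrt[:, None] * y
    # fix signs deterministically: largest-magnitude entry positive
    for i in range(psi.shape[1]):
        j = np.argmax(np.abs(psi[:, i]))
        if psi[j, i] < 0:
            psi[:, i] = -psi[:, i]
            y[:, i] = -y[:, i]
    spec = Spectrum(kappa=w, psi=psi, pi=pi)
    rate.spectrum = spec
    return spec


def rate_to_transition(rate: RateMatrix | sp.spmatrix, tau: float):
    """MSM transition matrix ``P(tau) = exp(Q tau)`` (row-stochastic)."""
    if tau < 0:
        raise ValueError("lag time must be non-negative")
    q = rate.Q if isinstance(rate, RateMatrix) else rate
    n = q.shape[0]
    if tau == 0:
        return np.eye(n)
    dense = q.toarray() if sp.issparse(q) else np.asarray(q, dtype=float)
    if n > _DENSE_LIMIT:
        raise ValueError("dense matrix exponential limited to small grids")
    return scipy.linalg.expm(dense * tau)


def implied_timescales(spectrum: Spectrum | np.ndarray) -> np.ndarray:
    """Relaxation timescales ``t_i = -1 / kappa_i`` [ps].

    The stationary eigenvalue kappa_0 = 0 is excluded; the result is
    positive and descending.
    """
    kappa = spectrum.kappa if isinstance(spectrum, Spectrum) else np.asarray(spectrum)
    kappa = np.sort(kappa)[::-1][1:]  # drop the stationary eigenvalue
    return -1.0 / kappa[kappa < 0]


def export_rate_matrix(rate: RateMatrix, path: str) -> None:
    """Sparse coordinate text dump: row, col, value with a metadata header."""
    coo = rate.Q.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# n_cells: {rate.n_cells}\n")
        if rate.params is not None:
            fh.write(
                f"# temperature_K: {rate.params.temperature} "
                f"diffusion_nm2_ps: {rate.params.diffusion}\n"
            )
        fh.write("row\tcol\tvalue\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{v:.12g}\n")
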