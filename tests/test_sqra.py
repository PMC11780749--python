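"""SqRA rate matrix: assembly, stationary distribution, spectrum."""

import numpy as np
import pytest
import scipy.sparse as sp

from gridbind.energy import EnergyTable
from gridbind.se3_grid import GridGeometry, chain_geometry
from gridbind.sqra import (
    BOLTZMANN_KJ_MOL_K,
    SqRAParams,
    build_rate_matrix,
    detailed_balance_residual,
    eigendecompose,
    implied_timescales,
    rate_to_transition,
    stationary_distribution,
)


def _two_cell(dv=0.0, kbt_multiple=None, temperature=300.0):
    geom = GridGeometry(
        edges=[[0, 1]], h=[1.0], S=[1.0], volumes=[1.0, 1.0]
    )
    if kbt_multiple is not None:
        dv = kbt_multiple * BOLTZMANN_KJ_MOL_K * temperature
    energies = EnergyTable([0.0, dv])
    params = SqRAParams(temperature=temperature, diffusion=1.0)
    return build_rate_matrix(geom, energies, params)


def _random_geometry(n, seed):
    """Random connected geometry with positive h, S, V."""
    rng = np.random.default_rng(seed)
    chain = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    extra = rng.integers(0, n, size=(n, 2))
    extra = extra[extra[:, 0] != extra[:, 1]]
    edges = np.unique(
        np.sort(np.vstack([chain, extra]), axis=1), axis=0
    )
    return GridGeometry(
        edges=edges,
        h=rng.uniform(0.5, 2.0, len(edges)),
        S=rng.uniform(0.5, 2.0, len(edges)),
        volumes=rng.uniform(0.5, 2.0, n),
    )


class TestParams:
    def test_diffusion_from_friction_and_mass(self):
        p = SqRAParams(temperature=300.0, tau_c=0.1, mass=18.0)
        assert p.diffusion == pytest.approx(
            BOLTZMANN_KJ_MOL_K * 300.0 * 0.1 / 18.0
        )

    def test_requires_one_specification(self):
        with pytest.raises(ValueError):
            SqRAParams(temperature=300.0)
        with pytest.raises(ValueError):
            SqRAParams(temperature=-1.0, diffusion=1.0)


class TestBuildRateMatrix:
    def test_two_cell_flat(self):
        rate = _two_cell()
        assert np.allclose(rate.Q.toarray(), [[-1, 1], [1, -1]])

    def test_row_sums_zero(self, tiny_water_rate):
        q = tiny_water_rate.Q
        rowsum = np.asarray(q.sum(axis=1)).ravel()
        scale = np.abs(q.diagonal()).max()
        assert np.abs(rowsum).max() < 1e-12 * scale

    def test_off_diagonal_nonnegative(self, tiny_water_rate):
        coo = tiny_water_rate.Q.tocoo()
        off = coo.row != coo.col
        assert np.all(coo.data[off] >= 0)

    def test_detailed_balance(self, tiny_water_rate, flat_tiny_rate):
        assert detailed_balance_residual(tiny_water_rate) < 1e-10
        assert detailed_balance_residual(flat_tiny_rate) < 1e-10

    def test_flat_potential_stationary_proportional_to_volumes(
        self, tiny_grid, flat_tiny_rate
    ):
        # oracle: solve pi Q = 0 directly and compare with the volumes
        pi_null = stationary_distribution(flat_tiny_rate.Q)
        vols = tiny_grid.volumes / tiny_grid.volumes.sum()
        assert np.allclose(pi_null, vols, atol=1e-8)
        assert np.allclose(flat_tiny_rate.pi, vols, atol=1e-12)

    def test_energy_length_mismatch_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            build_rate_matrix(
                tiny_grid,
                EnergyTable(np.zeros(5)),
                SqRAParams(temperature=300, diffusion=1.0),
            )

    def test_chain_matches_tridiagonal_toeplitz(self):
        n, a, d = 12, 0.05, 0.7
        rate = build_rate_matrix(
            chain_geometry(n, a),
            EnergyTable(np.zeros(n)),
            SqRAParams(temperature=300.0, diffusion=d),
        )
        q = rate.Q.toarray()
        assert np.allclose(q[0, 1], d / a**2)
        spec = eigendecompose(rate, k=n - 2)
        exact = -2 * d / a**2 * (1 - np.cos(np.arange(n - 1) * np.pi / n))
        assert np.abs(spec.kappa - exact).max() < 1e-10


class TestStationaryDistribution:
    def test_two_cell_boltzmann_ratio(self):
        rate = _two_cell(kbt_multiple=np.log(2.0))
        assert np.allclose(rate.pi, [2 / 3, 1 / 3])
        assert np.allclose(stationary_distribution(rate.Q), [2 / 3, 1 / 3])

    def test_closed_form_vs_nullspace_random_system(self):
        geom = _random_geometry(50, seed=8)
        rng = np.random.default_rng(9)
        energies = EnergyTable(rng.uniform(-5, 5, 50))
        params = SqRAParams(temperature=300.0, diffusion=0.3)
        rate = build_rate_matrix(geom, energies, params)
        kbt = params.kbt
        w = geom.volumes * np.exp(-(energies.energies - energies.energies.min()) / kbt)
        assert np.allclose(rate.pi, w / w.sum(), atol=1e-12)
        assert np.allclose(stationary_distribution(rate.Q), rate.pi, atol=1e-8)

    def test_residual_pi_q_zero(self, tiny_water_rate):
        flux = tiny_water_rate.pi @ tiny_water_rate.Q
        scale = np.abs(tiny_water_rate.pi * tiny_water_rate.Q.diagonal()).max()
        assert np.abs(flux).max() < 1e-10 * scale


class TestEigendecompose:
    def test_stationary_eigenpair(self, flat_tiny_rate):
        spec = eigendecompose(flat_tiny_rate, k=4)
        assert spec.kappa[0] == pytest.approx(0.0, abs=1e-10)
        psi0 = spec.psi[:, 0]
        assert np.allclose(psi0, psi0[0], rtol=1e-8)  # constant vector
        phi0 = spec.phi[:, 0]
        assert np.allclose(
            phi0 / phi0.sum(), flat_tiny_rate.pi, atol=1e-10
        )

    def test_two_cell_closed_form(self):
        spec = eigendecompose(_two_cell(), k=1)
        assert np.allclose(spec.kappa, [0.0, -2.0], atol=1e-12)

    def test_left_right_link(self, tiny_water_rate):
        spec = eigendecompose(tiny_water_rate, k=4)
        assert np.allclose(
            spec.phi, spec.pi[:, None] * spec.psi, atol=1e-8
        )

    def test_dense_and_sparse_paths_agree(self):
        # same 200-cell system through the dense path and the
        # shift-invert path
        geom = _random_geometry(200, seed=3)
        rng = np.random.default_rng(4)
        rate = build_rate_matrix(
            geom,
            EnergyTable(rng.uniform(-3, 3, 200)),
            SqRAParams(temperature=300.0, diffusion=1.0),
        )
        import gridbind.sqra as sqra_mod

        dense = eigendecompose(rate, k=4)
        old = sqra_mod._DENSE_LIMIT
        try:
            sqra_mod._DENSE_LIMIT = 10
            sparse = eigendecompose(rate, k=4)
        finally:
            sqra_mod._DENSE_LIMIT = old
        assert np.abs(dense.kappa - sparse.kappa).max() < 1e-8

    def test_non_reversible_rejected(self):
        from gridbind.sqra import RateMatrix

        q = sp.csr_matrix(
            np.array([[-1.0, 1.0, 0.0], [0.1, -0.2, 0.1], [0.0, 2.0, -2.0]])
        )
        rate = RateMatrix(Q=q, pi=np.full(3, 1 / 3))
        with pytest.raises(ValueError):
            eigendecompose(rate, k=1)


class TestRateToTransition:
    def test_zero_lag_is_identity(self, flat_tiny_rate):
        assert np.allclose(rate_to_transition(flat_tiny_rate, 0.0), np.eye(288))

    def test_two_cell_eigenvalue(self):
        rate = _two_cell()
        tau = np.log(2.0) / 2.0
        t = rate_to_transition(rate, tau)
        lams = np.sort(np.linalg.eigvals(t).real)
        assert lams[0] == pytest.approx(0.5, abs=1e-12)

    def test_rows_stochastic_and_spectral_map(self, flat_tiny_rate):
        tau = 3.7
        t = rate_to_transition(flat_tiny_rate, tau)
        assert np.allclose(t.sum(axis=1), 1.0, atol=1e-10)
        assert t.min() > -1e-12
        spec = eigendecompose(flat_tiny_rate, k=4)
        lam = np.sort(np.linalg.eigvals(t).real)[::-1][:5]
        assert np.allclose(lam, np.exp(spec.kappa * tau), atol=1e-8)

    def test_eigenvector_subspace_shared(self):
        # oracle: matrix exponential must preserve the slow subspace
        geom = _random_geometry(100, seed=6)
        rng = np.random.default_rng(7)
        rate = build_rate_matrix(
            geom,
            EnergyTable(rng.uniform(-2, 2, 100)),
            SqRAParams(temperature=300.0, diffusion=1.0),
        )
        spec = eigendecompose(rate, k=3)
        t = rate_to_transition(rate, 0.8)
        from scipy.linalg import subspace_angles

        w, v = np.linalg.eig(t)
        top = v[:, np.argsort(w.real)[::-1][:4]].real
        angles = subspace_angles(spec.psi[:, :4], top)
        assert angles.max() < 1e-6

    def test_probability_conservation(self, tiny_water_rate):
        # exp(Q tau) 1 = 1 via the action of Q on the constant vector
        ones = np.ones(tiny_water_rate.n_cells)
        scale = np.abs(tiny_water_rate.Q.diagonal()).max()
        assert np.abs(tiny_water_rate.Q @ ones).max() < 1e-12 * scale


class TestImpliedTimescales:
    def test_reciprocal_rule(self):
        from gridbind.sqra import Spectrum

        spec = Spectrum(
            kappa=np.array([0.0, -1.0, -4.0]),
            psi=np.zeros((3, 3)),
            pi=np.full(3, 1 / 3),
        )
        assert np.allclose(implied_timescales(spec), [1.0, 0.25])

    def test_scaling_with_diffusion(self):
        n = 30
        rng = np.random.default_rng(12)
        energies = EnergyTable(rng.uniform(-2, 2, n))
        geom = chain_geometry(n, 0.1)
        base = eigendecompose(
            build_rate_matrix(
                geom, energies, SqRAParams(temperature=300.0, diffusion=0.5)
            ),
            k=4,
        )
        scaled = eigendecompose(
            build_rate_matrix(
                geom, energies, SqRAParams(temperature=300.0, diffusion=1.5)
            ),
            k=4,
        )
        assert np.allclose(
            implied_timescales(base), 3.0 * implied_timescales(scaled)
        )

    def test_friction_span_scales_timescales(self):
        # t_i proportional to 1/D = M / (kB T tau_c): sweeping tau_c over
        # three decades rescales every timescale exactly
        n = 30
        rng = np.random.default_rng(13)
        energies = EnergyTable(rng.uniform(-2, 2, n))
        geom = chain_geometry(n, 0.1)
        products = []
        for tau_c in (0.001, 0.01, 0.1, 1.0):
            spec = eigendecompose(
                build_rate_matrix(
                    geom,
                    energies,
                    SqRAParams(temperature=300.0, tau_c=tau_c, mass=18.0),
                ),
                k=3,
            )
            products.append(implied_timescales(spec) * tau_c)
        for prod in products[1:]:
            assert np.allclose(prod, products[0], rtol=1e-8)


class TestContinuumLimit:
    def test_flat_chain_reaches_diffusion_spectrum(self):
        # slowest relaxation rate of reflecting diffusion on [0, L]:
        # kappa_1 = -D pi^2 / L^2
        n, a, d = 64, 0.02, 0.35
        length = n * a
        rate = build_rate_matrix(
            chain_geometry(n, a),
            EnergyTable(np.zeros(n)),
            SqRAParams(temperature=300.0, diffusion=d),
        )
        spec = eigendecompose(rate, k=1)
        continuum = -d * np.pi**2 / length**2
        assert spec.kappa[1] == pytest.approx(continuum, rel=0.02)
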