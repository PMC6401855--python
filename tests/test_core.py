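"""Field equations and solver: profiles, fractions, weights, invariants."""

import numpy as np
import pytest

from oligobrush import (
    BindingConstants,
    ChainGeometry,
    FieldState,
    Grid,
    build_sequence,
    generate_ensemble,
    solve_bulk,
)
from oligobrush.chains import ConformationEnsemble
from oligobrush.core import (
    SCFTProblem,
    grand_potential_per_area,
    residual_vector,
    solve_fields,
    solve_state_point,
)
from oligobrush.oracles import default_toy


@pytest.fixture(scope="module")
def toy_problem():
    return default_toy(with_mg=True).problem()


# ------------------------------------------------------------- densities
def test_zero_fields_recover_bulk(toy_problem):
    rho = toy_problem.species_densities(FieldState.zeros(toy_problem.grid))
    for s in ("w", "H", "OH", "Na", "Mg", "Cl"):
        np.testing.assert_allclose(rho[s], toy_problem.bulk.rho[s], rtol=1e-14)


def test_boltzmann_factors_carry_valence_and_volume(toy_problem):
    grid = toy_problem.grid
    f = FieldState.zeros(grid)
    f.psi[1] = 1.0
    rho = toy_problem.species_densities(f)
    b = toy_problem.bulk.rho
    assert rho["Mg"][1] / b["Mg"] == pytest.approx(np.exp(-2.0), rel=1e-12)
    assert rho["Cl"][1] / b["Cl"] == pytest.approx(np.exp(+1.0), rel=1e-12)
    assert rho["w"][1] == pytest.approx(b["w"], rel=1e-12)  # water blind to psi
    f2 = FieldState.zeros(grid)
    f2.pi[0] = 2.0
    rho2 = toy_problem.species_densities(f2)
    for s, v in (("w", 0.030), ("Na", 0.05), ("Mg", 0.18)):
        assert rho2[s][0] / b[s] == pytest.approx(np.exp(-2.0 * v), rel=1e-12)


# ------------------------------------------------------------- fractions
def test_fractions_all_constants_zero(toy_problem):
    prob = SCFTProblem(
        toy_problem.ensemble,
        toy_problem.bulk,
        BindingConstants(0, 0, 0, 0, 0, 0),
        sigma_p=0.0,
    )
    f = prob.monomer_fractions(FieldState.zeros(prob.grid))
    np.testing.assert_allclose(f.A["free"], 1.0)
    np.testing.assert_allclose(f.G["free"], 1.0)


def test_henderson_hasselbalch_limit():
    """With only protonation active, the bare fraction obeys 1/(1+10^(pKa-pH))."""
    bulk = solve_bulk(0.010, 0.0, 7.0)
    K = BindingConstants.from_parameters()
    prob = SCFTProblem(
        ConformationEnsemble.from_occupancies(Grid(3, 0.3), [1, 0, 0], [0, 1, 0]),
        bulk,
        BindingConstants(K_AH=K.K_AH, K_GH=K.K_GH, K_ANa=0, K_GNa=0, K_AMg=0, K_GMg=0),
        sigma_p=0.0,
    )
    f = prob.monomer_fractions(FieldState.zeros(prob.grid))
    ratio = f.A["free"] / (f.A["free"] + f.A["H"])
    assert ratio[0] == pytest.approx(1.0 / (1.0 + 10 ** (3.5 - 7.0)), rel=1e-10)


def test_fraction_normalization_everywhere(toy_problem):
    rng = np.random.default_rng(0)
    f = FieldState(
        pi=rng.uniform(-1, 5, toy_problem.grid.n_layers),
        psi=rng.uniform(-3, 3, toy_problem.grid.n_layers),
    )
    fr = toy_problem.monomer_fractions(f)
    for mono in ("A", "G"):
        fm = fr.for_type(mono)
        total = sum(fm[s] for s in ("free", "H", "Na", "Mg"))
        np.testing.assert_allclose(total, 1.0, atol=1e-14)
        assert all((0 <= fm[s]).all() and (fm[s] <= 1).all() for s in fm)


# ------------------------------------------------------- conformation pdf
def test_uniform_fields_give_multiplicity_weights(toy_problem):
    P = toy_problem.conformation_weights(
        FieldState.zeros(toy_problem.grid),
        toy_problem.monomer_fractions(FieldState.zeros(toy_problem.grid)),
    )
    g = toy_problem.ensemble.multiplicity
    np.testing.assert_allclose(P, g / g.sum(), rtol=1e-12)


def test_two_conformation_closed_form():
    """Log-weights {0, ln 3} give probabilities {1/4, 3/4}."""
    grid = Grid(3, 0.3)
    ens = ConformationEnsemble.from_occupancies(grid, [[1, 0, 0], [0, 1, 0]], [[0, 0, 0], [0, 0, 0]])
    bulk = solve_bulk(0.010, 0.0, 7.0)
    prob = SCFTProblem(ens, bulk, BindingConstants(0, 0, 0, 0, 0, 0), sigma_p=0.01)
    # craft fields so conformation 2's single A-monomer gains ln 3:
    # w_A(k) = pi v_p - psi; set psi(1)-psi(0) = ln 3 with pi = 0
    f = FieldState.zeros(grid)
    f.psi[:] = [0.0, np.log(3.0), 0.0]
    fr = prob.monomer_fractions(FieldState.zeros(grid))  # constants are zero
    P = prob.conformation_weights(f, fr)
    np.testing.assert_allclose(P, [0.25, 0.75], rtol=1e-12)
    assert P.sum() == pytest.approx(1.0, abs=1e-12)


def test_monomer_density_arithmetic():
    grid = Grid(3, 0.3)
    ens = ConformationEnsemble.from_occupancies(grid, [[0, 0, 1]], [[0, 0, 0]])
    bulk = solve_bulk(0.010, 0.0, 7.0)
    prob = SCFTProblem(ens, bulk, BindingConstants(0, 0, 0, 0, 0, 0), sigma_p=0.05)
    rho_A, rho_G = prob.average_monomer_densities(np.array([1.0]))
    assert rho_A[2] == pytest.approx(0.05 / 0.3, rel=1e-12)
    assert rho_G.sum() == 0.0


def test_charge_density_cancellations(toy_problem):
    grid = toy_problem.grid
    rho = toy_problem.species_densities(FieldState.zeros(grid))
    zero = np.zeros(grid.n_layers)
    # bulk ions, no polymer: exactly neutral
    q = toy_problem.charge_density(rho, zero, zero, toy_problem.monomer_fractions(FieldState.zeros(grid)))
    np.testing.assert_allclose(q, 0.0, atol=1e-14)
    # f_minus == f_Mg: polymer contributes nothing
    from oligobrush.core import MonomerFractions

    half = np.full(grid.n_layers, 0.5)
    zeros = np.zeros(grid.n_layers)
    fr = MonomerFractions(
        A={"free": half, "H": zeros, "Na": zeros, "Mg": half},
        G={"free": half, "H": zeros, "Na": zeros, "Mg": half},
    )
    q2 = toy_problem.charge_density(rho, np.full(grid.n_layers, 0.02), zero, fr)
    np.testing.assert_allclose(q2, 0.0, atol=1e-14)


# ------------------------------------------------------------- residuals
def test_bulk_is_exact_solution_without_polymer(toy_problem):
    prob = SCFTProblem(
        toy_problem.ensemble, toy_problem.bulk, toy_problem.constants, sigma_p=0.0
    )
    r = residual_vector(FieldState.zeros(prob.grid), prob)
    np.testing.assert_allclose(r, 0.0, atol=1e-12)
    sol = solve_fields(prob)
    assert sol.converged and sol.n_iter <= 2
    for s in sol.rho:
        np.testing.assert_allclose(sol.rho[s], prob.bulk.rho[s], rtol=1e-12)


def test_poisson_block_boundary_closures(toy_problem):
    """Constant psi: zero Laplacian in the interior and at the Neumann wall,
    nonzero at the far Dirichlet edge."""
    n = toy_problem.grid.n_layers
    psi = np.full(n, 0.7)
    r = toy_problem.poisson_residual(psi, np.zeros(n))
    np.testing.assert_allclose(r[:-1], 0.0, atol=1e-14)
    assert r[-1] != 0.0
    # linear psi violates the zero-field wall condition
    r2 = toy_problem.poisson_residual(np.linspace(0, 1, n), np.zeros(n))
    assert r2[0] != 0.0


def test_fd_gradient_of_grand_potential_matches_residual():
    """The scalar potential and the analytic residual are two routes to the
    same stationarity conditions: grad W = dz * residual."""
    from oligobrush.oracles import _fd_gradient

    prob = default_toy(with_mg=True).problem()
    rng = np.random.default_rng(3)
    x = 0.3 * rng.standard_normal(2 * prob.grid.n_layers)
    g = _fd_gradient(prob.grand_potential, x)
    r = prob.residual(x)
    np.testing.assert_allclose(g / prob.grid.dz, r, atol=5e-8)


def test_grand_potential_zero_without_polymer(toy_problem):
    prob = SCFTProblem(
        toy_problem.ensemble, toy_problem.bulk, toy_problem.constants, sigma_p=0.0
    )
    assert grand_potential_per_area(prob, FieldState.zeros(prob.grid)) == pytest.approx(0.0, abs=1e-14)


def test_grand_potential_stationary_at_convergence():
    toy = default_toy()
    prob = toy.problem()
    sol = solve_fields(prob, tol=1e-12)
    assert sol.converged
    W0 = prob.grand_potential(sol.fields.pack())
    eps = 1e-4
    for i in (0, 4):  # one pi layer, one psi layer
        x = sol.fields.pack()
        x[i] += eps
        Wp = prob.grand_potential(x)
        x[i] -= 2 * eps
        Wm = prob.grand_potential(x)
        # first-order change vanishes; curvature remains
        assert abs(Wp - Wm) / (2 * eps) < 1e-9
        assert abs(Wp + Wm - 2 * W0) > 0


# ------------------------------------------------------------- full solves
def test_converged_solution_invariants(solve_cache):
    """Packing, pdf normalization, mass-action consistency and monomer
    conservation at a brush state point."""
    sol = solve_cache(0.005, 0.003)
    prob = sol.problem
    # packing constraint per layer
    phi_free = sum(sol.rho[s] * prob.bulk.catalog.volume[s] for s in sol.rho)
    np.testing.assert_allclose(sol.phi_p + phi_free, 1.0, atol=1e-8)
    # pdf normalization
    assert sol.P.sum() == pytest.approx(1.0, abs=1e-12)
    # monomer conservation: dz * sum rho_i = 12 sigma_p
    total = prob.grid.dz * (sol.rho_A.sum() + sol.rho_G.sum())
    assert total == pytest.approx(12 * prob.sigma_p, rel=1e-10)
    # pointwise mass action re-evaluated from the returned profiles
    for mono in ("A", "G"):
        K_H, K_Na, K_Mg = prob.constants.for_type(mono)
        f = sol.fractions.for_type(mono)
        for K, s, ion in ((K_H, "H", "H"), (K_Na, "Na", "Na"), (K_Mg, "Mg", "Mg")):
            lhs = f[s]
            rhs = f["free"] * K * sol.rho[ion] * prob.vw
            np.testing.assert_allclose(lhs, rhs, atol=1e-10, rtol=1e-10)
    # no exponent clipping survives at convergence
    prob.clip_events = 0
    prob.residual(sol.fields.pack())
    assert prob.clip_events == 0


def test_global_electroneutrality_and_bulk_recovery(ci_ensemble, constants):
    """On a grid deep enough for the diffuse layer to decay, the net surface
    charge vanishes and the far field recovers the bulk."""
    deep = Grid(n_layers=200, dz=0.3)
    ens = generate_ensemble(
        build_sequence("A6G6"), ChainGeometry(), deep, rotations_per_state=1,
        seed=20181403, max_conformations=3000,
    )
    bulk = solve_bulk(0.010, 0.003, 7.0)
    sol = solve_state_point(ens, bulk, constants, 0.05)
    assert sol.converged
    net = deep.dz * sol.rho_q.sum()
    assert abs(net) < 1e-6
    for s in sol.rho:
        np.testing.assert_allclose(
            sol.rho[s][-10:], sol.problem.bulk.rho[s], rtol=1e-6
        )
    np.testing.assert_allclose(sol.fields.psi[-10:], 0.0, atol=1e-6)
    np.testing.assert_allclose(sol.fields.pi[-10:], 0.0, atol=1e-6)


def test_label_swap_metamorphic(ci_ensemble, constants):
    """Swapping sequence A6G6 <-> G6A6 together with the A/G parameter sets
    leaves every observable unchanged."""
    bulk = solve_bulk(0.010, 0.003, 7.0)
    sol1 = solve_state_point(ci_ensemble, bulk, constants, 0.01, tol=1e-11)
    sol2 = solve_state_point(ci_ensemble.swapped(), bulk, constants.swapped(), 0.01, tol=1e-11)
    np.testing.assert_allclose(sol1.fields.pi, sol2.fields.pi, atol=1e-8)
    np.testing.assert_allclose(sol1.fields.psi, sol2.fields.psi, atol=1e-8)
    np.testing.assert_allclose(sol1.phi_p, sol2.phi_p, atol=1e-9)
    np.testing.assert_allclose(sol1.rho_A, sol2.rho_G, atol=1e-9)


def test_ensemble_size_stability(geometry, grid, constants):
    """Doubling the conformation sample at the default ensemble size changes
    the polymer profile by less than 2% of its peak (sup-norm)."""
    seq = build_sequence("A6G6")
    e1 = generate_ensemble(seq, geometry, grid, rotations_per_state=38, seed=20181403)
    e2 = generate_ensemble(seq, geometry, grid, rotations_per_state=76, seed=20181403)
    bulk = solve_bulk(0.010, 0.003, 7.0)
    s1 = solve_state_point(e1, bulk, constants, 0.05)
    s2 = solve_state_point(e2, bulk, constants, 0.05)
    assert s1.converged and s2.converged
    diff = np.abs(s1.phi_p - s2.phi_p).max() / s2.phi_p.max()
    assert diff < 0.02


def test_nonconvergence_is_reported():
    toy = default_toy()
    prob = toy.problem()
    sol = solve_fields(prob, tol=1e-30, max_iter=2)
    assert not sol.converged
    assert len(sol.residual_history) >= 1
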