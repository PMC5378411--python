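import numpy as np
import pytest

from vegfpkpd.engine import (Model, assemble_rhs, build_model, simulate,
                             solve_steady_state)
from vegfpkpd.network import BASELINE, build_network
from vegfpkpd.species import Species, comp


def test_rhs_zero_at_empty_state_without_inputs(params):
    net = build_network(params)
    m = Model(params, net.registry, net.reactions, [], [], [], BASELINE)
    np.testing.assert_array_equal(m.rhs(np.zeros(m.n)), 0.0)


def test_secretion_only_linear_growth(params):
    """With reactions and losses stripped, secreted monomers grow linearly at
    the configured molecules/cell/s x cell count."""
    from vegfpkpd.trafficking import build_secretion_processes
    net = build_network(params)
    const = build_secretion_processes(params, net.registry)
    m = Model(params, net.registry, [], [], const, [], BASELINE)
    dy = m.rhs(np.zeros(m.n))
    from vegfpkpd.parameters import N_AVOGADRO
    geom = params.geometry["calf"]
    i = net.registry.idx(Species("calf", "fluid", comp("V165")))
    expected = (params.secretion.q_vegf * 0.77
                * geom.myonuclear_domain_count / N_AVOGADRO)
    assert dy[i] == pytest.approx(expected)
    assert np.all(dy >= 0)


def test_analytic_jacobian_matches_finite_differences(model):
    rng = np.random.default_rng(7)
    y = np.abs(rng.normal(size=model.n)) * 1e-13
    J = model.jac(y).toarray()
    f0 = model.rhs(y)
    cols = rng.choice(model.n, size=40, replace=False)
    for j in cols:
        # the rhs is exactly quadratic, so central differences are exact for
        # any step; a large step avoids cancellation against the secretion
        # constants
        h = max(0.25 * abs(y[j]), 1e-15)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        fd = (model.rhs(yp) - model.rhs(ym)) / (2 * h)
        scale = np.max(np.abs(J[:, j])) + np.max(np.abs(fd)) + 1e-12
        assert np.max(np.abs(J[:, j] - fd)) / scale < 1e-6


def test_assemble_rhs_is_side_effect_free(model):
    rhs, pattern = assemble_rhs(model)
    y = model.default_initial_state()
    y_copy = y.copy()
    _ = rhs(0.0, y)
    np.testing.assert_array_equal(y, y_copy)
    assert pattern.shape == (model.n, model.n)
    assert pattern.nnz > model.n  # coupling beyond the diagonal


def test_binding_toy_matches_quadratic_to_six_digits():
    from vegfpkpd.toys import make_binding_toy
    toy = make_binding_toy(total_l_mol=1.0e-14, total_r_mol=1.0e-15,
                           kd_M=1.0e-10)
    ss = solve_steady_state(toy.model, y0=toy.y0)
    reg = toy.model.registry
    bound = ss.y[reg.idx(Species("blood", "plasma", comp("V165", "sR1")))]
    free_l = ss.y[reg.idx(Species("blood", "plasma", comp("V165")))]
    assert bound == pytest.approx(toy.expected["bound_mol"], rel=1e-6)
    assert free_l == pytest.approx(toy.expected["free_l_mol"], rel=1e-6)


def test_steady_state_independent_of_initial_condition(model, baseline_ss):
    y0 = model.default_initial_state()
    y0_perturbed = y0 * 3.0 + 1e-16
    ss2 = solve_steady_state(model, y0=None)
    ss3 = solve_steady_state(model, y0=y0_perturbed)
    ref = np.abs(baseline_ss.y).max()
    mask = baseline_ss.y > 1e-9 * ref
    np.testing.assert_allclose(ss3.y[mask], baseline_ss.y[mask], rtol=1e-3)
    np.testing.assert_allclose(ss2.y[mask], baseline_ss.y[mask], rtol=1e-3)


def test_rtol_refinement_stability(model, baseline_ss):
    """Halving the integrator tolerance leaves headline outputs unchanged to
    0.1% (the Newton polish dominates the final accuracy)."""
    from vegfpkpd.calibration import model_outputs
    ss_fine = solve_steady_state(model, rtol=5e-7)
    a = model_outputs(model, baseline_ss)
    b = model_outputs(model, ss_fine)
    for k in a:
        assert b[k] == pytest.approx(a[k], rel=1e-3)


def test_matrix_sites_conserved_along_trajectory(model):
    y0 = model.default_initial_state()
    sol = simulate(model, y0, (0.0, 1.0e5))
    assert sol.success
    yT = sol.y[:, -1]
    for free_idx, members, total in model.conservation:
        assert sum(yT[m] for m in members) == pytest.approx(total, rel=1e-6)


def test_steady_state_nonnegative_and_converged(baseline_ss):
    assert np.all(baseline_ss.y >= 0.0)
    assert baseline_ss.residual_norm < 1e-6
    assert baseline_ss.params_hash


def test_state_dump_dataframe(baseline_ss):
    df = baseline_ss.to_dataframe()
    assert {"compartment", "location", "species", "amount_mol",
            "concentration", "units"} <= set(df.columns)
    assert len(df) == baseline_ss.model.n
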