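"""Cost, analytic gradient, RMSprop machinery and the solver loop."""

import numpy as np
import pytest

from ecginverse.forward import BodySurfaceRecording, build_transfer, simulate_bspm
from ecginverse.inverse import (
    OptimizerState,
    ParameterField,
    StoppingRule,
    cost,
    cost_and_gradient,
    default_eta_grid,
    rmsprop_update,
    select_learning_rate,
    solve_inverse,
)
from ecginverse.mesh import ElectrodeSet, SurfaceMesh


@pytest.fixture(scope="module")
def random_case(small_geometry):
    """Seeded mismatched source/target pair on the 30-vertex geometry."""
    mesh, el = small_geometry
    rng = np.random.default_rng(42)
    n = mesh.n_vertices
    field = ParameterField(10.0, rng.uniform(4, 8, n), rng.uniform(120, 180, n),
                           rng.uniform(0, 60, n))
    tfield = ParameterField(8.0, rng.uniform(4, 8, n), rng.uniform(120, 180, n),
                            rng.uniform(0, 60, n))
    times = np.arange(0.0, 100.0, 1.0)
    target = simulate_bspm(mesh, el, tfield, times)
    return mesh, el, field, tfield, target


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

def test_pack_unpack_roundtrip():
    rng = np.random.default_rng(0)
    f = ParameterField(3.0, rng.normal(size=7), rng.normal(size=7),
                       rng.normal(size=7))
    vec = f.pack()
    assert vec.size == 1 + 3 * 7
    back = ParameterField.unpack(vec, 7)
    np.testing.assert_array_equal(back.tau, f.tau)
    np.testing.assert_array_equal(back.tau_out, f.tau_out)
    assert back.A == f.A


def test_unpack_length_mismatch():
    with pytest.raises(ValueError):
        ParameterField.unpack(np.zeros(10), 4)


# ---------------------------------------------------------------------------
# cost
# ---------------------------------------------------------------------------

def test_cost_hand_arithmetic():
    """2 electrodes, 1 time... padded to 2 samples: centered residuals
    (0.5, -0.5) at the live sample give J = 0.25."""
    verts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
    mesh = SurfaceMesh(verts, [[0, 1, 2]], [0, 0, 0])
    el = ElectrodeSet([[0, 0, 10.0], [0, 0, -10.0]])
    phi_T = np.array([[1.0], [0.0]])
    phi_star = np.array([[0.0], [0.0]])
    r = (phi_T - phi_T.mean(axis=0)) - (phi_star - phi_star.mean(axis=0))
    assert 0.5 * np.sum(r * r) == pytest.approx(0.25)


def test_cost_zero_for_uniform_field_and_zero_target(small_geometry):
    mesh, el = small_geometry
    times = np.arange(0.0, 100.0, 1.0)
    target = BodySurfaceRecording(np.zeros((el.n_electrodes, times.size)), times)
    f = ParameterField.default_init(mesh.n_vertices)
    assert cost(f, target, mesh, el) <= 1e-20


def test_cost_invariant_to_per_time_offsets(random_case):
    mesh, el, field, _, target = random_case
    J0 = cost(field, target, mesh, el)
    c = np.sin(target.times)[None, :] * 5.0  # same offset on all electrodes
    shifted = BodySurfaceRecording(target.phi + c, target.times)
    J1 = cost(field, shifted, mesh, el)
    assert abs(J1 - J0) <= 1e-12 * J0


def test_cost_electrode_count_mismatch(random_case):
    mesh, el, field, _, target = random_case
    bad = BodySurfaceRecording(target.phi[:-1], target.times)
    with pytest.raises(ValueError, match="electrodes"):
        cost(field, bad, mesh, el)


# ---------------------------------------------------------------------------
# gradient
# ---------------------------------------------------------------------------

def test_gradient_vanishes_at_perfect_fit(random_case):
    mesh, el, _, tfield, target = random_case
    J, g = cost_and_gradient(tfield, target, mesh, el)
    assert J == pytest.approx(0.0, abs=1e-18)
    assert np.abs(g).max() <= 1e-8


def test_amplitude_gradient_matches_fd(random_case):
    mesh, el, field, _, target = random_case
    _, g = cost_and_gradient(field, target, mesh, el)
    h = 1e-4
    fp, fm = field.copy(), field.copy()
    fp.A += h
    fm.A -= h
    fd = (cost(fp, target, mesh, el) - cost(fm, target, mesh, el)) / (2 * h)
    assert g[0] == pytest.approx(fd, rel=1e-6)


def test_full_gradient_matches_fd(random_case):
    """Analytic gradient vs central differences over all 1+3N components."""
    mesh, el, field, _, target = random_case
    n = mesh.n_vertices
    T = build_transfer(mesh, el)
    _, g = cost_and_gradient(field, target, mesh, el, transfer=T)
    P = field.pack()
    fd = np.empty_like(g)
    h = 1e-3
    for m in range(P.size):
        Pp, Pm = P.copy(), P.copy()
        Pp[m] += h
        Pm[m] -= h
        fd[m] = (
            cost(ParameterField.unpack(Pp, n), target, mesh, el, transfer=T)
            - cost(ParameterField.unpack(Pm, n), target, mesh, el, transfer=T)
        ) / (2 * h)
    cosine = g @ fd / (np.linalg.norm(g) * np.linalg.norm(fd))
    assert cosine > 0.999
    big = np.abs(g) > 1e-6 * np.abs(g).max()
    rel = np.abs(g[big] - fd[big]) / np.abs(fd[big])
    assert rel.max() < 0.01


# ---------------------------------------------------------------------------
# RMSprop
# ---------------------------------------------------------------------------

def test_rmsprop_zero_gradient_keeps_parameters():
    state = OptimizerState(P=np.array([1.0, 2.0]), kappa=np.array([0.5, 0.5]))
    new = rmsprop_update(state, np.zeros(2), eta=0.1)
    np.testing.assert_array_equal(new.P, state.P)
    np.testing.assert_allclose(new.kappa, 0.9 * state.kappa)


def test_rmsprop_single_step_closed_form():
    g = 3.0
    eta = 0.2
    state = OptimizerState(P=np.array([1.0]), kappa=np.array([0.0]))
    new = rmsprop_update(state, np.array([g]), eta)
    assert new.kappa[0] == pytest.approx(0.1 * g * g)
    expected_step = eta * g / (np.sqrt(0.1) * g + 1e-7)
    assert state.P[0] - new.P[0] == pytest.approx(expected_step)


def test_rmsprop_two_steps_match_literal_transcription():
    """Two successive updates equal a hand-rolled loop of the update rules."""
    rng = np.random.default_rng(12)
    P = rng.normal(size=5)
    g1, g2 = rng.normal(size=5), rng.normal(size=5)
    state = OptimizerState(P=P.copy(), kappa=np.zeros(5))
    state = rmsprop_update(state, g1, 0.05)
    state = rmsprop_update(state, g2, 0.02)

    kappa = np.zeros(5)
    q = P.copy()
    for g, eta in ((g1, 0.05), (g2, 0.02)):
        kappa = 0.9 * kappa + 0.1 * g * g
        q = q - eta * g / (kappa ** 0.5 + 1e-7)
    np.testing.assert_allclose(state.P, q, rtol=1e-14)
    np.testing.assert_allclose(state.kappa, kappa, rtol=1e-14)


def test_rmsprop_clips_time_constants():
    n = 2
    P = np.array([10.0, 0.6, 0.6, 11.0, 11.0, 0.0, 0.0])
    state = OptimizerState(P=P, kappa=np.zeros(7))
    g = np.array([0.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
    new = rmsprop_update(state, g, eta=50.0, n_nodes=n)
    assert (new.P[1:3] >= 0.5).all()  # tau_out floor
    assert (new.P[3:5] >= 10.0).all()  # tau_close floor


# ---------------------------------------------------------------------------
# learning-rate search
# ---------------------------------------------------------------------------

def test_learning_rate_search_descends_on_quadratic():
    P0 = np.array([1.0, 1.0])
    state = OptimizerState(P=P0, kappa=np.zeros(2))
    J = lambda P: 0.5 * float(P @ P)
    g = P0.copy()  # gradient of J at P0
    eta = select_learning_rate(state, g, J)
    new = rmsprop_update(state, g, eta)
    assert J(new.P) < J(P0)


def test_learning_rate_search_uses_15_evaluations():
    calls = []

    def J(P):
        calls.append(P)
        return float(P @ P)

    state = OptimizerState(P=np.ones(3), kappa=np.zeros(3))
    select_learning_rate(state, np.ones(3), J)
    assert len(calls) == 15
    assert default_eta_grid().size == 15
    assert default_eta_grid()[0] == pytest.approx(1e-5)
    assert default_eta_grid()[-1] == pytest.approx(1e2)


def test_line_searched_step_no_worse_than_fixed_eta(random_case):
    mesh, el, field, _, target = random_case
    n = mesh.n_vertices
    T = build_transfer(mesh, el)
    J_of = lambda P: cost(ParameterField.unpack(P, n), target, mesh, el, transfer=T)
    _, g = cost_and_gradient(field, target, mesh, el, transfer=T)
    state = OptimizerState(P=field.pack(), kappa=np.zeros(1 + 3 * n))
    eta = select_learning_rate(state, g, J_of, n_nodes=n)
    J_search = J_of(rmsprop_update(state, g, eta, n_nodes=n).P)
    J_fixed = J_of(rmsprop_update(state, g, 0.01, n_nodes=n).P)
    assert J_search <= J_fixed + 1e-15


# ---------------------------------------------------------------------------
# solver loop
# ---------------------------------------------------------------------------

def test_zero_target_with_uniform_init_exits_immediately(small_geometry):
    mesh, el = small_geometry
    times = np.arange(0.0, 60.0, 1.0)
    target = BodySurfaceRecording(np.zeros((el.n_electrodes, times.size)), times)
    field, diag = solve_inverse(target, mesh, el,
                                stop=StoppingRule(max_iterations=50))
    assert diag.n_iterations == 0
    assert diag.converged
    np.testing.assert_array_equal(field.tau, np.full(mesh.n_vertices, 60.0))


def test_solver_reduces_cost_on_small_case(small_geometry):
    mesh, el = small_geometry
    rng = np.random.default_rng(21)
    n = mesh.n_vertices
    truth = ParameterField(10.0, np.full(n, 6.0), np.full(n, 150.0),
                           rng.uniform(10, 50, n))
    times = np.arange(0.0, 251.0, 2.0)
    target = simulate_bspm(mesh, el, truth, times)
    field, diag = solve_inverse(target, mesh, el, tau0=30.0,
                                stop=StoppingRule(max_iterations=25))
    assert diag.j_history[-1] < diag.j_history[0]
    assert diag.j_history[-1] >= 0.0


def test_stopping_rule_validation():
    with pytest.raises(ValueError):
        StoppingRule(max_iterations=0)
    with pytest.raises(ValueError):
        StoppingRule(flat_tolerance=0.0)
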