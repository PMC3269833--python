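"""Circuit models and their integration: fixed points, bistability, invariance."""

import numpy as np
import pytest

from switchscan import (
    IntegrationError,
    SimulationConfig,
    Trajectory,
    ValidationError,
    hysteresis_sweep,
    integrate,
    integrate_batch,
    make_self_activation_switch,
    make_standin_network,
    make_toggle_switch,
)
from switchscan.circuits import CircuitModel, repressor_level, with_graded_genes

from conftest import toggle_fixed_point

CFG = SimulationConfig(t_end=200.0, steady_tol=1e-7)


@pytest.mark.parametrize(
    "factory, bad",
    [
        (make_self_activation_switch, {"p": -1.0}),
        (make_self_activation_switch, {"K": 0.0}),
        (make_toggle_switch, {"alpha": -10.0}),
        (make_toggle_switch, {"d": 0.0}),
        (make_standin_network, {"g_rate": -0.1}),
    ],
)
def test_nonpositive_parameters_rejected(factory, bad):
    with pytest.raises(ValidationError):
        factory(parameters=bad)


def test_self_activation_zero_state_is_fixed(sa_model):
    """Production needs A (A^2 numerator), so A = 0 stays put at any stimulus."""
    for stim in [0.0, 10.0, 33.0]:
        deriv = sa_model.rhs(np.array([0.0]), stim, sa_model.parameters)
        assert deriv[0] == 0.0


def test_repressor_vanishes_at_unit_ki(sa_model):
    """K*i = 1 gives R = 0, so the repression factor 1/(1+R^2) is exactly 1."""
    i = 1.0 / sa_model.parameters["K"]
    assert repressor_level(i, sa_model.parameters["K"]) == 0.0
    # rhs then equals pure self-activation minus losses
    a = 2.0
    p, d = sa_model.parameters["p"], sa_model.parameters["d"]
    expected = p * a * a / (1 + a * a) - a / 2.5 - d * a
    assert sa_model.rhs(np.array([a]), i, sa_model.parameters)[0] == pytest.approx(expected)


def test_self_activation_bistable_by_grid_root_scan(sa_model):
    """Brute-force root scan: some repressor level admits >= 2 stable states."""
    p = sa_model.parameters
    a_grid = np.linspace(0.0, 50.0, 100_001)

    def n_stable(r):
        f = p["p"] * a_grid**2 / (1 + a_grid**2) / (1 + r * r) - a_grid / 2.5 - p["d"] * a_grid
        # sign changes from + to - are stable roots; A = 0 is stable
        # (local slope -(1/2.5 + d) < 0)
        down = np.nonzero((f[:-1] > 0) & (f[1:] < 0))[0]
        return 1 + down.size

    counts = [n_stable(r) for r in np.linspace(0.0, 10.0, 41)]
    assert max(counts) >= 2
    # strong repression leaves only the OFF state
    assert n_stable(10.0) == 1


def test_toggle_diagonal_is_invariant(toggle_model):
    """Symmetric equations: on A = B the two derivatives coincide."""
    for a in [0.0, 1.0, 2.086, 7.5]:
        da, db = toggle_model.rhs(np.array([a, a]), 0.0, toggle_model.parameters)
        assert da == db


def test_toggle_converges_to_oracle_fixed_point(toggle_model):
    fp = toggle_fixed_point()
    assert fp == pytest.approx([9.899, 0.101], abs=1e-3)
    traj = integrate(toggle_model, [10.0, 0.0], 0.0, CFG)
    assert traj.converged
    assert np.abs(traj.final_state - fp).max() < 1e-6


def test_integrate_preserves_exact_fixed_point(toggle_model):
    fp = toggle_fixed_point()
    traj = integrate(toggle_model, fp, 0.0, CFG)
    assert np.abs(traj.final_state - fp).max() < CFG.steady_tol * 10


def test_step_halving_changes_final_state_below_1e6(toggle_model):
    coarse = integrate(toggle_model, [10.0, 0.0], 0.0, CFG)
    fine = integrate(
        toggle_model, [10.0, 0.0], 0.0,
        SimulationConfig(t_end=200.0, steady_tol=1e-7, dt=CFG.dt / 2),
    )
    assert np.abs(coarse.final_state - fine.final_state).max() < 1e-6


def test_integrate_validates_inputs(toggle_model):
    with pytest.raises(ValidationError):
        integrate(toggle_model, [1.0], 0.0, CFG)
    with pytest.raises(ValidationError):
        integrate(toggle_model, [-1.0, 1.0], 0.0, CFG)
    with pytest.raises(ValidationError):
        integrate(toggle_model, [1.0, 1.0], np.inf, CFG)


def test_integration_failure_names_model_and_step():
    blowup = CircuitModel(
        name="blowup",
        state_names=("X",),
        rhs=lambda s, i, p: s * s,
        parameters={"k": 1.0},
    )
    with np.errstate(over="ignore", invalid="ignore"):
        with pytest.raises(IntegrationError, match="blowup"):
            integrate(blowup, np.array([5.0]), 0.0, SimulationConfig(t_end=50.0))


def test_trajectories_stay_nonnegative(toggle_model, sa_model):
    rng = np.random.default_rng(0)
    for model, stim in [(toggle_model, 0.0), (sa_model, 20.0)]:
        inits = rng.uniform(0.0, 12.0, size=(50, model.n_states))
        finals, _ = integrate_batch(model, inits, stim, CFG)
        assert finals.min() >= -CFG.steady_tol


def test_attractor_capture_small(toggle_model):
    """Off-diagonal initial states settle on one of the two oracle attractors."""
    fp = toggle_fixed_point()
    rng = np.random.default_rng(1)
    inits = rng.uniform(0.0, 12.0, size=(100, 2))
    inits = inits[np.abs(inits[:, 0] - inits[:, 1]) > 1e-3]
    finals, conv = integrate_batch(toggle_model, inits, 0.0, CFG)
    assert conv.all()
    dist = np.minimum(
        np.abs(finals - fp).max(axis=1), np.abs(finals - fp[::-1]).max(axis=1)
    )
    assert (dist < 1e-6).all()


def test_rk4_matches_scipy_reference(toggle_model):
    """Independent cross-check of the integrator against scipy's RK45."""
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, y: toggle_model.rhs(y, 0.0, toggle_model.parameters),
        (0.0, 30.0), [6.0, 1.0], rtol=1e-10, atol=1e-12,
    )
    traj = integrate(toggle_model, [6.0, 1.0], 0.0, SimulationConfig(t_end=30.0, steady_tol=1e-12))
    assert np.abs(traj.final_state - sol.y[:, -1]).max() < 1e-6


def test_standin_network_roles_and_rest_state():
    model = make_standin_network(n_graded=2)
    assert model.roles == ("switch", "effector", "graded", "graded")
    deriv = model.rhs(np.zeros(4), 0.0, model.parameters)
    assert np.all(deriv == 0.0)


def test_standin_graded_scales_linearly_with_stimulus():
    model = make_standin_network(n_graded=1)
    cfg = SimulationConfig(t_end=300.0, steady_tol=1e-9)
    lo = integrate(model, np.zeros(3), 5.0, cfg).final_state[2]
    hi = integrate(model, np.zeros(3), 10.0, cfg).final_state[2]
    assert hi / lo == pytest.approx(2.0, rel=1e-4)


def test_standin_switch_jumps_graded_does_not():
    """Stimulus sweep: the switch gene shows a discontinuous jump, graded genes ramp."""
    model = make_standin_network(n_graded=1)
    cfg = SimulationConfig(t_end=300.0)
    stims = np.linspace(0.0, 35.0, 200)
    init = np.zeros(3)
    init[0] = 1.0
    finals, _ = integrate_batch(model, np.tile(init, (200, 1)), stims, cfg)
    sw_steps = np.abs(np.diff(finals[:, 0]))
    gr_steps = np.abs(np.diff(finals[:, 2]))
    assert sw_steps.max() > 10 * max(np.median(sw_steps), 1e-9)
    assert gr_steps.max() < 10 * np.median(gr_steps)


def test_hysteresis_window_nonempty(sa_model):
    """Up/down sweeps switch at different stimuli (bistable window > 0)."""
    res = hysteresis_sweep(sa_model, np.linspace(15.0, 35.0, 21), CFG, basal=0.2)
    assert res.window_width > 0
    assert res.on_threshold > res.off_threshold


def test_with_graded_genes_extends_model(toggle_model):
    model = with_graded_genes(toggle_model, n_graded=2)
    assert model.n_states == 4
    assert model.roles[2:] == ("graded", "graded")
    deriv = model.rhs(np.zeros(4), 2.0, model.parameters)
    # toggle block unchanged; graded production = (k+1) * g_rate * stimulus
    assert deriv[2] == pytest.approx(model.parameters["g_rate"] * 2.0)
    assert deriv[3] == pytest.approx(2 * model.parameters["g_rate"] * 2.0)


def test_trajectory_invariants(toggle_model):
    traj = integrate(toggle_model, [3.0, 2.0], 0.0, CFG)
    assert isinstance(traj, Trajectory)
    assert np.all(np.diff(traj.times) > 0)
    assert np.all(np.isfinite(traj.states))
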