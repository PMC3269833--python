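"""Bistable gene-circuit models and their numerical integration.

Two canonical switch architectures are provided:

* a one-gene *self-activation* switch in which cooperative positive
  autoregulation (``p A^2 / (1 + A^2)``) competes with a
  stimulus-controlled repressor ``R(i) = 10 (1 - K i) / (1 + K i)`` acting
  through ``1 / (1 + R^2)``, a fixed first-order loss ``A / 2.5`` and a
  linear degradation ``d A``;
* a two-gene *toggle switch* with symmetric cross-repression
  ``dA/dt = alpha / (1 + B^2) - d A``, ``dB/dt = alpha / (1 + A^2) - d B``.

A third, composite "stand-in" network couples one self-activation switch
gene to a Hill-activated effector and a set of graded (linear) responder
genes, giving the qualitative switch/effector/graded gene trio used in
proof-of-concept simulations.

Integration is classic fixed-step fourth-order Runge-Kutta with an early
stop once the max-norm of the vector field falls below a steady-state
tolerance; the fixed step makes trajectories bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import IntegrationError, ValidationError

__all__ = [
    "CircuitModel",
    "Trajectory",
    "HysteresisResult",
    "make_self_activation_switch",
    "make_toggle_switch",
    "make_standin_network",
    "integrate",
    "integrate_batch",
    "hysteresis_sweep",
    "repressor_level",
]

#: default kinetic parameters of the one-gene self-activation switch,
#: chosen to place the circuit in a bistable regime for intermediate stimuli
SELF_ACTIVATION_DEFAULTS: dict[str, float] = {"p": 4.0, "K": 0.03, "d": 0.1}

#: default kinetic parameters of the two-gene toggle switch
TOGGLE_DEFAULTS: dict[str, float] = {"alpha": 10.0, "d": 1.0}


@dataclass(frozen=True)
class CircuitModel:
    """An ODE gene-circuit: named states, a vector field, and parameters.

    The vector field ``rhs(state, stimulus, params)`` must broadcast over
    leading axes of ``state`` (shape ``(..., n_states)``) so that batches
    of cells/clones integrate in one vectorized pass; parameter values may
    be scalars or arrays broadcastable against those leading axes.
    """

    name: str
    state_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, object, Mapping[str, object]], np.ndarray]
    parameters: dict[str, float]
    #: per-state role label: "switch", "effector" or "graded"
    roles: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for key, value in self.parameters.items():
            if not (np.isscalar(value) and float(value) > 0):
                raise ValidationError(
                    f"circuit {self.name!r}: parameter {key!r} must be a "
                    f"positive scalar, got {value!r}"
                )
        if self.roles and len(self.roles) != len(self.state_names):
            raise ValidationError("roles must match state_names in length")

    @property
    def n_states(self) -> int:
        return len(self.state_names)


@dataclass(frozen=True)
class Trajectory:
    """A single integrated trajectory.

    ``converged`` is True when the steady-state tolerance was met before
    the integration horizon.
    """

    times: np.ndarray
    states: np.ndarray
    converged: bool

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def _positive(params: Mapping[str, float], keys: Sequence[str], who: str) -> dict[str, float]:
    out = {}
    for key in keys:
        value = float(params[key])
        if not (value > 0 and math.isfinite(value)):
            raise ValidationError(f"{who}: parameter {key!r} must be positive, got {value}")
        out[key] = value
    return out


def repressor_level(stimulus, K):
    """Repressor abundance ``R(i) = 10 (1 - K i) / (1 + K i)``.

    Decreasing in the stimulus *i*: high stimulus relieves repression of
    the switch gene. ``K i = 1`` gives ``R = 0``.
    """
    ki = np.multiply(K, stimulus)
    return 10.0 * (1.0 - ki) / (1.0 + ki)


def make_self_activation_switch(parameters: Mapping[str, float] | None = None) -> CircuitModel:
    """One-gene switch with cooperative self-activation under repression.

    ``dA/dt = p A^2/(1+A^2) * 1/(1+R^2) - A/2.5 - d A`` with
    ``R = R(stimulus)``.  The ``A/2.5`` loss term and the linear
    degradation ``d A`` are both applied, as two separate first-order
    sinks.  ``A = 0`` is always a fixed point (production needs A), so the
    OFF state coexists with a high ON state whenever repression is weak
    enough — the source of bistability and hysteresis.
    """
    params = dict(SELF_ACTIVATION_DEFAULTS, **(parameters or {}))
    params = _positive(params, ("p", "K", "d"), "self_activation_switch")

    def rhs(state, stimulus, p):
        a = state[..., 0]
        r = repressor_level(stimulus, p["K"])
        production = p["p"] * a * a / (1.0 + a * a) / (1.0 + r * r)
        da = production - a / 2.5 - p["d"] * a
        return np.stack([da], axis=-1)

    return CircuitModel(
        name="self_activation_switch",
        state_names=("A",),
        rhs=rhs,
        parameters=params,
        roles=("switch",),
    )


def make_toggle_switch(parameters: Mapping[str, float] | None = None) -> CircuitModel:
    """Two-gene mutual-repression toggle switch.

    ``dA/dt = alpha/(1+B^2) - d A``; ``dB/dt = alpha/(1+A^2) - d B``.
    Symmetric, so the diagonal ``A = B`` is flow-invariant; for
    sufficiently strong cross-repression the symmetric fixed point is a
    saddle and two mirror-image attractors (A-high/B-low and its swap)
    appear.
    """
    params = dict(TOGGLE_DEFAULTS, **(parameters or {}))
    params = _positive(params, ("alpha", "d"), "toggle_switch")

    def rhs(state, stimulus, p):
        a = state[..., 0]
        b = state[..., 1]
        da = p["alpha"] / (1.0 + b * b) - p["d"] * a
        db = p["alpha"] / (1.0 + a * a) - p["d"] * b
        return np.stack([da, db], axis=-1)

    return CircuitModel(
        name="toggle_switch",
        state_names=("A", "B"),
        rhs=rhs,
        parameters=params,
        roles=("switch", "switch"),
    )


def make_standin_network(
    n_graded: int = 3, parameters: Mapping[str, float] | None = None
) -> CircuitModel:
    """Composite network: one switch gene, one effector, ``n_graded`` graded genes.

    The switch gene S follows the self-activation dynamics; the effector E
    is Hill-activated by S (``e_max S^2/(e_K^2+S^2) - e_d E``) and so
    inherits the all-or-none behavior; graded gene k has linear production
    in the stimulus, ``(k+1) g_rate * i - g_d * G_k``, hence a steady
    level proportional to the stimulus.
    """
    if n_graded < 1:
        raise ValidationError(f"n_graded must be >= 1, got {n_graded}")
    defaults = dict(
        SELF_ACTIVATION_DEFAULTS,
        e_max=1.0,
        e_K=2.0,
        e_d=0.5,
        g_rate=0.05,
        g_d=0.5,
    )
    params = dict(defaults, **(parameters or {}))
    params = _positive(
        params, ("p", "K", "d", "e_max", "e_K", "e_d", "g_rate", "g_d"), "standin_network"
    )
    graded_gain = np.arange(1, n_graded + 1, dtype=float)

    def _col(x):
        # give per-row parameter/stimulus arrays a trailing axis so they
        # broadcast against the (..., n_graded) graded-gene block
        x = np.asarray(x, dtype=float)
        return x[..., None] if x.ndim else x

    def rhs(state, stimulus, p):
        s = state[..., 0]
        e = state[..., 1]
        g = state[..., 2:]
        r = repressor_level(stimulus, p["K"])
        ds = p["p"] * s * s / (1.0 + s * s) / (1.0 + r * r) - s / 2.5 - p["d"] * s
        de = p["e_max"] * s * s / (np.square(p["e_K"]) + s * s) - p["e_d"] * e
        dg = graded_gain * _col(p["g_rate"]) * _col(stimulus) - _col(p["g_d"]) * g
        return np.concatenate(
            [np.stack([ds, de], axis=-1), np.broadcast_to(dg, g.shape)], axis=-1
        )

    names = ("S_switch", "E_effector") + tuple(f"G{k}_graded" for k in range(1, n_graded + 1))
    roles = ("switch", "effector") + ("graded",) * n_graded
    return CircuitModel(
        name="standin_network", state_names=names, rhs=rhs, parameters=params, roles=roles
    )


def with_graded_genes(
    model: CircuitModel, n_graded: int = 1, parameters: Mapping[str, float] | None = None
) -> CircuitModel:
    """Append stimulus-graded responder genes to an existing circuit.

    Graded gene k obeys ``dG_k/dt = (k+1) g_rate * stimulus - g_d * G_k``
    (linear production in the stimulus, linear degradation), so its steady
    level is proportional to the stimulus — the non-switch control genes
    planted next to a bistable circuit in benchmark datasets.
    """
    if n_graded < 1:
        raise ValidationError(f"n_graded must be >= 1, got {n_graded}")
    extra = _positive(
        dict({"g_rate": 0.05, "g_d": 0.5}, **(parameters or {})), ("g_rate", "g_d"), "graded_genes"
    )
    overlap = set(extra) & set(model.parameters)
    if overlap:
        raise ValidationError(f"graded-gene parameter names collide: {sorted(overlap)}")
    k0 = model.n_states
    graded_gain = np.arange(1, n_graded + 1, dtype=float)
    base_rhs = model.rhs

    def _col(x):
        x = np.asarray(x, dtype=float)
        return x[..., None] if x.ndim else x

    def rhs(state, stimulus, p):
        g = state[..., k0:]
        dg = graded_gain * _col(p["g_rate"]) * _col(stimulus) - _col(p["g_d"]) * g
        return np.concatenate(
            [base_rhs(state[..., :k0], stimulus, p), np.broadcast_to(dg, g.shape)], axis=-1
        )

    return CircuitModel(
        name=f"{model.name}+{n_graded}graded",
        state_names=model.state_names + tuple(f"G{k}_graded" for k in range(1, n_graded + 1)),
        rhs=rhs,
        parameters={**model.parameters, **extra},
        roles=(model.roles or ("unknown",) * k0) + ("graded",) * n_graded,
    )


def _rk4_step(model: CircuitModel, state, stimulus, params, h: float):
    k1 = model.rhs(state, stimulus, params)
    k2 = model.rhs(state + 0.5 * h * k1, stimulus, params)
    k3 = model.rhs(state + 0.5 * h * k2, stimulus, params)
    k4 = model.rhs(state + h * k3, stimulus, params)
    return state + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4), k1


def integrate(model: CircuitModel, init, stimulus, config) -> Trajectory:
    """Integrate one trajectory by fixed-step RK4 with steady-state early stop.

    Stops as soon as the max-norm of the vector field drops below
    ``config.steady_tol`` (the trajectory "has reached steady state") or at
    ``config.t_end``.  The final state of the returned :class:`Trajectory`
    is the steady-state expression readout.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (model.n_states,):
        raise ValidationError(
            f"init has shape {init.shape}, model {model.name!r} expects ({model.n_states},)"
        )
    if not np.all(np.isfinite(init)) or np.any(init < 0):
        raise ValidationError("initial state must be finite and non-negative")
    if not np.isfinite(stimulus):
        raise ValidationError("stimulus must be finite")
    h = config.dt
    n_steps = int(math.ceil(config.t_end / h))
    times = [0.0]
    states = [init]
    state = init
    converged = False
    for step in range(1, n_steps + 1):
        state, deriv = _rk4_step(model, state, stimulus, model.parameters, h)
        if not np.all(np.isfinite(state)):
            raise IntegrationError(
                f"non-finite state integrating {model.name!r} at step {step} "
                f"(t={step * h:.4g})"
            )
        times.append(step * h)
        states.append(state)
        if np.max(np.abs(deriv)) < config.steady_tol:
            converged = True
            break
    return Trajectory(
        times=np.asarray(times), states=np.asarray(states), converged=converged
    )


def integrate_batch(
    model: CircuitModel,
    inits: np.ndarray,
    stimuli,
    config,
    params: Mapping[str, object] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate many trajectories at once; returns (final_states, converged).

    ``inits`` has shape ``(m, n_states)``; ``stimuli`` is a scalar or an
    ``(m,)`` array; ``params`` may carry per-row parameter arrays (for
    clone-to-clone parameter noise).  Integration stops when every row
    satisfies the steady-state tolerance or at ``t_end``.
    """
    state = np.array(inits, dtype=float)
    if state.ndim != 2 or state.shape[1] != model.n_states:
        raise ValidationError(
            f"inits must have shape (m, {model.n_states}); got {state.shape}"
        )
    p = dict(model.parameters)
    if params:
        p.update(params)
    h = config.dt
    n_steps = int(math.ceil(config.t_end / h))
    row_max = np.full(state.shape[0], np.inf)
    for step in range(1, n_steps + 1):
        state, deriv = _rk4_step(model, state, stimuli, p, h)
        if step % 50 == 0 and not np.all(np.isfinite(state)):
            bad = int(np.argwhere(~np.isfinite(state))[0, 0])
            raise IntegrationError(
                f"non-finite state integrating {model.name!r} (batch row {bad}, step {step})"
            )
        row_max = np.max(np.abs(deriv), axis=-1)
        if np.all(row_max < config.steady_tol):
            break
    if not np.all(np.isfinite(state)):
        raise IntegrationError(f"non-finite state integrating {model.name!r} (final check)")
    return state, row_max < config.steady_tol


@dataclass(frozen=True)
class HysteresisResult:
    """Up/down stimulus-sweep steady levels of the switch state."""

    stimuli: np.ndarray
    up_levels: np.ndarray
    down_levels: np.ndarray
    on_threshold: float
    off_threshold: float
    window_width: float


def hysteresis_sweep(
    model: CircuitModel,
    stimuli: Sequence[float],
    config,
    basal: float = 0.2,
    switch_index: int = 0,
) -> HysteresisResult:
    """Quasi-static stimulus sweep up then down, carrying the steady state over.

    At each sweep point the initial condition is the previous steady state,
    floored at a small ``basal`` expression level (a cell never starts from
    exactly zero protein).  Different switch-on and switch-off stimulus
    thresholds — a nonempty bistable window — are the hysteresis signature.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    if stimuli.ndim != 1 or stimuli.size < 3 or np.any(np.diff(stimuli) <= 0):
        raise ValidationError("stimuli must be an increasing 1-D sequence (>= 3 points)")

    def sweep(order, start_state):
        state = start_state
        levels = np.empty(stimuli.size)
        for j in order:
            state = np.maximum(state, basal)
            traj = integrate(model, state, stimuli[j], config)
            state = traj.final_state
            levels[j] = state[switch_index]
        return levels, state

    start = np.full(model.n_states, basal)
    up, top_state = sweep(range(stimuli.size), start)
    down, _ = sweep(range(stimuli.size - 1, -1, -1), top_state)

    # bistable window: stimuli where the two sweeps disagree substantially
    # (down-sweep still on the high branch, up-sweep still low)
    diff = down - up
    level_range = max(up.max(), down.max()) - min(up.min(), down.min())
    window = diff > max(diff.max() / 2.0, 0.05 * max(level_range, 1e-12))
    if window.any():
        idx = np.nonzero(window)[0]
        off_threshold = float(stimuli[idx[0]])
        on_threshold = float(stimuli[idx[-1] + 1]) if idx[-1] + 1 < stimuli.size else float(
            stimuli[idx[-1]]
        )
        width = on_threshold - off_threshold
    else:
        on_threshold = off_threshold = float("nan")
        width = 0.0
    return HysteresisResult(
        stimuli=stimuli,
        up_levels=up,
        down_levels=down,
        on_threshold=on_threshold,
        off_threshold=off_threshold,
        window_width=float(width),
    )
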