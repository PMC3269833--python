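"""Sampling protocols that turn circuit models into synthetic expression data.

The generator emulates how a bistable circuit looks through the lens of a
condition compendium: each "sample" is a clone grown under its own random
initial condition (and optionally its own stimulus), with Gaussian
cell-to-cell variation inside the clone averaged over ``cells_per_clone``
cells, multiplicative Gaussian parameter noise between clones, and a
``log2(x + 1)`` readout with optional measurement noise.  Because every
clone relaxes to one of the circuit's attractors, switch genes come out
bimodal across clones while graded genes do not — the statistical
structure the bimodality screen is designed to detect.

All randomness flows through one seeded generator in a fixed draw order
(per clone: parameters, initial state, stimulus, cell states; measurement
noise last), so a dataset is a pure function of (model, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .circuits import (
    CircuitModel,
    integrate_batch,
    make_self_activation_switch,
)
from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "PlantedCompendium",
    "fixed_stimulus",
    "uniform_stimulus",
    "sample_clone_average",
    "generate_dataset",
    "generate_compendium",
]

logger = logging.getLogger(__name__)

#: parameter-noise multipliers are truncated below at this fraction of nominal,
#: keeping all kinetic rates strictly positive
PARAM_NOISE_FLOOR = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling protocol for a synthetic compendium.

    Defaults mirror the canonical protocol: 100 clones, 100 cells averaged
    per clone, 20% CV multiplicative Gaussian parameter noise, 10% CV
    cell-to-cell variation, uniform initial conditions, RK4 step 0.01 with
    steady-state tolerance 1e-6 over a 500 time-unit horizon.
    """

    n_clones: int = 100
    cells_per_clone: int = 100
    init_low: float = 0.0
    init_high: float = 12.0
    param_cv: float = 0.20
    cell_cv: float = 0.10
    t_end: float = 500.0
    steady_tol: float = 1e-6
    dt: float = 0.01
    seed: int = 0
    measurement_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValidationError(f"n_clones must be >= 1, got {self.n_clones}")
        if self.cells_per_clone < 1:
            raise ValidationError(f"cells_per_clone must be >= 1, got {self.cells_per_clone}")
        if not 0 <= self.param_cv < 1:
            raise ValidationError(f"param_cv must be in [0, 1), got {self.param_cv}")
        if not 0 <= self.cell_cv < 1:
            raise ValidationError(f"cell_cv must be in [0, 1), got {self.cell_cv}")
        if self.init_low < 0 or self.init_high < self.init_low:
            raise ValidationError("require 0 <= init_low <= init_high")
        if self.t_end <= 0 or self.steady_tol <= 0 or self.dt <= 0:
            raise ValidationError("t_end, steady_tol and dt must be positive")
        if self.measurement_noise_sd < 0:
            raise ValidationError("measurement_noise_sd must be >= 0")


def fixed_stimulus(level: float) -> Callable[[np.random.Generator], float]:
    """Stimulus sampler that always returns ``level``."""

    def sampler(rng: np.random.Generator) -> float:
        return float(level)

    sampler.label = f"fixed({level:g})"  # type: ignore[attr-defined]
    return sampler


def uniform_stimulus(low: float, high: float) -> Callable[[np.random.Generator], float]:
    """Stimulus sampler drawing uniformly from [low, high] per clone."""
    if not high > low:
        raise ValidationError("uniform_stimulus requires high > low")

    def sampler(rng: np.random.Generator) -> float:
        return float(rng.uniform(low, high))

    sampler.label = f"uniform({low:g},{high:g})"  # type: ignore[attr-defined]
    return sampler


def _perturbed_params(
    model: CircuitModel, rng: np.random.Generator, cv: float
) -> dict[str, float]:
    """Multiplicative Gaussian parameter noise, truncated at 10% of nominal."""
    names = sorted(model.parameters)
    if cv == 0:
        return {k: model.parameters[k] for k in names}
    mult = np.maximum(rng.normal(1.0, cv, size=len(names)), PARAM_NOISE_FLOOR)
    return {k: model.parameters[k] * m for k, m in zip(names, mult)}


def _cell_inits(
    clone_init: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    n = config.cells_per_clone
    if n == 1 or config.cell_cv == 0:
        return np.tile(clone_init, (n, 1))
    draws = rng.normal(clone_init, config.cell_cv * clone_init, size=(n, clone_init.size))
    return np.clip(draws, 0.0, None)


def sample_clone_average(
    model: CircuitModel,
    stimulus: float,
    config: SimulationConfig,
    clone_init,
    params: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Population-averaged steady state of one clone.

    Draws ``cells_per_clone`` initial states from a Gaussian around the
    clone's initial state (CV = ``cell_cv``, truncated at 0), integrates
    each cell to steady state, and returns the arithmetic mean of the
    final states — the quantity a bulk measurement of the clone reports.
    A clone straddling a separatrix averages cells from both attractors,
    landing between the two expression levels.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    clone_init = np.asarray(clone_init, dtype=float)
    if clone_init.shape != (model.n_states,):
        raise ValidationError(
            f"clone_init has shape {clone_init.shape}, expected ({model.n_states},)"
        )
    inits = _cell_inits(clone_init, config, rng)
    finals, _ = integrate_batch(model, inits, stimulus, config, params=params)
    return finals.mean(axis=0)


@dataclass
class SimulatedDataset:
    """A generated expression matrix with its ground truth."""

    matrix: ExpressionMatrix
    truth: pd.DataFrame  # gene_id, is_switch, circuit_role
    annotations: pd.DataFrame  # indexed by sample_id: stimulus, condition_category
    #: true (pre-noise, linear-scale) clone-average steady states, samples x genes
    steady_states: np.ndarray = field(repr=False, default=None)
    converged: np.ndarray = field(repr=False, default=None)


def generate_dataset(
    model: CircuitModel,
    config: SimulationConfig,
    stimulus_sampler: Callable[[np.random.Generator], float] | None = None,
) -> SimulatedDataset:
    """Sample ``n_clones`` clones of a circuit into an expression matrix.

    Per clone, in this fixed order: draw a perturbed parameter set
    (multiplicative Gaussian, CV ``param_cv``, truncated at 10% of
    nominal), a uniform initial state in [init_low, init_high] per gene, a
    stimulus from ``stimulus_sampler`` (default: constant 0), and the
    cell initial states; all cells of all clones are then integrated in
    one vectorized RK4 pass.  The readout is ``log2(mean_steady + 1)``
    plus optional Gaussian measurement noise.  Identical seeds give
    bitwise-identical matrices.
    """
    if config.n_clones < 2:
        raise ValidationError("generate_dataset needs n_clones >= 2")
    sampler = stimulus_sampler if stimulus_sampler is not None else fixed_stimulus(0.0)
    rng = np.random.default_rng(config.seed)
    k = model.n_states
    cells = config.cells_per_clone
    param_names = sorted(model.parameters)

    all_inits = np.empty((config.n_clones * cells, k))
    stimuli = np.empty(config.n_clones * cells)
    params = {name: np.empty(config.n_clones * cells) for name in param_names}
    clone_stimuli = np.empty(config.n_clones)
    for c in range(config.n_clones):
        sl = slice(c * cells, (c + 1) * cells)
        clone_params = _perturbed_params(model, rng, config.param_cv)
        clone_init = rng.uniform(config.init_low, config.init_high, size=k)
        clone_stimuli[c] = sampler(rng)
        all_inits[sl] = _cell_inits(clone_init, config, rng)
        stimuli[sl] = clone_stimuli[c]
        for name in param_names:
            params[name][sl] = clone_params[name]

    finals, cell_converged = integrate_batch(model, all_inits, stimuli, config, params=params)
    steady = finals.reshape(config.n_clones, cells, k).mean(axis=1)
    converged = cell_converged.reshape(config.n_clones, cells).all(axis=1)
    n_unconverged = int((~converged).sum())
    if n_unconverged:
        logger.warning(
            "%d/%d clones did not reach steady state before t_end=%g (included, flagged)",
            n_unconverged,
            config.n_clones,
            config.t_end,
        )

    values = np.log2(steady.T + 1.0)  # genes x samples
    if config.measurement_noise_sd > 0:
        values = values + rng.normal(0.0, config.measurement_noise_sd, size=values.shape)

    sample_ids = [f"S{c + 1:04d}" for c in range(config.n_clones)]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=list(model.state_names), columns=sample_ids),
        provenance=f"simulated:{model.name}:seed={config.seed}",
    )
    roles = model.roles or ("unknown",) * k
    truth = pd.DataFrame(
        {
            "gene_id": list(model.state_names),
            "is_switch": [r == "switch" for r in roles],
            "circuit_role": list(roles),
        }
    )
    if np.ptp(clone_stimuli) > 0:
        edges = np.quantile(clone_stimuli, [1 / 3, 2 / 3])
        category = np.array(["stim_low", "stim_mid", "stim_high"])[
            np.searchsorted(edges, clone_stimuli, side="left")
        ]
    else:
        category = np.full(config.n_clones, "fixed_stimulus")
    annotations = pd.DataFrame(
        {"stimulus": clone_stimuli, "condition_category": category},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SimulatedDataset(
        matrix=matrix,
        truth=truth,
        annotations=annotations,
        steady_states=steady,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Planted compendium: the end-to-end screening benchmark
# ---------------------------------------------------------------------------

#: stimulus putting the self-activation switch in its monostable ON regime
STIMULUS_ON = 33.0
#: stimulus inside the bistable window (history decides the state), far
#: enough from the saddle-node that parameter noise rarely destroys the
#: ON attractor
STIMULUS_BISTABLE = 30.0
#: upper bound of the initial-condition draw for type-1 genes inside the
#: target block; with the separatrix near A ~ 0.2 under 10% parameter
#: noise this yields roughly an 80/20 ON/OFF split within the target
#: phenotype (the estrogen-receptor-like pattern)
TYPE1_INIT_HIGH = 1.15


@dataclass
class PlantedCompendium:
    """Global + paired-validation matrices with planted switch genes."""

    matrix: ExpressionMatrix
    annotations: pd.DataFrame  # indexed by sample_id: phenotype, condition_category
    truth: pd.DataFrame  # gene_id, is_switch, switch_type
    validation_matrix: ExpressionMatrix
    validation_annotations: pd.DataFrame  # indexed by sample_id: phenotype, pair_id
    pairs: pd.DataFrame  # pair_id, tumor_sample, normal_sample


def _simulate_switch_genes(
    model: CircuitModel,
    stimuli: np.ndarray,
    inits: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Steady levels of G one-state switch genes across m samples.

    ``inits`` is (G, m); every (gene, sample) cell gets its own perturbed
    parameter set; all G*m trajectories integrate in one vectorized pass.
    Returns the (G, m) steady levels on the linear scale.
    """
    n_genes, m = inits.shape
    names = sorted(model.parameters)
    if config.param_cv > 0:
        mult = np.maximum(
            rng.normal(1.0, config.param_cv, size=(len(names), n_genes * m)),
            PARAM_NOISE_FLOOR,
        )
        params = {k: model.parameters[k] * mm for k, mm in zip(names, mult)}
    else:
        params = None
    finals, _ = integrate_batch(
        model, inits.reshape(-1, 1), np.tile(stimuli, n_genes), config, params=params
    )
    return finals[:, 0].reshape(n_genes, m)


def generate_compendium(
    n_type2: int = 20,
    n_type1: int = 10,
    n_null: int = 970,
    n_samples: int = 300,
    n_target: int = 100,
    n_pairs: int = 40,
    seed: int = 0,
    target_label: str = "cancer",
    param_cv: float = 0.10,
    measurement_noise_sd: float = 0.30,
    type1_on_fraction_init: float = TYPE1_INIT_HIGH,
) -> PlantedCompendium:
    """Build a planted screening benchmark from the self-activation circuit.

    A block of ``n_target`` samples carries the target phenotype.  Planted
    type-2 switch genes are driven into their ON attractor throughout that
    block (stimulus in the monostable-ON regime) and left OFF elsewhere;
    planted type-1 genes receive a bistable-window stimulus in the block
    with initial conditions straddling the separatrix, so the block itself
    splits into ON and OFF sub-states (roughly 80/20).  Null genes are
    graded responders — their steady level is the closed-form balance
    ``gain * stimulus / degradation`` of linear kinetics — or stimulus-free
    housekeeping genes; neither tracks the phenotype.  A second, paired
    tumor/normal matrix is generated from the same gene set for
    independent validation.

    Per-sample parameter noise (CV ``param_cv``) perturbs the switch
    kinetics, and all readouts are ``log2(x + 1)`` plus Gaussian
    measurement noise.
    """
    if min(n_type2, n_type1) < 1 or n_null < 0:
        raise ValidationError("need at least one planted gene of each switch type")
    if not 2 <= n_target <= n_samples - 2:
        raise ValidationError("n_target must leave >= 2 samples in each phenotype group")
    rng = np.random.default_rng(seed)
    model = make_self_activation_switch()
    sim = SimulationConfig(
        n_clones=2, cells_per_clone=1, t_end=200.0, steady_tol=1e-6, dt=0.01, param_cv=param_cv
    )

    is_target = np.zeros(n_samples, dtype=bool)
    is_target[:n_target] = True
    sample_ids = [f"S{j + 1:04d}" for j in range(n_samples)]

    def switch_block(n_genes: int, stimuli: np.ndarray, init_fn) -> np.ndarray:
        inits = np.stack([init_fn() for _ in range(n_genes)])
        return _simulate_switch_genes(model, stimuli, inits, sim, rng)

    stim_t2 = np.where(is_target, STIMULUS_ON, 0.0)
    stim_t1 = np.where(is_target, STIMULUS_BISTABLE, 0.0)

    def t2_init():
        return np.ones(n_samples)

    def t1_init():
        draws = rng.uniform(0.0, type1_on_fraction_init, size=n_samples)
        return np.where(is_target, draws, 1.0)

    linear_t2 = switch_block(n_type2, stim_t2, t2_init)
    linear_t1 = switch_block(n_type1, stim_t1, t1_init)

    n_graded = n_null // 2
    n_house = n_null - n_graded
    graded_gain = rng.uniform(0.2, 2.0, size=n_graded)

    def null_block(n_cols: int) -> np.ndarray:
        """log2-scale null genes: graded responders + housekeeping genes."""
        u = rng.uniform(0.5, 10.0, size=(n_graded, n_cols))
        graded = np.log2(1.0 + graded_gain[:, None] * u)
        house = rng.normal(
            house_mu[:, None], house_sd[:, None], size=(n_house, n_cols)
        )
        return np.vstack([graded, house]) if n_null else np.empty((0, n_cols))

    house_mu = rng.uniform(2.0, 8.0, size=n_house)
    house_sd = rng.uniform(0.3, 0.8, size=n_house)

    log_switch = np.log2(np.vstack([linear_t2, linear_t1]) + 1.0)
    values = np.vstack([log_switch, null_block(n_samples)])
    values = values + rng.normal(0.0, measurement_noise_sd, size=values.shape)

    gene_ids = (
        [f"SW2_{g + 1:03d}" for g in range(n_type2)]
        + [f"SW1_{g + 1:03d}" for g in range(n_type1)]
        + [f"BG_{g + 1:04d}" for g in range(n_null)]
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        provenance=f"planted_compendium:seed={seed}",
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_switch": [True] * (n_type2 + n_type1) + [False] * n_null,
            "switch_type": ["type2"] * n_type2 + ["type1"] * n_type1 + ["none"] * n_null,
        }
    )
    other_categories = np.array(["heat_shock", "cell_cycle", "carbon_source", "other"])
    category = np.where(
        is_target, target_label, other_categories[rng.integers(0, 4, size=n_samples)]
    )
    annotations = pd.DataFrame(
        {
            "phenotype": np.where(is_target, target_label, "other"),
            "condition_category": category,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # independent paired validation set: n_pairs tumors + matched normals
    tumor_ids = [f"T{j + 1:03d}" for j in range(n_pairs)]
    normal_ids = [f"N{j + 1:03d}" for j in range(n_pairs)]
    v_target = np.concatenate([np.ones(n_pairs, bool), np.zeros(n_pairs, bool)])
    v_stim_t2 = np.where(v_target, STIMULUS_ON, 0.0)
    v_stim_t1 = np.where(v_target, STIMULUS_BISTABLE, 0.0)

    def v_t2_init():
        return np.ones(2 * n_pairs)

    def v_t1_init():
        draws = rng.uniform(0.0, type1_on_fraction_init, size=2 * n_pairs)
        return np.where(v_target, draws, 1.0)

    v_linear = np.vstack(
        [
            switch_block(n_type2, v_stim_t2, v_t2_init),
            switch_block(n_type1, v_stim_t1, v_t1_init),
        ]
    )
    v_values = np.vstack([np.log2(v_linear + 1.0), null_block(2 * n_pairs)])
    v_values = v_values + rng.normal(0.0, measurement_noise_sd, size=v_values.shape)
    validation_matrix = ExpressionMatrix(
        pd.DataFrame(v_values, index=gene_ids, columns=tumor_ids + normal_ids),
        provenance=f"planted_validation:seed={seed}",
    )
    pairs = pd.DataFrame(
        {
            "pair_id": [f"P{j + 1:03d}" for j in range(n_pairs)],
            "tumor_sample": tumor_ids,
            "normal_sample": normal_ids,
        }
    )
    validation_annotations = pd.DataFrame(
        {
            "phenotype": [target_label] * n_pairs + ["normal"] * n_pairs,
            "pair_id": pairs["pair_id"].tolist() * 2,
        },
        index=pd.Index(tumor_ids + normal_ids, name="sample_id"),
    )
    return PlantedCompendium(
        matrix=matrix,
        annotations=annotations,
        truth=truth,
        validation_matrix=validation_matrix,
        validation_annotations=validation_annotations,
        pairs=pairs,
    )
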