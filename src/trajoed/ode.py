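"""Core ODE abstractions: models, experiments, trajectories, simulation.

An :class:`OdeModel` bundles a vector field ``f(x, u, k, t)``, an output map
``h(x)`` and a parameter-dependent initial state ``x0(u, k)``.  Free
parameters are handled on the log10 scale throughout the package (``theta =
log10 k``); the vector field itself works with linear-scale rate constants
``k``.  Perturbation inputs ``u`` are per-species multipliers on basal
synthesis rates, applied at t = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "SimulationError",
    "ConfigError",
    "Experiment",
    "Trajectory",
    "OdeModel",
    "simulate",
    "apply_input",
    "build_catalogue",
]


class SimulationError(RuntimeError):
    """Raised when numerical integration fails (stiff blow-up, non-finite
    derivative, negative-overflow).  Carries the offending parameter vector
    and experiment index so callers can map the failure to -inf
    log-likelihood or skip the draw."""

    def __init__(self, message: str, theta=None, experiment_index=None):
        super().__init__(message)
        self.theta = None if theta is None else np.asarray(theta, float)
        self.experiment_index = experiment_index


class ConfigError(ValueError):
    """Invalid model / experiment configuration."""


class _DivergedState(Exception):
    """Internal: aborts the stepper as soon as states diverge."""


def guard_rhs(raw_fun):
    """Wrap a right-hand side so the stepper fails fast instead of
    grinding against a blow-up or NaN region with ever-shrinking steps.
    The squared norm is a cheap single check: ``not (q < 1e200)`` catches
    NaN, inf and magnitudes beyond ~1e100 at once."""

    def fun(t, x):
        q = x @ x
        if not (q < 1e200):
            raise _DivergedState()
        dx = raw_fun(t, x)
        q = dx @ dx
        if not (q < 1e200):
            raise _DivergedState()
        return dx

    return fun


@dataclass(frozen=True)
class Experiment:
    """One candidate experiment: an input perturbation, the outputs that may
    be measured, and the admissible measurement-time grid (hours)."""

    index: int
    input: tuple[float, ...]
    outputs: tuple[str, ...]
    time_grid: tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        grid = np.asarray(self.time_grid, float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
            raise ConfigError(
                "time_grid must be strictly increasing with all times > 0"
            )
        if len(self.outputs) == 0:
            raise ConfigError("an experiment must expose at least one output")

    @property
    def t_end(self) -> float:
        return float(self.time_grid[-1])

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.time_grid, float)


@dataclass
class Trajectory:
    """Simulated solution sampled on a time vector (linear scale)."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    outputs: np.ndarray  # (n_times, n_outputs)

    def output(self, model: "OdeModel", output_id: str) -> np.ndarray:
        return self.outputs[:, model.output_names.index(output_id)]


@dataclass
class OdeModel:
    """ODE model with output map and parameter-dependent initial state.

    ``vector_field(x, u, k, t)`` returns dx/dt for linear-scale free
    parameters ``k`` (the simulator converts from log10).  ``output_map``
    maps a state array of shape (..., n_states) to (..., n_outputs) and must
    not depend on inputs or parameters.  ``initial_state(u, k)`` is
    deterministic given its arguments.
    """

    name: str
    state_names: tuple[str, ...]
    output_names: tuple[str, ...]
    param_names: tuple[str, ...]
    fixed_params: dict[str, float]
    vector_field: Callable[[np.ndarray, np.ndarray, np.ndarray, float], np.ndarray]
    output_map: Callable[[np.ndarray], np.ndarray]
    initial_state: Callable[[np.ndarray, np.ndarray], np.ndarray]
    jacobian: Callable | None = None
    #: optional fast path: prepare_solver(u, k) -> (fun(t, x), jac(t, x))
    #: with all parameters bound, e.g. compiled kernels over a packed
    #: parameter vector; falls back to vector_field/jacobian when None
    prepare_solver: Callable | None = None
    rtol: float = 1e-8
    atol: float = 1e-10
    solve_counter: dict = field(default_factory=lambda: {"n_solves": 0})

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_outputs(self) -> int:
        return len(self.output_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def simulate(
    model: OdeModel,
    theta: np.ndarray,
    experiment: Experiment,
    times: Sequence[float] | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the model at log10 parameters ``theta`` under an
    experiment's input and sample exactly at ``times``.

    Parameters
    ----------
    times : time vector within [0, t_end]; defaults to the experiment grid.
    x0 : optional precomputed initial state (callers that simulate many
        experiments at the same theta can reuse the pre-equilibrated state).

    Raises :class:`SimulationError` instead of returning partial results.
    """
    theta = np.asarray(theta, float)
    if not np.all(np.isfinite(theta)):
        raise SimulationError("non-finite parameters", theta, experiment.index)
    k = 10.0 ** theta
    u = np.asarray(experiment.input, float)
    t_req = experiment.grid if times is None else np.asarray(times, float)
    if t_req.ndim != 1 or t_req.size == 0:
        raise ConfigError("times must be a non-empty 1-D vector")
    if t_req[0] < 0 or t_req[-1] > experiment.t_end + 1e-9:
        raise ConfigError("requested times outside [0, t_end]")

    if x0 is None:
        x0 = model.initial_state(u, k)
    x0 = np.asarray(x0, float)

    if model.prepare_solver is not None:
        raw_fun, jac = model.prepare_solver(u, k)
    else:
        raw_fun = lambda t, x: model.vector_field(x, u, k, t)
        jac = None
        if model.jacobian is not None:
            jac = lambda t, x: model.jacobian(x, u, k, t)
    fun = guard_rhs(raw_fun)

    # LSODA through the low-overhead odeint loop; integration starts at
    # t = 0 where x0 is defined
    if t_req[0] > 0.0:
        t_solve = np.concatenate([[0.0], t_req])
        skip = 1
    else:
        t_solve = t_req
        skip = 0
    model.solve_counter["n_solves"] += 1
    try:
        y, info = odeint(
            fun,
            x0,
            t_solve,
            Dfun=jac,
            tfirst=True,
            rtol=model.rtol,
            atol=model.atol,
            mxstep=10000,
            full_output=True,
        )
    except _DivergedState:
        raise SimulationError(
            f"non-finite derivative or diverging state in experiment "
            f"{experiment.index}",
            theta,
            experiment.index,
        ) from None
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"integration failed for experiment {experiment.index}: "
            f"{info['message']}",
            theta,
            experiment.index,
        )
    states = y[skip:]
    if not np.all(np.isfinite(states)):
        raise SimulationError(
            "non-finite states in solution", theta, experiment.index
        )
    outputs = np.asarray(model.output_map(states), float)
    return Trajectory(times=t_req.copy(), states=states, outputs=outputs)


def apply_input(
    basal_rates: Mapping[str, float], input: Mapping[str, float]
) -> dict[str, float]:
    """Scale basal synthesis rates by per-species perturbation multipliers.

    ``input`` maps species id -> multiplier (0.1 knockdown, 1 untouched,
    10 overexpression); the species' basal rate key is ``"b_<species>"``.
    Rates not named in ``input`` are untouched.
    """
    rates = dict(basal_rates)
    for species, mult in input.items():
        key = f"b_{species}"
        if key not in rates:
            raise ConfigError(f"unknown perturbable species {species!r}")
        rates[key] = rates[key] * float(mult)
    return rates


def build_catalogue(
    perturbable_species: Sequence[str],
    levels: Sequence[float],
    t_end: float,
    n_times: int,
    outputs: Sequence[str],
) -> list[Experiment]:
    """Enumerate every perturbation permutation of the given species.

    Returns ``len(levels) ** len(species)`` experiments in lexicographic
    order (species-major, level order as given), each carrying all
    observable outputs and an equidistant grid of ``n_times`` points
    spanning (0, t_end]: t_k = k * t_end / n_times, k = 1..n_times.
    """
    if len(levels) == 0:
        raise ConfigError("levels must be non-empty")
    if n_times < 1:
        raise ConfigError("n_times must be >= 1")
    grid = tuple(t_end * k / n_times for k in range(1, n_times + 1))
    experiments = []
    for idx, combo in enumerate(
        itertools.product(*[levels] * len(perturbable_species)), start=1
    ):
        label = ",".join(
            f"{sp}x{lv:g}" for sp, lv in zip(perturbable_species, combo)
        )
        experiments.append(
            Experiment(
                index=idx,
                input=tuple(float(v) for v in combo),
                outputs=tuple(outputs),
                time_grid=grid,
                label=label,
            )
        )
    return experiments
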