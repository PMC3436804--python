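"""Trajectory-oriented Bayesian experiment design.

The design objective is the spread of the posterior trajectory ensemble:
simulate every candidate experiment at a subsample of posterior parameter
draws, compute per-time-point sample variances of the log10 outputs, pick
for each (experiment, output) the time of maximal variance, zero out
variances at or below the noise floor (the pooled measurement-variance
estimate — measuring there cannot beat the measurement process itself), and
propose the experiment maximizing the summed surviving variances.  When no
(experiment, output) anywhere exceeds the floor the campaign stops.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import Dataset, pooled_variance
from .inference import PosteriorSample, estimate_entropy, sample_posterior, Prior
from .ode import Experiment, OdeModel, SimulationError, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryEnsemble",
    "Pick",
    "DesignProposal",
    "predict_ensemble",
    "predict_ensembles",
    "trajectory_variance",
    "select_time",
    "apply_stopping",
    "select_experiment",
    "propose_bayes",
    "BayesianTrajectoryDesign",
    "BayesianDesignResults",
]


@dataclass
class TrajectoryEnsemble:
    """log10 output trajectories of one (experiment, output) pair simulated
    at posterior draws; one row per draw that integrated successfully."""

    experiment_index: int
    output_id: str
    times: np.ndarray
    values: np.ndarray  # (n_draws_ok, n_times), log10 scale
    n_failed: int = 0


@dataclass(frozen=True)
class Pick:
    output_id: str
    time: float
    expected_variance: float


@dataclass
class DesignProposal:
    """Successor experiment, its (output, time) measurement requests with
    expected variances, and the stopping flag."""

    algorithm: str
    experiment_index: int | None
    picks: list[Pick]
    stop: bool
    threshold: float
    scores: dict[int, float] = field(default_factory=dict)
    round: int | None = None

    def to_json(self, path=None) -> str:
        obj = {
            "round": self.round,
            "algorithm": self.algorithm,
            "experiment_index": self.experiment_index,
            "picks": [
                {
                    "output": p.output_id,
                    "time_h": p.time,
                    "expected_variance": p.expected_variance,
                }
                for p in self.picks
            ],
            "stop": self.stop,
            "threshold": self.threshold,
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @property
    def requests(self) -> list[tuple[str, float]]:
        return [(p.output_id, p.time) for p in self.picks]


def predict_ensembles(
    sample: PosteriorSample,
    model: OdeModel,
    experiments: Sequence[Experiment],
    n_draws: int = 1000,
    seed: int = 0,
    draw_indices: np.ndarray | None = None,
    max_failure_frac: float = 0.1,
) -> dict[int, list[TrajectoryEnsemble]]:
    """Simulate ``n_draws`` posterior draws (uniform, without replacement)
    over the full grid of every experiment; returns, per experiment index,
    one :class:`TrajectoryEnsemble` per output.

    Draws are iterated in the outer loop so a model with a cached
    parameter-dependent initial state pays one pre-equilibration per draw.
    Draws that fail to integrate are excluded and counted; more than
    ``max_failure_frac`` failures for an experiment raise
    :class:`SimulationError`.
    """
    if draw_indices is None:
        if n_draws > sample.n:
            raise ValueError("n_draws exceeds posterior sample size")
        rng = np.random.default_rng(seed)
        draw_indices = rng.choice(sample.n, size=n_draws, replace=False)
    thetas = sample.draws[np.asarray(draw_indices)]
    n_draws = thetas.shape[0]
    floor = 1e-300  # guards log10 of an exactly-zero output
    rows: dict[int, list[np.ndarray]] = {e.index: [] for e in experiments}
    failed: dict[int, int] = {e.index: 0 for e in experiments}
    for theta in thetas:
        for exp in experiments:
            try:
                traj = simulate(model, theta, exp)
            except SimulationError:
                failed[exp.index] += 1
                continue
            rows[exp.index].append(
                np.log10(np.maximum(traj.outputs, floor))
            )
    result: dict[int, list[TrajectoryEnsemble]] = {}
    for exp in experiments:
        if failed[exp.index] > max_failure_frac * n_draws:
            raise SimulationError(
                f"{failed[exp.index]}/{n_draws} draws failed for experiment "
                f"{exp.index}; posterior inconsistent with model",
                experiment_index=exp.index,
            )
        vals = np.stack(rows[exp.index])  # (n_ok, n_times, n_outputs)
        result[exp.index] = [
            TrajectoryEnsemble(
                experiment_index=exp.index,
                output_id=oid,
                times=exp.grid,
                values=vals[:, :, j],
                n_failed=failed[exp.index],
            )
            for j, oid in enumerate(model.output_names)
        ]
    return result


def predict_ensemble(
    sample: PosteriorSample,
    model: OdeModel,
    experiment: Experiment,
    n_draws: int = 1000,
    seed: int = 0,
) -> list[TrajectoryEnsemble]:
    """Trajectory ensembles (one per output) for a single experiment."""
    return predict_ensembles(
        sample, model, [experiment], n_draws=n_draws, seed=seed
    )[experiment.index]


def trajectory_variance(
    ensemble: TrajectoryEnsemble,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time unbiased sample variance (divisor N-1) and sample mean of
    the log10 ensemble values across draws."""
    if ensemble.values.shape[0] < 2:
        raise ValueError("trajectory variance undefined for < 2 ensemble rows")
    return (
        ensemble.values.var(axis=0, ddof=1),
        ensemble.values.mean(axis=0),
    )


def select_time(
    variances: np.ndarray, grid: np.ndarray
) -> tuple[float, float]:
    """Grid time of maximal predicted variance (earliest time on ties)."""
    variances = np.asarray(variances, float)
    grid = np.asarray(grid, float)
    if variances.shape != grid.shape:
        raise ValueError("variances and grid must have the same length")
    i = int(np.argmax(variances))  # argmax returns the first maximum
    return float(grid[i]), float(variances[i])


def apply_stopping(
    max_variances: Mapping[tuple[int, str], float], threshold: float
) -> dict[tuple[int, str], float]:
    """Noise-floor thresholding: v stays if strictly above the pooled
    measurement-variance estimate, else it is set to 0."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return {
        key: (v if v > threshold else 0.0) for key, v in max_variances.items()
    }


def select_experiment(
    tilde_v: Mapping[tuple[int, str], float],
    times: Mapping[tuple[int, str], float] | None = None,
    threshold: float = 0.0,
    algorithm: str = "bayes",
) -> DesignProposal:
    """Successor experiment maximizing the per-experiment sum of surviving
    expected variances (lowest index on ties); picks are the winner's
    outputs with nonzero thresholded variance at their argmax times.  The
    stop flag is raised iff every thresholded variance is zero."""
    sums: dict[int, float] = {}
    for (i, _j), v in tilde_v.items():
        sums[i] = sums.get(i, 0.0) + v
    if not sums:
        raise ValueError("empty candidate map")
    stop = all(v == 0.0 for v in tilde_v.values())
    if stop:
        return DesignProposal(
            algorithm=algorithm, experiment_index=None, picks=[],
            stop=True, threshold=threshold, scores=sums,
        )
    best = min(i for i, s in sums.items() if s == max(sums.values()))
    picks = [
        Pick(j, 0.0 if times is None else float(times[(i, j)]), float(v))
        for (i, j), v in sorted(tilde_v.items(), key=lambda kv: kv[0][1])
        if i == best and v > 0.0
    ]
    return DesignProposal(
        algorithm=algorithm, experiment_index=best, picks=picks,
        stop=False, threshold=threshold, scores=sums,
    )


def propose_bayes(
    ensembles: Mapping[int, list[TrajectoryEnsemble]], threshold: float
) -> DesignProposal:
    """Full Bayesian design step from precomputed trajectory ensembles:
    per-(experiment, output) argmax-variance time, noise-floor
    thresholding, experiment selection."""
    max_v: dict[tuple[int, str], float] = {}
    t_star: dict[tuple[int, str], float] = {}
    for i, ens_list in ensembles.items():
        for ens in ens_list:
            var, _ = trajectory_variance(ens)
            t, v = select_time(var, ens.times)
            max_v[(i, ens.output_id)] = v
            t_star[(i, ens.output_id)] = t
    tilde = apply_stopping(max_v, threshold)
    return select_experiment(tilde, times=t_star, threshold=threshold)


class BayesianTrajectoryDesign:
    """Model object for one design round: the ODE model, the candidate
    experiment catalogue, the data measured so far and the prior.

    ``fit`` runs the adaptive-Metropolis posterior sampler and returns a
    :class:`BayesianDesignResults` from which predictions, design proposals,
    entropy estimates and summaries are obtained.
    """

    def __init__(
        self,
        model: OdeModel,
        experiments: Sequence[Experiment],
        dataset: Dataset,
        prior: Prior,
        sigma: float | None = None,
    ):
        self.model = model
        self.experiments = list(experiments)
        self.experiment_map = {e.index: e for e in self.experiments}
        self.dataset = dataset
        self.prior = prior
        #: noise s.d. used in the likelihood and (squared) as the design
        #: stopping threshold; profiled from the data when not given
        self.sigma = float(
            np.sqrt(pooled_variance(dataset)) if sigma is None else sigma
        )

    def fit(self, n_chains: int = 4, n_steps: int = 20000, seed: int = 0,
            **mcmc_kwargs) -> "BayesianDesignResults":
        posterior = sample_posterior(
            self.dataset, self.sigma, self.model, self.prior,
            self.experiment_map, n_chains=n_chains, n_steps=n_steps,
            seed=seed, **mcmc_kwargs,
        )
        return BayesianDesignResults(self, posterior)


class BayesianDesignResults:
    """Posterior-backed results: design proposals, ensemble predictions,
    entropy and summary hang off this object."""

    def __init__(self, design: BayesianTrajectoryDesign, posterior: PosteriorSample):
        self.design = design
        self.posterior = posterior

    def predict(
        self, n_draws: int = 1000, seed: int = 0,
        experiments: Sequence[Experiment] | None = None,
    ) -> dict[int, list[TrajectoryEnsemble]]:
        n_draws = min(n_draws, self.posterior.n)
        return predict_ensembles(
            self.posterior, self.design.model,
            experiments if experiments is not None else self.design.experiments,
            n_draws=n_draws, seed=seed,
        )

    def propose(
        self, n_draws: int = 1000, seed: int = 0,
        threshold: float | None = None,
    ) -> DesignProposal:
        thr = self.design.sigma ** 2 if threshold is None else threshold
        return propose_bayes(self.predict(n_draws=n_draws, seed=seed), thr)

    def entropy(self, n_eval: int = 1000, seed: int = 0) -> float:
        """KDE posterior-entropy estimate in nats (boundary-corrected at
        the prior box, the posterior's support)."""
        return estimate_entropy(
            self.posterior, n_eval=n_eval, seed=seed, support=self.design.prior
        )

    def summary(self) -> str:
        names = self.posterior.param_names or tuple(
            f"theta{i+1}" for i in range(self.posterior.n_params)
        )
        q = np.percentile(self.posterior.draws, [2.5, 50, 97.5], axis=0)
        lines = [
            "Trajectory-oriented Bayesian design: posterior summary",
            f"  draws: {self.posterior.n}   sigma: {self.design.sigma:.4g}   "
            f"data points: {self.design.dataset.n_points}",
            f"  {'param':>10}  {'median':>9}  {'2.5%':>9}  {'97.5%':>9}",
        ]
        for j, name in enumerate(names):
            lines.append(
                f"  {name:>10}  {q[1, j]:9.3f}  {q[0, j]:9.3f}  {q[2, j]:9.3f}"
            )
        acc = self.posterior.diagnostics.get("acceptance_rates")
        if acc is not None:
            lines.append(
                "  acceptance rates: "
                + ", ".join(f"{a:.2f}" for a in acc)
            )
        return "\n".join(lines)

    def plot_ensemble(self, experiment: Experiment, n_draws: int = 200,
                      seed: int = 0, ax=None):
        """Spaghetti plot of posterior-predicted log10 trajectories per
        output, with the argmax-variance proposal times as vertical lines."""
        import matplotlib.pyplot as plt

        ens_list = predict_ensemble(
            self.posterior, self.design.model, experiment,
            n_draws=min(n_draws, self.posterior.n), seed=seed,
        )
        if ax is None:
            _, axes = plt.subplots(
                1, len(ens_list), figsize=(3 * len(ens_list), 2.5),
                squeeze=False,
            )
            axes = axes[0]
        else:
            axes = np.atleast_1d(ax)
        for a, ens in zip(axes, ens_list):
            a.plot(ens.times, ens.values.T, color="C0", alpha=0.05, lw=0.5)
            var, _ = trajectory_variance(ens)
            t_star, _ = select_time(var, ens.times)
            a.axvline(t_star, color="C3", lw=1)
            a.set_title(ens.output_id)
            a.set_xlabel("t [h]")
        return axes
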