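"""A-optimal Fisher-design comparator.

Sensitivities of log10 outputs to log10 parameters come from central finite
differences; Fisher information matrices (FIMs) are assembled as sums of
outer products g g^T / sigma^2 over measured points, so they superpose over
experiments, outputs and times.  The selection criterion is the modified
(inversion-free) A-optimality: maximize trace(F).  Because the trace is
additive, the best time per (experiment, output), the best m-output subset
per experiment, and the best successor experiment all decouple exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import Dataset, pooled_variance
from .bayes import DesignProposal, Pick
from .inference import MleResult, Prior, find_mle
from .ode import Experiment, OdeModel, SimulationError, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "FisherMatrix",
    "sensitivities",
    "assemble_fim",
    "candidate_traces",
    "a_optimal_select",
    "AOptimalDesign",
    "AOptimalResults",
    "fisher_round",
]


@dataclass
class FisherMatrix:
    """Symmetric PSD information matrix with the measured points that
    produced it; adding two FisherMatrix objects concatenates the point
    lists and sums the matrices (superposition)."""

    matrix: np.ndarray
    contributing_points: list[tuple[int, str, float]] = field(default_factory=list)

    def __add__(self, other: "FisherMatrix") -> "FisherMatrix":
        return FisherMatrix(
            self.matrix + other.matrix,
            self.contributing_points + other.contributing_points,
        )

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))


def sensitivities(
    model: OdeModel,
    theta_hat: np.ndarray,
    experiment: Experiment,
    times: np.ndarray | None = None,
    step: float = 0.01,
    prior: Prior | None = None,
) -> np.ndarray:
    """Finite-difference sensitivities d(log10 y)/d(theta) on the log10
    parameter scale, shape (n_times, n_outputs, n_params).

    Central differences of step ``step`` (log10 units); when a prior box is
    given and theta_hat sits within ``step`` of a boundary, the difference
    for that parameter is one-sided.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    theta_hat = np.asarray(theta_hat, float)
    t = experiment.grid if times is None else np.asarray(times, float)
    floor = 1e-300
    n_p = theta_hat.size
    sens = np.empty((t.size, model.n_outputs, n_p))
    for kparam in range(n_p):
        lo_ok = up_ok = True
        if prior is not None:
            lo_ok = theta_hat[kparam] - step >= prior.lo[kparam]
            up_ok = theta_hat[kparam] + step <= prior.up[kparam]
            if not (lo_ok or up_ok):
                raise ValueError("prior box narrower than the difference step")

        def log10_y(theta):
            try:
                traj = simulate(model, theta, experiment, times=t)
            except SimulationError as err:
                raise SimulationError(
                    f"sensitivity simulation failed for parameter "
                    f"{model.param_names[kparam]}",
                    theta, experiment.index,
                ) from err
            return np.log10(np.maximum(traj.outputs, floor))

        th_up, th_lo = theta_hat.copy(), theta_hat.copy()
        if lo_ok and up_ok:
            th_up[kparam] += step
            th_lo[kparam] -= step
            denom = 2.0 * step
        elif up_ok:
            th_up[kparam] += step
            denom = step
        else:
            th_lo[kparam] -= step
            denom = step
        sens[:, :, kparam] = (log10_y(th_up) - log10_y(th_lo)) / denom
    return sens


def assemble_fim(
    sens: np.ndarray,
    sigma: float,
    points: Sequence[tuple[str, float]],
    model: OdeModel,
    experiment: Experiment,
    times: np.ndarray | None = None,
    n_replicates: int = 1,
) -> FisherMatrix:
    """FIM of a set of (output, time) points: sum over points (and
    replicates) of g g^T / sigma^2 with g the sensitivity vector."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = experiment.grid if times is None else np.asarray(times, float)
    t_index = {float(tv): i for i, tv in enumerate(t)}
    out_index = {oid: j for j, oid in enumerate(model.output_names)}
    n_p = sens.shape[2]
    F = np.zeros((n_p, n_p))
    pts = []
    for oid, tv in points:
        g = sens[t_index[float(tv)], out_index[oid]]
        F += n_replicates * np.outer(g, g) / sigma ** 2
        pts.append((experiment.index, oid, float(tv)))
    return FisherMatrix(F, pts)


def candidate_traces(
    model: OdeModel,
    theta_hat: np.ndarray,
    experiments: Sequence[Experiment],
    sigma: float,
    step: float = 0.01,
    prior: Prior | None = None,
    n_replicates: int = 1,
) -> dict[int, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Anticipatory update-FIM traces for every candidate (experiment,
    output, time): trace(g g^T)/sigma^2 = |g|^2 n_repl / sigma^2, returned
    as {exp index: {output: (times, traces)}}."""
    result: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for exp in experiments:
        sens = sensitivities(model, theta_hat, exp, step=step, prior=prior)
        per_out = {}
        for j, oid in enumerate(exp.outputs):
            jm = model.output_names.index(oid)
            tr = n_replicates * np.sum(sens[:, jm, :] ** 2, axis=1) / sigma ** 2
            per_out[oid] = (exp.grid, tr)
        result[exp.index] = per_out
    return result


def a_optimal_select(
    current_fim: FisherMatrix,
    candidates: Mapping[int, Mapping[str, tuple[np.ndarray, np.ndarray]]],
    m: int,
) -> DesignProposal:
    """Modified A-optimal successor selection.

    For each candidate (experiment, output) the best measurement time
    maximizes the update-FIM trace; per experiment the best m-output subset
    is the top-m by trace (exact, since traces superpose); the successor
    experiment maximizes the subset's summed trace.  Ties break toward
    lowest experiment index, output catalogue order and earliest time.  The
    current FIM contributes a selection-independent constant to
    trace(F + dF), so decisions depend on the update traces only.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not candidates:
        raise ValueError("empty candidate set")
    if m > max(len(per_out) for per_out in candidates.values()):
        raise ValueError("m exceeds the number of outputs of every experiment")
    best_i, best_sum, best_picks = None, -np.inf, None
    for i in sorted(candidates):
        per_out = candidates[i]
        per_out_best = []
        for oid, (times, traces) in per_out.items():
            kk = int(np.argmax(traces))  # first max -> earliest time
            per_out_best.append((float(traces[kk]), oid, float(times[kk])))
        if len(per_out_best) < m:
            continue
        # top-m by trace; stable order so catalogue order breaks ties
        chosen = sorted(
            per_out_best, key=lambda r: -r[0]
        )[:m]
        total = sum(r[0] for r in chosen)
        if total > best_sum:
            best_i, best_sum, best_picks = i, total, chosen
    picks = [
        Pick(oid, tv, tr) for tr, oid, tv in best_picks
    ]
    return DesignProposal(
        algorithm="a_optimal",
        experiment_index=best_i,
        picks=picks,
        stop=False,
        threshold=0.0,
        scores={
            i: float(
                sum(sorted((np.max(tr) for _, (_, tr) in per.items()), reverse=True)[:m])
            )
            for i, per in candidates.items()
            if len(per) >= m
        },
    )


class AOptimalDesign:
    """Model object for one Fisher-design round; ``fit`` re-estimates the
    MLE by multi-start optimization and builds the current FIM from all
    performed measurements."""

    def __init__(
        self,
        model: OdeModel,
        experiments: Sequence[Experiment],
        dataset: Dataset,
        prior: Prior,
        sigma: float | None = None,
        step: float = 0.01,
    ):
        self.model = model
        self.experiments = list(experiments)
        self.experiment_map = {e.index: e for e in self.experiments}
        self.dataset = dataset
        self.prior = prior
        self.sigma = float(
            np.sqrt(pooled_variance(dataset)) if sigma is None else sigma
        )
        self.step = step

    def fit(self, n_starts: int = 4, seed: int = 0, maxiter: int = 200) -> "AOptimalResults":
        mle = find_mle(
            self.dataset, self.sigma, self.model, self.prior,
            self.experiment_map, n_starts=n_starts, seed=seed, maxiter=maxiter,
        )
        at_boundary = np.any(
            (mle.theta - self.step < self.prior.lo)
            | (mle.theta + self.step > self.prior.up)
        )
        if at_boundary:
            logger.warning(
                "MLE at prior boundary; one-sided sensitivities will be used"
            )
        return AOptimalResults(self, mle)


class AOptimalResults:
    """MLE-backed results: current FIM and A-optimal proposals."""

    def __init__(self, design: AOptimalDesign, mle: MleResult):
        self.design = design
        self.mle = mle

    @property
    def theta_hat(self) -> np.ndarray:
        return self.mle.theta

    def current_fim(self) -> FisherMatrix:
        """FIM of all already-performed measurements at the MLE."""
        d = self.design
        n_p = len(d.model.param_names)
        total = FisherMatrix(np.zeros((n_p, n_p)))
        by_exp: dict[int, list] = {}
        for meas in d.dataset.measurements:
            by_exp.setdefault(meas.experiment_index, []).append(meas)
        for ei, ms in sorted(by_exp.items()):
            exp = d.experiment_map[ei]
            times = np.array(sorted({m.time for m in ms}))
            sens = sensitivities(
                d.model, self.theta_hat, exp, times=times,
                step=d.step, prior=d.prior,
            )
            for m in ms:
                total += assemble_fim(
                    sens, d.sigma, [(m.output_id, m.time)], d.model, exp,
                    times=times, n_replicates=len(m.replicates),
                )
        return total

    def propose(self, m: int, n_replicates: int = 3) -> DesignProposal:
        cands = candidate_traces(
            self.design.model, self.theta_hat, self.design.experiments,
            self.design.sigma, step=self.design.step, prior=self.design.prior,
            n_replicates=n_replicates,
        )
        return a_optimal_select(self.current_fim(), cands, m)

    def summary(self) -> str:
        F = self.current_fim()
        eig = np.linalg.eigvalsh(F.matrix)
        lines = [
            "A-optimal Fisher design: MLE summary",
            f"  log-likelihood: {self.mle.log_likelihood:.3f}   "
            f"data points: {self.design.dataset.n_points}",
            "  theta_hat: "
            + ", ".join(f"{v:.3f}" for v in self.theta_hat),
            f"  current FIM trace: {F.trace:.4g}   "
            f"eigenvalue range: [{eig.min():.3g}, {eig.max():.3g}]",
        ]
        return "\n".join(lines)


def fisher_round(
    model: OdeModel,
    experiments: Sequence[Experiment],
    dataset: Dataset,
    prior: Prior,
    m: int,
    sigma: float | None = None,
    n_starts: int = 4,
    seed: int = 0,
    step: float = 0.01,
    n_replicates: int = 3,
    maxiter: int = 200,
) -> DesignProposal:
    """One full Fisher-design round: re-estimate the MLE from the current
    data, build candidate update FIMs, and select the successor experiment
    with exactly ``m`` measurements (the fairness-coupled count from the
    matched Bayesian round)."""
    res = AOptimalDesign(
        model, experiments, dataset, prior, sigma=sigma, step=step
    ).fit(n_starts=n_starts, seed=seed, maxiter=maxiter)
    return res.propose(m, n_replicates=n_replicates)
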