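"""Likelihood, prior, maximum-likelihood estimation, adaptive-Metropolis
posterior sampling with convergence screening, and kernel-density entropy
estimation.

All parameters live on the log10 scale inside a bounded log-uniform prior
box (four orders of magnitude per coordinate by default).  The likelihood is
Gaussian on log10-transformed data: each replicate z of a simulated output y
contributes ``log N(log10 z | log10 y, sigma^2)``; simulation failures map
to -inf so the samplers and optimizers treat the parameter point as
infeasible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data import Dataset
from .ode import Experiment, OdeModel, SimulationError, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "Prior",
    "PosteriorSample",
    "MleResult",
    "log_likelihood",
    "find_mle",
    "adaptive_metropolis",
    "sample_posterior",
    "gelman_rubin",
    "estimate_entropy",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Prior:
    """Bounded log-uniform prior box in log10-parameter space."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self):
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != up.shape or np.any(up <= lo):
            raise ValueError("prior needs upper > lower in every coordinate")

    @classmethod
    def centered(cls, center: np.ndarray, half_width: float = 2.0) -> "Prior":
        """Box of width ``2 * half_width`` decades around a centre (the
        default half-width 2 gives the four-decade support)."""
        c = np.asarray(center, float)
        return cls(tuple(c - half_width), tuple(c + half_width))

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.lower, float)

    @property
    def up(self) -> np.ndarray:
        return np.asarray(self.upper, float)

    @property
    def n_params(self) -> int:
        return len(self.lower)

    def contains(self, theta: np.ndarray) -> bool:
        t = np.asarray(theta, float)
        return bool(np.all(t >= self.lo) and np.all(t <= self.up))

    def log_pdf(self, theta: np.ndarray) -> float:
        if not self.contains(theta):
            return -np.inf
        return -float(np.sum(np.log(self.up - self.lo)))

    def sample(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        size = (self.n_params,) if n is None else (n, self.n_params)
        return rng.uniform(self.lo, self.up, size=size)

    @property
    def entropy(self) -> float:
        """Differential entropy of the uniform box, nats."""
        return float(np.sum(np.log(self.up - self.lo)))


def log_likelihood(
    theta: np.ndarray,
    dataset: Dataset,
    sigma: float,
    model: OdeModel,
    experiments: Mapping[int, Experiment],
) -> float:
    """Gaussian log-likelihood of log10 replicates around log10 simulated
    outputs, summed over all measurements (independence assumption); one ODE
    solve per experiment present in the dataset.  Returns -inf when
    simulation fails at theta."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    by_exp: dict[int, list] = {}
    for m in dataset.measurements:
        by_exp.setdefault(m.experiment_index, []).append(m)
    out_index = {oid: j for j, oid in enumerate(model.output_names)}
    total = 0.0
    for ei, ms in sorted(by_exp.items()):
        times = sorted({m.time for m in ms})
        try:
            traj = simulate(model, theta, experiments[ei], times=np.array(times))
        except SimulationError:
            logger.warning("simulation failure at theta in experiment %d -> -inf", ei)
            return -np.inf
        t_index = {t: i for i, t in enumerate(times)}
        for m in ms:
            y = traj.outputs[t_index[m.time], out_index[m.output_id]]
            if y <= 0 or not np.isfinite(y):
                return -np.inf
            resid = np.log10(np.asarray(m.replicates)) - np.log10(y)
            total += float(
                -0.5 * np.sum((resid / sigma) ** 2)
                - len(resid) * (np.log(sigma) + _LOG_SQRT_2PI)
            )
    return total


@dataclass
class MleResult:
    """Best local optimum over multi-starts, with the per-start optima kept
    so callers can detect non-identifiability across restarts."""

    theta: np.ndarray
    log_likelihood: float
    all_optima: list[tuple[np.ndarray, float]]


def find_mle(
    dataset: Dataset,
    sigma: float,
    model: OdeModel,
    prior: Prior,
    experiments: Mapping[int, Experiment],
    n_starts: int = 4,
    seed: int = 0,
    maxiter: int = 200,
) -> MleResult:
    """Multi-start maximum-likelihood estimation constrained to the prior
    box (L-BFGS-B with numerical gradients from prior-uniform starts)."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    bounds = list(zip(prior.lo, prior.up))
    big = 1e12

    def neg_ll(theta):
        ll = log_likelihood(theta, dataset, sigma, model, experiments)
        return big if not np.isfinite(ll) else -ll

    optima: list[tuple[np.ndarray, float]] = []
    for _ in range(n_starts):
        x0 = prior.sample(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                neg_ll, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter},
            )
        optima.append((np.asarray(res.x), -float(res.fun)))
    best_theta, best_ll = max(optima, key=lambda p: p[1])
    if not np.isfinite(best_ll) or best_ll <= -big / 2:
        logger.warning("no MLE start improved on an infeasible objective")
    return MleResult(theta=best_theta, log_likelihood=best_ll, all_optima=optima)


def adaptive_metropolis(
    log_target: Callable[[np.ndarray], float],
    x0s: np.ndarray,
    n_steps: int,
    seed: int = 0,
    adapt_interval: int = 100,
    adapt_start: int = 200,
    initial_scale: float = 0.1,
    jitter: float = 1e-10,
    prev: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Haario-style adaptive Metropolis on an arbitrary log-target.

    Gaussian random-walk proposals; every ``adapt_interval`` steps (after
    ``adapt_start``) the proposal covariance is re-estimated from the
    pooled history of all chains, scaled by 2.38^2 / d, with a small
    diagonal jitter.  Chains run in lockstep and share the proposal, so
    the spread between chains feeds back into the proposal and parallel
    chains mix into each other's regions far faster than with per-chain
    adaptation.  On box-constrained sloppy targets the resulting
    acceptance rate runs below the 0.234 Gaussian optimum; the
    deliberately over-dispersed proposals are what carries chains across
    flat directions, so no acceptance-rate steering is applied.

    A previous run's (chains, log_targets) can be passed as ``prev`` to
    continue sampling warm: chains resume from their last states and the
    pooled adaptation history includes the earlier draws.

    Returns (chains, log_targets, acceptance_rates) with chains of shape
    (n_chains, n_prev + n_steps, d); acceptance rates cover the new block.
    """
    x0s = np.atleast_2d(np.asarray(x0s, float))
    n_chains, d = x0s.shape
    rng = np.random.default_rng(seed)
    n_prev = 0 if prev is None else prev[0].shape[1]
    chains = np.empty((n_chains, n_prev + n_steps, d))
    logps = np.empty((n_chains, n_prev + n_steps))
    scale = 2.38 ** 2 / d
    if prev is None:
        xs = x0s.copy()
        lps = np.array([log_target(x) for x in xs])
        if not np.all(np.isfinite(lps)):
            raise ValueError("chain start has zero target density")
        chol = np.linalg.cholesky(np.eye(d) * initial_scale ** 2 / d)
    else:
        chains[:, :n_prev] = prev[0]
        logps[:, :n_prev] = prev[1]
        xs = prev[0][:, -1].copy()
        lps = prev[1][:, -1].copy()
        hist = prev[0].reshape(-1, d)
        chol = np.linalg.cholesky(
            scale * np.cov(hist.T) + max(jitter, 1e-8) * np.eye(d)
        )
    n_acc = np.zeros(n_chains)
    for s in range(n_prev, n_prev + n_steps):
        noise = rng.standard_normal((n_chains, d))
        logu = np.log(rng.uniform(size=n_chains))
        for c in range(n_chains):
            prop = xs[c] + chol @ noise[c]
            lp_prop = log_target(prop)
            if logu[c] < lp_prop - lps[c]:
                xs[c], lps[c] = prop, lp_prop
                n_acc[c] += 1
        chains[:, s] = xs
        logps[:, s] = lps
        if s + 1 >= adapt_start and (s + 1) % adapt_interval == 0:
            hist = chains[:, : s + 1].reshape(-1, d)
            cov = scale * np.cov(hist.T) + jitter * np.eye(d)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                chol = np.linalg.cholesky(cov + 1e-8 * np.eye(d))
    return chains, logps, n_acc / n_steps


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Split potential-scale-reduction statistic per parameter for chains of
    shape (n_chains, n_steps, d)."""
    n_chains, n_steps, d = chains.shape
    half = n_steps // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n, _ = split.shape
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(W > 0, rhat, 1.0)


@dataclass
class PosteriorSample:
    """Merged posterior draws in log10 space with provenance."""

    draws: np.ndarray  # (N, d)
    log_posterior: np.ndarray  # (N,)
    chain_ids: np.ndarray  # (N,)
    converged: dict[int, bool]
    diagnostics: dict = field(default_factory=dict)
    param_names: tuple[str, ...] | None = None

    @property
    def n(self) -> int:
        return self.draws.shape[0]

    @property
    def n_params(self) -> int:
        return self.draws.shape[1]

    def to_csv(self, path, sidecar: str | None = None) -> None:
        names = self.param_names or tuple(
            f"theta{i+1}" for i in range(self.n_params)
        )
        df = pd.DataFrame(self.draws, columns=list(names))
        df.insert(0, "chain", self.chain_ids)
        df["log_posterior"] = self.log_posterior
        df.to_csv(path, index=False)
        if sidecar is not None:
            meta = {
                "converged": {str(k): bool(v) for k, v in self.converged.items()},
                "diagnostics": _jsonify(self.diagnostics),
                "param_names": list(names),
            }
            with open(sidecar, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path, sidecar: str | None = None) -> "PosteriorSample":
        df = pd.read_csv(path, float_precision="round_trip")
        names = tuple(c for c in df.columns if c not in ("chain", "log_posterior"))
        converged, diagnostics = {}, {}
        if sidecar is not None:
            with open(sidecar) as fh:
                meta = json.load(fh)
            converged = {int(k): v for k, v in meta.get("converged", {}).items()}
            diagnostics = meta.get("diagnostics", {})
        return cls(
            draws=df[list(names)].to_numpy(),
            log_posterior=df["log_posterior"].to_numpy(),
            chain_ids=df["chain"].to_numpy(),
            converged=converged or {int(c): True for c in np.unique(df["chain"])},
            diagnostics=diagnostics,
            param_names=names,
        )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def sample_posterior(
    dataset: Dataset,
    sigma: float,
    model: OdeModel,
    prior: Prior,
    experiments: Mapping[int, Experiment],
    n_chains: int = 4,
    n_steps: int = 20000,
    seed: int = 0,
    burn_frac: float = 0.5,
    thin: int = 1,
    rhat_threshold: float = 1.1,
    init: str | np.ndarray = "mle",
    adapt_interval: int = 100,
    adapt_start: int = 200,
    mle_starts: int = 3,
    mle_maxiter: int = 60,
    max_extensions: int = 2,
    allow_partial: bool = False,
) -> PosteriorSample:
    """Adaptive-Metropolis posterior sampling with convergence screening.

    Chains start either from jittered multi-start MLE points
    (``init="mle"``, the default — random prior starts take far longer to
    burn in) or from prior-uniform points (``init="prior"``).  After
    discarding burn-in (the first ``burn_frac`` of each chain), chains
    whose removal is needed to bring the split potential-scale-reduction
    statistic under ``rhat_threshold`` are discarded (at least two chains
    are always retained).  If the retained chains still exceed the
    threshold, sampling continues warm for another ``n_steps`` block, up
    to ``max_extensions`` times, before all chains are flagged
    non-converged and an error is raised — unless ``allow_partial`` is
    set, in which case the least-discrepant chain subset is returned with
    every chain flagged non-converged (callers that must complete a
    protocol, like the campaign driver, use this and record the flag).
    """
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2 for convergence screening")
    rng = np.random.default_rng(seed)
    d = prior.n_params

    def log_target(theta):
        lp = prior.log_pdf(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + log_likelihood(theta, dataset, sigma, model, experiments)

    if isinstance(init, np.ndarray):
        x0s = np.atleast_2d(init)
    elif init == "prior" or len(dataset) == 0:
        x0s = prior.sample(rng, n_chains)
    elif init == "mle":
        mle = find_mle(
            dataset, sigma, model, prior, experiments,
            n_starts=mle_starts, seed=int(rng.integers(2 ** 31)),
            maxiter=mle_maxiter,
        )
        jit = 0.05 * rng.standard_normal((n_chains, d))
        x0s = np.clip(mle.theta + jit, prior.lo, prior.up)
    else:
        raise ValueError(f"unknown init {init!r}")
    # ensure finite start density
    for c in range(x0s.shape[0]):
        for _ in range(200):
            if np.isfinite(log_target(x0s[c])):
                break
            x0s[c] = prior.sample(rng)
        else:
            raise RuntimeError("could not find a feasible chain start")

    prev = None
    for extension in range(max_extensions + 1):
        chains, logps, acc = adaptive_metropolis(
            log_target, x0s, n_steps, seed=int(rng.integers(2 ** 31)),
            adapt_interval=adapt_interval, adapt_start=adapt_start,
            prev=prev,
        )
        prev = (chains, logps)
        total = chains.shape[1]
        burn = int(burn_frac * total)
        post = chains[:, burn::thin]
        post_lp = logps[:, burn::thin]

        kept = list(range(n_chains))
        rhat = gelman_rubin(post)
        while np.max(rhat) > rhat_threshold and len(kept) > 2:
            # drop the chain whose mean is farthest from the median mean
            means = post[kept].mean(axis=1)
            med = np.median(means, axis=0)
            spread = post[kept].std(axis=(0, 1)) + 1e-12
            dist = np.sum(((means - med) / spread) ** 2, axis=1)
            kept.pop(int(np.argmax(dist)))
            rhat = gelman_rubin(post[kept])
        if np.max(rhat) <= rhat_threshold:
            break
        if extension < max_extensions:
            logger.warning(
                "max R-hat %.2f above %.2f; extending chains warm by %d "
                "steps", np.max(rhat), rhat_threshold, n_steps,
            )
    converged = {c: (c in kept and bool(np.max(rhat) <= rhat_threshold))
                 for c in range(n_chains)}
    partial = not any(converged.values())
    if partial:
        if not allow_partial:
            raise RuntimeError(
                "no chain passed convergence screening "
                f"(max R-hat {np.max(rhat):.3f}); increase n_steps"
            )
        logger.warning(
            "proceeding with non-converged posterior (max R-hat %.2f, "
            "%d retained chains); treat downstream metrics with care",
            np.max(rhat), len(kept),
        )

    draws = np.concatenate([post[c] for c in kept], axis=0)
    lp = np.concatenate([post_lp[c] for c in kept], axis=0)
    ids = np.concatenate([np.full(post.shape[1], c) for c in kept])
    return PosteriorSample(
        draws=draws,
        log_posterior=lp,
        chain_ids=ids,
        converged=converged,
        diagnostics={
            "acceptance_rates": acc.tolist(),
            "rhat": gelman_rubin(post[kept]).tolist(),
            "n_steps": total,
            "burn": burn,
            "kept_chains": kept,
            "partial": partial,
        },
        param_names=model.param_names,
    )


def estimate_entropy(
    sample: "PosteriorSample | np.ndarray",
    n_eval: int = 1000,
    seed: int = 0,
    support: tuple[np.ndarray, np.ndarray] | Prior | None = None,
    chunk: int = 50,
) -> float:
    """Differential-entropy estimate of a sample, in nats.

    Fits a Gaussian-product kernel density estimator on the full sample
    (diagonal bandwidth matrix, per-dimension Silverman rule) and returns
    ``-(1/n_eval) * sum log P_hat(theta_s)`` over a without-replacement
    evaluation subsample of the draws.  The evaluation point's own kernel
    is left out (Ahmad-Lin style) — keeping it biases the estimate low by
    the self-contribution, severely so in high dimension.  When the sample
    has known bounded support (``support=(lower, upper)`` or a
    :class:`Prior` box, as for any posterior under a box prior), the kernel
    is reflected at the faces, removing the boundary deficit of the plain
    product KDE.  Zero-variance dimensions get a bandwidth floor (with a
    warning)."""
    draws = sample.draws if isinstance(sample, PosteriorSample) else np.asarray(sample, float)
    draws = np.atleast_2d(draws)
    n, d = draws.shape
    if n < 2:
        raise ValueError("need at least two draws")
    n_eval = min(n_eval, n)
    if n_eval < 1:
        raise ValueError("need at least one evaluation point")
    sd = draws.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        logger.warning("degenerate sample dimension; applying bandwidth floor")
        sd = np.maximum(sd, 1e-8)
    h = sd * (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))
    if isinstance(support, Prior):
        support = (support.lo, support.up)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_eval, replace=False) if n_eval < n else np.arange(n)
    pts = draws[idx]
    log_norm = np.log(n - 1) + np.sum(np.log(h)) + d * 0.5 * np.log(2.0 * np.pi)
    logp = np.empty(n_eval)
    for start in range(0, n_eval, chunk):
        block = pts[start : start + chunk]
        L = np.zeros((block.shape[0], n))
        for kdim in range(d):
            diff = (block[:, kdim, None] - draws[None, :, kdim]) / h[kdim]
            A = -0.5 * diff * diff
            if support is not None:
                lo, up = support[0][kdim], support[1][kdim]
                rlo = (block[:, kdim, None] - (2 * lo - draws[None, :, kdim])) / h[kdim]
                rup = (block[:, kdim, None] - (2 * up - draws[None, :, kdim])) / h[kdim]
                A = np.logaddexp(
                    A, np.logaddexp(-0.5 * rlo * rlo, -0.5 * rup * rup)
                )
            L += A
        L[np.arange(block.shape[0]), idx[start : start + chunk]] = -np.inf
        logp[start : start + chunk] = logsumexp(L, axis=1) - log_norm
    return float(-np.mean(logp))
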