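"""Campaign orchestration: the full in silico design study.

A campaign starts from a joint initial experiment, then alternates
posterior update -> metric computation (mean prediction variance, posterior
entropy) -> experiment design -> virtual measurement, for the Bayesian arm
and/or the A-optimal Fisher arm, until the Bayesian stopping criterion is
met or a round cap is reached.  Fairness coupling: in ``both`` mode the
Fisher arm requests exactly as many measurements per round as the Bayesian
arm did in the matched round.  All randomness derives from a master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .bayes import (
    BayesianTrajectoryDesign,
    DesignProposal,
    predict_ensembles,
    propose_bayes,
    trajectory_variance,
)
from .data import Dataset, generate_data, pooled_variance
from .fisher import fisher_round
from .golgi import TRUE_THETA, trans_golgi_catalogue, trans_golgi_model
from .inference import PosteriorSample, Prior, estimate_entropy, find_mle
from .ode import Experiment, OdeModel

logger = logging.getLogger(__name__)

__all__ = [
    "McmcSettings",
    "CampaignConfig",
    "RoundRecord",
    "CampaignLog",
    "run_campaign",
    "mean_prediction_variance",
    "decision_stability",
]


def derive_seed(master: int, *indices) -> int:
    """Deterministic sub-seed from the master seed and context indices
    (run, round, phase); always below 2**31."""
    entropy = [int(master)] + [
        int(i) if not isinstance(i, str) else sum(ord(c) for c in i)
        for i in indices
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


@dataclass
class McmcSettings:
    """Adaptive-Metropolis settings for the per-round posterior updates.

    Defaults are a scaled-down study size; full-scale campaigns of this
    kind use multi-million-point merged posteriors.
    """

    n_chains: int = 4
    n_steps: int = 10000
    burn_frac: float = 0.5
    thin: int = 1
    rhat_threshold: float = 1.5
    adapt_interval: int = 100
    adapt_start: int = 200
    init: str = "mle"
    mle_starts: int = 3
    mle_maxiter: int = 60
    max_extensions: int = 2
    allow_partial: bool = True


@dataclass
class CampaignConfig:
    """Study protocol: model, true parameters, noise, catalogue, rounds."""

    model: str = "trans_golgi"
    theta_true: list[float] | None = None  # default: model nominal truth
    sigma_true: float = 0.15
    prior_half_width: float = 2.0  # decades each side -> 4-decade support
    t_end: float = 72.0
    n_times: int = 105
    n_replicates: int = 3
    n_draws: int = 1000  # posterior draws per prediction ensemble
    n_entropy_eval: int = 1000
    max_rounds: int = 8
    n_runs: int = 5
    master_seed: int = 0
    algorithm: str = "both"  # bayes | a_optimal | both
    initial_times: list[float] = field(default_factory=lambda: [24.0, 48.0, 72.0])
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    fisher_step: float = 0.01
    fisher_mle_starts: int = 3
    fisher_mle_maxiter: int = 60
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        if self.algorithm not in ("bayes", "a_optimal", "both"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if isinstance(self.mcmc, dict):
            self.mcmc = McmcSettings(**self.mcmc)

    def to_yaml(self, path) -> None:
        obj = dataclasses.asdict(self)
        obj["config_version"] = 1
        with open(path, "w") as fh:
            yaml.safe_dump(obj, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CampaignConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        obj.pop("config_version", None)
        return cls(**obj)

    def build_model(self) -> OdeModel:
        if self.model != "trans_golgi":
            raise ValueError(
                "unknown model id; pass a plug-in OdeModel to run_campaign "
                "via the `model` argument"
            )
        return trans_golgi_model(rtol=self.rtol, atol=self.atol)

    def build_catalogue(self) -> list[Experiment]:
        return trans_golgi_catalogue(t_end=self.t_end, n_times=self.n_times)

    def true_theta(self) -> np.ndarray:
        return (
            TRUE_THETA.copy()
            if self.theta_true is None
            else np.asarray(self.theta_true, float)
        )


@dataclass
class RoundRecord:
    """Everything measured and decided in one round of one arm."""

    run: int
    algorithm: str
    round: int
    n_datapoints: int
    n_values: int
    pooled_sigma2: float
    entropy_nats: float
    mean_prediction_variance: float
    proposal: DesignProposal | None
    stop: bool
    n_solves_inference: int = 0
    n_solves_design: int = 0
    diagnostics: dict = field(default_factory=dict)


@dataclass
class CampaignLog:
    """Per-round records for every run and arm, plus the config used."""

    config: CampaignConfig
    records: list[RoundRecord] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "run": r.run,
                    "algorithm": r.algorithm,
                    "round": r.round,
                    "n_datapoints": r.n_datapoints,
                    "mean_variance": r.mean_prediction_variance,
                    "entropy_nats": r.entropy_nats,
                    "pooled_sigma2": r.pooled_sigma2,
                    "stop": r.stop,
                    "chosen_experiment": (
                        None
                        if r.proposal is None
                        else r.proposal.experiment_index
                    ),
                    "n_picks": 0 if r.proposal is None else len(r.proposal.picks),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        obj = {
            "config": _plain(dataclasses.asdict(self.config)),
            "records": [
                {
                    **{
                        k: _plain(v)
                        for k, v in dataclasses.asdict(r).items()
                        if k != "proposal"
                    },
                    "proposal": (
                        None
                        if r.proposal is None
                        else json.loads(r.proposal.to_json())
                    ),
                }
                for r in self.records
            ],
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def arm(self, algorithm: str, run: int | None = None) -> list[RoundRecord]:
        return [
            r
            for r in self.records
            if r.algorithm == algorithm and (run is None or r.run == run)
        ]


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def _grand_mean_variance(ensembles) -> float:
    """Unweighted grand mean of per-time ensemble variances over all
    experiments, outputs and grid times."""
    stacks = [
        trajectory_variance(ens)[0]
        for ens_list in ensembles.values()
        for ens in ens_list
    ]
    return float(np.mean(np.concatenate(stacks)))


def mean_prediction_variance(
    sample: PosteriorSample,
    model: OdeModel,
    experiments: Sequence[Experiment],
    n_draws: int = 1000,
    seed: int = 0,
) -> float:
    """Overall mean expected prediction variance: grand unweighted mean of
    the per-time log10-trajectory variances over every catalogue
    experiment, output and grid time."""
    ens = predict_ensembles(
        sample, model, experiments, n_draws=min(n_draws, sample.n), seed=seed
    )
    return _grand_mean_variance(ens)


def _initial_experiment(catalogue: Sequence[Experiment]) -> Experiment:
    for exp in catalogue:
        if all(v == 1.0 for v in exp.input):
            return exp
    raise ValueError("catalogue lacks an unperturbed experiment")


def _initial_requests(
    exp: Experiment, times: Sequence[float]
) -> list[tuple[str, float]]:
    grid = set(float(t) for t in exp.time_grid)
    for t in times:
        if float(t) not in grid:
            raise ValueError(f"initial time {t} h not on the experiment grid")
    return [(oid, float(t)) for oid in exp.outputs for t in times]


def run_campaign(
    config: CampaignConfig,
    out_dir: str | Path | None = None,
    model: OdeModel | None = None,
) -> CampaignLog:
    """Execute the full design exercise for every run and requested arm.

    Round 0 is the joint initial experiment (unperturbed input, every
    output measured at the configured times); each later round designs,
    virtually measures and re-fits.  Bit-reproducible given the master
    seed.  When ``out_dir`` is given, the campaign log, metric series and
    per-arm datasets are written there (also on failure, as a checkpoint).
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log = CampaignLog(config=config)
    try:
        for run in range(config.n_runs):
            _run_single(config, run, log, model_override=model, out=out)
    finally:
        if out is not None:
            log.to_json(out / "campaign_log.json")
            log.frame().to_csv(out / "metrics.csv", index=False)
            config.to_yaml(out / "config.yaml")
    return log


def _run_single(config, run, log, model_override=None, out=None):
    model = model_override if model_override is not None else config.build_model()
    catalogue = config.build_catalogue()
    exp_map = {e.index: e for e in catalogue}
    theta_true = config.true_theta()
    prior = Prior.centered(theta_true, config.prior_half_width)
    init_exp = _initial_experiment(catalogue)
    requests0 = _initial_requests(init_exp, config.initial_times)
    data0 = Dataset(
        generate_data(
            model, theta_true, init_exp, requests0, config.sigma_true,
            n_replicates=config.n_replicates,
            seed=derive_seed(config.master_seed, run, 0, "data"),
        ),
        sigma_true=config.sigma_true,
    )

    arms = (
        ["bayes", "a_optimal"] if config.algorithm == "both" else [config.algorithm]
    )
    m_bayes: list[int] = []
    n_bayes_rounds = None
    for arm in arms:
        dataset = data0
        for rnd in range(config.max_rounds + 1):
            rec = _one_round(
                config, model, catalogue, exp_map, prior, theta_true,
                dataset, run, arm, rnd, m_bayes,
            )
            log.records.append(rec)
            if arm == "bayes" and rec.proposal is not None and not rec.stop:
                m_bayes.append(len(rec.proposal.picks))
            stop_now = rec.stop or rnd == config.max_rounds
            if arm == "a_optimal" and n_bayes_rounds is not None:
                # fairness: the Fisher arm performs exactly as many design
                # rounds as the Bayesian arm did
                stop_now = stop_now or rnd >= n_bayes_rounds
            if stop_now:
                if arm == "bayes":
                    n_bayes_rounds = rnd
                break
            new = generate_data(
                model, theta_true, exp_map[rec.proposal.experiment_index],
                rec.proposal.requests, config.sigma_true,
                n_replicates=config.n_replicates,
                seed=derive_seed(config.master_seed, run, rnd + 1, arm, "data"),
            )
            dataset = dataset.extend(new)
            if out is not None:
                dataset.to_csv(out / f"dataset_run{run}_{arm}.csv")


def _one_round(
    config, model, catalogue, exp_map, prior, theta_true,
    dataset, run, arm, rnd, m_bayes,
) -> RoundRecord:
    sigma2_hat = pooled_variance(dataset)
    sigma_hat = float(np.sqrt(sigma2_hat))
    mcmc = config.mcmc
    n0 = model.solve_counter["n_solves"]
    design_model = BayesianTrajectoryDesign(
        model, catalogue, dataset, prior, sigma=sigma_hat
    )

    # sample_posterior extends chains warm when screening fails; with
    # allow_partial the round proceeds on the best chain subset and the
    # non-convergence is recorded in the round diagnostics
    results = design_model.fit(
        n_chains=mcmc.n_chains, n_steps=mcmc.n_steps,
        seed=derive_seed(config.master_seed, run, rnd, arm, "mcmc"),
        burn_frac=mcmc.burn_frac, thin=mcmc.thin,
        rhat_threshold=mcmc.rhat_threshold,
        adapt_interval=mcmc.adapt_interval, adapt_start=mcmc.adapt_start,
        init=mcmc.init, mle_starts=mcmc.mle_starts,
        mle_maxiter=mcmc.mle_maxiter, max_extensions=mcmc.max_extensions,
        allow_partial=mcmc.allow_partial,
    )
    n1 = model.solve_counter["n_solves"]
    entropy = results.entropy(
        n_eval=config.n_entropy_eval,
        seed=derive_seed(config.master_seed, run, rnd, arm, "entropy"),
    )  # boundary-corrected at the prior box
    ensembles = results.predict(
        n_draws=config.n_draws,
        seed=derive_seed(config.master_seed, run, rnd, arm, "predict"),
    )
    mean_var = _grand_mean_variance(ensembles)
    bayes_proposal = propose_bayes(ensembles, sigma2_hat)
    if arm == "bayes":
        proposal = bayes_proposal
    else:
        if bayes_proposal.stop:
            proposal = bayes_proposal  # noise floor reached; nothing to request
            proposal.algorithm = "a_optimal"
        else:
            m = m_bayes[rnd] if rnd < len(m_bayes) else (
                m_bayes[-1] if m_bayes else len(bayes_proposal.picks)
            )
            proposal = fisher_round(
                model, catalogue, dataset, prior, m=m, sigma=sigma_hat,
                n_starts=config.fisher_mle_starts,
                seed=derive_seed(config.master_seed, run, rnd, arm, "mle"),
                step=config.fisher_step, n_replicates=config.n_replicates,
                maxiter=config.fisher_mle_maxiter,
            )
    n2 = model.solve_counter["n_solves"]
    proposal.round = rnd
    rec = RoundRecord(
        run=run, algorithm=arm, round=rnd,
        n_datapoints=dataset.n_points, n_values=dataset.n_values,
        pooled_sigma2=sigma2_hat, entropy_nats=entropy,
        mean_prediction_variance=mean_var, proposal=proposal,
        stop=bool(proposal.stop),
        n_solves_inference=n1 - n0, n_solves_design=n2 - n1,
        diagnostics={
            "rhat": results.posterior.diagnostics.get("rhat"),
            "acceptance_rates": results.posterior.diagnostics.get(
                "acceptance_rates"
            ),
            "posterior_n": results.posterior.n,
        },
    )
    logger.info(
        "run %d %s round %d: sigma2=%.4g entropy=%.2f mean_var=%.4g "
        "chose=%s stop=%s", run, arm, rnd, sigma2_hat, entropy, mean_var,
        proposal.experiment_index, proposal.stop,
    )
    return rec


def decision_stability(
    model: OdeModel,
    catalogue: Sequence[Experiment],
    dataset: Dataset,
    prior: Prior,
    algorithm: str,
    n_repeats: int = 100,
    seed: int = 0,
    posterior: PosteriorSample | None = None,
    n_draws: int = 1000,
    m: int = 5,
    sigma: float | None = None,
    mle_starts: int = 1,
    mle_maxiter: int = 60,
) -> pd.DataFrame:
    """Repeat one design step ``n_repeats`` times and tabulate decisions.

    ``bayes``: re-draws the prediction ensemble from a fixed posterior each
    repeat.  ``a_optimal``: re-estimates the MLE from a fresh multi-start
    each repeat.  Returns a frequency table over (experiment, measurement
    times).
    """
    sigma_hat = float(
        np.sqrt(pooled_variance(dataset)) if sigma is None else sigma
    )
    exp_map = {e.index: e for e in catalogue}
    decisions = []
    for rep in range(n_repeats):
        rep_seed = derive_seed(seed, rep, algorithm)
        if algorithm == "bayes":
            if posterior is None:
                raise ValueError("bayes stability needs a posterior sample")
            ens = predict_ensembles(
                posterior, model, catalogue,
                n_draws=min(n_draws, posterior.n), seed=rep_seed,
            )
            prop = propose_bayes(ens, sigma_hat ** 2)
        elif algorithm == "a_optimal":
            prop = fisher_round(
                model, catalogue, dataset, prior, m=m, sigma=sigma_hat,
                n_starts=mle_starts, seed=rep_seed, maxiter=mle_maxiter,
            )
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        decisions.append(
            (
                prop.experiment_index,
                tuple(round(p.time, 6) for p in prop.picks),
            )
        )
    df = (
        pd.Series(decisions)
        .value_counts()
        .rename_axis("decision")
        .reset_index(name="count")
    )
    df["experiment_index"] = df["decision"].map(lambda d: d[0])
    df["times"] = df["decision"].map(lambda d: d[1])
    df["frequency"] = df["count"] / n_repeats
    return df[["experiment_index", "times", "count", "frequency"]]
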