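"""Log-normal measurement model, virtual data generation and pooled
noise-variance estimation.

A measurement replicate of output y at time t is ``z = y * 10**eps`` with
``eps ~ Normal(0, sigma^2)`` i.i.d.; all log transforms in the package are
base 10, so ``sigma`` is the standard deviation of ``log10 z`` around
``log10 y``.  The same sigma applies to every output and experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ode import Experiment, OdeModel, simulate

__all__ = [
    "Measurement",
    "Dataset",
    "generate_data",
    "pooled_variance",
]


@dataclass(frozen=True)
class Measurement:
    """Replicate measurements of one output at one time in one experiment."""

    experiment_index: int
    output_id: str
    time: float
    replicates: tuple[float, ...]

    def __post_init__(self):
        if any(r <= 0 for r in self.replicates):
            raise ValueError("replicates must be strictly positive (log-normal support)")

    @property
    def key(self) -> tuple:
        return (self.experiment_index, self.output_id, self.time)


@dataclass
class Dataset:
    """Collection of measurements with at most one record per
    (experiment, output, time) key."""

    measurements: list[Measurement] = field(default_factory=list)
    sigma_true: float | None = None  # generation provenance

    def __post_init__(self):
        self._check_unique()

    def _check_unique(self):
        keys = [m.key for m in self.measurements]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (experiment, output, time) keys in dataset")

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def n_points(self) -> int:
        """Number of (experiment, output, time) measurement requests."""
        return len(self.measurements)

    @property
    def n_values(self) -> int:
        return sum(len(m.replicates) for m in self.measurements)

    @property
    def experiment_indices(self) -> list[int]:
        return sorted({m.experiment_index for m in self.measurements})

    def extend(self, new: list[Measurement]) -> "Dataset":
        """Return a new Dataset with additional measurements appended.

        Re-measuring an existing (experiment, output, time) point merges
        the new replicates into that point's record, preserving the
        one-record-per-key invariant."""
        merged = {m.key: m for m in self.measurements}
        for m in new:
            old = merged.get(m.key)
            merged[m.key] = (
                m if old is None else
                Measurement(m.experiment_index, m.output_id, m.time,
                            old.replicates + m.replicates)
            )
        return Dataset(list(merged.values()), sigma_true=self.sigma_true)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "experiment_index": m.experiment_index,
                "output_id": m.output_id,
                "time_h": m.time,
                "replicate_index": ri,
                "value": v,
            }
            for m in self.measurements
            for ri, v in enumerate(m.replicates, start=1)
        ]
        return pd.DataFrame(
            rows,
            columns=["experiment_index", "output_id", "time_h", "replicate_index", "value"],
        )

    def to_csv(self, path) -> None:
        # pandas' default float repr is shortest-round-trip, i.e. lossless
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sigma_true: float | None = None) -> "Dataset":
        ms = []
        for (ei, oid, t), grp in df.groupby(
            ["experiment_index", "output_id", "time_h"], sort=True
        ):
            grp = grp.sort_values("replicate_index")
            ms.append(
                Measurement(int(ei), str(oid), float(t), tuple(grp["value"].tolist()))
            )
        return cls(ms, sigma_true=sigma_true)

    @classmethod
    def from_csv(cls, path, sigma_true: float | None = None) -> "Dataset":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(df, sigma_true=sigma_true)


def generate_data(
    model: OdeModel,
    theta_true: np.ndarray,
    experiment: Experiment,
    requests: list[tuple[str, float]],
    sigma: float,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[Measurement]:
    """Virtual measurements from the "true system": simulate at theta_true
    and corrupt each replicate with log-normal noise ``y * 10**eps``,
    ``eps ~ N(0, sigma^2)``.  Deterministic given the seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    times = sorted({t for _, t in requests})
    traj = simulate(model, theta_true, experiment, times=np.array(times))
    t_index = {t: i for i, t in enumerate(times)}
    out_index = {oid: j for j, oid in enumerate(model.output_names)}
    measurements = []
    for output_id, t in requests:
        y = traj.outputs[t_index[t], out_index[output_id]]
        eps = rng.normal(0.0, sigma, size=n_replicates)
        reps = tuple(float(v) for v in y * 10.0 ** eps)
        measurements.append(Measurement(experiment.index, output_id, float(t), reps))
    return measurements


def pooled_variance(dataset: Dataset) -> float:
    """Replicate-pooled unbiased variance of log10 replicates:
    sum over measurements of within-group squared deviations divided by the
    summed degrees of freedom sum(n_m - 1)."""
    ss = 0.0
    dof = 0
    for m in dataset.measurements:
        if len(m.replicates) < 2:
            continue
        logs = np.log10(np.asarray(m.replicates))
        ss += float(np.sum((logs - logs.mean()) ** 2))
        dof += len(m.replicates) - 1
    if dof == 0:
        raise ValueError(
            "pooled variance undefined: no measurement has >= 2 replicates"
        )
    return ss / dof
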