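"""Training loop: alternating inference and batch learning.

The network is initialized with zero inhibition, a uniform threshold, and
Gaussian white-noise feed-forward weights.  Training then alternates
strictly between inference (spike counts for each patch of a batch, with
the parameters frozen) and learning (one averaged update of ``W``,
``theta`` and ``Q`` per batch, followed by clipping of negative inhibitory
weights).  Learning rates follow a staged schedule that starts large and is
reduced over the run; convergence is monitored through a diagnostic trace
(mean spike count, mean absolute pairwise correlation, linear reconstruction
error, and parameter-change norms) rather than auto-detected.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from . import analysis
from .dynamics import DynamicsConfig, NetworkParams, run_inference
from .errors import ConfigError, ShapeError, StreamExhaustedError, ValidationError
from .plasticity import (
    BatchStats,
    LearningConfig,
    update_feedforward_local,
    update_inhibitory,
    update_thresholds,
)

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "default_schedule",
    "initialize",
    "train",
    "compute_reconstruction_error",
]


def default_schedule(n_batches: int) -> tuple[tuple[int, float], ...]:
    """Three-stage rate decay: full rate, then x0.5, then x0.1."""
    if n_batches < 1:
        raise ConfigError("n_batches must be positive")
    return ((0, 1.0), (n_batches // 2, 0.5), ((3 * n_batches) // 4, 0.1))


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    """Run-length, initialization, and schedule settings.

    ``schedule`` is a sequence of ``(batch_index, rate_multiplier)`` pairs
    with strictly increasing indices; the multiplier of the last pair whose
    index has been reached applies.  ``None`` selects the default
    three-stage decay.  ``init_theta`` is the uniform initial threshold;
    ``init_q_scale`` the standard deviation of the Gaussian feed-forward
    initialization (default ``1/sqrt(K)``, giving unit-variance initial
    drive for standardized patches).
    """

    n_batches: int = 200
    schedule: tuple[tuple[int, float], ...] | None = None
    seed: int = 0
    init_theta: float = 5.0
    init_q_scale: float | None = None
    checkpoint_every: int = 10

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ConfigError("n_batches must be positive")
        if self.checkpoint_every < 1:
            raise ConfigError("checkpoint_every must be positive")
        if self.init_q_scale is not None and self.init_q_scale <= 0:
            raise ConfigError("init_q_scale must be positive")
        if self.schedule is not None:
            sched = tuple((int(b), float(m)) for b, m in self.schedule)
            object.__setattr__(self, "schedule", sched)
            indices = [b for b, _ in sched]
            if indices != sorted(set(indices)):
                raise ConfigError("schedule batch indices must be strictly increasing")
            if any(m <= 0 for _, m in sched):
                raise ConfigError("schedule multipliers must be positive")

    def resolved_schedule(self) -> tuple[tuple[int, float], ...]:
        return self.schedule if self.schedule is not None else default_schedule(
            self.n_batches
        )

    def multiplier(self, batch_index: int) -> float:
        mult = 1.0
        for start, m in self.resolved_schedule():
            if batch_index >= start:
                mult = m
        return mult


@dataclasses.dataclass
class TrainingTrace:
    """Per-checkpoint diagnostics recorded during training."""

    batch: list[int] = dataclasses.field(default_factory=list)
    rate_multiplier: list[float] = dataclasses.field(default_factory=list)
    mean_count: list[float] = dataclasses.field(default_factory=list)
    mean_abs_corr: list[float] = dataclasses.field(default_factory=list)
    recon_error: list[float] = dataclasses.field(default_factory=list)
    dq_norm: list[float] = dataclasses.field(default_factory=list)
    dw_norm: list[float] = dataclasses.field(default_factory=list)
    dtheta_norm: list[float] = dataclasses.field(default_factory=list)

    _FIELDS = (
        "batch",
        "rate_multiplier",
        "mean_count",
        "mean_abs_corr",
        "recon_error",
        "dq_norm",
        "dw_norm",
        "dtheta_norm",
    )

    def __len__(self) -> int:
        return len(self.batch)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: np.asarray(getattr(self, name)) for name in self._FIELDS}

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(self._FIELDS)
            for row in zip(*(getattr(self, name) for name in self._FIELDS)):
                writer.writerow(row)

    @classmethod
    def from_dict(cls, data: dict) -> "TrainingTrace":
        trace = cls()
        for name in cls._FIELDS:
            values = data.get(name, [])
            getattr(trace, name).extend(
                int(v) if name == "batch" else float(v) for v in np.asarray(values)
            )
        return trace


def initialize(
    n_neurons: int,
    n_pixels: int,
    cfg: TrainingConfig | None = None,
    seed: int | None = None,
) -> NetworkParams:
    """Fresh network: ``W = 0``, uniform thresholds, Gaussian white-noise Q."""
    if n_neurons < 1 or n_pixels < 1:
        raise ConfigError("network sizes must be positive")
    if cfg is None:
        cfg = TrainingConfig()
    if seed is None:
        seed = cfg.seed
    scale = cfg.init_q_scale if cfg.init_q_scale is not None else 1.0 / math.sqrt(n_pixels)
    rng = np.random.default_rng(seed)
    Q = rng.normal(0.0, scale, size=(n_neurons, n_pixels))
    W = np.zeros((n_neurons, n_neurons))
    theta = np.full(n_neurons, float(cfg.init_theta))
    return NetworkParams(Q, W, theta)


def compute_reconstruction_error(
    params: NetworkParams, responses, stimuli
) -> float:
    """Mean squared error of the linear generative model over images.

    ``E = mean_b mean_k (x_k - sum_i n_i Q_ik)^2``; zero exactly when the
    count-weighted sum of feed-forward rows reproduces every patch.
    """
    counts = analysis._counts_matrix(responses)
    X = analysis._stimulus_matrix(stimuli)
    if counts.shape[0] != X.shape[0]:
        raise ShapeError("responses and stimuli are misaligned")
    if counts.shape[1] != params.n_neurons or X.shape[1] != params.n_pixels:
        raise ShapeError("responses/stimuli do not match the network shape")
    xhat = counts @ params.Q
    return float(np.mean((X - xhat) ** 2))


def _take_batch(stream: Iterator, size: int) -> list:
    batch = []
    for _ in range(size):
        try:
            batch.append(next(stream))
        except StopIteration:
            raise StreamExhaustedError(
                f"stimulus stream exhausted after {len(batch)} of {size} patches"
            ) from None
    return batch


def train(
    params: NetworkParams,
    stimulus_stream: Iterable,
    learn_cfg: LearningConfig,
    train_cfg: TrainingConfig,
    dynamics: DynamicsConfig | None = None,
    callback: Callable[[int, dict], None] | None = None,
) -> tuple[NetworkParams, TrainingTrace]:
    """Run the alternating inference/learning loop.

    For each of ``n_batches`` batches: draw ``batch_size`` patches from the
    stream, run inference on each with the current (frozen) parameters,
    apply the three batch-averaged learning rules scaled by the schedule
    multiplier, and clip negative inhibitory weights.  Diagnostics are
    recorded at the first batch, every ``checkpoint_every`` batches, and the
    final batch.  Returns fresh parameters and the trace; the input
    parameters are not modified.
    """
    if dynamics is None:
        dynamics = DynamicsConfig()
    params = params.copy()
    stream = iter(stimulus_stream)
    trace = TrainingTrace()

    for b in range(train_cfg.n_batches):
        patches = _take_batch(stream, learn_cfg.batch_size)
        X = analysis._stimulus_matrix(patches)
        if X.shape[1] != params.n_pixels:
            raise ShapeError(
                f"stream patches have {X.shape[1]} pixels, network expects {params.n_pixels}"
            )
        counts = np.stack(
            [run_inference(params, x, dynamics).counts for x in X]
        ).astype(np.float64)
        stats = BatchStats(counts, X)
        scaled = learn_cfg.scaled(train_cfg.multiplier(b))

        new_w = update_inhibitory(params.W, stats, scaled)
        new_theta = update_thresholds(params.theta, stats, scaled)
        new_q = update_feedforward_local(params.Q, stats, scaled)
        for name, arr in (("Q", new_q), ("W", new_w), ("theta", new_theta)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"{name} became non-finite at batch {b}; "
                    "reduce the learning rates"
                )

        is_checkpoint = (
            b % train_cfg.checkpoint_every == 0 or b == train_cfg.n_batches - 1
        )
        if is_checkpoint:
            with np.errstate(invalid="ignore"):
                r = analysis.pairwise_correlations(counts)
            mean_abs_corr = float(np.nanmean(np.abs(r))) if np.any(
                np.isfinite(r)
            ) else float("nan")
            record = {
                "batch": b,
                "rate_multiplier": train_cfg.multiplier(b),
                "mean_count": float(counts.mean()),
                "mean_abs_corr": mean_abs_corr,
                "recon_error": compute_reconstruction_error(params, counts, X),
                "dq_norm": float(np.linalg.norm(new_q - params.Q)),
                "dw_norm": float(np.linalg.norm(new_w - params.W)),
                "dtheta_norm": float(np.linalg.norm(new_theta - params.theta)),
            }
            for name, value in record.items():
                getattr(trace, name).append(value)
            if callback is not None:
                callback(b, record)

        params = NetworkParams(
            new_q, new_w, new_theta, nonnegative_w=scaled.clip_negative_w
        )
    return params, trace
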