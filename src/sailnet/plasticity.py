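"""Synaptically local learning rules.

Three quantities adapt, each using only information available at the synapse
(pre-synaptic activity, post-synaptic activity, and the current strength):

* lateral inhibition (anti-Hebbian): ``dW_im = alpha * (n_i n_m - p^2)`` for
  ``i != m``, clipped at zero so the recurrent weights stay inhibitory;
* firing thresholds (homeostasis): ``dtheta_i = gamma * (n_i - p)``, which
  drives every unit toward the same target of ``p`` spikes per image;
* feed-forward weights (Oja's Hebbian rule):
  ``dQ_ik = beta * n_i * (x_k - n_i Q_ik)``.

Updates are averaged over a batch of images before being applied.  The
module also implements the *non-local* gradient rule
``dQ_ik = beta * n_i * (x_k - sum_j Q_jk n_j)`` used by classic sparse
coding algorithms.  It is kept purely as a validation oracle: in the limit
of sparse (small ``p``) and uncorrelated unit activity the batch-averaged
local rule approximates it, and :func:`local_nonlocal_discrepancy` measures
how closely.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np

from .errors import ShapeError, ValidationError

__all__ = [
    "LearningConfig",
    "BatchStats",
    "update_inhibitory",
    "update_thresholds",
    "update_feedforward_local",
    "update_feedforward_nonlocal",
    "local_nonlocal_discrepancy",
]


@dataclasses.dataclass(frozen=True)
class LearningConfig:
    """Learning rates and targets.

    Parameters
    ----------
    p:
        Target mean spike count per image (lifetime sparseness target).
        Well below one spike per image, so that units are silent for most
        stimuli.
    alpha, beta, gamma:
        Learning rates for the inhibitory weights, feed-forward weights, and
        thresholds respectively.  ``beta`` must be much smaller than the
        other two so that activity stays sparse and decorrelated while the
        feed-forward weights drift; a ratio above 0.5 triggers a warning.
    batch_size:
        Number of images whose updates are averaged before being applied.
    clip_negative_w:
        Keep recurrent weights non-negative (inhibitory).  Setting this to
        False enables the sign-free recurrent variant, offered as an option
        only.
    """

    p: float = 0.05
    alpha: float = 0.01
    beta: float = 0.001
    gamma: float = 0.01
    batch_size: int = 100
    clip_negative_w: bool = True

    def __post_init__(self) -> None:
        if not (self.p > 0 and math.isfinite(self.p)):
            raise ValidationError(f"p must be positive, got {self.p}")
        for name in ("alpha", "beta", "gamma"):
            rate = getattr(self, name)
            if rate < 0 or not math.isfinite(rate):
                raise ValidationError(f"{name} must be >= 0 and finite, got {rate}")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be a positive integer")
        for name in ("alpha", "gamma"):
            other = getattr(self, name)
            if other > 0 and self.beta / other > 0.5:
                warnings.warn(
                    f"beta ({self.beta}) should be much smaller than {name} "
                    f"({other}); sparseness and decorrelation may break down",
                    stacklevel=2,
                )

    def scaled(self, multiplier: float) -> "LearningConfig":
        """All three rates multiplied by a schedule factor."""
        if multiplier < 0:
            raise ValidationError("rate multiplier must be non-negative")
        return dataclasses.replace(
            self,
            alpha=self.alpha * multiplier,
            beta=self.beta * multiplier,
            gamma=self.gamma * multiplier,
        )


@dataclasses.dataclass
class BatchStats:
    """Per-image spike counts and stimuli for one training batch.

    ``counts`` has shape ``(B, N)`` (images by units) and ``stimuli`` has
    shape ``(B, K)``.
    """

    counts: np.ndarray
    stimuli: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.stimuli = np.asarray(self.stimuli, dtype=np.float64)
        if self.counts.ndim != 2 or self.stimuli.ndim != 2:
            raise ShapeError("counts and stimuli must both be 2-D (B, .) arrays")
        if self.counts.shape[0] != self.stimuli.shape[0]:
            raise ShapeError(
                f"counts has {self.counts.shape[0]} images but stimuli has "
                f"{self.stimuli.shape[0]}"
            )
        if self.counts.shape[0] == 0:
            raise ValidationError("batch must contain at least one image")
        if np.any(self.counts < 0):
            raise ValidationError("spike counts must be non-negative")
        for name, arr in (("counts", self.counts), ("stimuli", self.stimuli)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite entries")

    @property
    def n_images(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]


def _check_n(batch: BatchStats, n: int, what: str) -> None:
    if batch.n_neurons != n:
        raise ShapeError(
            f"batch has counts for {batch.n_neurons} units but {what} is for {n}"
        )


def update_inhibitory(
    W: np.ndarray, batch: BatchStats, cfg: LearningConfig
) -> np.ndarray:
    """Anti-Hebbian update of the lateral inhibitory weights.

    For each ordered pair ``i != m`` the weight moves by
    ``alpha * mean_b(n_i n_m - p^2)``; afterwards negative entries are set
    to zero (unless the sign-free variant is enabled) and the diagonal is
    forced to zero.  Pairs that fire together more often than two
    independent units at the target rate would (``p^2``) become more
    strongly mutually inhibited, which drives decorrelation.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ShapeError(f"W must be square, got shape {W.shape}")
    _check_n(batch, W.shape[0], "W")
    coactivation = (batch.counts.T @ batch.counts) / batch.n_images
    new = W + cfg.alpha * (coactivation - cfg.p**2)
    if cfg.clip_negative_w:
        np.maximum(new, 0.0, out=new)
    np.fill_diagonal(new, 0.0)
    if not np.all(np.isfinite(new)):
        raise ValidationError("inhibitory update produced non-finite weights")
    return new


def update_thresholds(
    theta: np.ndarray, batch: BatchStats, cfg: LearningConfig
) -> np.ndarray:
    """Homeostatic threshold update ``theta_i += gamma * mean_b(n_i - p)``.

    Units firing above the target rate raise their threshold, units firing
    below it lower theirs.  Thresholds are unclamped and may become
    arbitrarily large or negative.
    """
    theta = np.asarray(theta, dtype=np.float64).ravel()
    _check_n(batch, theta.size, "theta")
    new = theta + cfg.gamma * (batch.counts.mean(axis=0) - cfg.p)
    if not np.all(np.isfinite(new)):
        raise ValidationError("threshold update produced non-finite values")
    return new


def update_feedforward_local(
    Q: np.ndarray, batch: BatchStats, cfg: LearningConfig
) -> np.ndarray:
    """Oja-rule update ``Q_ik += beta * mean_b(n_i (x_k - n_i Q_ik))``.

    Synaptically local: the update for synapse ``(i, k)`` uses only the
    pre-synaptic pixel value ``x_k``, the post-synaptic count ``n_i``, and
    the current weight ``Q_ik``.  The decay term bounds weight growth and
    places the fixed point at ``Q_i = <n_i x> / <n_i^2>``.
    """
    Q = np.asarray(Q, dtype=np.float64)
    if Q.ndim != 2:
        raise ShapeError(f"Q must be 2-D, got shape {Q.shape}")
    _check_n(batch, Q.shape[0], "Q")
    if batch.stimuli.shape[1] != Q.shape[1]:
        raise ShapeError(
            f"stimuli have {batch.stimuli.shape[1]} pixels but Q has {Q.shape[1]} columns"
        )
    b = batch.n_images
    hebb = (batch.counts.T @ batch.stimuli) / b
    decay = (batch.counts**2).mean(axis=0)
    new = Q + cfg.beta * (hebb - decay[:, None] * Q)
    if not np.all(np.isfinite(new)):
        raise ValidationError("feed-forward update produced non-finite weights")
    return new


def update_feedforward_nonlocal(
    Q: np.ndarray, batch: BatchStats, cfg: LearningConfig
) -> np.ndarray:
    """Gradient rule ``Q_ik += beta * mean_b(n_i (x_k - sum_j Q_jk n_j))``.

    This is the residual-driven update used by classic (non-spiking) sparse
    coding algorithms.  It is non-local -- synapse ``(i, k)`` needs the
    weights and activities of every other unit -- and is provided here only
    as the oracle against which the local rule is validated.
    """
    Q = np.asarray(Q, dtype=np.float64)
    if Q.ndim != 2:
        raise ShapeError(f"Q must be 2-D, got shape {Q.shape}")
    _check_n(batch, Q.shape[0], "Q")
    if batch.stimuli.shape[1] != Q.shape[1]:
        raise ShapeError(
            f"stimuli have {batch.stimuli.shape[1]} pixels but Q has {Q.shape[1]} columns"
        )
    b = batch.n_images
    residual = batch.stimuli - batch.counts @ Q  # (B, K)
    new = Q + cfg.beta * (batch.counts.T @ residual) / b
    if not np.all(np.isfinite(new)):
        raise ValidationError("feed-forward update produced non-finite weights")
    return new


def local_nonlocal_discrepancy(
    Q: np.ndarray, batches: Sequence[BatchStats], cfg: LearningConfig
) -> float:
    """Relative difference between averaged local and non-local updates.

    Both rules are batch-averaged over all supplied batches and the
    Frobenius-norm difference of the two mean updates, relative to the norm
    of the non-local (gradient) update, is returned.  The discrepancy
    shrinks as the target rate ``p`` shrinks and as pairwise count
    correlations vanish; it is exactly zero when at most one unit is active
    per image.
    """
    if len(batches) == 0:
        raise ValidationError("at least one batch is required")
    Q = np.asarray(Q, dtype=np.float64)
    d_local = np.zeros_like(Q)
    d_nonlocal = np.zeros_like(Q)
    for batch in batches:
        d_local += update_feedforward_local(Q, batch, cfg) - Q
        d_nonlocal += update_feedforward_nonlocal(Q, batch, cfg) - Q
    d_local /= len(batches)
    d_nonlocal /= len(batches)
    denom = np.linalg.norm(d_nonlocal)
    if denom == 0.0:
        return 0.0 if np.linalg.norm(d_local) == 0.0 else np.inf
    return float(np.linalg.norm(d_local - d_nonlocal) / denom)
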