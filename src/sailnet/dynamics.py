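"""Leaky integrate-and-fire inference dynamics.

The network encodes one image patch at a time.  Each of the ``N`` units
carries a continuous internal variable ``u_i`` -- the membrane-potential
analog -- which is charged by the feed-forward drive ``Q x``, discharged by
a passive leak, and pushed down by lateral inhibition ``-W y`` whenever
other units spike.  A unit whose internal variable exceeds its threshold
``theta_i`` after the update at one step emits a binary, one-step spike at
the *next* step, at which point its internal variable is reset to the
resting value and can charge up again immediately.

The membrane time constant ``tau`` defines the unit of time.  Each patch is
presented for a window of five time constants, integrated with a forward
Euler step of ``0.1 tau`` (50 steps by default), so per-unit spike counts
are bounded by the number of integration steps.  The computational output
for a patch is the vector of spike counts ``n_i`` over the window.  The
dynamics contain no noise source: identical inputs yield identical spike
trains.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, ShapeError, ValidationError

__all__ = [
    "DynamicsConfig",
    "StimulusPatch",
    "NetworkParams",
    "SpikeResponse",
    "run_inference",
    "run_inference_batch",
    "count_matrix",
]


@dataclasses.dataclass(frozen=True)
class DynamicsConfig:
    """Integration parameters for one stimulus presentation.

    Parameters
    ----------
    tau:
        Membrane (RC) time constant; defines the time unit.
    dt:
        Euler integration step.  Defaults to ``0.1 * tau``.
    window:
        Total inference duration per patch.  Defaults to ``5 * tau``.
    reset_value:
        Resting value the internal variable is reset to after a spike.
    """

    tau: float = 1.0
    dt: float | None = None
    window: float | None = None
    reset_value: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise ConfigError(f"tau must be positive and finite, got {self.tau}")
        if self.dt is None:
            object.__setattr__(self, "dt", 0.1 * self.tau)
        if self.window is None:
            object.__setattr__(self, "window", 5.0 * self.tau)
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ConfigError(f"dt must be positive and finite, got {self.dt}")
        if not (self.window > 0 and math.isfinite(self.window)):
            raise ConfigError(f"window must be positive and finite, got {self.window}")
        ratio = self.window / self.dt
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio) or round(ratio) < 1:
            raise ConfigError(
                f"window ({self.window}) must be a positive integer multiple of dt ({self.dt})"
            )
        if not math.isfinite(self.reset_value):
            raise ConfigError("reset_value must be finite")

    @property
    def n_steps(self) -> int:
        """Number of Euler steps per stimulus presentation."""
        return int(round(self.window / self.dt))

    @property
    def eta(self) -> float:
        """Dimensionless Euler step ``dt / tau``."""
        return self.dt / self.tau


@dataclasses.dataclass
class StimulusPatch:
    """One preprocessed image patch, stored as a flat row-major pixel vector."""

    pixels: np.ndarray
    side: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64).ravel()
        if self.side <= 0 or self.side * self.side != self.pixels.size:
            raise ShapeError(
                f"side**2 ({self.side}**2) must equal the pixel count ({self.pixels.size})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("stimulus pixels must all be finite")

    @classmethod
    def from_array(cls, image: np.ndarray) -> "StimulusPatch":
        """Build a patch from a square 2-D pixel array."""
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 2 or image.shape[0] != image.shape[1]:
            raise ShapeError(f"expected a square 2-D array, got shape {image.shape}")
        return cls(image.ravel(), image.shape[0])

    def image(self) -> np.ndarray:
        """The patch reshaped to ``side x side`` for display."""
        return self.pixels.reshape(self.side, self.side)

    def is_standardized(self, tol: float = 1e-8) -> bool:
        """True if pixel mean is ~0 and pixel standard deviation is ~1."""
        return bool(
            abs(self.pixels.mean()) < tol and abs(self.pixels.std() - 1.0) < tol
        )


@dataclasses.dataclass
class NetworkParams:
    """The learnable network state.

    Attributes
    ----------
    Q:
        Feed-forward weights, shape ``(N, K)``; row ``i`` is unit *i*'s set
        of synapses from the ``K`` input pixels.
    W:
        Lateral inhibitory weights, shape ``(N, N)``; non-negative with a
        zero diagonal (no self-inhibition).
    theta:
        Per-unit firing thresholds, shape ``(N,)``.
    nonnegative_w:
        If True (default), construction enforces ``W >= 0``.  The sign-free
        recurrent variant sets this to False; it is offered as a
        configuration option only.
    """

    Q: np.ndarray
    W: np.ndarray
    theta: np.ndarray
    nonnegative_w: bool = True

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=np.float64)
        self.W = np.asarray(self.W, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64).ravel()
        n = self.theta.size
        if self.Q.ndim != 2 or self.Q.shape[0] != n:
            raise ShapeError(
                f"Q must be (N, K) with N={n} rows, got shape {self.Q.shape}"
            )
        if self.W.shape != (n, n):
            raise ShapeError(f"W must be ({n}, {n}), got shape {self.W.shape}")
        for name, arr in (("Q", self.Q), ("W", self.W), ("theta", self.theta)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite entries")
        if np.any(np.diagonal(self.W) != 0.0):
            raise ValidationError("W must have an exactly zero diagonal")
        if self.nonnegative_w and np.any(self.W < 0.0):
            raise ValidationError("W entries must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.theta.size

    @property
    def n_pixels(self) -> int:
        return self.Q.shape[1]

    @property
    def overcompleteness(self) -> float:
        """Ratio of coding units to input pixels (> 1 means overcomplete)."""
        return self.n_neurons / self.n_pixels

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.Q.copy(), self.W.copy(), self.theta.copy(), self.nonnegative_w
        )


@dataclasses.dataclass
class SpikeResponse:
    """Binary spike raster for one stimulus presentation.

    ``spikes[i, t]`` is 1 if unit *i* emitted a spike at integration step
    *t*.  Spike counts are the row sums of the raster, so the
    counts-match-raster invariant holds by construction.
    """

    spikes: np.ndarray

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ShapeError("spikes must be a 2-D (N, S) binary matrix")
        if self.spikes.size and not np.isin(self.spikes, (0, 1)).all():
            raise ValidationError("spikes must be binary")
        self.spikes = self.spikes.astype(np.uint8)

    @property
    def counts(self) -> np.ndarray:
        """Spikes per unit over the whole window (``n_i``)."""
        return self.spikes.sum(axis=1).astype(np.int64)

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]


def _stimulus_vector(stimulus, n_pixels: int) -> np.ndarray:
    if isinstance(stimulus, StimulusPatch):
        x = stimulus.pixels
    else:
        x = np.asarray(stimulus, dtype=np.float64).ravel()
        if not np.all(np.isfinite(x)):
            raise ValidationError("stimulus contains non-finite entries")
    if x.size != n_pixels:
        raise ShapeError(
            f"stimulus has {x.size} pixels but the network expects {n_pixels}"
        )
    return x


def run_inference(
    params: NetworkParams,
    stimulus,
    config: DynamicsConfig | None = None,
) -> SpikeResponse:
    """Simulate the LIF dynamics for one patch and return the spike raster.

    Per Euler step the internal variable is updated as
    ``u <- u + (dt/tau) * (-u + Q x - W y)`` where ``y`` is the vector of
    spikes emitted at the current step.  A threshold crossing detected after
    the update at step ``t`` produces a spike at step ``t + 1``; the spiking
    unit's internal variable is reset to the resting value on the step the
    spike is emitted.  All units are updated synchronously.
    """
    if config is None:
        config = DynamicsConfig()
    x = _stimulus_vector(stimulus, params.n_pixels)
    n = params.n_neurons
    n_steps = config.n_steps
    eta = config.eta
    reset = config.reset_value

    drive = params.Q @ x
    u = np.full(n, reset, dtype=np.float64)
    y = np.zeros(n, dtype=bool)
    spikes = np.zeros((n, n_steps), dtype=np.uint8)

    for t in range(n_steps):
        if y.any():
            spikes[:, t] = y
            u[y] = reset
            u += eta * (drive - params.W @ y.astype(np.float64) - u)
        else:
            u += eta * (drive - u)
        np.greater(u, params.theta, out=y)
    return SpikeResponse(spikes)


def run_inference_batch(
    params: NetworkParams,
    stimuli: Sequence,
    config: DynamicsConfig | None = None,
) -> list[SpikeResponse]:
    """Map :func:`run_inference` over a sequence of patches.

    Element-wise identical to calling :func:`run_inference` on each patch;
    provided as plumbing for batch training and probing.
    """
    if config is None:
        config = DynamicsConfig()
    return [run_inference(params, s, config) for s in stimuli]


def count_matrix(
    params: NetworkParams,
    stimuli: Iterable,
    config: DynamicsConfig | None = None,
) -> np.ndarray:
    """Spike counts for a sequence of patches, shape ``(B, N)``."""
    if config is None:
        config = DynamicsConfig()
    rows = [run_inference(params, s, config).counts for s in stimuli]
    if not rows:
        return np.zeros((0, params.n_neurons), dtype=np.int64)
    return np.stack(rows)
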