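"""Desk-scale study configurations.

The published-scale network (1536 units on 16x16 patches, millions of
presentations) is far beyond what a regression suite should run, so the
package ships one documented desk-scale configuration -- a 64-unit network
on 8x8 patches trained for 200 batches of 100 synthetic whitened patches
(2 x 10^4 presentations) -- used consistently by the examples, the test
suite, and the reproduction script.  The sparseness target (p = 0.05 spikes
per image) and all structural choices match the full-scale model; only the
problem size and the learning-rate magnitudes are adapted so that the run
reaches its dynamic equilibrium within the shorter budget.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np

from .dynamics import DynamicsConfig, NetworkParams, StimulusPatch
from .plasticity import LearningConfig
from .stimuli import (
    SyntheticImageConfig,
    WhiteningConfig,
    patch_stream,
    sample_patches,
    synthesize_images,
    whiten_image,
)
from .training import TrainingConfig, TrainingTrace, initialize, train

__all__ = [
    "TOY_N_NEURONS",
    "TOY_PATCH_SIDE",
    "TOY_N_BATCHES",
    "toy_learning_config",
    "toy_training_config",
    "toy_image_ensemble",
    "toy_patch_stream",
    "toy_probe_patches",
    "train_toy_network",
    "ToyRun",
]

TOY_N_NEURONS = 64
TOY_PATCH_SIDE = 8
TOY_N_BATCHES = 200
_IMAGE_SIZE = 128
_N_IMAGES = 10


def toy_learning_config() -> LearningConfig:
    """Learning rates for the desk-scale run.

    The ordering (feed-forward rate much smaller than the inhibition and
    threshold rates) matches the full-scale model; the magnitudes are larger
    so the 200-batch run reaches dynamic equilibrium, with the schedule
    decay restoring small end-of-run step sizes.
    """
    return LearningConfig(p=0.05, alpha=0.3, beta=0.03, gamma=0.3, batch_size=100)


def toy_training_config(seed: int = 1) -> TrainingConfig:
    """Desk-scale run length, schedule, and initialization.

    The initial threshold is set near the initial drive scale (1.0) rather
    than the full-scale default of 5.0: with a tiny sparseness target the
    downward homeostatic step is bounded by ``gamma * p`` per batch, so a
    high threshold takes thousands of batches to anneal, which the
    short desk-scale budget does not cover.  Starting at 1.0 the units fire
    densely at first and homeostasis raises thresholds quickly, which
    converges within the budget.
    """
    return TrainingConfig(
        n_batches=TOY_N_BATCHES,
        seed=seed,
        init_theta=1.0,
        checkpoint_every=10,
    )


def toy_image_ensemble(seed: int) -> list[np.ndarray]:
    """Whitened synthetic 1/f images used as the toy training corpus."""
    images = synthesize_images(
        SyntheticImageConfig(
            size=_IMAGE_SIZE,
            spectrum_exponent=1.0,
            n_gabor_components=0,
            n_images=_N_IMAGES,
            seed=seed,
        )
    )
    wcfg = WhiteningConfig()
    return [whiten_image(im, wcfg) for im in images]


def toy_patch_stream(seed: int = 1) -> Iterator[StimulusPatch]:
    """Infinite stream of standardized training patches."""
    return patch_stream(toy_image_ensemble(seed), TOY_PATCH_SIDE, seed=seed + 1)


def toy_probe_patches(seed: int = 1, n: int = 10_000) -> list[StimulusPatch]:
    """Probe patches from the same ensemble statistics (fresh positions)."""
    return sample_patches(toy_image_ensemble(seed), TOY_PATCH_SIDE, n, seed=seed + 2)


@dataclasses.dataclass
class ToyRun:
    """A completed desk-scale training run with its configuration."""

    params_initial: NetworkParams
    params: NetworkParams
    trace: TrainingTrace
    learn_cfg: LearningConfig
    train_cfg: TrainingConfig
    dynamics: DynamicsConfig
    seed: int


def train_toy_network(seed: int = 1) -> ToyRun:
    """Train the desk-scale network end to end (about 2 x 10^4 presentations)."""
    learn_cfg = toy_learning_config()
    train_cfg = toy_training_config(seed)
    dynamics = DynamicsConfig()
    params0 = initialize(TOY_N_NEURONS, TOY_PATCH_SIDE**2, train_cfg)
    params, trace = train(
        params0, toy_patch_stream(seed), learn_cfg, train_cfg, dynamics
    )
    return ToyRun(params0, params, trace, learn_cfg, train_cfg, dynamics, seed)
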