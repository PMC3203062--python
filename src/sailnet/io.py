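"""Configuration files, checkpoints, and run manifests.

Checkpoints are single HDF5 files holding the full learnable state (``Q``,
``W``, ``theta``), the diagnostic trace, the serialized run configuration,
and the random-generator state, under a versioned schema -- enough to
resume a run exactly or to reproduce it from the manifest.  An NPZ fallback
covers environments where HDF5 files are inconvenient.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Any

import h5py
import numpy as np
import yaml

from .dynamics import DynamicsConfig, NetworkParams
from .errors import CheckpointError, ConfigError
from .plasticity import LearningConfig
from .training import TrainingConfig, TrainingTrace

__all__ = [
    "StimulusSpec",
    "AnalysisToggles",
    "RunConfig",
    "load_config",
    "save_config",
    "save_params",
    "load_params",
    "save_checkpoint",
    "load_checkpoint",
    "Checkpoint",
    "run_manifest",
]

SCHEMA_VERSION = 1


@dataclasses.dataclass(frozen=True)
class StimulusSpec:
    """Where training patches come from.

    ``kind="synthetic"`` generates whitened 1/f surrogate images in memory;
    ``kind="file"`` reads an image collection (HDF5 ``images`` dataset, NPZ,
    NPY, or a standard image file) from ``path``.
    """

    kind: str = "synthetic"
    path: str | None = None
    image_size: int = 128
    n_images: int = 10
    spectrum_exponent: float = 1.0
    n_gabor_components: int = 0
    whiten: bool = True
    standardize: str = "per-patch"

    def __post_init__(self) -> None:
        if self.kind not in ("synthetic", "file"):
            raise ConfigError(f"stimulus kind must be 'synthetic' or 'file', got {self.kind!r}")
        if self.kind == "file" and not self.path:
            raise ConfigError("stimulus kind 'file' requires a path")


@dataclasses.dataclass(frozen=True)
class AnalysisToggles:
    receptive_fields: bool = True
    gabor: bool = True
    rates: bool = True
    correlations: bool = True
    weights: bool = True
    overlap: bool = True


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one training run."""

    n_neurons: int
    patch_side: int
    seed: int = 0
    dynamics: DynamicsConfig = dataclasses.field(default_factory=DynamicsConfig)
    learning: LearningConfig = dataclasses.field(default_factory=LearningConfig)
    training: TrainingConfig = dataclasses.field(default_factory=TrainingConfig)
    stimulus: StimulusSpec = dataclasses.field(default_factory=StimulusSpec)
    analysis: AnalysisToggles = dataclasses.field(default_factory=AnalysisToggles)

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigError("n_neurons must be >= 1")
        if self.patch_side < 1:
            raise ConfigError("patch_side must be >= 1")
        if self.stimulus.kind == "synthetic" and self.stimulus.image_size < 2 * self.patch_side:
            raise ConfigError(
                "synthetic image_size must be at least twice the patch side"
            )

    @property
    def n_pixels(self) -> int:
        return self.patch_side**2


_NESTED = {
    "dynamics": DynamicsConfig,
    "learning": LearningConfig,
    "training": TrainingConfig,
    "stimulus": StimulusSpec,
    "analysis": AnalysisToggles,
}


def _build_dataclass(cls, mapping: dict, context: str):
    if not isinstance(mapping, dict):
        raise ConfigError(f"{context} must be a mapping, got {type(mapping).__name__}")
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - field_names)
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {', '.join(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in mapping.items():
        if key == "schedule" and value is not None:
            value = tuple((int(b), float(m)) for b, m in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML (or JSON) run configuration."""
    path = pathlib.Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a mapping at the top level")
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - top_fields)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {', '.join(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _NESTED:
            kwargs[key] = _build_dataclass(_NESTED[key], value or {}, key)
        else:
            kwargs[key] = value
    if "n_neurons" not in kwargs or "patch_side" not in kwargs:
        raise ConfigError("config must set n_neurons and patch_side")
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid run config: {exc}") from exc


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    sched = d["training"].get("schedule")
    if sched is not None:
        d["training"]["schedule"] = [list(pair) for pair in sched]
    return d


def save_config(cfg: RunConfig, path) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump(_config_dict(cfg), sort_keys=False))


def config_hash(cfg: RunConfig) -> str:
    canonical = json.dumps(_config_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


# ---------------------------------------------------------------------------
# parameter and checkpoint persistence


def save_params(params: NetworkParams, path) -> None:
    """Persist Q, W, theta bit-exactly (HDF5 by default, NPZ by suffix)."""
    path = pathlib.Path(path)
    if path.suffix == ".npz":
        np.savez(path, Q=params.Q, W=params.W, theta=params.theta)
        return
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["kind"] = "sailnet-params"
        fh.create_dataset("Q", data=params.Q)
        fh.create_dataset("W", data=params.W)
        fh.create_dataset("theta", data=params.theta)


def load_params(path) -> NetworkParams:
    path = pathlib.Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return NetworkParams(data["Q"], data["W"], data["theta"])
    try:
        with h5py.File(path, "r") as fh:
            return NetworkParams(fh["Q"][...], fh["W"][...], fh["theta"][...])
    except (OSError, KeyError) as exc:
        raise CheckpointError(f"{path} is not a readable parameter file: {exc}") from exc


@dataclasses.dataclass
class Checkpoint:
    params: NetworkParams
    trace: TrainingTrace | None
    rng_state: dict | None
    config: dict | None
    batch_index: int | None = None


def save_checkpoint(
    path,
    params: NetworkParams,
    trace: TrainingTrace | None = None,
    rng_state: dict | None = None,
    config: RunConfig | dict | None = None,
    batch_index: int | None = None,
) -> None:
    """Write a versioned HDF5 checkpoint (parameters, trace, RNG state)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["kind"] = "sailnet-checkpoint"
        fh.create_dataset("Q", data=params.Q)
        fh.create_dataset("W", data=params.W)
        fh.create_dataset("theta", data=params.theta)
        if batch_index is not None:
            fh.attrs["batch_index"] = int(batch_index)
        if trace is not None:
            grp = fh.create_group("trace")
            for name, values in trace.as_dict().items():
                grp.create_dataset(name, data=values)
        if rng_state is not None:
            fh.attrs["rng_state"] = json.dumps(rng_state)
        if config is not None:
            if isinstance(config, RunConfig):
                config = _config_dict(config)
            fh.attrs["config"] = yaml.safe_dump(config, sort_keys=False)


def load_checkpoint(path) -> Checkpoint:
    """Read a checkpoint; raises :class:`CheckpointError` on schema problems."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise CheckpointError(f"{path} is not an HDF5 checkpoint: {exc}") from exc
    with fh:
        kind = fh.attrs.get("kind")
        if kind not in ("sailnet-checkpoint", "sailnet-params"):
            raise CheckpointError(f"{path}: not a checkpoint (kind={kind!r})")
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise CheckpointError(
                f"{path}: schema version {version} not supported (expected {SCHEMA_VERSION})"
            )
        try:
            params = NetworkParams(fh["Q"][...], fh["W"][...], fh["theta"][...])
        except KeyError as exc:
            raise CheckpointError(f"{path}: missing dataset {exc}") from exc
        trace = None
        if "trace" in fh:
            trace = TrainingTrace.from_dict(
                {name: fh["trace"][name][...] for name in fh["trace"]}
            )
        rng_state = None
        if "rng_state" in fh.attrs:
            rng_state = json.loads(fh.attrs["rng_state"])
        config = None
        if "config" in fh.attrs:
            config = yaml.safe_load(fh.attrs["config"])
        batch_index = (
            int(fh.attrs["batch_index"]) if "batch_index" in fh.attrs else None
        )
    return Checkpoint(params, trace, rng_state, config, batch_index)


def run_manifest(cfg: RunConfig, extra: dict | None = None) -> dict:
    """Reproducibility manifest: config hash, seed, and library versions."""
    import scipy

    from . import __version__

    manifest = {
        "config_sha256": config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "sailnet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "h5py": h5py.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    return manifest
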