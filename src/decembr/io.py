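"""Configuration files, tables, state serialization, and run manifests.

Formats: YAML for configs, TSV for anything tabular (embeddings, per-epoch
logs, summaries), JSON for mixture states and run manifests, HDF5 (via
:mod:`decembr.data`) for datasets and model checkpoints.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .mixture import TMixtureState
from .training import TrainConfig

__all__ = [
    "load_config",
    "save_config",
    "save_embeddings_tsv",
    "load_embeddings_tsv",
    "save_mixture_state",
    "load_mixture_state",
    "save_checkpoint",
    "load_checkpoint",
    "RunManifest",
]

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(TrainConfig)}


def load_config(path: str | Path) -> TrainConfig:
    """Parse and validate a YAML config; unknown keys are rejected and
    missing keys take the documented defaults (dof 2.1, clamp_floor 1e-6)."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return TrainConfig(**raw)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid config: {e}") from e


def save_config(config: TrainConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def save_embeddings_tsv(Z, path: str | Path) -> None:
    """One row per neuron: `neuron_id` then feature columns f0..f{K-1}."""
    Z = np.asarray(Z, dtype=np.float64)
    df = pd.DataFrame(Z, columns=[f"f{k}" for k in range(Z.shape[1])])
    df.insert(0, "neuron_id", np.arange(Z.shape[0]))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_embeddings_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = [c for c in df.columns if c.startswith("f")]
    return df[cols].to_numpy(dtype=np.float64)


def save_mixture_state(state: TMixtureState, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(state.to_dict(), f, indent=1)


def load_mixture_state(path: str | Path) -> TMixtureState:
    with open(path) as f:
        return TMixtureState.from_dict(json.load(f))


def save_checkpoint(model, path: str | Path) -> None:
    """Model parameters in an HDF5 container keyed by parameter name."""
    from .models import CoreReadoutModel, LinearNeuronModel

    with h5py.File(path, "w") as f:
        if isinstance(model, LinearNeuronModel):
            f.attrs["kind"] = "linear-toy"
            f.create_dataset("weights", data=model.weights)
        elif isinstance(model, CoreReadoutModel):
            f.attrs["kind"] = "core-readout"
            for k, v in model.params.items():
                f.create_dataset(k, data=v)
        else:
            raise ValueError(f"unknown model type {type(model)!r}")


def load_checkpoint(path: str | Path):
    from .models import CoreReadoutModel, LinearNeuronModel

    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        if kind == "linear-toy":
            return LinearNeuronModel(f["weights"][...])
        return CoreReadoutModel({k: f[k][...] for k in f.keys()})


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Snapshot of a run: config, seed streams, digests of inputs/outputs."""

    command: str
    config: dict
    seed: int
    streams: dict
    package_version: str
    input_digests: dict
    output_digests: dict
    timestamp: str

    @classmethod
    def create(
        cls,
        command: str,
        config: TrainConfig | None,
        seed: int,
        inputs: list = (),
        outputs: list = (),
        streams: dict | None = None,
    ) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=config.to_dict() if config is not None else {},
            seed=seed,
            streams=streams or {},
            package_version=__version__,
            input_digests={str(p): _digest(Path(p)) for p in inputs},
            output_digests={str(p): _digest(Path(p)) for p in outputs},
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as f:
            return cls(**json.load(f))
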