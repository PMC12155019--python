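"""Stimulus-response dataset container and HDF5 persistence."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from numpy.typing import NDArray

__all__ = ["StimulusResponseDataset"]


@dataclass
class StimulusResponseDataset:
    """Paired stimuli and per-neuron responses, with optional ground truth.

    ``stimuli`` is (B, ...) — flat (B, K) vectors for linear neurons or
    (B, H, W, C) images for the core-readout model. ``responses`` is (B, N)
    and nonnegative. Ground-truth cluster labels and true readout weights are
    carried only by synthetic datasets. ``behavior`` is an optional (B, 3)
    block of behavioral covariates accepted as extra stimulus channels
    downstream (interface hook; unused by the experiments here).
    """

    stimuli: NDArray[np.float64]
    responses: NDArray[np.float64]
    true_labels: NDArray[np.int64] | None = None
    true_weights: NDArray[np.float64] | None = None
    behavior: NDArray[np.float64] | None = None
    nonnegative: bool = False  # spike counts; linear-neuron responses are signed
    true_positions: NDArray[np.float64] | None = None  # planted RF positions

    def __post_init__(self):
        if self.stimuli.shape[0] != self.responses.shape[0]:
            raise ValueError("stimuli and responses disagree on the number of trials")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if self.nonnegative and np.any(self.responses < 0):
            raise ValueError("responses must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.stimuli.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[1]

    def split(self, val_fraction: float = 0.1):
        """(train, validation) split on trailing trials; generators keep the
        trial order random so a tail split is unbiased."""
        n_val = max(1, int(round(self.n_trials * val_fraction)))
        n_train = self.n_trials - n_val
        tr = StimulusResponseDataset(
            self.stimuli[:n_train], self.responses[:n_train],
            self.true_labels, self.true_weights,
            None if self.behavior is None else self.behavior[:n_train],
            self.nonnegative,
            self.true_positions,
        )
        va = StimulusResponseDataset(
            self.stimuli[n_train:], self.responses[n_train:],
            self.true_labels, self.true_weights,
            None if self.behavior is None else self.behavior[n_train:],
            self.nonnegative,
            self.true_positions,
        )
        return tr, va

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("stimuli", data=self.stimuli)
            f.create_dataset("responses", data=self.responses)
            if self.true_labels is not None:
                f.create_dataset("true_labels", data=self.true_labels)
            if self.true_weights is not None:
                f.create_dataset("true_weights", data=self.true_weights)
            if self.behavior is not None:
                f.create_dataset("behavior", data=self.behavior)
            if self.true_positions is not None:
                f.create_dataset("true_positions", data=self.true_positions)
            f.attrs["nonnegative"] = self.nonnegative

    @classmethod
    def load(cls, path: str | Path) -> "StimulusResponseDataset":
        with h5py.File(path, "r") as f:
            return cls(
                stimuli=f["stimuli"][...],
                responses=f["responses"][...],
                true_labels=f["true_labels"][...] if "true_labels" in f else None,
                true_weights=f["true_weights"][...] if "true_weights" in f else None,
                behavior=f["behavior"][...] if "behavior" in f else None,
                nonnegative=bool(f.attrs.get("nonnegative", False)),
                true_positions=(
                    f["true_positions"][...] if "true_positions" in f else None
                ),
            )
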