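"""Paired geometry/WSS samples and the cohort container used for training."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import InputTensor, VesselGraph, WSSNormalizer
from .errors import ValidationError
from .oracle import WSSField
from .stenosis import StenosisSpec


@dataclass
class CaseSample:
    """One vessel: cropped feature tensor, vessel graph and target WSS."""

    tensor: InputTensor
    graph: VesselGraph
    wss: WSSField                      # cropped, Pa
    specs: tuple[StenosisSpec, ...] = ()
    case_id: int = 0
    #: full-resolution geometry, kept only when exporting mesh files
    lattice: object = None
    centerline: object = None

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.wss.values.shape


@dataclass
class WSSDataset:
    """A cohort of cases with a train/val/test split and frozen target
    normalization statistics (fit on the training split only)."""

    samples: list[CaseSample]
    train_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    val_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    test_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    normalizer: WSSNormalizer | None = None

    def __len__(self) -> int:
        return len(self.samples)

    def split(self, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> "WSSDataset":
        """Deterministic seeded-shuffle split; fits the normalizer on the
        training targets."""
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")
        n = len(self.samples)
        order = np.random.default_rng(seed).permutation(n)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        if n_train == 0 or n_val == 0 or n_train + n_val >= n:
            if n < 3:
                raise ValidationError("dataset too small to split")
        self.train_idx = order[:n_train]
        self.val_idx = order[n_train:n_train + n_val]
        self.test_idx = order[n_train + n_val:]
        train_targets = np.stack(
            [self.samples[i].wss.values for i in self.train_idx]
        )
        self.normalizer = WSSNormalizer.fit(train_targets)
        return self

    def subset(self, which: str) -> list[CaseSample]:
        idx = {"train": self.train_idx, "val": self.val_idx,
               "test": self.test_idx}[which]
        return [self.samples[i] for i in idx]

    def targets_normalized(self, which: str) -> np.ndarray:
        """(n_cases, n_ax, n_theta) normalized targets for a split."""
        if self.normalizer is None:
            raise ValidationError("call split() first")
        return np.stack(
            [self.normalizer.transform(s.wss.values) for s in self.subset(which)]
        )
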