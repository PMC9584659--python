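"""Synthetic high-dimensional labelled data with planted informative features.

Emulates the shape of microarray / gene-expression benchmarks: thousands
of features, tens of samples, 2-11 classes, where only a handful of
features carry class signal.  Noise features are i.i.d. Gaussian(0,
noise_sd^2); informative features of a class-k sample are Gaussian(k *
mean_shift, noise_sd^2), so classes sit ``mean_shift`` noise-SDs apart
along every informative axis.  Ground-truth informative positions are a
seeded random subset of columns and are returned alongside the data so
recovery can be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import LabeledDataset

__all__ = ["SyntheticSpec", "make_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    mean_shift is the between-class separation of informative features in
    units of the noise standard deviation; class_balance (optional)
    gives per-class proportions summing to 1, default balanced.
    """

    n_samples: int = 100
    n_features: int = 2000
    n_informative: int = 10
    n_classes: int = 2
    mean_shift: float = 3.0
    noise_sd: float = 1.0
    class_balance: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.class_balance is not None:
            if len(self.class_balance) != self.n_classes:
                raise ValueError("class_balance length must equal n_classes")
            if abs(sum(self.class_balance) - 1.0) > 1e-9:
                raise ValueError("class_balance must sum to 1")

    def class_sizes(self) -> np.ndarray:
        """Per-class sample counts by largest remainder; each must be >= 2."""
        props = (np.full(self.n_classes, 1.0 / self.n_classes)
                 if self.class_balance is None
                 else np.asarray(self.class_balance, dtype=float))
        raw = props * self.n_samples
        sizes = np.floor(raw).astype(int)
        remainder = self.n_samples - sizes.sum()
        order = np.argsort(-(raw - sizes), kind="stable")
        sizes[order[:remainder]] += 1
        if sizes.min() < 2:
            raise ValueError(
                f"infeasible class balance: smallest class would have "
                f"{sizes.min()} samples (need >= 2)"
            )
        return sizes


def make_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, set[int]]:
    """Generate a planted-feature dataset and its ground-truth index set.

    Same spec and seed give an identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.class_sizes()
    labels = np.repeat(np.arange(spec.n_classes), sizes)

    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_features))
    informative = rng.choice(spec.n_features, size=spec.n_informative,
                             replace=False)
    X[:, informative] += labels[:, None] * spec.mean_shift

    dataset = LabeledDataset(
        matrix=X,
        labels=tuple(f"class_{k}" for k in labels),
        feature_names=tuple(f"f{j}" for j in range(spec.n_features)),
        sample_ids=tuple(f"s{i:04d}" for i in range(spec.n_samples)),
    )
    return dataset, set(int(j) for j in informative)
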