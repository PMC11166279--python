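"""Class balancing by oversampling + random dropout, and the 80/20 split.

Seizure windows are rare next to interictal ones, so the minority class is
resampled with replacement up to the majority count and a seeded random
dropout then trims whichever class exceeds the target until counts are
exactly equal.  Every output item is a copy of an input item — no synthetic
interpolation.

To avoid leaking duplicated minority windows into evaluation, the split is
performed first (stratified by class) and oversampling is applied to the
training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TypeVar

import numpy as np

from .preprocessing import LabeledWindow

W = TypeVar("W", bound=LabeledWindow)


@dataclass
class SplitDataset:
    train: list[LabeledWindow]
    test: list[LabeledWindow]
    seed: int
    class_counts: dict[str, dict[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_counts:
            self.class_counts = {
                "train": _counts(self.train),
                "test": _counts(self.test),
            }


def _counts(windows: Sequence[LabeledWindow]) -> dict[int, int]:
    out = {0: 0, 1: 0}
    for w in windows:
        out[w.label] += 1
    return out


def oversample_equalize(windows: Sequence[W], seed: int,
                        target: int | None = None) -> list[W]:
    """Equalize class counts: resample the minority with replacement up to the
    majority count (or ``target``), then randomly drop any excess so final
    counts are exactly equal."""
    by_class: dict[int, list[W]] = {0: [], 1: []}
    for w in windows:
        by_class[w.label].append(w)
    for label, items in by_class.items():
        if not items:
            raise ValueError(f"class {label} has no members; cannot balance")
    rng = np.random.default_rng(seed)
    n_target = target if target is not None else max(len(v) for v in by_class.values())
    out: list[W] = []
    for label in (0, 1):
        items = list(by_class[label])
        if len(items) < n_target:
            extra = rng.integers(0, len(items), size=n_target - len(items))
            items = items + [items[i] for i in extra]
        elif len(items) > n_target:
            keep = rng.permutation(len(items))[:n_target]
            items = [items[i] for i in sorted(keep)]
        out.extend(items)
    return out


def split_train_test(windows: Sequence[W], train_fraction: float = 0.8,
                     seed: int = 0) -> SplitDataset:
    """Seeded, class-stratified random split.

    Per class, ``round(train_fraction * count)`` windows go to training; the
    split is by window identity, so no window object appears in both parts.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    by_class: dict[int, list[W]] = {0: [], 1: []}
    for w in windows:
        by_class[w.label].append(w)
    rng = np.random.default_rng(seed)
    train: list[W] = []
    test: list[W] = []
    for label in (0, 1):
        items = by_class[label]
        n_train = int(round(train_fraction * len(items)))
        order = rng.permutation(len(items))
        train.extend(items[i] for i in sorted(order[:n_train]))
        test.extend(items[i] for i in sorted(order[n_train:]))
    return SplitDataset(train=train, test=test, seed=seed)


def balanced_split(windows: Sequence[W], train_fraction: float = 0.8,
                   seed: int = 0) -> SplitDataset:
    """Split first, then oversample-equalize the training portion only."""
    split = split_train_test(windows, train_fraction=train_fraction, seed=seed)
    balanced_train = oversample_equalize(split.train, seed=seed + 1)
    return SplitDataset(train=balanced_train, test=split.test, seed=seed,
                        class_counts={"train": _counts(balanced_train),
                                      "test": _counts(split.test)})
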