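"""Stratified train/test splitting and cross-validation folds.

The cohort split follows the study design: a 4:1 random split in which
the per-class test count is ``round(test_fraction * n_class)`` with
half-up rounding, which on the 149 pMCI / 363 sMCI cohort reproduces
the published 30/73 test and 119/290 training composition.  Five-fold
cross-validation folds are carved from the training split, stratified
so per-class fold sizes differ by at most one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplitPlan", "FoldPlan", "stratified_split", "make_cv_folds"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SplitPlan:
    """Disjoint train/test id lists with the seed that produced them."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    test_fraction: float

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "test_fraction": self.test_fraction,
                "train_ids": list(self.train_ids),
                "test_ids": list(self.test_ids),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(d["train_ids"], d["test_ids"], d["seed"], d["test_fraction"])


@dataclass
class FoldPlan:
    """Stratified assignment of ids to folds 1..k."""

    k: int
    assignments: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f == fold]

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k, "seed": self.seed, "assignments": self.assignments}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(d["k"], {str(k): int(v) for k, v in d["assignments"].items()}, d["seed"])


def stratified_split(labels: dict[str, int], test_fraction: float, seed: int) -> SplitPlan:
    """Per-class random split: round(test_fraction * n_class) subjects of
    each class go to the test set; deterministic for a fixed seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly in (0, 1)")
    classes = set(labels.values())
    if classes != {0, 1}:
        raise ValueError(f"both classes must be present, got labels {sorted(classes)}")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in (0, 1):
        ids = sorted(i for i, y in labels.items() if y == cls)
        n_test = _round_half_up(test_fraction * len(ids))
        perm = rng.permutation(len(ids))
        test_ids += [ids[j] for j in perm[:n_test]]
        train_ids += [ids[j] for j in perm[n_test:]]
    return SplitPlan(sorted(train_ids), sorted(test_ids), seed, test_fraction)


def make_cv_folds(labels: dict[str, int], k: int, seed: int) -> FoldPlan:
    """Stratified k-fold partition: within each class ids are shuffled
    and dealt round-robin, so per-class fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    for cls in sorted(set(labels.values())):
        ids = sorted(i for i, y in labels.items() if y == cls)
        if len(ids) < k:
            raise ValueError(f"class {cls} has {len(ids)} members, fewer than k={k}")
        perm = rng.permutation(len(ids))
        for j, idx in enumerate(perm):
            assignments[ids[idx]] = (j % k) + 1
    return FoldPlan(k=k, assignments=assignments, seed=seed)
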