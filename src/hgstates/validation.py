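"""Blocked cross-validation with a temporal buffer, class balancing, and the
finite-sample binomial chance level.

Naturalistic recordings are strongly autocorrelated, so folds are contiguous
time blocks rather than random splits, and the fold(s) temporally adjacent to
the test fold are excluded from training (the "1-fold buffer"), keeping test
and training epochs at least one fold's duration apart.  Because the epoch
count is finite, "chance" is not 1/n_classes but the 95th percentile of the
binomial null: the smallest accuracy that a label-guessing classifier would
reach with probability < alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class CVPlan:
    """Contiguous-block fold assignment with buffered training sets."""

    n_folds: int
    fold_of_epoch: np.ndarray
    buffer_folds: int = 1

    def __post_init__(self) -> None:
        self.fold_of_epoch = np.asarray(self.fold_of_epoch, dtype=int)
        if np.any(np.diff(self.fold_of_epoch) < 0):
            raise ValueError("folds must be contiguous in (chronological) epoch order")

    @property
    def n_epochs(self) -> int:
        return self.fold_of_epoch.size

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_epoch == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        """All epochs outside the test fold and its buffer folds."""
        excluded = np.abs(self.fold_of_epoch - fold) <= self.buffer_folds
        return np.flatnonzero(~excluded)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_folds": self.n_folds,
                "buffer_folds": self.buffer_folds,
                "fold_of_epoch": self.fold_of_epoch.tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "CVPlan":
        d = json.loads(payload)
        return cls(d["n_folds"], np.asarray(d["fold_of_epoch"]), d["buffer_folds"])


def make_cv_plan(n_epochs: int, k: int = 7, buffer_folds: int = 1) -> CVPlan:
    """Split chronologically ordered epochs into ``k`` contiguous folds.

    Fold sizes differ by at most one epoch.  For each test fold the
    ``buffer_folds`` temporally adjacent folds on each side are excluded from
    training (one-sided at the edges).
    """
    if n_epochs < 2 * k:
        raise ValueError(f"too few epochs ({n_epochs}) for {k}-fold blocked CV")
    sizes = np.full(k, n_epochs // k)
    sizes[: n_epochs % k] += 1
    return CVPlan(k, np.repeat(np.arange(k), sizes), buffer_folds)


def balance_classes(
    indices: np.ndarray,
    labels: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Subsample ``indices`` so every class count equals the minimum count.

    Uniform random subsampling without replacement, deterministic given the
    seed; the result is returned in chronological (sorted index) order.
    """
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = np.unique(labels)
    per_class = {c: indices[labels[indices] == c] for c in classes}
    for c, idx in per_class.items():
        if idx.size == 0:
            raise ValueError(f"class {c!r} absent from the index set")
    n_min = min(idx.size for idx in per_class.values())
    chosen = np.concatenate(
        [rng.choice(idx, size=n_min, replace=False) for c, idx in sorted(per_class.items())]
    )
    return np.sort(chosen)


@dataclass
class ChanceLevel:
    """Finite-sample chance accuracy from the binomial CDF."""

    n_trials: int
    n_classes: int
    alpha: float
    level_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_classes < 2:
            raise ValueError("need n_trials >= 1 and n_classes >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        k_star = int(stats.binom.ppf(1 - self.alpha, self.n_trials, 1.0 / self.n_classes))
        # ppf returns the smallest k with CDF >= 1 - alpha
        self.level_pct = 100.0 * k_star / self.n_trials

    @property
    def level_pct_rounded(self) -> int:
        return int(round(self.level_pct))


def chance_level(n_trials: int, n_classes: int, alpha: float = 0.05) -> ChanceLevel:
    """Smallest accuracy a guessing classifier reaches with prob. < ``alpha``.

    level = 100 * k* / n with k* the smallest integer such that
    BinomCDF(k*; n, 1/n_classes) >= 1 - alpha.
    """
    return ChanceLevel(n_trials, n_classes, alpha)
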