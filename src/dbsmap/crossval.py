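"""Cross-validation scaffolding shared by the sweet-spot and fiber models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stats import pearson_with_p


@dataclass
class CVResult:
    """Out-of-fold predictions and their agreement with observed outcomes.

    ``r`` is the Pearson correlation of predicted vs observed (NaN with
    ``degenerate=True`` when predictions are constant); ``n_fallback``
    counts held-out patients whose prediction had to fall back (empty
    intersection with the trained map / no connected selected fibers).
    """

    patient_ids: list
    predicted: np.ndarray
    observed: np.ndarray
    scheme: str
    k: int | None = None
    seed: int | None = None
    n_fallback: int = 0
    r: float = field(init=False)
    p_value: float = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.predicted.shape != self.observed.shape:
            raise ValueError("predicted and observed must align")
        self.r, self.p_value = pearson_with_p(self.predicted, self.observed)
        self.degenerate = not np.isfinite(self.r)


def make_folds(n: int, scheme: str, k: int = 10, seed: int | None = None) -> list:
    """Index folds: leave-one-out, or a seeded k-fold partition of 0..n-1."""
    if scheme == "loocv":
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        if not 2 <= k <= n:
            raise ValueError(f"k={k} must be in [2, {n}]")
        perm = np.random.default_rng(seed).permutation(n)
        return [np.sort(f) for f in np.array_split(perm, k)]
    raise ValueError(f"unknown CV scheme {scheme!r} (loocv or kfold)")
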