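"""Voxel-wise sweet/sour-spot mapping with FDR control and cross-validation.

The mapping follows the group-level VTA statistics approach: an N-image
counts how many patients' VTAs cover each voxel; voxels covered by fewer
than a coverage fraction (default 20%) of VTAs are excluded; each remaining
voxel's covering patients contribute their outcome change scores to a mean
effect map and to a two-sided Wilcoxon signed-rank test against zero;
p-values are Benjamini-Hochberg adjusted over the kept voxels at alpha
(default 0.05).  Sweet = significantly positive mean change, sour =
significantly negative.

Prediction for a held-out patient is the mean of the trained mean-effect
map under the patient's VTA restricted to significant voxels, falling back
to all kept voxels, then to 0 (flagged).  Alternatives ("sum",
"sweet_minus_sour" overlap volumes) are available via ``predictor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy.stats import false_discovery_control

from ._stats import signed_rank_p
from .core import CohortDataset, ImageVolume
from .crossval import CVResult, make_folds
from .vta import DEFAULT_E_THRESHOLD, compute_cohort_vtas

# ---------------------------------------------------------------------------
# map-building operations


def build_n_image(vta_indices: list, grid: ImageVolume) -> ImageVolume:
    """Integer count of covering VTAs per voxel.

    ``vta_indices``: one array of flat voxel indices per patient (already
    the union over hemispheres if the analysis is bilateral).
    """
    n_vox = int(np.prod(grid.shape))
    counts = np.zeros(n_vox, dtype=np.int32)
    for idx in vta_indices:
        counts[idx] += 1
    return grid.like(counts.reshape(grid.shape))


def coverage_threshold(n_vtas: int, fraction: float = 0.2) -> int:
    """Minimum count for a voxel to be kept: covered by >= fraction of VTAs."""
    if not 0 < fraction < 1:
        raise ValueError("coverage fraction must be in (0, 1)")
    return ceil(fraction * n_vtas)


def coverage_filter(n_image: ImageVolume, n_vtas: int, fraction: float = 0.2) -> ImageVolume:
    """Boolean mask of voxels covered by at least ``fraction`` of the VTAs."""
    return n_image.like(n_image.data >= coverage_threshold(n_vtas, fraction))


def mean_effect_map(vta_indices: list, changes: np.ndarray, kept_mask: ImageVolume) -> ImageVolume:
    """Per-voxel mean change score over covering patients; NaN outside kept."""
    n_vox = int(np.prod(kept_mask.shape))
    sums = np.zeros(n_vox)
    counts = np.zeros(n_vox)
    for idx, c in zip(vta_indices, np.asarray(changes, dtype=float)):
        sums[idx] += c
        counts[idx] += 1
    out = np.full(n_vox, np.nan)
    kept = kept_mask.data.ravel().astype(bool)
    assert counts[kept].min(initial=np.inf) > 0, "kept voxel with no covering VTA"
    out[kept] = sums[kept] / counts[kept]
    return kept_mask.like(out.reshape(kept_mask.shape))


def _coverage_patterns(vta_indices: list, kept_flat: np.ndarray, n_vox: int):
    """Boolean patients x kept-voxels coverage, deduplicated by voxel.

    Returns (patterns, inverse): ``patterns`` is (n_unique, n_patients);
    voxel j's covering set is ``patterns[inverse[j]]``.  VTAs are spatially
    coherent, so the number of distinct covering sets is far below the
    number of kept voxels — each signed-rank test is run once per set.
    """
    pos = np.full(n_vox, -1, dtype=np.int64)
    pos[kept_flat] = np.arange(kept_flat.size)
    mat = np.zeros((len(vta_indices), kept_flat.size), dtype=bool)
    for i, idx in enumerate(vta_indices):
        sel = pos[idx]
        mat[i, sel[sel >= 0]] = True
    packed = np.packbits(mat, axis=0).T.copy()
    _, first, inverse = np.unique(packed, axis=0, return_index=True, return_inverse=True)
    return mat[:, first].T, inverse.ravel()


def voxelwise_signed_rank(vta_indices: list, changes: np.ndarray, kept_mask: ImageVolume) -> ImageVolume:
    """Two-sided signed-rank p-value per kept voxel (NaN outside)."""
    kept_flat = np.flatnonzero(kept_mask.data.ravel())
    n_vox = int(np.prod(kept_mask.shape))
    changes = np.asarray(changes, dtype=float)
    patterns, inverse = _coverage_patterns(vta_indices, kept_flat, n_vox)
    p_unique = np.array([signed_rank_p(changes[pat]) for pat in patterns])
    out = np.full(n_vox, np.nan)
    out[kept_flat] = p_unique[inverse]
    return kept_mask.like(out.reshape(kept_mask.shape))


def fdr_correct(p_map: ImageVolume) -> ImageVolume:
    """Benjamini-Hochberg q-values over the kept (non-NaN) voxels."""
    p = p_map.data.ravel()
    kept = np.isfinite(p)
    out = np.full(p.shape, np.nan)
    if kept.any():
        out[kept] = false_discovery_control(p[kept], method="bh")
    return p_map.like(out.reshape(p_map.shape))


def classify_sweet_sour(mean_effect: ImageVolume, q_map: ImageVolume, alpha: float = 0.05) -> ImageVolume:
    """+1 sweet (q <= alpha, mean > 0), -1 sour, 0 ns, NaN excluded."""
    m = mean_effect.data
    q = q_map.data
    out = np.full(m.shape, np.nan)
    kept = np.isfinite(q)
    out[kept] = 0.0
    out[kept & (q <= alpha) & (m > 0)] = 1.0
    out[kept & (q <= alpha) & (m < 0)] = -1.0
    return mean_effect.like(out)


# ---------------------------------------------------------------------------
# flat-array fit used by both the public fit and the CV loop


@dataclass
class _FlatMaps:
    kept_flat: np.ndarray       # flat indices of kept voxels
    mean: np.ndarray            # per kept voxel
    p: np.ndarray
    q: np.ndarray
    label: np.ndarray           # +1 / -1 / 0
    n_vox: int
    train_mean: float = 0.0     # mean change of the (training) cohort


def _fit_flat(vta_indices: list, changes: np.ndarray, n_vox: int,
              coverage_fraction: float, alpha: float) -> _FlatMaps:
    counts = np.zeros(n_vox, dtype=np.int32)
    sums = np.zeros(n_vox)
    changes = np.asarray(changes, dtype=float)
    for idx, c in zip(vta_indices, changes):
        counts[idx] += 1
        sums[idx] += c
    thresh = coverage_threshold(len(vta_indices), coverage_fraction)
    kept_flat = np.flatnonzero(counts >= thresh)
    cohort_mean = float(changes.mean())
    if kept_flat.size == 0:
        z = np.array([])
        return _FlatMaps(kept_flat, z, z, z, z, n_vox, cohort_mean)
    mean = sums[kept_flat] / counts[kept_flat]
    patterns, inverse = _coverage_patterns(vta_indices, kept_flat, n_vox)
    p = np.array([signed_rank_p(changes[pat]) for pat in patterns])[inverse]
    q = false_discovery_control(p, method="bh")
    label = np.zeros(kept_flat.size)
    label[(q <= alpha) & (mean > 0)] = 1.0
    label[(q <= alpha) & (mean < 0)] = -1.0
    return _FlatMaps(kept_flat, mean, p, q, label, n_vox, cohort_mean)


def _predict_flat(maps: _FlatMaps, vta_idx: np.ndarray, predictor: str = "mean") -> tuple:
    """Predict one held-out patient from trained flat maps -> (value, fallback).

    Map values enter relative to the training-cohort mean change: the
    grand mean carries no spatial information, and leaving it in would
    give leave-one-out predictions a spurious negative correlation with
    the observed outcomes (the held-out score is missing from every
    training mean).
    """
    pos = np.full(maps.n_vox, -1, dtype=np.int64)
    pos[maps.kept_flat] = np.arange(maps.kept_flat.size)
    sel = pos[np.asarray(vta_idx, dtype=np.int64)]
    sel = sel[sel >= 0]
    if sel.size == 0:
        return 0.0, True
    if predictor == "sweet_minus_sour":
        return float(maps.label[sel].sum()), False
    sig = sel[maps.label[sel] != 0]
    use = sig if sig.size else sel
    centered = maps.mean[use] - maps.train_mean
    if predictor == "sum":
        return float(centered.sum()), sig.size == 0
    return float(centered.mean()), sig.size == 0


# ---------------------------------------------------------------------------
# model / results


class SweetSpotModel:
    """Voxel-wise outcome mapping for one clinical scale.

    Parameters
    ----------
    cohort : CohortDataset
    outcome : scale name, e.g. "HAMA"; the mapped quantity is its change
        score (pre - post), or the improvement rate when
        ``use_improvement_rate`` is set.
    hemisphere : None for the bilateral VTA union (default), or
        "left"/"right" to map a single hemisphere's VTAs.
    coverage_fraction : minimum fraction of VTAs covering a voxel.
    alpha : FDR level for sweet/sour classification.
    predictor : "mean" (default), "sum" or "sweet_minus_sour".
    """

    def __init__(self, cohort: CohortDataset, outcome: str = "HAMA",
                 hemisphere: str | None = None, coverage_fraction: float = 0.2,
                 alpha: float = 0.05, e_threshold: float = DEFAULT_E_THRESHOLD,
                 use_improvement_rate: bool = False, predictor: str = "mean"):
        self.cohort = cohort
        self.outcome = outcome
        self.hemisphere = hemisphere
        self.coverage_fraction = coverage_fraction
        self.alpha = alpha
        self.e_threshold = e_threshold
        self.use_improvement_rate = use_improvement_rate
        self.predictor = predictor

        self.grid = cohort.atlas.volume
        self._n_vox = int(np.prod(self.grid.shape))
        vtas = compute_cohort_vtas(cohort, e_threshold)
        self.patients = cohort.patients
        self.vta_indices = []
        for pid in self.patients:
            parts = [v.flat_indices for (p, h), v in vtas.items()
                     if p == pid and (hemisphere is None or h == hemisphere)]
            self.vta_indices.append(
                np.unique(np.concatenate(parts)) if parts else np.array([], dtype=np.int64))
        self.changes = (cohort.improvement_rates(outcome) if use_improvement_rate
                        else cohort.changes(outcome))

    def fit(self) -> "SweetSpotResults":
        flat = _fit_flat(self.vta_indices, self.changes, self._n_vox,
                         self.coverage_fraction, self.alpha)
        return SweetSpotResults(self, flat)

    def cross_validate(self, scheme: str = "loocv", k: int = 10,
                       seed: int | None = None) -> CVResult:
        """Out-of-fold prediction: maps (including the coverage filter) are
        rebuilt on the training patients of each fold only."""
        n = len(self.patients)
        if n < 8:
            raise ValueError("cross-validation needs at least 8 patients")
        folds = make_folds(n, scheme, k, seed)
        predicted = np.empty(n)
        fallback = np.zeros(n, dtype=bool)
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            maps = _fit_flat([self.vta_indices[i] for i in train], self.changes[train],
                             self._n_vox, self.coverage_fraction, self.alpha)
            for i in fold:
                predicted[i], fallback[i] = _predict_flat(maps, self.vta_indices[i],
                                                          self.predictor)
        return CVResult(self.patients, predicted, self.changes.copy(), scheme,
                        k=(k if scheme == "kfold" else None), seed=seed,
                        n_fallback=int(fallback.sum()))


class SweetSpotResults:
    """Fitted sweet/sour maps plus convenience accessors."""

    def __init__(self, model: SweetSpotModel, flat: _FlatMaps):
        self.model = model
        self._flat = flat
        grid = model.grid

        def unflatten(values, fill=np.nan):
            out = np.full(flat.n_vox, fill)
            out[flat.kept_flat] = values
            return grid.like(out.reshape(grid.shape))

        self.n_image = build_n_image(model.vta_indices, grid)
        kept = np.zeros(flat.n_vox, dtype=bool)
        kept[flat.kept_flat] = True
        self.kept_mask = grid.like(kept.reshape(grid.shape))
        self.mean_effect = unflatten(flat.mean)
        self.p_map = unflatten(flat.p)
        self.q_map = unflatten(flat.q)
        self.label_map = unflatten(flat.label)

    @property
    def n_kept(self) -> int:
        return int(self._flat.kept_flat.size)

    @property
    def n_sweet(self) -> int:
        return int((self._flat.label == 1).sum())

    @property
    def n_sour(self) -> int:
        return int((self._flat.label == -1).sum())

    def significant_fraction(self) -> float:
        """Fraction of kept voxels classified sweet or sour."""
        return (self.n_sweet + self.n_sour) / self.n_kept if self.n_kept else 0.0

    def predict(self, vta_flat_indices: np.ndarray) -> tuple:
        """Predicted outcome change for a VTA given as flat voxel indices;
        returns (value, fallback_flag)."""
        return _predict_flat(self._flat, vta_flat_indices, self.model.predictor)

    def dice_against(self, flat_indices: np.ndarray, label: int = 1) -> float:
        """Dice overlap between sweet (label=1) or sour (-1) voxels and a
        reference voxel set restricted to the kept region."""
        ours = set(self._flat.kept_flat[self._flat.label == label].tolist())
        ref = set(np.asarray(flat_indices).tolist()) & set(self._flat.kept_flat.tolist())
        if not ours and not ref:
            return float("nan")
        return 2 * len(ours & ref) / (len(ours) + len(ref))

    def summary(self) -> str:
        m = self.model
        hemi = m.hemisphere or "bilateral"
        lines = [
            "Sweet-spot mapping results",
            "==========================",
            f"outcome: {m.outcome} ({'improvement rate' if m.use_improvement_rate else 'change score'})",
            f"patients: {len(m.patients)}   VTAs: {hemi}",
            f"coverage: >= {coverage_threshold(len(m.patients), m.coverage_fraction)}"
            f"/{len(m.patients)} VTAs ({m.coverage_fraction:.0%})   alpha (FDR): {m.alpha}",
            f"kept voxels: {self.n_kept}",
            f"sweet voxels: {self.n_sweet}   sour voxels: {self.n_sour}",
        ]
        if self.n_kept:
            lines.append(f"significant fraction: {self.significant_fraction():.3f}")
        return "\n".join(lines)

    def plot_slices(self, ax=None, z_world: float | None = None):
        """Plot one axial slice of the mean-effect map with sweet/sour
        contours; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        grid = self.model.grid
        if z_world is None:
            sweet = self._flat.kept_flat[self._flat.label == 1]
            src = sweet if sweet.size else self._flat.kept_flat
            ijk = np.unravel_index(src, grid.shape)
            kz = int(np.median(ijk[2])) if src.size else grid.shape[2] // 2
        else:
            kz = int(round(grid.world_to_voxel([[0, 0, z_world]])[0][2]))
        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.mean_effect.data[:, :, kz].T, origin="lower", cmap="coolwarm")
        lab = self.label_map.data[:, :, kz].T
        ax.contour(np.nan_to_num(lab) > 0, colors="r", linewidths=0.8)
        ax.contour(np.nan_to_num(lab) < 0, colors="b", linewidths=0.8)
        ax.set_xlabel("x (voxels)")
        ax.set_ylabel("y (voxels)")
        ax.set_title(f"mean {self.model.outcome} change, slice k={kz}")
        return ax


def recovery_dice(results: SweetSpotResults, cohort: CohortDataset) -> float:
    """Dice between sweet voxels and the planted sphere ∩ kept voxels
    (synthetic cohorts with ground truth only)."""
    from .synthetic import sweet_sphere_indices

    gt = cohort.ground_truth
    if gt is None:
        raise ValueError("cohort has no ground truth")
    sphere = sweet_sphere_indices(cohort.atlas.volume, gt.sweet_center, gt.sweet_radius_mm)
    return results.dice_against(sphere, label=1)
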