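"""DBS fiber filtering: per-streamline T-scores and outcome prediction.

Each streamline of a shared (normative-style) tractogram is marked
connected to a patient when any of its points — resampled at half-voxel
steps along the polyline so thin masks are not skipped between vertices —
falls inside the patient's VTA (union of both hemispheres).  Fibers
connected to fewer than a prevalence fraction (default 20%) of patients are
discarded.  Each remaining fiber receives a "fiber T-score": a pooled-
variance two-sample t statistic contrasting outcome changes of connected
vs unconnected patients (positive = connected patients improved more).
The top fraction (default 30%) by |T| forms the predictive fiber set; a
held-out patient's prediction is the mean T-score of the selected fibers
their VTA connects to.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from ._stats import pooled_t
from .core import CohortDataset, ImageVolume, Tractogram
from .crossval import CVResult, make_folds
from .vta import DEFAULT_E_THRESHOLD, compute_cohort_vtas, patient_vta_indices


@dataclass
class ConnectivityMatrix:
    """Boolean fibers x patients incidence: streamline intersects VTA."""

    matrix: np.ndarray          # (n_fibers, n_patients) bool
    fiber_ids: np.ndarray
    patient_ids: list

    @property
    def n_fibers(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[1]


def resample_streamline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Points at most ``step_mm`` apart along the polyline (endpoints kept)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    length = float(seg.sum())
    if length == 0:
        return points[:1]
    t = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(ceil(length / step_mm)) + 1, 2)
    ti = np.linspace(0.0, length, n)
    return np.column_stack([np.interp(ti, t, points[:, ax]) for ax in range(3)])


def streamline_vta_connectivity(
    tractogram: Tractogram,
    patient_vtas: list,
    grid: ImageVolume,
    patient_ids: list | None = None,
    step_fraction: float = 0.5,
) -> ConnectivityMatrix:
    """Connectivity of every streamline to every patient's VTA.

    ``patient_vtas``: per patient, flat voxel indices of the VTA (union of
    hemispheres).  Streamlines are sampled at ``step_fraction`` of the voxel
    size along their course.
    """
    if tractogram.count == 0:
        raise ValueError("empty tractogram")
    step = step_fraction * float(grid.voxel_size_mm.min())
    sampled = [resample_streamline(s, step) for s in tractogram.streamlines]
    counts = np.array([len(s) for s in sampled])
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pts = np.vstack(sampled)

    ijk = np.rint(grid.world_to_voxel(pts)).astype(np.int64)
    valid = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
    flat = np.zeros(len(ijk), dtype=np.int64)
    flat[valid] = np.ravel_multi_index(tuple(ijk[valid].T), grid.shape)

    n_vox = int(np.prod(grid.shape))
    matrix = np.zeros((tractogram.count, len(patient_vtas)), dtype=bool)
    inmask = np.zeros(n_vox, dtype=bool)
    for p, vta_idx in enumerate(patient_vtas):
        vta_idx = np.asarray(vta_idx, dtype=np.int64)
        if vta_idx.size == 0:
            continue
        inmask[vta_idx] = True
        hit = inmask[flat] & valid
        matrix[:, p] = np.add.reduceat(hit, offsets) > 0
        inmask[vta_idx] = False
    ids = patient_ids if patient_ids is not None else list(range(len(patient_vtas)))
    return ConnectivityMatrix(matrix, np.arange(tractogram.count), ids)


def prevalence_filter(conn: ConnectivityMatrix, fraction: float = 0.2,
                      columns: np.ndarray | None = None) -> np.ndarray:
    """Fiber ids connected to at least ``fraction`` of patients (ceil rule).

    ``columns`` restricts to a patient subset (used per CV fold).
    """
    if not 0 < fraction < 1:
        raise ValueError("prevalence fraction must be in (0, 1)")
    m = conn.matrix if columns is None else conn.matrix[:, columns]
    need = ceil(fraction * m.shape[1])
    return conn.fiber_ids[m.sum(axis=1) >= need]


def fiber_t_scores(conn: ConnectivityMatrix, changes: np.ndarray,
                   kept_ids: np.ndarray | None = None,
                   columns: np.ndarray | None = None) -> pd.DataFrame:
    """Pooled-variance two-sample t per fiber: connected vs unconnected.

    NaN (flagged ``degenerate``) when either group has < 2 patients or the
    pooled variance is zero.
    """
    changes = np.asarray(changes, dtype=float)
    m = conn.matrix if columns is None else conn.matrix[:, columns]
    c = changes if columns is None else changes[columns]
    if kept_ids is None:
        kept_ids = conn.fiber_ids
    sub = m[kept_ids]                                      # (K, P)
    n1 = sub.sum(axis=1).astype(float)
    n0 = sub.shape[1] - n1
    s1 = sub @ c
    ss1 = sub @ (c**2)
    s0 = c.sum() - s1
    ss0 = (c**2).sum() - ss1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m0 = s0 / n0
        v1 = (ss1 - n1 * m1**2) / (n1 - 1)
        v0 = (ss0 - n0 * m0**2) / (n0 - 1)
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        t = (m1 - m0) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    bad = (n1 < 2) | (n0 < 2) | ~(sp2 > 0)
    t[bad] = np.nan
    return pd.DataFrame({
        "fiber_id": kept_ids,
        "t_score": t,
        "n_connected": n1.astype(int),
        "n_unconnected": n0.astype(int),
        "degenerate": bad,
    })


def select_top_fraction(scores: pd.DataFrame, fraction: float = 0.3) -> np.ndarray:
    """Fiber ids of the top ``ceil(fraction * n_kept)`` by |t|.

    Ties are broken toward the lower fiber id for determinism; degenerate
    (NaN) scores are never selected.
    """
    if not 0 < fraction <= 1:
        raise ValueError("top fraction must be in (0, 1]")
    n_top = ceil(fraction * len(scores))
    ok = scores[~scores["t_score"].isna()].copy()
    ok["abs_t"] = ok["t_score"].abs()
    ok = ok.sort_values(["abs_t", "fiber_id"], ascending=[False, True])
    return ok["fiber_id"].to_numpy()[:n_top]


def predict_from_fibers(scores: pd.DataFrame, selected_ids: np.ndarray,
                        conn_row: np.ndarray) -> tuple:
    """Mean trained T-score of selected fibers the held-out VTA connects to.

    ``conn_row``: boolean over all fibers for the held-out patient.
    Returns (value, fallback_flag); value 0 when no selected fiber connects.
    """
    t_by_id = scores.set_index("fiber_id")["t_score"]
    sel = np.asarray(selected_ids, dtype=int)
    connected = sel[conn_row[sel]]
    if connected.size == 0:
        return 0.0, True
    return float(t_by_id.loc[connected].mean()), False


class FiberFilterModel:
    """Fiber-filtering outcome model for one clinical scale.

    Connectivity uses the union of bilateral VTAs per patient.  ``welch``
    switches the per-fiber statistic to Welch's t (unequal variances).
    """

    def __init__(self, cohort: CohortDataset, outcome: str = "HAMA",
                 prevalence: float = 0.2, top_fraction: float = 0.3,
                 e_threshold: float = DEFAULT_E_THRESHOLD,
                 use_improvement_rate: bool = False, welch: bool = False):
        self.cohort = cohort
        self.outcome = outcome
        self.prevalence = prevalence
        self.top_fraction = top_fraction
        self.welch = welch
        self.patients = cohort.patients
        vtas = compute_cohort_vtas(cohort, e_threshold)
        self.vta_indices = patient_vta_indices(cohort, vtas)
        self.conn = streamline_vta_connectivity(
            cohort.tractogram, self.vta_indices, cohort.atlas.volume,
            patient_ids=self.patients)
        self.changes = (cohort.improvement_rates(outcome) if use_improvement_rate
                        else cohort.changes(outcome))

    def _scores(self, columns: np.ndarray | None = None):
        kept = prevalence_filter(self.conn, self.prevalence, columns)
        if self.welch:
            scores = self._welch_scores(kept, columns)
        else:
            scores = fiber_t_scores(self.conn, self.changes, kept, columns)
        selected = select_top_fraction(scores, self.top_fraction) if len(scores) else np.array([], dtype=int)
        return kept, scores, selected

    def _welch_scores(self, kept_ids, columns):
        from scipy.stats import ttest_ind

        m = self.conn.matrix if columns is None else self.conn.matrix[:, columns]
        c = self.changes if columns is None else self.changes[columns]
        rows = []
        for fid in kept_ids:
            a, b = c[m[fid]], c[~m[fid]]
            t = (ttest_ind(a, b, equal_var=False).statistic
                 if a.size >= 2 and b.size >= 2 else np.nan)
            rows.append({"fiber_id": fid, "t_score": t, "n_connected": a.size,
                         "n_unconnected": b.size, "degenerate": not np.isfinite(t)})
        return pd.DataFrame(rows)

    def fit(self) -> "FiberFilterResults":
        kept, scores, selected = self._scores()
        return FiberFilterResults(self, kept, scores, selected)

    def cross_validate(self, scheme: str = "loocv", k: int = 10,
                       seed: int | None = None) -> CVResult:
        """Prevalence filter, T-scores and top-fraction selection are all
        recomputed on the training patients of each fold."""
        n = len(self.patients)
        if n < 8:
            raise ValueError("cross-validation needs at least 8 patients")
        folds = make_folds(n, scheme, k, seed)
        predicted = np.empty(n)
        fallback = np.zeros(n, dtype=bool)
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            _, scores, selected = self._scores(columns=train)
            for i in fold:
                predicted[i], fallback[i] = predict_from_fibers(
                    scores, selected, self.conn.matrix[:, i])
        return CVResult(self.patients, predicted, self.changes.copy(), scheme,
                        k=(k if scheme == "kfold" else None), seed=seed,
                        n_fallback=int(fallback.sum()))


class FiberFilterResults:
    """Fitted fiber scores: prevalence-kept fibers, T-scores, selected set."""

    def __init__(self, model: FiberFilterModel, kept_ids, scores: pd.DataFrame, selected):
        self.model = model
        self.kept_ids = np.asarray(kept_ids, dtype=int)
        self.selected_ids = np.asarray(selected, dtype=int)
        sc = scores.copy()
        sc["kept_by_prevalence"] = True
        sc["selected_top"] = sc["fiber_id"].isin(self.selected_ids)
        self.scores = sc

    def predict(self, conn_row: np.ndarray) -> tuple:
        return predict_from_fibers(self.scores, self.selected_ids, conn_row)

    def selected_sign_fractions(self, fiber_ids: np.ndarray) -> tuple:
        """Of ``fiber_ids`` that were selected: (fraction t>0, fraction t<0)."""
        sub = self.scores[self.scores["fiber_id"].isin(fiber_ids)
                          & self.scores["selected_top"]]
        if len(sub) == 0:
            return float("nan"), float("nan")
        t = sub["t_score"].to_numpy()
        return float((t > 0).mean()), float((t < 0).mean())

    def selected_tractograms(self) -> tuple:
        """(positive, negative) Tractograms of the selected fibers."""
        t_by_id = self.scores.set_index("fiber_id")["t_score"]
        pos = [self.model.cohort.tractogram.streamlines[i]
               for i in self.selected_ids if t_by_id.loc[i] > 0]
        neg = [self.model.cohort.tractogram.streamlines[i]
               for i in self.selected_ids if t_by_id.loc[i] < 0]
        return Tractogram(pos) if pos else Tractogram([]), Tractogram(neg) if neg else Tractogram([])

    def summary(self) -> str:
        m = self.model
        t = self.scores.loc[self.scores["selected_top"], "t_score"]
        lines = [
            "Fiber-filtering results",
            "=======================",
            f"outcome: {m.outcome}   patients: {len(m.patients)}",
            f"fibers: {m.conn.n_fibers} total, {len(self.kept_ids)} kept "
            f"(prevalence >= {m.prevalence:.0%}), {len(self.selected_ids)} selected "
            f"(top {m.top_fraction:.0%} by |T|)",
        ]
        if len(t):
            lines.append(f"selected T-scores: {int((t > 0).sum())} positive, "
                         f"{int((t < 0).sum())} negative "
                         f"(range {t.min():.2f} .. {t.max():.2f})")
        return "\n".join(lines)
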