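"""Clinical scale statistics: improvement rates, normality-gated paired
tests, and Spearman correlations linking stimulation geometry to outcomes.

Conventions follow common movement-disorders reporting: improvement rate =
[(pre - post) / pre] x 100%; paired pre/post comparisons use a paired t
test when the Shapiro-Wilk test does not reject normality of the paired
differences (alpha = 0.05) and a Wilcoxon signed-rank test otherwise, with
mean +/- SD vs median (Q1, Q3) summaries per branch.  Correlations are
Spearman's rank correlation, uncorrected (a Benjamini-Hochberg flag is
available for the correlation families).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import false_discovery_control

from ._stats import signed_rank_test, spearman_test
from .core import CohortDataset
from .vta import active_contact_coordinates, cohort_overlap_table

DEFAULT_MOOD_SCALES = ("HAMA", "HAMD")


def improvement_rate(pre: float, post: float) -> float:
    """[(pre - post) / pre] x 100, percent. NaN (undefined) when pre == 0."""
    if pre == 0:
        return float("nan")
    return (pre - post) / pre * 100.0


def normality_gate(differences: np.ndarray, alpha: float = 0.05) -> str:
    """Choose the paired test: Shapiro-Wilk non-rejection -> "paired_t",
    otherwise "wilcoxon_signed_rank" (also for constant differences)."""
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("normality gate needs at least 3 differences")
    if np.ptp(d) == 0:
        return "wilcoxon_signed_rank"
    return "paired_t" if sps.shapiro(d).pvalue > alpha else "wilcoxon_signed_rank"


@dataclass
class PairedTestResult:
    scale: str
    n: int
    statistic: float            # t (paired t) or z (signed-rank approx)
    p_value: float
    test_used: str
    summary_pre: str
    summary_post: str


def _summary(x: np.ndarray, parametric: bool) -> str:
    if parametric:
        return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def paired_change_test(pre: np.ndarray, post: np.ndarray, scale: str = "score",
                       alpha: float = 0.05) -> PairedTestResult:
    """Pre vs post paired comparison with the normality gate."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have the same length")
    d = pre - post
    test = normality_gate(d, alpha)
    if test == "paired_t":
        res = sps.ttest_rel(pre, post)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        sr = signed_rank_test(d)
        stat = sr.z if np.isfinite(sr.z) else sr.w_plus
        p = sr.p_value
    parametric = test == "paired_t"
    return PairedTestResult(scale, pre.size, stat, p, test,
                            _summary(pre, parametric), _summary(post, parametric))


def _corr_frame(rows: list, fdr: bool) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if fdr and len(df):
        ok = df["p_value"].notna()
        df.loc[ok, "q_value"] = false_discovery_control(df.loc[ok, "p_value"], method="bh")
    return df


def coordinate_outcome_correlations(cohort: CohortDataset,
                                    scales=DEFAULT_MOOD_SCALES,
                                    fdr: bool = False,
                                    average_hemispheres: bool = False) -> pd.DataFrame:
    """Spearman correlation of active-contact coordinates (X, Y, Z, per
    hemisphere) with per-patient improvement rates.

    The per-hemisphere join repeats each patient's improvement rate for
    both sides; ``average_hemispheres`` instead correlates the mean of the
    two contacts' coordinates (one row per patient)."""
    coords = active_contact_coordinates(cohort)
    rows = []
    groups = ([("mean", coords.groupby("patient_id")[["x", "y", "z"]].mean().reset_index())]
              if average_hemispheres else
              [(h, coords[coords["hemisphere"] == h]) for h in ("left", "right")])
    for scale in scales:
        rates = {p: cohort.clinical_record(p).improvement_rate(scale) for p in cohort.patients}
        for hemi, sub in groups:
            y = sub["patient_id"].map(rates).to_numpy(dtype=float)
            for axis in ("x", "y", "z"):
                r = spearman_test(sub[axis].to_numpy(dtype=float), y)
                rows.append({"scale": scale, "hemisphere": hemi, "axis": axis,
                             "n": r.n, "rho": r.rho, "p_value": r.p_value,
                             "method": r.method})
    return _corr_frame(rows, fdr)


def overlap_outcome_correlations(cohort: CohortDataset,
                                 overlap_table: pd.DataFrame | None = None,
                                 scales=DEFAULT_MOOD_SCALES,
                                 fdr: bool = False) -> pd.DataFrame:
    """Spearman correlation of VTA-region overlap volumes (mm^3) with
    improvement rates, per hemisphere x STN (sub)region x scale."""
    tab = overlap_table if overlap_table is not None else cohort_overlap_table(cohort)
    rows = []
    for scale in scales:
        rates = {p: cohort.clinical_record(p).improvement_rate(scale) for p in cohort.patients}
        for hemi in ("left", "right"):
            regions = [f"STN_{hemi}"] + [f"STN_{hemi}_{s}"
                                         for s in ("sensorimotor", "associative", "limbic")]
            for region in regions:
                sub = tab[(tab["hemisphere"] == hemi) & (tab["region"] == region)]
                x = sub["overlap_mm3"].to_numpy(dtype=float)
                y = sub["patient_id"].map(rates).to_numpy(dtype=float)
                r = spearman_test(x, y)
                rows.append({"scale": scale, "hemisphere": hemi, "region": region,
                             "n": r.n, "rho": r.rho, "p_value": r.p_value,
                             "method": r.method,
                             "degenerate": r.method == "degenerate"})
    return _corr_frame(rows, fdr)


def summarize_cohort(cohort: CohortDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Baseline vs follow-up summary per scale (normality-gated paired
    tests) plus mean stimulation parameters — a Table-1-style overview."""
    rows = []
    scales = sorted({s for c in cohort.clinical for s in c.scores})
    for scale in scales:
        pre = np.array([cohort.clinical_record(p).pre(scale) for p in cohort.patients])
        post = np.array([cohort.clinical_record(p).post(scale) for p in cohort.patients])
        res = paired_change_test(pre, post, scale, alpha)
        rows.append({"variable": scale, "baseline": res.summary_pre,
                     "followup": res.summary_post, "statistic": round(res.statistic, 3),
                     "p_value": res.p_value, "test": res.test_used})
    for name, attr in (("DBS amplitude (V)", "amplitude_v"),
                       ("DBS frequency (Hz)", "frequency_hz"),
                       ("DBS pulse width (us)", "pulse_width_us")):
        vals = np.array([getattr(e, attr) for e in cohort.electrodes])
        rows.append({"variable": name, "baseline": "-",
                     "followup": _summary(vals, parametric=True),
                     "statistic": np.nan, "p_value": np.nan, "test": "-"})
    return pd.DataFrame(rows)
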