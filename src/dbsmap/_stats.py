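"""Low-level statistical primitives shared across modules.

The Wilcoxon signed-rank p-value here is computed from the *exact* null
distribution whenever n (after dropping zero differences) is at most
``EXACT_N_MAX``.  The exact path uses a subset-sum convolution over doubled
midranks, so ties are handled exactly as well — the resulting p equals a
brute-force enumeration of all 2^n sign assignments with midranked absolute
values.  Beyond that, a normal approximation with the standard tie
correction of the variance is used (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice, permutations
from math import erfc, factorial, sqrt

import numpy as np
from scipy import stats as sps

#: largest n for which the exact signed-rank null distribution is used
EXACT_N_MAX = 25

_SQRT2 = sqrt(2.0)


@dataclass
class SignedRankResult:
    n: int                 # non-zero differences actually tested
    w_plus: float          # sum of ranks of positive differences
    z: float               # normal-approximation deviate (NaN when n == 0)
    p_value: float
    method: str            # "exact" | "approx" | "degenerate"


def _subset_sum_counts(ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per achievable W+ (integer rank units).

    Convolves the generating polynomial prod_i (1 + x^{r_i}); exact in
    float64 for n <= 25 (counts <= 2^25 << 2^53).
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks:
        counts[r:] = counts[r:] + counts[:-r if r else None]
    return counts


#: cached cumulative exact null (tie-free case: ranks are 1..n) per n
_EXACT_CUM: dict = {}


def _exact_signed_rank_p(ranks_int: np.ndarray, w: int, tie_free_n: int | None = None) -> float:
    """Two-sided exact p for W+ = ``w`` given integer ranks.

    When ``tie_free_n`` is given the ranks are exactly 1..n and the
    cumulative null distribution is cached per n.
    """
    if tie_free_n is not None:
        cum = _EXACT_CUM.get(tie_free_n)
        if cum is None:
            cum = np.cumsum(_subset_sum_counts(np.arange(1, tie_free_n + 1)))
            _EXACT_CUM[tie_free_n] = cum
        denom = 2.0 ** tie_free_n
        p_le = cum[w] / denom
        p_ge = (cum[-1] - (cum[w - 1] if w > 0 else 0.0)) / denom
    else:
        counts = _subset_sum_counts(ranks_int)
        denom = 2.0 ** len(ranks_int)
        p_le = counts[: w + 1].sum() / denom
        p_ge = counts[w:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def signed_rank_test(diffs: np.ndarray) -> SignedRankResult:
    """Two-sided one-sample Wilcoxon signed-rank test against zero.

    Zero differences are dropped (Wilcoxon convention); an all-zero input
    yields p = 1.0 by convention.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return SignedRankResult(0, 0.0, float("nan"), 1.0, "degenerate")

    absd = np.abs(d)
    order = np.argsort(absd)
    has_ties = bool((absd[order][1:] == absd[order][:-1]).any())
    if has_ties:
        ranks = sps.rankdata(absd)
        _, tie_counts = np.unique(absd, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum()) / 48.0
    else:
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        tie_term = 0.0
    w_plus = float(ranks[d > 0].sum())

    # tie-corrected variance for the z statistic (reported in both branches)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mu) / np.sqrt(var) if var > 0 else float("nan")

    if n <= EXACT_N_MAX:
        if has_ties:
            # doubled midranks stay integral under ties
            p = _exact_signed_rank_p(np.rint(2 * ranks).astype(np.int64),
                                     int(round(2 * w_plus)))
        else:
            p = _exact_signed_rank_p(None, int(round(w_plus)), tie_free_n=n)
        return SignedRankResult(n, w_plus, z, p, "exact")
    p = erfc(abs(z) / _SQRT2) if np.isfinite(z) else 1.0
    return SignedRankResult(n, w_plus, z, min(p, 1.0), "approx")


def signed_rank_p(diffs: np.ndarray) -> float:
    return signed_rank_test(diffs).p_value


# ---------------------------------------------------------------------------
# Spearman

@dataclass
class SpearmanResult:
    n: int
    rho: float
    p_value: float
    method: str            # "exact_permutation" | "t_approx" | "degenerate"


#: largest n for which the exact permutation p-value is enumerated (n! cases)
SPEARMAN_EXACT_N_MAX = 10


def _perm_chunks(n: int, chunk: int = 200_000):
    it = permutations(range(n))
    while True:
        block = list(islice(it, chunk))
        if not block:
            return
        yield np.asarray(block, dtype=np.intp)


def spearman_test(x: np.ndarray, y: np.ndarray) -> SpearmanResult:
    """Spearman rank correlation: rank-then-Pearson rho; p exact by full
    permutation enumeration for n <= 10, Student-t approximation above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return SpearmanResult(n, float("nan"), float("nan"), "degenerate")
    rxc = (rx - rx.mean()) / sx
    ryc = (ry - ry.mean()) / sy
    rho = float(np.clip((rxc * ryc).mean(), -1.0, 1.0))

    if n <= SPEARMAN_EXACT_N_MAX:
        hits = 0
        thresh = abs(rho) - 1e-12
        for perms in _perm_chunks(n):
            rhos = (ryc[perms] * rxc).mean(axis=1)
            hits += int((np.abs(rhos) >= thresh).sum())
        return SpearmanResult(n, rho, hits / factorial(n), "exact_permutation")

    if abs(rho) == 1.0:
        return SpearmanResult(n, rho, 0.0, "t_approx")
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(n, rho, min(p, 1.0), "t_approx")


# ---------------------------------------------------------------------------
# two-sample pooled t

def pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    """Student two-sample t with pooled variance; sign = mean(a) - mean(b).
    NaN when either group has < 2 members or the pooled variance is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return float("nan")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple:
    """Pearson r and two-sided p; (nan, nan) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
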