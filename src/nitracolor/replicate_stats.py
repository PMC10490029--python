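"""Agreement statistics for device replicates and device-vs-reference data.

Three association measures are applied pairwise to replicate columns:
Pearson's r (linear association), Kendall's tau-b (monotone association),
and the roughness-of-concomitant-ranks (RCR) permutation test, which is
sensitive to smooth nonlinear, non-monotone relationships that the rank
correlation misses.  Device and spectrophotometer results are compared with
an independent-samples t-test (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "TTestResult",
    "pearson_test",
    "pearson_matrix",
    "kendall_test",
    "rcr_statistic",
    "rcr_test",
    "device_vs_reference_ttest",
    "pairwise_table",
]


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p_value: float
    method: str
    pair: tuple[int, int] | None = None


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    method: str


def _validate_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    return x, y


def pearson_test(x, y, pair: tuple[int, int] | None = None) -> AssociationResult:
    """Pearson correlation with the two-sided p-value from the t transform,
    t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom."""
    x, y = _validate_pair(x, y, 3)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector: Pearson correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    r = min(1.0, max(-1.0, r))
    n = x.size
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return AssociationResult(r, float(p), "pearson", pair)


def pearson_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r and p-values over the replicate columns of a
    rectangular table (samples × replicates).

    Returns (r_matrix, p_matrix), both k×k, symmetric, with unit diagonal
    r and zero diagonal p.
    """
    cols = list(table.columns)
    k = len(cols)
    if len(table) < 3:
        raise ValueError("need >= 3 samples")
    for c in cols:
        if table[c].std(ddof=0) == 0:
            raise ValueError(f"zero-variance replicate column {c!r}")
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = pearson_test(table[cols[i]], table[cols[j]], (i, j))
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.p_value
    return r, p


def kendall_test(x, y, pair: tuple[int, int] | None = None) -> AssociationResult:
    """Kendall's tau-b with tie correction; exact null p-value for small
    untied samples, normal approximation otherwise (scipy's auto rule)."""
    x, y = _validate_pair(x, y, 3)
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("all-tied vector: Kendall tau undefined")
    res = stats.kendalltau(x, y, variant="b")
    return AssociationResult(float(res.statistic), float(res.pvalue), "kendall", pair)


def rcr_statistic(x, y) -> float:
    """Roughness of concomitant ranks: Σᵢ (rᵢ₊₁ − rᵢ)² where rᵢ are the
    ranks of y after sorting the observations by ascending x.

    Smooth functional relationships between x and y — monotone or not —
    make successive concomitant ranks close, so the roughness is small;
    under independence the ranks are a random permutation and the roughness
    is large.  The minimum value is n−1 (attained by any strictly monotone
    relationship).
    """
    x, y = _validate_pair(x, y, 4)
    order = np.argsort(x, kind="stable")  # stable: ties in x keep input order
    ranks = stats.rankdata(y[order], method="ordinal")
    return float(np.sum(np.diff(ranks) ** 2))


def rcr_test(
    x,
    y,
    n_perm: int = 9999,
    seed: int | None = None,
    pair: tuple[int, int] | None = None,
) -> AssociationResult:
    """RCR permutation test of association.

    The observed roughness is compared with its distribution under random
    relabelings of y; the p-value is the left-tail probability
    P(roughness ≤ observed), with the observed arrangement counted once
    (add-one permutation p-value).
    """
    x, y = _validate_pair(x, y, 4)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if np.unique(x).size < x.size:
        import warnings

        warnings.warn("ties in x broken by stable input order", stacklevel=2)
    obs = rcr_statistic(x, y)
    rng = np.random.default_rng(seed)
    n = x.size
    order = np.argsort(x, kind="stable")
    y_sorted = y[order]
    # permuting y is equivalent to permuting the concomitant ranks
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    permuted = y_sorted[perms]
    ranks = stats.rankdata(permuted, method="ordinal", axis=1)
    stats_null = np.sum(np.diff(ranks, axis=1) ** 2, axis=1)
    p = (1.0 + np.sum(stats_null <= obs)) / (n_perm + 1.0)
    return AssociationResult(obs, float(p), "rcr", pair)


def device_vs_reference_ttest(
    device, reference, equal_var: bool = False
) -> TTestResult:
    """Independent-samples t-test between device and reference values.

    Welch's unequal-variance form by default (``equal_var=False``); the
    pooled-variance Student form is available.  Two degenerate samples with
    zero variance and equal means give p = 1 by convention.
    """
    d = np.asarray(device, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    if d.size < 2 or r.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if d.std(ddof=1) == 0 and r.std(ddof=1) == 0:
        if d.mean() == r.mean():
            return TTestResult(0.0, float(d.size + r.size - 2), 1.0, "degenerate")
        return TTestResult(float("inf"), float(d.size + r.size - 2), 0.0, "degenerate")
    res = stats.ttest_ind(d, r, equal_var=equal_var)
    method = "student" if equal_var else "welch"
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), method)


def pairwise_table(
    table: pd.DataFrame,
    methods: tuple[str, ...] = ("pearson", "kendall", "rcr"),
    n_perm: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy table of pairwise association results over replicate columns.

    Columns: method, i, j, statistic, p_value (i, j are 0-based column
    indices, i < j).
    """
    cols = list(table.columns)
    rows = []
    for m in methods:
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                x = table[cols[i]].to_numpy()
                y = table[cols[j]].to_numpy()
                if m == "pearson":
                    res = pearson_test(x, y, (i, j))
                elif m == "kendall":
                    res = kendall_test(x, y, (i, j))
                elif m == "rcr":
                    res = rcr_test(x, y, n_perm=n_perm, seed=seed, pair=(i, j))
                else:
                    raise ValueError(f"unknown method {m!r}")
                rows.append(
                    {
                        "method": m,
                        "i": i,
                        "j": j,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                    }
                )
    return pd.DataFrame(rows)
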