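"""Univariate group statistics, chi-square feature ranking, and exact
Shapley-value explanations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "TTestResult",
    "two_sample_ttest",
    "univariate_table",
    "RankedFeatures",
    "chi2_importance",
    "chi2_rank_features",
    "shapley_values",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    significant: bool  # after Bonferroni correction


def two_sample_ttest(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> TTestResult:
    """Pooled-variance (Student) two-sample t-test, two-sided.

    ``t > 0`` when ``mean(x) > mean(y)``. The significance flag applies a
    Bonferroni correction: ``p < alpha / n_comparisons``. Two identical
    constant samples give ``t = 0, p = 1`` rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    import warnings

    with warnings.catch_warnings():
        # identical/constant samples trip scipy's precision warning; the
        # degenerate case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sst.ttest_ind(x, y, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):  # zero pooled variance
        t, p = 0.0, 1.0
    return TTestResult(
        t=t, p=p,
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)), sd_y=float(y.std(ddof=1)),
        significant=p < alpha / n_comparisons,
    )


def univariate_table(
    table: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("HC", "SZ"),
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Per-feature group comparison (mean +- SD, t, p, Bonferroni flag).

    ``t > 0`` means the first group's mean is higher. The Bonferroni family
    size defaults to the number of features tested but is configurable.
    """
    cols = [
        c for c in table.columns
        if c not in (group_col, "subject_id", "epoch")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    m = n_comparisons if n_comparisons is not None else len(cols)
    a = table.loc[table[group_col] == groups[0]]
    b = table.loc[table[group_col] == groups[1]]
    rows = []
    for c in cols:
        r = two_sample_ttest(a[c].to_numpy(), b[c].to_numpy(), alpha, m)
        rows.append({
            "feature": c,
            f"mean_{groups[0]}": r.mean_x, f"sd_{groups[0]}": r.sd_x,
            f"mean_{groups[1]}": r.mean_y, f"sd_{groups[1]}": r.sd_y,
            "t": r.t, "p": r.p, "significant": r.significant,
        })
    return pd.DataFrame(rows)


@dataclass
class RankedFeatures:
    """Features ordered by descending chi-square importance."""

    names: list[str]
    scores: np.ndarray  # -log10(p), aligned with names

    def top(self, k: int) -> list[str]:
        return self.names[:k]


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into (at most) ``n_bins`` equal-frequency bins.

    Duplicate quantile edges (heavy ties) are merged, so a constant
    feature collapses to a single bin.
    """
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def chi2_importance(x: np.ndarray, classes: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Chi-square importance of one feature: ``(-log10 p, statistic)``.

    The feature is binned into equal-frequency bins and a Pearson
    chi-square test (no continuity correction) is run on the bin-by-class
    contingency table. A single-bin (constant) feature scores 0.
    """
    binned = _equal_frequency_bins(np.asarray(x, dtype=float), n_bins)
    bins = np.unique(binned)
    if bins.size < 2:
        return 0.0, 0.0
    cls = np.unique(classes)
    cont = np.array([
        [np.count_nonzero((binned == b) & (classes == c)) for c in cls]
        for b in bins
    ])
    stat, p, _, _ = sst.chi2_contingency(cont, correction=False)
    p = max(float(p), 1e-300)  # keep -log10 finite for extreme separations
    return float(-np.log10(p)), float(stat)


def chi2_rank_features(
    table: pd.DataFrame,
    class_col: str = "group",
    n_bins: int = 10,
) -> RankedFeatures:
    """Rank all feature columns by chi-square importance, descending.

    Importance is ``-log10(p)``; ties are broken by the chi-square
    statistic and then by column name, so the ordering is deterministic.
    """
    classes = table[class_col].to_numpy()
    if np.unique(classes).size < 2:
        raise ValueError("need at least 2 classes to rank features")
    cols = [
        c for c in table.columns
        if c not in (class_col, "subject_id", "epoch")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    scored = []
    for c in cols:
        imp, stat = chi2_importance(table[c].to_numpy(), classes, n_bins)
        scored.append((imp, stat, c))
    scored.sort(key=lambda s: (-s[0], -s[1], s[2]))
    return RankedFeatures(
        names=[c for _, _, c in scored],
        scores=np.array([imp for imp, _, _ in scored]),
    )


def shapley_values(
    score_fn,
    query: np.ndarray,
    background: np.ndarray,
    max_exact: int = 12,
    n_samples: int = 2048,
    seed: int = 0,
) -> np.ndarray:
    """Exact interventional Shapley values of a model score at a query.

    The value of a coalition ``S`` is the model score averaged over the
    background rows with the query's values substituted on ``S``. For up
    to ``max_exact`` features all ``2^d`` coalitions are enumerated, which
    makes the attribution exact: the contributions sum to
    ``score(query) - mean score(background)``. Beyond that, a seeded
    permutation-sampling estimator is used.

    Parameters
    ----------
    score_fn
        Callable mapping ``(n, d)`` arrays to ``n`` scalar scores.
    query
        The ``(d,)`` point to explain.
    background
        ``(n_background, d)`` reference data defining the average
        prediction.
    """
    query = np.asarray(query, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D array")
    d = query.size
    if background.shape[1] != d:
        raise ValueError("query/background dimension mismatch")

    if d <= max_exact:
        v = np.empty(2**d)
        for mask in range(2**d):
            x = background.copy()
            for i in range(d):
                if mask >> i & 1:
                    x[:, i] = query[i]
            v[mask] = float(np.mean(score_fn(x)))
        from math import factorial

        fact = [factorial(i) for i in range(d + 1)]
        phi = np.zeros(d)
        for mask in range(2**d):
            s = bin(mask).count("1")
            w = fact[s] * fact[d - s - 1] / fact[d]
            for i in range(d):
                if not mask >> i & 1:
                    phi[i] += w * (v[mask | (1 << i)] - v[mask])
        return phi

    rng = np.random.default_rng(seed)
    phi = np.zeros(d)
    x = background.copy()
    base = float(np.mean(score_fn(background)))
    for _ in range(n_samples):
        perm = rng.permutation(d)
        x[:] = background
        prev = base
        for i in perm:
            x[:, i] = query[i]
            cur = float(np.mean(score_fn(x)))
            phi[i] += cur - prev
            prev = cur
    return phi / n_samples
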