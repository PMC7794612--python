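"""Statistical battery for index tables.

Welch's t, one-way ANOVA, Cohen's d, Tukey-Kramer pairwise comparisons and a
correlation-matrix PCA with a fixed sign convention.  The tests wrap scipy;
PCA and Cohen's d are computed in-package (the PCA sign/scale conventions
are part of the classifier contract downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PCModel",
    "welch_t",
    "one_way_anova",
    "cohens_d",
    "pca_fit",
    "pca_scores",
    "tukey_kramer",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    pvalue: float
    effect_size: float | None = None
    degenerate: bool = False


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    for g in out:
        if not np.all(np.isfinite(g)):
            raise ValueError("groups must contain finite values only")
    return out


def welch_t(a, b) -> TestResult:
    """Two-sided Welch's t-test with Welch-Satterthwaite degrees of freedom."""
    a, b = _as_groups([a, b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(statistic=float(res.statistic), df=float(res.df),
                      pvalue=float(res.pvalue))


def one_way_anova(*groups) -> TestResult:
    """One-way fixed-effects ANOVA; F with (k-1, N-k) degrees of freedom.

    Perfect separation (zero within-group variance with distinct means) is
    returned as an infinite F flagged degenerate rather than raising.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
    k = len(gs)
    n_total = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df = (float(k - 1), float(n_total - k))
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(statistic=0.0, df=df, pvalue=1.0)
        return TestResult(statistic=np.inf, df=df, pvalue=0.0, degenerate=True)
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(f, df[0], df[1]))
    return TestResult(statistic=float(f), df=df, pvalue=p)


def cohens_d(a, b) -> float:
    """Cohen's d: mean difference over the pooled standard deviation."""
    a, b = _as_groups([a, b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / pooled)


def tukey_kramer(groups, labels=None) -> pd.DataFrame:
    """All-pairs Tukey-Kramer comparisons (studentised range, unequal n).

    Returns a tidy frame with one row per unordered pair.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
    labels = list(labels) if labels is not None else list(range(len(gs)))
    res = sps.tukey_hsd(*gs)
    rows = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(res.statistic[i, j]),
                    "pvalue": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA on the correlation matrix of the pooled standardised indices
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class PCModel:
    """Correlation-matrix PCA of an index table.

    ``loadings`` columns are orthonormal eigenvectors ordered by decreasing
    explained variance; each column is flipped so its largest-magnitude
    loading is positive (reproducible sign convention).
    """

    columns: list[str]
    mean: np.ndarray          # (p,) per-index scaling means
    sd: np.ndarray            # (p,) per-index scaling SDs
    loadings: np.ndarray      # (p, p)
    explained_variance: np.ndarray  # (p,) fractions, non-increasing, sum 1


def pca_fit(table: pd.DataFrame, columns: list[str] | None = None) -> PCModel:
    """Fit PCA on the correlation matrix of the given index columns."""
    from .indices import INDEX_COLUMNS

    columns = columns if columns is not None else INDEX_COLUMNS
    x = table[columns].to_numpy(dtype=float)
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more rows than index columns to fit a PC model")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    for name, s in zip(columns, sd):
        if s == 0.0:
            raise ValueError(f"index {name!r} is constant; cannot scale for PCA")
    z = (x - mean) / sd
    corr = (z.T @ z) / (z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    return PCModel(
        columns=list(columns), mean=mean, sd=sd, loadings=evecs,
        explained_variance=evals / evals.sum(),
    )


def pca_scores(model: PCModel, table: pd.DataFrame) -> pd.DataFrame:
    """Project an index table into the PC space of a fitted model."""
    x = table[model.columns].to_numpy(dtype=float)
    z = (x - model.mean) / model.sd
    scores = z @ model.loadings
    return pd.DataFrame(
        scores, index=table.index,
        columns=[f"pc{j + 1}" for j in range(scores.shape[1])],
    )
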