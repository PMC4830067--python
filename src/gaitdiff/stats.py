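"""Univariate group comparison and PCA of the feature matrix.

The univariate pathway tests each of the 112 discrete variables between two
groups with a one-way ANOVA, quantifies the standardized mean difference
with Cohen's d using average-variance pooling,

    d = |m1 - m2| / sqrt((s1^2 + s2^2) / 2),

controls the family-wise error rate over all variables with the
Holm-Bonferroni step-down adjustment, and flags a variable as significant
and meaningful when the adjusted p < 0.05 AND d > 0.8.

The multivariate pathway first standardizes columns to zero mean and unit
sample SD (n-1 denominator) and computes principal components by singular
value decomposition of the standardized matrix: coefficients V (112 x 112
orthonormal), eigenvalues L of the correlation matrix (squared singular
values / (n-1), non-increasing, at most n-1 nonzero), and scores
Z = X_std V restricted to the retained components. Component signs are
pinned by making each component's largest-magnitude loading positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateColumnError,
    InfiniteEffectError,
    InsufficientRowsError,
    InvalidGroupingError,
    InvalidPValueError,
)

SIGNIFICANCE_P = 0.05
MEANINGFUL_D = 0.8


# ---------------------------------------------------------------------------
# standardization and PCA
# ---------------------------------------------------------------------------

def standardize(X: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise standardization to mean 0, sample SD 1.

    Returns (standardized matrix, column means, column SDs). A column with
    zero variance cannot be standardized and raises
    :class:`DegenerateColumnError` naming it.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    A = np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    means = A.mean(axis=0)
    sds = A.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sds > 0))
    if bad.size:
        name = cols[bad[0]] if cols else f"column {bad[0]}"
        raise DegenerateColumnError(f"zero-variance column: {name}")
    return (A - means) / sds, means, sds


@dataclass
class PCAModel:
    """PCA of a standardized feature matrix (see module docstring)."""

    column_means: np.ndarray
    column_sds: np.ndarray
    coefficients: np.ndarray  # V, p x p, orthonormal columns
    eigenvalues: np.ndarray  # L, length min(n-1, p), non-increasing
    scores: np.ndarray  # Z, n x len(L)

    @property
    def variance_explained(self) -> np.ndarray:
        """Cumulative proportion of total variance per retained component."""
        total = self.column_sds.size  # unit-variance columns
        return np.cumsum(self.eigenvalues) / total


def pca_svd(Xn: np.ndarray) -> PCAModel:
    """Principal components of an already-standardized matrix via SVD.

    Components beyond the rank bound min(n-1, p) are dropped from the
    eigenvalues and scores (the coefficient matrix V stays p x p). Signs
    are pinned per component: the largest-magnitude loading is positive.
    """
    A = np.asarray(Xn, dtype=float)
    n, p = A.shape
    if n < 2:
        raise InsufficientRowsError(f"PCA needs >=2 rows, got {n}")
    U, S, Vt = np.linalg.svd(A, full_matrices=True)
    V = Vt.T  # p x p
    k = min(n - 1, p)
    # deterministic sign convention
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    V = V * flip
    eig = np.zeros(k)
    m = min(S.size, k)
    eig[:m] = (S[:m] ** 2) / (n - 1)
    Z = A @ V[:, :k]
    means = np.zeros(p)
    sds = np.ones(p)
    return PCAModel(means, sds, V, eig, Z)


def fit_pca(X: np.ndarray | pd.DataFrame) -> PCAModel:
    """Standardize then decompose; stores the standardization used."""
    Xn, means, sds = standardize(X)
    model = pca_svd(Xn)
    model.column_means = means
    model.column_sds = sds
    return model


# ---------------------------------------------------------------------------
# effect sizes and tests
# ---------------------------------------------------------------------------

def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d with average-variance pooling, |m1-m2|/sqrt((s1^2+s2^2)/2).

    This pooling (not the (n-1)-weighted pooled SD) is what reproduces the
    published group-comparison effect sizes from printed means and SDs.
    """
    if sd1 < 0 or sd2 < 0:
        raise InvalidGroupingError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise InvalidGroupingError("each group needs n >= 2")
    denom = np.sqrt((sd1**2 + sd2**2) / 2.0)
    diff = abs(mean1 - mean2)
    if denom == 0:
        if diff == 0:
            return 0.0
        raise InfiniteEffectError("both SDs zero with unequal means")
    return float(diff / denom)


def anova_oneway(values: np.ndarray, group_labels: np.ndarray) -> tuple[float, float]:
    """Classical one-way ANOVA (between/within decomposition).

    With two groups, F equals the square of the pooled two-sample t
    statistic and p matches the two-sided t test.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    groups = [v[g == lab] for lab in pd.unique(g)]
    if len(groups) < 2:
        raise InvalidGroupingError("need >=2 groups")
    if any(x.size < 2 for x in groups):
        raise InvalidGroupingError("every group needs >=2 members")
    if all(np.ptp(x) == 0 for x in groups) and len({x[0] for x in groups}) == 1:
        return 0.0, 1.0
    F, p = sps.f_oneway(*groups)
    return float(F), float(p)


def holm_bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order.

    Sort ascending; adjusted p_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)).
    The adjustment is monotone in the sorted order and never below the raw
    p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InvalidPValueError("p-values must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidPValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def effect_size_table(
    X: pd.DataFrame,
    labels: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Per-variable two-group comparison table.

    For every column of ``X``: group means, SDs and sizes, Cohen's d,
    ANOVA F and raw p, Holm-adjusted p over all columns (the family is all
    variables of this comparison), and the significance flag
    (adjusted p < 0.05 and d > 0.8).
    """
    g = np.asarray(labels)
    level_names = list(pd.unique(g))
    if len(level_names) != 2:
        raise InvalidGroupingError("effect-size table requires exactly 2 groups")
    a, b = level_names
    ia, ib = g == a, g == b
    if ia.sum() < 2 or ib.sum() < 2:
        raise InvalidGroupingError("every group needs >=2 members")
    rows = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        m1, s1 = v[ia].mean(), v[ia].std(ddof=1)
        m2, s2 = v[ib].mean(), v[ib].std(ddof=1)
        d = cohens_d(m1, s1, int(ia.sum()), m2, s2, int(ib.sum()))
        F, p = anova_oneway(v, g)
        rows.append(
            {
                "variable": col,
                f"mean_{a}": m1,
                f"sd_{a}": s1,
                f"n_{a}": int(ia.sum()),
                f"mean_{b}": m2,
                f"sd_{b}": s2,
                f"n_{b}": int(ib.sum()),
                "d": d,
                "F": F,
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("variable")
    table["p_adjusted"] = holm_bonferroni(table["p"].to_numpy())
    return flag_significant(table)


def flag_significant(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the significance flag: adjusted p < 0.05 AND d > 0.8."""
    table = table.copy()
    table["significant"] = (table["p_adjusted"] < SIGNIFICANCE_P) & (
        table["d"] > MEANINGFUL_D
    )
    return table
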