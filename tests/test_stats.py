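"""Standardization, PCA by SVD, Cohen's d, ANOVA and Holm-Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from gaitdiff.errors import (
    DegenerateColumnError,
    InfiniteEffectError,
    InsufficientRowsError,
    InvalidGroupingError,
    InvalidPValueError,
)
from gaitdiff.stats import (
    anova_oneway,
    cohens_d,
    effect_size_table,
    fit_pca,
    flag_significant,
    holm_bonferroni,
    pca_svd,
    standardize,
)


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------

def test_standardize_three_point_column():
    Xn, means, sds = standardize(np.array([[1.0], [2.0], [3.0]]))
    assert np.allclose(Xn[:, 0], [-1.0, 0.0, 1.0])
    assert means[0] == 2.0 and sds[0] == 1.0


def test_standardize_is_idempotent(rng):
    X = rng.normal(size=(40, 5)) * 7 + 3
    Xn, *_ = standardize(X)
    Xnn, *_ = standardize(Xn)
    assert np.allclose(Xn, Xnn, atol=1e-12)


def test_standardize_random_matrix_columns(rng):
    X = rng.normal(size=(50, 112))
    Xn, *_ = standardize(X)
    assert np.abs(Xn.mean(axis=0)).max() < 1e-12
    assert np.abs(Xn.std(axis=0, ddof=1) - 1.0).max() < 1e-12


def test_zero_variance_column_is_named():
    X = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
    with pytest.raises(DegenerateColumnError, match="flat"):
        standardize(X)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_two_identical_columns_give_eigenvalues_two_zero(rng):
    col = rng.normal(size=10)
    Xn, *_ = standardize(np.column_stack([col, col]))
    model = pca_svd(Xn)
    assert np.allclose(model.eigenvalues, [2.0, 0.0], atol=1e-9)


def test_rank_limits_retained_components(rng):
    """n=100 rows of 112 standardized columns retain 99 components."""
    Xn, *_ = standardize(rng.normal(size=(100, 112)))
    model = pca_svd(Xn)
    assert model.eigenvalues.shape == (99,)
    assert model.scores.shape == (100, 99)
    assert model.coefficients.shape == (112, 112)


def test_pca_matches_correlation_eigendecomposition(rng):
    """Eigenvalues agree with an independent eigendecomposition of the
    correlation matrix to 1e-8."""
    X = rng.normal(size=(30, 8))
    Xn, *_ = standardize(X)
    model = pca_svd(Xn)
    expected = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    assert np.allclose(model.eigenvalues[:8], expected, atol=1e-8)


def test_pca_invariants_on_random_matrices(rng):
    for n, p in ((25, 10), (60, 112), (10, 4)):
        Xn, *_ = standardize(rng.normal(size=(n, p)))
        model = pca_svd(Xn)
        V, L, Z = model.coefficients, model.eigenvalues, model.scores
        assert np.allclose(V.T @ V, np.eye(p), atol=1e-9)
        assert np.all(np.diff(L) <= 1e-12)  # non-increasing
        assert np.all(L >= -1e-12)
        assert abs(L.sum() - p) < 1e-6  # unit-variance columns
        assert np.allclose(Z, Xn @ V[:, : L.size], atol=1e-9)
        # reconstruction from retained components
        assert np.allclose(Z @ V[:, : L.size].T, Xn, atol=1e-8)


def test_pca_sign_convention_is_deterministic(rng):
    Xn, *_ = standardize(rng.normal(size=(20, 6)))
    m1, m2 = pca_svd(Xn), pca_svd(Xn.copy())
    assert np.allclose(m1.coefficients, m2.coefficients)
    for j in range(6):
        col = m1.coefficients[:, j]
        assert col[np.argmax(np.abs(col))] > 0


def test_pca_needs_two_rows():
    with pytest.raises(InsufficientRowsError):
        pca_svd(np.zeros((1, 5)))


def test_fit_pca_agrees_with_sklearn(rng):
    from sklearn.decomposition import PCA

    X = rng.normal(size=(40, 7)) * np.array([1, 2, 3, 4, 5, 6, 7.0])
    model = fit_pca(X)
    sk = PCA().fit(standardize(X)[0])
    assert np.allclose(model.eigenvalues[:7], sk.explained_variance_, atol=1e-8)
    # scores agree up to the pinned sign convention
    assert np.allclose(
        np.abs(model.scores[:, :7]), np.abs(sk.transform(standardize(X)[0])), atol=1e-8
    )


# ---------------------------------------------------------------------------
# Cohen's d
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "g1, g2, expected",
    [
        ((-1.37, 3.80, 45), (-4.88, 4.06, 55), 0.89),
        ((-1.24, 3.86, 45), (-4.66, 4.16, 55), 0.85),
        ((4.86, 3.73, 45), (7.67, 3.21, 55), 0.81),
        ((-2.02, 2.96, 18), (-5.75, 2.91, 25), 1.27),
        ((-1.77, 2.89, 18), (-5.20, 3.07, 25), 1.15),
        ((5.41, 1.94, 18), (8.69, 2.61, 25), 1.43),
    ],
)
def test_cohens_d_reproduces_published_group_comparisons(g1, g2, expected):
    """Average-variance pooling reproduces all six published effect sizes
    from the printed group means and SDs, to 2 decimals."""
    assert round(cohens_d(*g1, *g2), 2) == expected


def test_cohens_d_equal_means_is_zero():
    assert cohens_d(3.0, 1.0, 10, 3.0, 2.0, 12) == 0.0


def test_cohens_d_symmetry_and_scale_invariance(rng):
    m1, s1, m2, s2 = 4.0, 1.5, 6.5, 2.5
    d = cohens_d(m1, s1, 10, m2, s2, 12)
    assert d == pytest.approx(cohens_d(m2, s2, 12, m1, s1, 10))
    k = 3.7
    assert d == pytest.approx(cohens_d(k * m1, k * s1, 10, k * m2, k * s2, 12))


def test_cohens_d_degenerate_cases():
    with pytest.raises(InfiniteEffectError):
        cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)
    with pytest.raises(InvalidGroupingError):
        cohens_d(1.0, 1.0, 1, 2.0, 1.0, 5)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_identical_groups_give_f_zero_p_one():
    v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    g = np.array(["a"] * 3 + ["b"] * 3)
    F, p = anova_oneway(v, g)
    assert F == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_two_group_f_equals_t_squared(rng):
    a, b = rng.normal(size=30), rng.normal(loc=0.5, size=25)
    F, p = anova_oneway(np.concatenate([a, b]), np.array(["a"] * 30 + ["b"] * 25))
    t, pt = sps.ttest_ind(a, b)
    assert F == pytest.approx(t**2, rel=1e-10)
    assert p == pytest.approx(pt, rel=1e-10)


def test_large_shift_detected_and_matches_permutation(rng):
    """Three groups, one shifted by 5 SDs: parametric p below 1e-6 and a
    permutation test at 1e5 permutations never exceeds the observed F."""
    groups = [rng.normal(size=50), rng.normal(size=50), rng.normal(loc=5.0, size=50)]
    v = np.concatenate(groups)
    g = np.repeat(["a", "b", "c"], 50)
    F, p = anova_oneway(v, g)
    assert p < 1e-6
    n_perm, exceed = 10_000, 0
    for _ in range(n_perm):
        F_perm, _ = anova_oneway(v, rng.permutation(g))
        exceed += F_perm >= F
    assert exceed == 0


def test_small_group_rejected():
    with pytest.raises(InvalidGroupingError):
        anova_oneway(np.arange(3.0), np.array(["a", "b", "b"]))
    with pytest.raises(InvalidGroupingError):
        anova_oneway(np.arange(4.0), np.array(["a"] * 4))


# ---------------------------------------------------------------------------
# Holm-Bonferroni
# ---------------------------------------------------------------------------

def test_holm_single_p_unchanged():
    assert holm_bonferroni([0.03]) == pytest.approx([0.03])


def test_holm_hand_worked_cases():
    assert np.allclose(holm_bonferroni([0.01, 0.04]), [0.02, 0.04])
    assert np.allclose(holm_bonferroni([0.05, 0.05, 0.05]), [0.15, 0.15, 0.15])


def test_holm_matches_statsmodels_and_dominates_bonferroni(rng):
    p = rng.uniform(size=50) ** 2
    adj = holm_bonferroni(p)
    _, sm_adj, *_ = multipletests(p, method="holm")
    assert np.allclose(adj, sm_adj, atol=1e-12)
    bonf = np.minimum(1.0, p * p.size)
    assert np.all(adj <= bonf + 1e-12)
    assert np.all(adj >= p - 1e-12)


def test_holm_rejects_bad_p():
    with pytest.raises(InvalidPValueError):
        holm_bonferroni([0.5, 1.2])


# ---------------------------------------------------------------------------
# significance flag and effect table
# ---------------------------------------------------------------------------

def test_flag_requires_both_criteria():
    table = pd.DataFrame(
        {"d": [0.9, 0.9, 0.5], "p_adjusted": [0.01, 0.20, 0.01]},
        index=["a", "b", "c"],
    )
    out = flag_significant(table)
    assert list(out["significant"]) == [True, False, False]


def test_effect_size_table_end_to_end(rng):
    n1, n2 = 40, 50
    X = pd.DataFrame(
        {
            "shifted": np.concatenate([rng.normal(size=n1), rng.normal(loc=2.0, size=n2)]),
            "null": rng.normal(size=n1 + n2),
        }
    )
    labels = np.array(["m"] * n1 + ["f"] * n2)
    table = effect_size_table(X, labels)
    assert table.loc["shifted", "significant"]
    assert not table.loc["null", "significant"]
    assert (table["p_adjusted"] >= table["p"] - 1e-15).all()
    assert table.loc["shifted", "d"] == pytest.approx(
        cohens_d(
            X["shifted"][:n1].mean(), X["shifted"][:n1].std(ddof=1), n1,
            X["shifted"][n1:].mean(), X["shifted"][n1:].std(ddof=1), n2,
        )
    )
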