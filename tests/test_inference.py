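import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meadowsucc.inference import (
    anova_tukey,
    compact_letter_display,
    correlation_matrix,
    lmg_importance,
    mantel_test,
    simple_regression,
    zscore_euclidean_distance,
)
from meadowsucc.io import ValidationError


# ---------------------------------------------------------------------------
# ANOVA + Tukey

def test_identical_groups_share_one_letter(rng):
    y = np.tile(rng.normal(size=10), 4)
    g = np.repeat([1, 2, 3, 4], 10)
    res = anova_tukey(y, g)
    assert (res.tukey["p_adj"] > 0.9).all()
    assert len(set(res.letters.values())) == 1


def test_overwhelming_separation_gives_four_letters(rng):
    y = np.concatenate([rng.normal(m, 0.01, size=30) for m in (0, 10, 20, 30)])
    g = np.repeat([1, 2, 3, 4], 30)
    res = anova_tukey(y, g)
    assert (res.tukey["p_adj"] < 1e-6).all()
    assert sorted(res.letters.values()) == ["a", "b", "c", "d"]
    assert res.p_value < 1e-10


def test_tukey_two_groups_equals_pooled_t_test(rng):
    """At k=2 the studentized range reduces to the two-sample t."""
    for _ in range(10):
        a = rng.normal(0, 1, size=12)
        b = rng.normal(0.8, 1, size=15)
        res = anova_tukey(np.concatenate([a, b]), np.repeat([1, 2], [12, 15]))
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert res.tukey["p_adj"].iloc[0] == pytest.approx(t_p, rel=1e-6, abs=1e-9)


def test_tukey_invariant_to_group_relabeling(rng):
    y = rng.normal(size=60)
    g = np.repeat([1, 2, 3], 20)
    r1 = anova_tukey(y, g)
    relabel = {1: 3, 2: 1, 3: 2}
    r2 = anova_tukey(y, np.vectorize(relabel.get)(g))
    p1 = {frozenset((relabel[a], relabel[b])): p for (a, b), p in zip(
        zip(r1.tukey.group1, r1.tukey.group2), r1.tukey.p_adj)}
    p2 = {frozenset((a, b)): p for (a, b), p in zip(
        zip(r2.tukey.group1, r2.tukey.group2), r2.tukey.p_adj)}
    for k in p1:
        assert p1[k] == pytest.approx(p2[k], rel=1e-9)


def test_small_group_errors():
    with pytest.raises(ValidationError):
        anova_tukey([1.0, 2.0, 3.0], [1, 1, 2])


def test_cld_consistent_with_pairwise_matrix(rng):
    """Groups share a letter iff they are not significantly different."""
    for trial in range(20):
        groups = [1, 2, 3, 4]
        pairs = list(itertools.combinations(groups, 2))
        p = {pair: float(rng.uniform()) for pair in pairs}
        letters = compact_letter_display(groups, p, alpha=0.05)
        for (a, b), pv in p.items():
            shared = set(letters[a]) & set(letters[b])
            if pv < 0.05:
                assert not shared, (trial, a, b, letters)
            else:
                assert shared, (trial, a, b, letters)


# ---------------------------------------------------------------------------
# simple regression

def test_regression_hand_cases():
    r = simple_regression([0, 1, 2], [1, 3, 5])
    assert r.slope == pytest.approx(2) and r.intercept == pytest.approx(1)
    assert r.r_squared == pytest.approx(1)

    r = simple_regression([0, 1, 2], [0, 1, 1])
    assert r.slope == pytest.approx(0.5)
    assert r.r_squared == pytest.approx(0.75)

    r = simple_regression([0, 1, 2, 3], [2, 2, 2, 2])
    assert r.slope == pytest.approx(0) and r.r_squared == pytest.approx(0)


def test_regression_errors():
    with pytest.raises(ValidationError):
        simple_regression([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValidationError):
        simple_regression([1, 2], [1, 2])


# ---------------------------------------------------------------------------
# Mantel test

def _random_distance(rng, n, d=3):
    return zscore_euclidean_distance(rng.normal(size=(n, d)))


def test_mantel_identity_gives_r_one_and_min_p(rng):
    d = _random_distance(rng, 8)
    res = mantel_test(d, d, n_permutations=99, seed=0)
    assert res.r == pytest.approx(1.0)
    # identity permutation always ties the observed statistic
    assert res.p_value >= 1 / 100


def test_mantel_matches_exhaustive_enumeration_at_n4(rng):
    for trial in range(5):
        dA = _random_distance(rng, 4)
        dB = _random_distance(rng, 4)
        iu = np.triu_indices(4, 1)
        a = dA[iu]
        r_obs = stats.pearsonr(a, dB[iu]).statistic
        count = sum(
            stats.pearsonr(a, dB[np.ix_(p, p)][iu]).statistic >= r_obs
            for p in map(list, itertools.permutations(range(4))))
        exact = count / 24
        res = mantel_test(dA, dB, n_permutations=30000, seed=trial)
        assert res.p_value == pytest.approx(exact, abs=0.02)


def test_mantel_agrees_with_scikit_bio(rng):
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    dA = _random_distance(rng, 10)
    dB = 0.5 * dA + 0.5 * _random_distance(rng, 10)
    res = mantel_test(dA, dB, n_permutations=999, seed=1)
    r_sk, p_sk, _ = skbio_distance.mantel(
        skbio_distance.DistanceMatrix(dA), skbio_distance.DistanceMatrix(dB),
        method="pearson", permutations=999, alternative="greater")
    assert res.r == pytest.approx(float(r_sk), abs=1e-10)
    assert res.p_value == pytest.approx(float(p_sk), abs=0.05)


def test_mantel_invariant_to_simultaneous_relabeling(rng):
    dA = _random_distance(rng, 7)
    dB = _random_distance(rng, 7)
    perm = rng.permutation(7)
    r1 = mantel_test(dA, dB, n_permutations=10, seed=0).r
    r2 = mantel_test(dA[np.ix_(perm, perm)], dB[np.ix_(perm, perm)],
                     n_permutations=10, seed=0).r
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_mantel_reproducible_under_seed(rng):
    dA, dB = _random_distance(rng, 9), _random_distance(rng, 9)
    p1 = mantel_test(dA, dB, n_permutations=200, seed=5).p_value
    p2 = mantel_test(dA, dB, n_permutations=200, seed=5).p_value
    assert p1 == p2


def test_mantel_input_validation(rng):
    ok = _random_distance(rng, 5)
    bad = ok.copy()
    bad[0, 1] += 1.0
    with pytest.raises(ValidationError):
        mantel_test(bad, ok, 10)
    with pytest.raises(ValidationError):
        mantel_test(ok[:3, :3], ok[:3, :3], 10)
    with pytest.raises(ValidationError):
        mantel_test(ok, _random_distance(rng, 6), 10)


# ---------------------------------------------------------------------------
# correlation matrix

def test_correlation_matrix_hand_values(rng):
    x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
    y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
    z = -x
    r, p, flagged = correlation_matrix(pd.DataFrame({"x": x, "y": y, "z": z}))
    assert not flagged
    np.testing.assert_allclose(np.diag(r), 1.0)
    assert r.loc["x", "z"] == pytest.approx(-1.0)
    expected = stats.pearsonr(x, y)
    assert r.loc["x", "y"] == pytest.approx(expected.statistic)
    assert p.loc["x", "y"] == pytest.approx(expected.pvalue)
    assert r.loc["x", "y"] == r.loc["y", "x"]


def test_correlation_matrix_flags_constant_column():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    r, p, flagged = correlation_matrix(df)
    assert flagged == ["b"]
    assert math.isnan(r.loc["a", "b"]) and math.isnan(p.loc["a", "b"])
    assert r.loc["a", "a"] == 1.0


# ---------------------------------------------------------------------------
# LMG importance

def _brute_force_lmg(X, y):
    cols = list(X.columns)
    p = len(cols)
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    yc = np.asarray(y, dtype=float)
    yc = yc - yc.mean()

    def r2(idx):
        if not idx:
            return 0.0
        beta, *_ = np.linalg.lstsq(Xc[:, list(idx)], yc, rcond=None)
        resid = yc - Xc[:, list(idx)] @ beta
        return 1 - (resid @ resid) / (yc @ yc)

    shares = dict.fromkeys(cols, 0.0)
    orders = list(itertools.permutations(range(p)))
    for order in orders:
        seen = []
        for j in order:
            before = r2(seen)
            seen.append(j)
            shares[cols[j]] += (r2(seen) - before) / len(orders)
    return shares


def test_lmg_single_predictor_share_is_r2(rng):
    x = rng.normal(size=30)
    y = 2 * x + rng.normal(size=30)
    res = lmg_importance(pd.DataFrame({"x": x}), y)
    expected = simple_regression(x, y).r_squared
    assert res.shares["x"] == pytest.approx(expected, abs=1e-12)
    assert res.r_squared == pytest.approx(expected, abs=1e-12)


def test_lmg_orthogonal_predictors_get_marginal_r2(rng):
    Q, _ = np.linalg.qr(rng.normal(size=(40, 2)))
    x1, x2 = Q[:, 0], Q[:, 1]
    x1, x2 = x1 - x1.mean(), x2 - x2.mean()
    # re-orthogonalise after centering
    x2 = x2 - (x2 @ x1) / (x1 @ x1) * x1
    y = 1.5 * x1 - 1.0 * x2 + rng.normal(0, 0.3, size=40)
    res = lmg_importance(pd.DataFrame({"x1": x1, "x2": x2}), y)
    m1 = simple_regression(x1, y).r_squared
    m2 = simple_regression(x2, y).r_squared
    assert res.shares["x1"] == pytest.approx(m1, abs=1e-10)
    assert res.shares["x2"] == pytest.approx(m2, abs=1e-10)


def test_lmg_matches_factorial_brute_force(rng):
    for p in (2, 3, 4, 5):
        X = pd.DataFrame(rng.normal(size=(25, p)),
                         columns=[f"x{i}" for i in range(p)])
        beta = rng.normal(size=p)
        y = X.to_numpy() @ beta + rng.normal(size=25)
        res = lmg_importance(X, y)
        brute = _brute_force_lmg(X, y)
        for c in X.columns:
            assert res.shares[c] == pytest.approx(brute[c], abs=1e-9)
        assert sum(res.shares.values()) == pytest.approx(res.r_squared, abs=1e-9)


def test_lmg_shares_sum_to_r2_and_bounds(rng):
    X = pd.DataFrame(rng.normal(size=(60, 6)),
                     columns=[f"x{i}" for i in range(6)])
    y = X["x0"] + 0.5 * X["x1"] + rng.normal(size=60)
    res = lmg_importance(X, y)
    assert sum(res.shares.values()) == pytest.approx(res.r_squared, abs=1e-10)
    for v in res.shares.values():
        assert -1e-10 <= v <= res.r_squared + 1e-10
    assert sum(res.normalized_shares.values()) == pytest.approx(1.0)


def test_lmg_rejects_singular_design(rng):
    x = rng.normal(size=30)
    X = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.raises(ValidationError, match="collinear"):
        lmg_importance(X, rng.normal(size=30))
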