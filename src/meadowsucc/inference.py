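"""Inferential layer: stage contrasts, simple regressions, Mantel tests,
correlation matrices, and an averaging-over-orderings R² decomposition.

Stage contrasts use one-way fixed-effects ANOVA with Tukey's HSD for the
pairwise family and a compact letter display (insert-and-absorb).  The
Mantel test correlates the upper triangles of two distance matrices and
assesses significance by simultaneous row/column permutation of the second
matrix, with the add-one p-value convention.  Relative importance of
predictors uses the LMG decomposition: each predictor's share of the
model R² is its average R² increment over all orderings in which it can
enter the model, computed by subset enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import ValidationError

__all__ = [
    "StageContrast",
    "MantelResult",
    "ImportanceResult",
    "RegressionResult",
    "anova_tukey",
    "compact_letter_display",
    "simple_regression",
    "mantel_test",
    "correlation_matrix",
    "lmg_importance",
    "zscore_euclidean_distance",
]


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD

@dataclass
class StageContrast:
    variable: str
    group_stats: pd.DataFrame           # index group: mean, sd, n
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame                 # columns group1, group2, meandiff, p_adj
    letters: dict                       # group -> compact letters
    alpha: float


def compact_letter_display(
    groups: Sequence, pairwise_p: Mapping[tuple, float], alpha: float = 0.05
) -> dict:
    """Insert-and-absorb compact letter display.

    Groups not significantly different at ``alpha`` share at least one
    letter.  Ties are resolved by the given group order (ascending stage).
    """
    groups = list(groups)
    sets: list[set] = [set(groups)]
    for (g1, g2), p in pairwise_p.items():
        if p >= alpha:
            continue
        new_sets: list[set] = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.extend([s - {g1}, s - {g2}])
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        absorbed: list[set] = []
        for s in new_sets:
            if s and not any(s < t or (s == t and t in absorbed) for t in new_sets
                             if t is not s):
                if s not in absorbed:
                    absorbed.append(s)
        sets = absorbed if absorbed else [set()]
    # letter order follows the first (lowest-ordered) member of each set
    sets.sort(key=lambda s: min(groups.index(g) for g in s) if s else len(groups))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for g in groups:
            if g in s:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def anova_tukey(values, group_labels, alpha: float = 0.05,
                variable: str = "value") -> StageContrast:
    """One-way ANOVA with Tukey HSD pairwise contrasts and letters."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    if y.shape != g.shape:
        raise ValidationError("values and groups must have equal length")
    uniq = sorted(set(g.tolist()))
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    samples = [y[g == u] for u in uniq]
    for u, s in zip(uniq, samples):
        if s.size < 2:
            raise ValidationError(f"group {u!r} has < 2 observations")
    f_stat, p_val = stats.f_oneway(*samples)

    res = pairwise_tukeyhsd(y, g, alpha=alpha)
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj"]]
    tukey.columns = ["group1", "group2", "meandiff", "p_adj"]
    tukey["p_adj"] = np.asarray(res.pvalues, dtype=float)
    tukey["meandiff"] = np.asarray(res.meandiffs, dtype=float)

    pairwise_p = {
        (row.group1, row.group2): float(row.p_adj)
        for row in tukey.itertuples()
    }
    letters = compact_letter_display(uniq, pairwise_p, alpha=alpha)
    group_stats = pd.DataFrame(
        {
            "mean": [s.mean() for s in samples],
            "sd": [s.std(ddof=1) for s in samples],
            "n": [s.size for s in samples],
        },
        index=pd.Index(uniq, name="group"),
    )
    return StageContrast(
        variable=variable,
        group_stats=group_stats,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        tukey=tukey,
        letters=letters,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# simple regression

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def simple_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 paired points")
    if np.var(x) == 0:
        raise ValidationError("x has zero variance")
    if np.var(y) == 0:
        # flat response: zero slope, nothing explained
        return RegressionResult(slope=0.0, intercept=float(y.mean()),
                                r_squared=0.0, p_value=1.0, n=int(x.size))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Mantel test

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"{name} must be square")
    if d.shape[0] < 4:
        raise ValidationError(f"{name} must have dimension >= 4")
    if not np.allclose(d, d.T):
        raise ValidationError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValidationError(f"{name} must have a zero diagonal")
    return d


def zscore_euclidean_distance(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Euclidean distance matrix on column-z-scored variables."""
    M = np.asarray(X, dtype=float)
    sd = M.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValidationError("zero-variance column in distance input")
    Z = (M - M.mean(axis=0)) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def mantel_test(dA, dB, n_permutations: int = 9999,
                seed: int | None = None) -> MantelResult:
    """One-sided (greater) Mantel test by row/column permutation of dB.

    p = (1 + #{permuted r >= observed r}) / (1 + n_permutations).
    """
    dA = _check_distance_matrix(dA, "dA")
    dB = _check_distance_matrix(dB, "dB")
    if dA.shape != dB.shape:
        raise ValidationError("distance matrices must have the same shape")
    n = dA.shape[0]
    iu = np.triu_indices(n, k=1)
    a = dA[iu]
    a_c = a - a.mean()
    a_norm = math.sqrt(float(a_c @ a_c))
    if a_norm == 0:
        raise ValidationError("dA has constant off-diagonal entries")

    def corr_with_a(bm: np.ndarray) -> float:
        b = bm[iu]
        b_c = b - b.mean()
        b_norm = math.sqrt(float(b_c @ b_c))
        if b_norm == 0:
            raise ValidationError("dB has constant off-diagonal entries")
        return float(a_c @ b_c) / (a_norm * b_norm)

    r_obs = corr_with_a(dB)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr_with_a(dB[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(r=r_obs, p_value=p,
                        n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# correlation matrix

def correlation_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pearson correlations with pairwise p-values.

    Returns (r matrix, p matrix, flagged zero-variance columns).  Entries
    involving a flagged column are NaN by construction, never silently.
    """
    cols = list(df.columns)
    if len(df) < 3:
        raise ValidationError("need >= 3 observations")
    flagged = [c for c in cols if np.std(df[c].to_numpy(dtype=float)) == 0]
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    np.fill_diagonal(p.values, 0.0)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            if ci in flagged or cj in flagged:
                r.loc[ci, cj] = r.loc[cj, ci] = np.nan
                p.loc[ci, cj] = p.loc[cj, ci] = np.nan
                continue
            rv, pv = stats.pearsonr(df[ci], df[cj])
            r.loc[ci, cj] = r.loc[cj, ci] = float(rv)
            p.loc[ci, cj] = p.loc[cj, ci] = float(pv)
    return r, p, flagged


# ---------------------------------------------------------------------------
# LMG relative importance

@dataclass
class ImportanceResult:
    shares: dict[str, float]
    r_squared: float
    n: int

    @property
    def normalized_shares(self) -> dict[str, float]:
        """Shares rescaled to sum to 1 (proportions of explained variance)."""
        if self.r_squared == 0:
            return {k: 0.0 for k in self.shares}
        return {k: v / self.r_squared for k, v in self.shares.items()}


def _subset_r2(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(y @ y)
    return 1.0 - float(resid @ resid) / tss


def lmg_importance(X: pd.DataFrame, y, max_predictors: int = 12) -> ImportanceResult:
    """LMG decomposition of the linear-model R² into per-predictor shares.

    share_j = sum over subsets S of the other predictors of
    |S|! (p-|S|-1)! / p!  *  (R²(S ∪ {j}) − R²(S)), i.e. the average
    increment of j over all entry orders.  Shares are non-negative for
    well-conditioned designs and sum to the full-model R².
    """
    cols = list(X.columns)
    p = len(cols)
    if p < 1:
        raise ValidationError("need >= 1 predictor")
    if p > max_predictors:
        raise ValidationError(
            f"{p} predictors exceed the enumeration limit {max_predictors}")
    Xm = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if Xm.shape[0] != n or n <= p + 2:
        raise ValidationError("need n > p + 2 observations")
    if np.linalg.matrix_rank(Xm - Xm.mean(axis=0)) < p:
        raise ValidationError(
            "predictor matrix is collinear to singularity; remove a predictor")
    Xc = Xm - Xm.mean(axis=0)
    yc = yv - yv.mean()
    if float(yc @ yc) == 0:
        raise ValidationError("response has zero variance")

    r2 = {0: 0.0}
    for mask in range(1, 1 << p):
        idx = [j for j in range(p) if mask >> j & 1]
        r2[mask] = _subset_r2(Xc[:, idx], yc)

    fact = [math.factorial(k) for k in range(p + 1)]
    shares = np.zeros(p)
    for mask in range(1 << p):
        k = bin(mask).count("1")
        if k == p:
            continue
        w = fact[k] * fact[p - k - 1] / fact[p]
        for j in range(p):
            if not mask >> j & 1:
                shares[j] += w * (r2[mask | (1 << j)] - r2[mask])
    full = r2[(1 << p) - 1]
    return ImportanceResult(
        shares=dict(zip(cols, shares.tolist())), r_squared=full, n=n)
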