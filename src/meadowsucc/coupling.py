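"""Plant-soil coupling coordination degree (EC_SP).

Per quadrat, each subsystem (soil; plant) is summarised by a weighted sum of
polarity-aware min-max-standardised indicators:

    S(X) = sum_s W_s * X'_s        P(Y) = sum_p W_p * Y'_p

with indicator weights derived from a principal-component analysis of the
standardised subsystem matrix (Kaiser criterion, eigenvalue >= 1 on the
correlation matrix; weight of indicator i = retained-variance-share-weighted
mean of |loadings|, normalised to sum 1).  The two subsystem integrals are
then combined into

    C = 2 * sqrt(S*P) / (S+P)      -- coupling degree, 1 iff S = P
    T = alpha*S + beta*P           -- coordination (overall level)
    D = C * T                      -- coupling coordination degree

The classical form D = sqrt(C*T) is available as ``variant="sqrt"``.  All of
S, P, C, T, D lie in [0, 1].  Min-max bounds are taken over the full fitted
table (all stages pooled) so D is comparable across stages.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import SubsystemSpec, ValidationError, default_subsystem_spec

__all__ = [
    "minmax_standardize",
    "pca_weights",
    "subsystem_integral",
    "coupling_coordination",
    "CouplingCoordinationModel",
    "coupling_table",
]

logger = logging.getLogger(__name__)


def minmax_standardize(values, polarity: str = "positive") -> np.ndarray:
    """Min-max rescale a vector to [0, 1]; negative polarity reflects it.

    A constant vector is mapped to all 0.5 with a logged warning: the
    indicator carries no ranking information, and 0.5 keeps it neutral in
    the subsystem integral.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("minmax_standardize needs >= 2 values")
    if polarity not in ("positive", "negative"):
        raise ValidationError(f"polarity must be positive/negative, got {polarity!r}")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        logger.warning("constant indicator column; standardised to 0.5")
        return np.full_like(x, 0.5)
    if polarity == "positive":
        return (x - lo) / (hi - lo)
    return (hi - x) / (hi - lo)


def pca_weights(standardized: pd.DataFrame | np.ndarray,
                columns: Sequence[str] | None = None) -> dict[str, float]:
    """PCA-derived indicator weights for one subsystem.

    Eigen-decomposition of the correlation matrix of the standardised
    indicators; components with eigenvalue >= 1 are retained (always at
    least one).  Raw weight of indicator i is the sum over retained
    components k of (variance share of k among retained) * |loading_ik|,
    where loading_ik = eigvec_ik * sqrt(eigval_k); weights are normalised
    to sum to 1.  A single-indicator subsystem bypasses the PCA (weight 1).
    """
    if isinstance(standardized, pd.DataFrame):
        cols = list(standardized.columns)
        X = standardized.to_numpy(dtype=float)
    else:
        X = np.asarray(standardized, dtype=float)
        cols = list(columns) if columns is not None else [
            f"x{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if p == 1:
        return {cols[0]: 1.0}
    if n < 3:
        raise ValidationError("pca_weights needs >= 3 quadrats")
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [cols[i] for i in np.flatnonzero(sds == 0)]
        raise ValidationError(f"zero-variance indicator column(s): {bad}")
    R = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    retained = np.flatnonzero(eigvals >= 1.0)
    if retained.size == 0:
        retained = np.array([0])
    lam = eigvals[retained]
    shares = lam / lam.sum()
    loadings = np.abs(eigvecs[:, retained]) * np.sqrt(lam)
    raw = loadings @ shares
    w = raw / raw.sum()
    return dict(zip(cols, w.tolist()))


def subsystem_integral(standardized_row, weights) -> float:
    """Weighted sum of standardised indicator values; lies in [0, 1]."""
    x = np.asarray(standardized_row, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValidationError(
            f"length mismatch: {x.shape} values vs {w.shape} weights")
    if not math.isclose(float(w.sum()), 1.0, abs_tol=1e-9):
        raise ValidationError("weights must sum to 1")
    return float(x @ w)


def coupling_coordination(
    S, P, alpha: float = 0.5, beta: float = 0.5, variant: str = "product"
):
    """Coupling degree C, coordination T and coordination degree D.

    Accepts scalars or arrays; C is defined as 0 where S + P = 0.
    """
    S = np.asarray(S, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any((S < 0) | (S > 1)) or np.any((P < 0) | (P > 1)):
        raise ValidationError("subsystem integrals must lie in [0, 1]")
    if not math.isclose(alpha + beta, 1.0, abs_tol=1e-12):
        raise ValidationError("alpha + beta must equal 1")
    if variant not in ("product", "sqrt"):
        raise ValidationError(f"unknown variant {variant!r}")
    total = S + P
    # sqrt(S)*sqrt(P) rather than sqrt(S*P): the product can underflow for
    # subnormal integrals even though the quotient is well-defined
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(total > 0,
                     2.0 * np.sqrt(S) * np.sqrt(P) / np.where(total > 0, total, 1.0),
                     0.0)
    T = alpha * S + beta * P
    D = C * T if variant == "product" else np.sqrt(C * T)
    if S.ndim == 0:
        return float(C), float(T), float(D)
    return C, T, D


class CouplingCoordinationModel(TransformerMixin, BaseEstimator):
    """Fit min-max bounds and PCA weights, then score quadrats with D_sp.

    Parameters
    ----------
    spec : SubsystemSpec or None
        Subsystem membership and polarities; defaults to the 7-soil /
        5-plant split with SBD as the only negative indicator.
    variant : {"product", "sqrt"}
        Outer combination of C and T.

    Attributes
    ----------
    ranges_ : dict indicator -> (min, max) used for standardisation.
    soil_weights_, plant_weights_ : dict indicator -> PCA weight.
    """

    def __init__(self, spec: SubsystemSpec | None = None,
                 variant: str = "product"):
        self.spec = spec
        self.variant = variant

    def _spec(self) -> SubsystemSpec:
        return self.spec if self.spec is not None else default_subsystem_spec()

    def _standardize(self, X: pd.DataFrame, indicators: Mapping[str, str],
                     fit: bool) -> pd.DataFrame:
        out = {}
        for name, polarity in indicators.items():
            if name not in X.columns:
                raise ValidationError(f"indicator column {name!r} missing")
            col = X[name].to_numpy(dtype=float)
            if fit:
                self.ranges_[name] = (float(col.min()), float(col.max()))
            lo, hi = self.ranges_[name]
            if hi == lo:
                logger.warning("constant indicator %r standardised to 0.5", name)
                out[name] = np.full(len(col), 0.5)
            elif polarity == "positive":
                out[name] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
            else:
                out[name] = np.clip((hi - col) / (hi - lo), 0.0, 1.0)
        return pd.DataFrame(out, index=X.index)

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._spec()
        if len(X) < 3:
            raise ValidationError("need >= 3 quadrats to fit PCA weights")
        self.ranges_ = {}
        soil_std = self._standardize(X, spec.soil_indicators, fit=True)
        plant_std = self._standardize(X, spec.plant_indicators, fit=True)
        self.soil_weights_ = pca_weights(soil_std)
        self.plant_weights_ = pca_weights(plant_std)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-quadrat S, P, C, T and D as a DataFrame indexed like X."""
        check_is_fitted(self, "soil_weights_")
        spec = self._spec()
        soil_std = self._standardize(X, spec.soil_indicators, fit=False)
        plant_std = self._standardize(X, spec.plant_indicators, fit=False)
        ws = np.array([self.soil_weights_[c] for c in soil_std.columns])
        wp = np.array([self.plant_weights_[c] for c in plant_std.columns])
        S = soil_std.to_numpy() @ ws
        P = plant_std.to_numpy() @ wp
        C, T, D = coupling_coordination(
            S, P, spec.alpha, spec.beta, self.variant)
        return pd.DataFrame({"S": S, "P": P, "C": C, "T": T, "D": D},
                            index=X.index)


def coupling_table(X: pd.DataFrame, spec: SubsystemSpec | None = None,
                   variant: str = "product") -> pd.DataFrame:
    """Fit-and-transform convenience over :class:`CouplingCoordinationModel`."""
    return CouplingCoordinationModel(spec=spec, variant=variant).fit_transform(X)
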