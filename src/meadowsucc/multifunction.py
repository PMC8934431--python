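"""Ecosystem multifunctionality by z-score averaging.

Each of the 12 plant/soil function indicators is z-scored over the analysed
quadrats (population standard deviation, i.e. divide by n); composite
indices are row means of z-score subsets:

* PGI — plant growth index (AGB, BGB, plant density, plant height),
* SCI — soil carbon accumulation index (STC),
* SNI — soil nutrient cycling index (STN, STP, STS),
* EMF — ecosystem multifunctionality, the mean over all 12 functions.

No polarity reversal is applied inside the index: plain z-scores enter the
average, so indicators that rise with degradation (e.g. bulk density) raise
EMF — a deliberate difference from the coupling module's polarity handling.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import EMF_FUNCTIONS, ValidationError

__all__ = [
    "DEFAULT_INDEX_GROUPS",
    "zscore",
    "composite_index",
    "MultifunctionalityIndex",
    "multifunction_table",
]

DEFAULT_INDEX_GROUPS: dict[str, tuple[str, ...]] = {
    "PGI": ("agb", "bgb", "plant_density", "plant_height"),
    "SCI": ("stc",),
    "SNI": ("stn", "stp", "sts"),
}


def zscore(column, name: str = "column") -> np.ndarray:
    """(x - mean) / sd with the population (divide-by-n) convention."""
    x = np.asarray(column, dtype=float)
    if x.size < 2:
        raise ValidationError(f"zscore needs >= 2 values in {name!r}")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValidationError(f"function {name!r} has zero variance")
    return (x - x.mean()) / sd


def composite_index(z: pd.DataFrame, subset: Sequence[str]) -> pd.Series:
    """Row mean of z-scores over a named function subset."""
    subset = list(subset)
    if not subset:
        raise ValidationError("composite_index needs a non-empty subset")
    unknown = [s for s in subset if s not in z.columns]
    if unknown:
        raise ValidationError(f"unknown function name(s): {unknown}")
    return z[subset].mean(axis=1)


class MultifunctionalityIndex(TransformerMixin, BaseEstimator):
    """Z-score the function indicators and average them into indices.

    Parameters
    ----------
    functions : sequence of str
        Indicator columns entering EMF (default: the 12 standard functions).
    index_groups : mapping name -> subset
        Sub-index definitions (default PGI/SCI/SNI as in the module
        docstring).

    Attributes
    ----------
    means_, sds_ : per-function standardisation constants (population sd).
    """

    def __init__(self, functions: Sequence[str] = EMF_FUNCTIONS,
                 index_groups: Mapping[str, Sequence[str]] | None = None):
        self.functions = functions
        self.index_groups = index_groups

    def _groups(self) -> dict[str, tuple[str, ...]]:
        groups = (DEFAULT_INDEX_GROUPS if self.index_groups is None
                  else dict(self.index_groups))
        for name, subset in groups.items():
            extra = set(subset) - set(self.functions)
            if extra:
                raise ValidationError(
                    f"index group {name!r} uses non-EMF functions {sorted(extra)}")
        return {k: tuple(v) for k, v in groups.items()}

    def fit(self, X: pd.DataFrame, y=None):
        missing = [f for f in self.functions if f not in X.columns]
        if missing:
            raise ValidationError(f"missing function column(s): {missing}")
        if len(X) < 2:
            raise ValidationError("need >= 2 quadrats")
        self.means_ = {}
        self.sds_ = {}
        for f in self.functions:
            col = X[f].to_numpy(dtype=float)
            sd = col.std(ddof=0)
            if sd == 0:
                raise ValidationError(f"function {f!r} has zero variance")
            self.means_[f] = float(col.mean())
            self.sds_[f] = float(sd)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Z-score table plus PGI/SCI/SNI/EMF columns, indexed like X."""
        check_is_fitted(self, "means_")
        z = pd.DataFrame(
            {f: (X[f].to_numpy(dtype=float) - self.means_[f]) / self.sds_[f]
             for f in self.functions},
            index=X.index,
        )
        out = z.copy()
        for name, subset in self._groups().items():
            out[name] = composite_index(z, subset)
        out["EMF"] = composite_index(z, list(self.functions))
        return out


def multifunction_table(
    X: pd.DataFrame,
    functions: Sequence[str] = EMF_FUNCTIONS,
    index_groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Fit-and-transform convenience over :class:`MultifunctionalityIndex`."""
    return MultifunctionalityIndex(
        functions=functions, index_groups=index_groups).fit_transform(X)
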