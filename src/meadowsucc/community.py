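"""Community-level metrics: richness, gamma diversity, Camargo evenness and
functional-group biomass shares.

Camargo's evenness compares every unordered pair of species' biomass
proportions:

    E = 1 - sum_{i<j} |P_i - P_j| / S

with S the number of species present (biomass > 0) in the quadrat.  E lies in
(0, 1] and equals 1 exactly when all proportions are equal.  Proportions are
computed on biomass, over present species only, so the index does not depend
on the species universe or on richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    FunctionalGroupMap,
    FUNCTIONAL_GROUPS,
    QuadratRecord,
    SurveyTable,
    ValidationError,
)

__all__ = [
    "CommunitySummary",
    "species_richness",
    "gamma_diversity",
    "camargo_evenness",
    "functional_group_shares",
    "community_summary",
    "analysis_frame",
]


@dataclass
class CommunitySummary:
    quadrat_id: str
    sr: int
    ev: float
    fg_share: dict[str, float]

    @property
    def toxic_share(self) -> float:
        return self.fg_share.get("toxic_forb", 0.0)


def species_richness(record: QuadratRecord) -> int:
    """Number of species with strictly positive biomass in the quadrat."""
    return sum(1 for b in record.species_biomass.values() if b > 0)


def gamma_diversity(table: SurveyTable, stage: int) -> int:
    """Pooled species count (biomass > 0 anywhere) over a stage's quadrats."""
    recs = table.stage_records(stage)  # raises on unknown stage
    pooled: set[str] = set()
    for rec in recs:
        pooled.update(sp for sp, b in rec.species_biomass.items() if b > 0)
    return len(pooled)


def camargo_evenness(biomass) -> float:
    """Camargo evenness over species with positive biomass.

    Raises on an all-zero (or empty) vector: evenness of nothing is undefined.
    """
    b = np.asarray(list(biomass), dtype=float)
    if b.size and (b < 0).any():
        raise ValidationError("biomass values must be non-negative")
    b = b[b > 0]
    if b.size == 0:
        raise ValidationError("camargo_evenness needs at least one positive biomass")
    p = b / b.sum()
    s = p.size
    # sum over unordered pairs of |P_i - P_j|; O(S log S) via the sorted form
    q = np.sort(p)
    ranks = np.arange(1, s + 1)
    pair_sum = float(np.sum((2 * ranks - s - 1) * q))
    return 1.0 - pair_sum / s


def functional_group_shares(
    record: QuadratRecord, fgmap: FunctionalGroupMap
) -> dict[str, float]:
    """Biomass proportion per functional group; groups absent get 0."""
    shares = dict.fromkeys(FUNCTIONAL_GROUPS, 0.0)
    total = 0.0
    for sp, b in record.species_biomass.items():
        if b > 0:
            shares[fgmap[sp]] += b  # raises naming the species if unmapped
            total += b
    if total == 0:
        raise ValidationError(
            f"quadrat {record.quadrat_id!r} has no positive biomass"
        )
    return {g: v / total for g, v in shares.items()}


def community_summary(
    table: SurveyTable, fgmap: FunctionalGroupMap
) -> pd.DataFrame:
    """Per-quadrat SR, EV and functional-group shares as a DataFrame."""
    rows = []
    for rec in table.records:
        shares = functional_group_shares(rec, fgmap)
        rows.append(
            {
                "quadrat_id": rec.quadrat_id,
                "stage": rec.stage,
                "sr": species_richness(rec),
                "ev": camargo_evenness(list(rec.species_biomass.values())),
                **{f"share_{g}": shares[g] for g in FUNCTIONAL_GROUPS},
                "toxic_share": shares["toxic_forb"],
            }
        )
    return pd.DataFrame(rows).set_index("quadrat_id")


def analysis_frame(table: SurveyTable, fgmap: FunctionalGroupMap | None = None) -> pd.DataFrame:
    """Covariates + derived SR/AGB (+ EV and group shares when a map is given).

    This is the indicator table consumed by the coupling, multifunctionality
    and inference layers; one row per quadrat.
    """
    cov = table.covariate_frame()
    if fgmap is not None:
        cov = cov.join(community_summary(table, fgmap).drop(columns=["stage", "sr"]))
    return cov
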