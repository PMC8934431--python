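"""Data model and delimited-text I/O for quadrat survey tables.

A survey table holds one row per quadrat (0.5 x 0.5 m sampling frame) with
per-species aboveground dry biomass and the plant/soil covariates used by the
downstream analyses.  Two CSV layouts are supported:

* **wide** — one column per species, prefixed ``sp:``, plus covariate columns;
* **long** — one row per (quadrat, species) pair with columns ``quadrat_id``,
  ``species``, ``biomass``; covariates repeat within a quadrat.

All files are comma-separated UTF-8 with a header row and ``.`` decimals.
A species biomass of exactly 0 means "recorded absent" and is distinct from a
missing cell (absent key): richness counting needs the distinction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "FUNCTIONAL_GROUPS",
    "SOIL_VARIABLES",
    "PLANT_VARIABLES",
    "COVARIATE_COLUMNS",
    "EMF_FUNCTIONS",
    "QuadratRecord",
    "SurveyTable",
    "FunctionalGroupMap",
    "SubsystemSpec",
    "AnalysisConfig",
    "default_subsystem_spec",
    "read_survey_table",
    "write_survey_table",
    "read_functional_groups",
    "write_functional_groups",
    "write_results",
]


class SchemaError(ValueError):
    """A required column or field is missing or mistyped."""


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. negative biomass)."""


#: Functional groups by ecological role / palatability.
FUNCTIONAL_GROUPS = ("sedge", "grass", "desirable_forb", "toxic_forb", "shrub")

#: Soil covariates: bulk density (g cm^-3), moisture (vol %), temperature (degC),
#: total carbon / nitrogen / phosphorus / sulfur (g kg^-1).
SOIL_VARIABLES = ("sbd", "sm", "st", "stc", "stn", "stp", "sts")

#: Plant covariates other than the species table: belowground biomass
#: (g per 0.25 m^2), density (individuals per 0.25 m^2), height (cm).
PLANT_VARIABLES = ("bgb", "plant_density", "plant_height")

#: Required numeric covariate columns in a survey CSV ("agb" is optional:
#: when absent it is derived as the species-biomass sum).
COVARIATE_COLUMNS = PLANT_VARIABLES + SOIL_VARIABLES

#: The 12 plant and soil function indicators entering the multifunctionality
#: index ("sr" and "agb" are derived from the species table when not stored).
EMF_FUNCTIONS = (
    "agb", "bgb", "sr", "plant_density", "plant_height",
    "st", "sm", "sbd", "stc", "stn", "stp", "sts",
)

_AGB_RTOL = 1e-6


@dataclass
class QuadratRecord:
    """One quadrat: species biomass composition plus plant/soil covariates.

    Biomass fields are g dry mass per 0.25 m^2 quadrat.  ``agb`` may be
    recorded independently of the species-wise sum; when both are present
    they must agree to numerical tolerance.
    """

    quadrat_id: str
    species_biomass: dict[str, float]
    bgb: float
    plant_density: float
    plant_height: float
    sbd: float
    sm: float
    st: float
    stc: float
    stn: float
    stp: float
    sts: float
    agb: float | None = None
    transect_id: str = ""
    stage: int | None = None

    def __post_init__(self) -> None:
        for name, value in self.species_biomass.items():
            if value < 0:
                raise ValidationError(
                    f"negative biomass {value!r} for species {name!r} "
                    f"in quadrat {self.quadrat_id!r}"
                )
        for fieldname in ("bgb", "plant_density"):
            if getattr(self, fieldname) < 0:
                raise ValidationError(
                    f"negative {fieldname} in quadrat {self.quadrat_id!r}"
                )
        if self.agb is not None:
            if self.agb < 0:
                raise ValidationError(f"negative agb in quadrat {self.quadrat_id!r}")
            total = sum(self.species_biomass.values())
            if self.species_biomass and not math.isclose(
                self.agb, total, rel_tol=_AGB_RTOL, abs_tol=1e-9
            ):
                raise ValidationError(
                    f"agb {self.agb} disagrees with species biomass sum {total} "
                    f"in quadrat {self.quadrat_id!r}"
                )
        if self.stage is not None and self.stage < 1:
            raise ValidationError(f"stage must be >= 1, got {self.stage}")

    @property
    def total_agb(self) -> float:
        """Aboveground biomass: the stored value, else the species sum."""
        if self.agb is not None:
            return self.agb
        return sum(self.species_biomass.values())


class SurveyTable:
    """Ordered collection of :class:`QuadratRecord` with a species universe."""

    def __init__(
        self,
        records: Sequence[QuadratRecord],
        species_universe: Sequence[str] | None = None,
    ) -> None:
        self.records: list[QuadratRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.quadrat_id in seen:
                raise ValidationError(f"duplicate quadrat_id {rec.quadrat_id!r}")
            seen.add(rec.quadrat_id)
        if species_universe is None:
            universe: dict[str, None] = {}
            for rec in self.records:
                for sp in rec.species_biomass:
                    universe.setdefault(sp)
            self.species_universe: list[str] = list(universe)
        else:
            self.species_universe = list(species_universe)
            known = set(self.species_universe)
            for rec in self.records:
                extra = set(rec.species_biomass) - known
                if extra:
                    raise ValidationError(
                        f"quadrat {rec.quadrat_id!r} has species outside the "
                        f"universe: {sorted(extra)}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyTable):
            return NotImplemented
        return (
            self.species_universe == other.species_universe
            and self.records == other.records
        )

    @property
    def stages(self) -> list[int]:
        """Sorted distinct stage labels present in the table."""
        return sorted({r.stage for r in self.records if r.stage is not None})

    def stage_records(self, stage: int) -> list[QuadratRecord]:
        recs = [r for r in self.records if r.stage == stage]
        if not recs:
            raise ValidationError(f"no quadrats with stage {stage!r}")
        return recs

    def covariate_frame(self) -> pd.DataFrame:
        """Covariates (+ derived agb/sr) as a DataFrame indexed by quadrat_id."""
        rows = []
        for rec in self.records:
            row = {c: getattr(rec, c) for c in COVARIATE_COLUMNS}
            row["agb"] = rec.total_agb
            row["sr"] = sum(1 for b in rec.species_biomass.values() if b > 0)
            row["stage"] = rec.stage
            rows.append(row)
        return pd.DataFrame(rows, index=pd.Index(
            [r.quadrat_id for r in self.records], name="quadrat_id"))

    def species_matrix(self) -> pd.DataFrame:
        """Quadrat x species biomass matrix (absent keys become 0)."""
        data = np.zeros((len(self.records), len(self.species_universe)))
        col = {sp: j for j, sp in enumerate(self.species_universe)}
        for i, rec in enumerate(self.records):
            for sp, b in rec.species_biomass.items():
                data[i, col[sp]] = b
        return pd.DataFrame(
            data,
            index=pd.Index([r.quadrat_id for r in self.records], name="quadrat_id"),
            columns=list(self.species_universe),
        )


class FunctionalGroupMap:
    """Mapping species name -> functional group.

    Every species with positive biomass must be mapped before any
    functional-group operation; an unmapped species is an error, never a
    silent "other" bucket.
    """

    def __init__(self, mapping: Mapping[str, str]) -> None:
        bad = {s: g for s, g in mapping.items() if g not in FUNCTIONAL_GROUPS}
        if bad:
            raise ValidationError(
                f"unknown functional groups {sorted(set(bad.values()))}; "
                f"expected one of {FUNCTIONAL_GROUPS}"
            )
        self.mapping: dict[str, str] = dict(mapping)

    def __getitem__(self, species: str) -> str:
        try:
            return self.mapping[species]
        except KeyError:
            raise ValidationError(
                f"species {species!r} has no functional-group assignment"
            ) from None

    def __contains__(self, species: str) -> bool:
        return species in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def check_covers(self, species: Iterable[str]) -> None:
        missing = sorted(set(species) - set(self.mapping))
        if missing:
            raise ValidationError(
                f"functional-group map does not cover species: {missing}"
            )


@dataclass(frozen=True)
class SubsystemSpec:
    """Soil vs plant subsystem membership with per-indicator polarity.

    ``alpha`` and ``beta`` are the soil and plant contribution weights in the
    coordination term T = alpha*S(X) + beta*P(Y); they must sum to 1.
    Polarity is "positive" (more is better) or "negative" (less is better,
    e.g. bulk density, which rises as the meadow degrades).
    """

    soil_indicators: Mapping[str, str]
    plant_indicators: Mapping[str, str]
    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not self.soil_indicators or not self.plant_indicators:
            raise ValidationError("soil and plant indicator sets must be non-empty")
        overlap = set(self.soil_indicators) & set(self.plant_indicators)
        if overlap:
            raise ValidationError(f"indicators in both subsystems: {sorted(overlap)}")
        for pol in list(self.soil_indicators.values()) + list(
            self.plant_indicators.values()
        ):
            if pol not in ("positive", "negative"):
                raise ValidationError(f"polarity must be positive/negative, got {pol!r}")
        if not math.isclose(self.alpha + self.beta, 1.0, abs_tol=1e-12):
            raise ValidationError("alpha + beta must equal 1")
        if not (0 <= self.alpha <= 1):
            raise ValidationError("alpha must lie in [0, 1]")


def default_subsystem_spec(alpha: float = 0.5) -> SubsystemSpec:
    """Default membership: 7 soil indicators (SBD negative) vs 5 plant ones."""
    soil = {v: "positive" for v in SOIL_VARIABLES}
    soil["sbd"] = "negative"
    plant = {v: "positive" for v in ("agb", "bgb", "plant_density", "plant_height", "sr")}
    return SubsystemSpec(soil_indicators=soil, plant_indicators=plant,
                         alpha=alpha, beta=1.0 - alpha)


_DEFAULT_INDEX_GROUPS = {
    "PGI": ("agb", "bgb", "plant_density", "plant_height"),
    "SCI": ("stc",),
    "SNI": ("stn", "stp", "sts"),
}


@dataclass
class AnalysisConfig:
    """End-to-end analysis settings (YAML-serialisable)."""

    subsystem_spec: SubsystemSpec = field(default_factory=default_subsystem_spec)
    emf_functions: tuple[str, ...] = EMF_FUNCTIONS
    index_groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_INDEX_GROUPS))
    n_clusters: int = 4
    n_permutations: int = 9999
    rng_seed: int = 0
    coupling_variant: str = "product"

    def __post_init__(self) -> None:
        if len(set(self.emf_functions)) != len(self.emf_functions):
            raise ValidationError("emf_functions contains duplicates")
        for name, subset in self.index_groups.items():
            extra = set(subset) - set(self.emf_functions)
            if extra:
                raise ValidationError(
                    f"index group {name!r} uses non-EMF functions {sorted(extra)}"
                )
        if self.coupling_variant not in ("product", "sqrt"):
            raise ValidationError(
                f"coupling_variant must be 'product' or 'sqrt', "
                f"got {self.coupling_variant!r}"
            )
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")

    def to_dict(self) -> dict:
        return {
            "subsystem_spec": {
                "soil_indicators": dict(self.subsystem_spec.soil_indicators),
                "plant_indicators": dict(self.subsystem_spec.plant_indicators),
                "alpha": self.subsystem_spec.alpha,
                "beta": self.subsystem_spec.beta,
            },
            "emf_functions": list(self.emf_functions),
            "index_groups": {k: list(v) for k, v in self.index_groups.items()},
            "n_clusters": self.n_clusters,
            "n_permutations": self.n_permutations,
            "rng_seed": self.rng_seed,
            "coupling_variant": self.coupling_variant,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "subsystem_spec" in d:
            ss = d["subsystem_spec"]
            d["subsystem_spec"] = SubsystemSpec(
                soil_indicators=dict(ss["soil_indicators"]),
                plant_indicators=dict(ss["plant_indicators"]),
                alpha=float(ss.get("alpha", 0.5)),
                beta=float(ss.get("beta", 0.5)),
            )
        if "emf_functions" in d:
            d["emf_functions"] = tuple(d["emf_functions"])
        if "index_groups" in d:
            d["index_groups"] = {k: tuple(v) for k, v in d["index_groups"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers

_SP_PREFIX = "sp:"


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _record_from_row(quadrat_id: str, row: Mapping, species_biomass: dict) -> QuadratRecord:
    agb = row.get("agb")
    if agb is not None and (isinstance(agb, float) and math.isnan(agb)):
        agb = None
    stage = row.get("stage")
    if stage is not None and not (isinstance(stage, float) and math.isnan(stage)):
        stage = int(stage)
    else:
        stage = None
    kwargs = {c: float(row[c]) for c in COVARIATE_COLUMNS}
    return QuadratRecord(
        quadrat_id=str(quadrat_id),
        transect_id=str(row.get("transect_id", "") or ""),
        stage=stage,
        species_biomass=species_biomass,
        agb=None if agb is None else float(agb),
        **kwargs,
    )


def read_survey_table(path: str | Path, layout: str = "wide") -> SurveyTable:
    """Read a survey CSV in ``wide`` or ``long`` layout.

    Missing numeric covariate cells raise a :class:`SchemaError` rather than
    being silently imputed; a missing species cell in the wide layout means
    the species was not recorded in that quadrat.
    """
    path = Path(path)
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    df = pd.read_csv(path)
    _require_columns(df, ["quadrat_id"], path)

    if layout == "wide":
        _require_columns(df, COVARIATE_COLUMNS, path)
        sp_cols = [c for c in df.columns if c.startswith(_SP_PREFIX)]
        if not sp_cols:
            raise SchemaError(f"{path}: no species columns (prefixed {_SP_PREFIX!r})")
        _check_no_missing(df, COVARIATE_COLUMNS, path)
        records = []
        for _, row in df.iterrows():
            biomass = {}
            for c in sp_cols:
                v = row[c]
                if pd.notna(v):
                    biomass[c[len(_SP_PREFIX):]] = float(v)
            records.append(_record_from_row(row["quadrat_id"], row, biomass))
        universe = [c[len(_SP_PREFIX):] for c in sp_cols]
        return SurveyTable(records, species_universe=universe)

    _require_columns(df, ["species", "biomass"] + list(COVARIATE_COLUMNS), path)
    _check_no_missing(df, ["species", "biomass"] + list(COVARIATE_COLUMNS), path)
    records = []
    universe: dict[str, None] = {}
    for qid, grp in df.groupby("quadrat_id", sort=False):
        biomass = {}
        for _, r in grp.iterrows():
            biomass[str(r["species"])] = float(r["biomass"])
            universe.setdefault(str(r["species"]))
        records.append(_record_from_row(qid, grp.iloc[0].to_dict(), biomass))
    return SurveyTable(records, species_universe=sorted(universe))


def _check_no_missing(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        if df[c].isna().any():
            bad = df.loc[df[c].isna(), "quadrat_id"].tolist()
            raise SchemaError(
                f"{path}: missing values in column {c!r} for quadrats {bad}"
            )


def write_survey_table(table: SurveyTable, path: str | Path,
                       layout: str = "wide") -> None:
    """Write a survey table as CSV (inverse of :func:`read_survey_table`)."""
    path = Path(path)
    if layout == "wide":
        rows = []
        for rec in table.records:
            row: dict = {"quadrat_id": rec.quadrat_id,
                         "transect_id": rec.transect_id, "stage": rec.stage}
            for c in COVARIATE_COLUMNS:
                row[c] = getattr(rec, c)
            row["agb"] = rec.agb
            for sp in table.species_universe:
                row[_SP_PREFIX + sp] = rec.species_biomass.get(sp)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    elif layout == "long":
        rows = []
        for rec in table.records:
            base: dict = {"quadrat_id": rec.quadrat_id,
                          "transect_id": rec.transect_id, "stage": rec.stage}
            for c in COVARIATE_COLUMNS:
                base[c] = getattr(rec, c)
            base["agb"] = rec.agb
            for sp, b in rec.species_biomass.items():
                rows.append({**base, "species": sp, "biomass": b})
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def read_functional_groups(path: str | Path) -> FunctionalGroupMap:
    df = pd.read_csv(path)
    _require_columns(df, ["species", "group"], path)
    return FunctionalGroupMap(dict(zip(df["species"].astype(str), df["group"])))


def write_functional_groups(fgmap: FunctionalGroupMap, path: str | Path) -> None:
    pd.DataFrame(
        {"species": list(fgmap.mapping), "group": list(fgmap.mapping.values())}
    ).to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Write named result tables as CSV plus a JSON run manifest.

    Numeric cells are printed with 12 significant digits so a re-read table
    reproduces values to that precision; the manifest records the config,
    seed, library versions and per-file checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tables": {},
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    for name, df in tables.items():
        fname = f"{name}.csv"
        fpath = out_dir / fname
        df.to_csv(fpath, index=False, float_format="%.12g")
        manifest["tables"][name] = {
            "file": fname,
            "rows": int(len(df)),
            "sha256": _sha256(fpath),
        }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
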