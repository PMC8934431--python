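"""Stage-structured synthetic quadrat surveys.

Emulates a four-stage grazing-succession design on an alpine meadow:
stage-specific species pools, functional-group biomass compositions, and
soil/plant covariates whose stage orderings mirror the degradation gradient
(sedge-dominated Stage 1 through toxic-forb-dominated Stage 4).

Generative model per quadrat:

* species presence — independent Bernoulli draws over the stage pool
  (dominant species are near-certain);
* biomass composition — Dirichlet-type allocation (gamma draws) whose
  expectation matches the stage's functional-group proportions, split within
  each group (dominants up-weighted);
* total aboveground biomass — log-normal;
* soil and plant covariates — Gaussian, truncated at physical bounds.

The stage compositions and pool sizes are fixed design targets; the soil
means/sds and plant covariates are synthetic calibration chosen as plausible
alpine-meadow magnitudes with the qualitative stage orderings above, not
measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .io import QuadratRecord, SurveyTable, FunctionalGroupMap, ValidationError

__all__ = [
    "StageTemplate",
    "GeneratorConfig",
    "default_stage_templates",
    "default_functional_group_map",
    "generate_survey",
]

_COVARIATES = ("bgb", "plant_density", "plant_height",
               "sbd", "sm", "st", "stc", "stn", "stp", "sts")

#: physical truncation bounds for covariate draws
_BOUNDS = {
    "bgb": (0.0, np.inf),
    "plant_density": (1.0, np.inf),
    "plant_height": (0.5, np.inf),
    "sbd": (0.2, 2.2),
    "sm": (0.0, 100.0),
    "st": (-5.0, 40.0),
    "stc": (0.0, np.inf),
    "stn": (0.0, np.inf),
    "stp": (0.0, np.inf),
    "sts": (0.0, np.inf),
}

_MAX_REDRAWS = 100


@dataclass
class StageTemplate:
    """Distributional targets for one succession stage."""

    stage: int
    fg_proportions: Mapping[str, float]
    species_pool: Mapping[str, str]        # species name -> functional group
    soil_means: Mapping[str, float]
    soil_sds: Mapping[str, float]
    detection_prob: float = 0.5
    biomass_dispersion: float = 150.0
    agb_median: float = 80.0               # g per 0.25 m^2, log-normal median
    agb_log_sd: float = 0.25
    dominant_species: tuple[str, ...] = ()
    dominant_weight: float = 4.0           # within-group Dirichlet up-weighting
    dominant_detection: float = 0.9

    def __post_init__(self) -> None:
        total = sum(self.fg_proportions.values())
        if total > 1 + 1e-9:
            raise ValidationError("fg_proportions must sum to <= 1")
        if not (0 < self.detection_prob <= 1):
            raise ValidationError("detection_prob must lie in (0, 1]")
        if self.biomass_dispersion <= 0:
            raise ValidationError("biomass_dispersion must be > 0")
        if any(sd < 0 for sd in self.soil_sds.values()):
            raise ValidationError("soil_sds must be >= 0")
        missing = set(self.dominant_species) - set(self.species_pool)
        if missing:
            raise ValidationError(f"dominant species not in pool: {sorted(missing)}")

    @property
    def pool_size(self) -> int:
        return len(self.species_pool)


@dataclass
class GeneratorConfig:
    templates: tuple[StageTemplate, ...]
    n_quadrats_per_stage: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_quadrats_per_stage < 2:
            raise ValidationError("n_quadrats_per_stage must be >= 2")


# --------------------------------------------------------------------------
# default templates

# Dominant species per stage; genera follow the site's flora (Kobresia/Carex
# sedges, Elymus/Poa grasses, Saussurea/Anemone forbs, Gentiana toxic forbs).
_DOMINANTS = {
    1: (("Kobresia graminifolia", "sedge"), ("Elymus nutans", "grass"),
        ("Poa pratensis", "grass"), ("Anemone rivularis", "toxic_forb"),
        ("Tibetia himalaica", "desirable_forb")),
    2: (("Elymus nutans", "grass"), ("Scirpus pumilus", "sedge"),
        ("Pleurospermum camtschaticum", "desirable_forb"),
        ("Saussurea hieracioides", "desirable_forb"),
        ("Potentilla fragarioides", "desirable_forb")),
    3: (("Anaphalis lactea", "desirable_forb"),
        ("Saussurea hieracioides", "desirable_forb"),
        ("Anemone trullifolia", "toxic_forb"), ("Aster tataricus", "desirable_forb")),
    4: (("Gentiana macrophylla", "toxic_forb"), ("Anemone rivularis", "toxic_forb"),
        ("Saussurea hieracioides", "desirable_forb"),
        ("Oxytropis kansuensis", "toxic_forb")),
}

# Printed stage compositions (biomass shares by functional group); the small
# remainders for unlisted groups are synthetic so each stage sums to 1.
_FG_PROPORTIONS = {
    1: {"sedge": 0.46, "grass": 0.15, "desirable_forb": 0.28,
        "toxic_forb": 0.08, "shrub": 0.03},
    2: {"sedge": 0.24, "grass": 0.25, "desirable_forb": 0.36,
        "toxic_forb": 0.10, "shrub": 0.05},
    3: {"sedge": 0.23, "grass": 0.08, "desirable_forb": 0.38,
        "toxic_forb": 0.29, "shrub": 0.02},
    4: {"sedge": 0.06, "grass": 0.11, "desirable_forb": 0.37,
        "toxic_forb": 0.44, "shrub": 0.02},
}

# Stage pool sizes (gamma diversities) and their functional-group make-up.
_POOL_COUNTS = {
    1: {"sedge": 10, "grass": 12, "desirable_forb": 24, "toxic_forb": 10, "shrub": 5},
    2: {"sedge": 9, "grass": 12, "desirable_forb": 22, "toxic_forb": 9, "shrub": 3},
    3: {"sedge": 7, "grass": 9, "desirable_forb": 18, "toxic_forb": 10, "shrub": 3},
    4: {"sedge": 6, "grass": 9, "desirable_forb": 18, "toxic_forb": 13, "shrub": 3},
}

# Synthetic global flora: a shared list per group so stage pools overlap the
# way real space-for-time plots do (nested draws from one regional flora).
_FLORA_GENERA = {
    "sedge": ("Kobresia", "Carex", "Scirpus", "Eriophorum"),
    "grass": ("Elymus", "Poa", "Agrostis", "Festuca", "Stipa", "Koeleria"),
    "desirable_forb": ("Saussurea", "Potentilla", "Tibetia", "Pleurospermum",
                       "Anaphalis", "Aster", "Taraxacum", "Leontopodium"),
    "toxic_forb": ("Gentiana", "Anemone", "Oxytropis", "Euphorbia",
                   "Ranunculus", "Stellera"),
    "shrub": ("Salix", "Potentilla-fruticosa", "Caragana", "Rhododendron"),
}


def _global_flora() -> dict[str, list[str]]:
    flora: dict[str, list[str]] = {}
    for group, genera in _FLORA_GENERA.items():
        names = []
        for i in range(40):
            genus = genera[i % len(genera)]
            names.append(f"{genus} sp{i // len(genera) + 1:02d}")
        flora[group] = names
    return flora


# Synthetic covariate calibration (means per stage, in field units).  The
# stage orderings encode the degradation gradient: bulk density and soil
# temperature peak in Stage 4; total N (and C) peak in Stage 3 and bottom out
# in Stage 4; biomass, density, height decline toward Stage 4; moisture flat.
_SOIL_MEANS = {
    #            bgb   pd    ph    sbd   sm    st    stc  stn  stp   sts
    1: dict(bgb=310, plant_density=120, plant_height=12.5, sbd=0.95, sm=28.0,
            st=10.8, stc=46.0, stn=4.2, stp=0.72, sts=0.82),
    2: dict(bgb=290, plant_density=112, plant_height=10.5, sbd=1.00, sm=27.5,
            st=11.2, stc=48.0, stn=4.0, stp=0.74, sts=0.84),
    3: dict(bgb=270, plant_density=100, plant_height=9.0, sbd=1.05, sm=28.0,
            st=11.5, stc=58.0, stn=4.8, stp=0.80, sts=0.92),
    4: dict(bgb=180, plant_density=62, plant_height=5.0, sbd=1.28, sm=27.0,
            st=13.2, stc=38.0, stn=2.9, stp=0.62, sts=0.70),
}
_SOIL_SDS = dict(bgb=35.0, plant_density=14.0, plant_height=1.2, sbd=0.06,
                 sm=3.0, st=0.7, stc=5.0, stn=0.40, stp=0.07, sts=0.08)

_AGB_MEDIANS = {1: 90.0, 2: 80.0, 3: 85.0, 4: 45.0}
_DETECTION = {1: 0.50, 2: 0.48, 3: 0.45, 4: 0.33}
# Dirichlet concentration totals: tight within-stage compositions, emulating
# clearly differentiated community states (the degraded Stage 4 is looser).
_DISPERSION = {1: 150.0, 2: 150.0, 3: 150.0, 4: 105.0}


def default_stage_templates() -> tuple[StageTemplate, ...]:
    """Four stage templates with the printed compositions and pool sizes.

    Functional-group proportions per stage equal the reported stage
    compositions; pool sizes are (61, 55, 47, 49); covariate means follow the
    qualitative stage orderings documented in the module docstring.
    """
    flora = _global_flora()
    templates = []
    for stage in (1, 2, 3, 4):
        pool: dict[str, str] = {name: grp for name, grp in _DOMINANTS[stage]}
        for group, count in _POOL_COUNTS[stage].items():
            n_dom = sum(1 for g in pool.values() if g == group)
            for name in flora[group]:
                if sum(1 for g in pool.values() if g == group) >= count:
                    break
                pool.setdefault(name, group)
            assert sum(1 for g in pool.values() if g == group) == count, (stage, group, n_dom)
        templates.append(
            StageTemplate(
                stage=stage,
                fg_proportions=_FG_PROPORTIONS[stage],
                species_pool=pool,
                soil_means=_SOIL_MEANS[stage],
                soil_sds=dict(_SOIL_SDS),
                detection_prob=_DETECTION[stage],
                biomass_dispersion=_DISPERSION[stage],
                agb_median=_AGB_MEDIANS[stage],
                dominant_species=tuple(n for n, _ in _DOMINANTS[stage]),
            )
        )
    return tuple(templates)


def default_functional_group_map(
    templates: tuple[StageTemplate, ...] | None = None,
) -> FunctionalGroupMap:
    """Group assignments covering every species of the given (or default) pools."""
    if templates is None:
        templates = default_stage_templates()
    mapping: dict[str, str] = {}
    for t in templates:
        mapping.update(t.species_pool)
    return FunctionalGroupMap(mapping)


# --------------------------------------------------------------------------
# generation

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_quadrat(rng: np.random.Generator, t: StageTemplate,
                  quadrat_id: str, transect_id: str) -> QuadratRecord:
    species = list(t.species_pool)
    groups = [t.species_pool[s] for s in species]
    dominants = set(t.dominant_species)

    present_idx: list[int] = []
    for _ in range(_MAX_REDRAWS):
        probs = np.array(
            [max(t.detection_prob, t.dominant_detection) if s in dominants
             else t.detection_prob for s in species])
        present = rng.random(len(species)) < probs
        present_idx = np.flatnonzero(present).tolist()
        if present_idx:
            break
    else:
        raise ValidationError(
            f"stage {t.stage}: no species present after {_MAX_REDRAWS} redraws")

    # target biomass shares: group proportions renormalised over the groups
    # present, split within group (dominants up-weighted)
    present_groups = {groups[i] for i in present_idx}
    gp = {g: t.fg_proportions.get(g, 0.0) for g in present_groups}
    gp_total = sum(gp.values())
    if gp_total == 0:
        gp = {g: 1.0 for g in present_groups}
        gp_total = float(len(present_groups))
    targets = np.empty(len(present_idx))
    for g in present_groups:
        idx = [k for k, i in enumerate(present_idx) if groups[i] == g]
        w = np.array([t.dominant_weight if species[present_idx[k]] in dominants
                      else 1.0 for k in idx])
        targets[idx] = (gp[g] / gp_total) * w / w.sum()

    shape = t.biomass_dispersion * targets
    draws = rng.gamma(np.maximum(shape, 1e-9))
    if draws.sum() == 0:
        draws = np.ones_like(draws)
    shares = draws / draws.sum()

    agb_total = float(rng.lognormal(np.log(t.agb_median), t.agb_log_sd))
    biomass = {species[i]: float(shares[k] * agb_total)
               for k, i in enumerate(present_idx)}

    cov = {
        c: _truncated_normal(rng, t.soil_means[c], t.soil_sds[c], *_BOUNDS[c])
        for c in _COVARIATES
    }
    return QuadratRecord(
        quadrat_id=quadrat_id,
        transect_id=transect_id,
        stage=t.stage,
        species_biomass=biomass,
        agb=agb_total,
        **cov,
    )


def generate_survey(config: GeneratorConfig) -> SurveyTable:
    """Draw a full survey; the true stage is carried on each record.

    Fully reproducible from ``config.rng_seed``; downstream stage-recovery
    scoring compares clustered labels against the carried stage field.
    """
    rng = np.random.default_rng(config.rng_seed)
    records = []
    for t in sorted(config.templates, key=lambda t: t.stage):
        for q in range(config.n_quadrats_per_stage):
            qid = f"S{t.stage}-Q{q + 1:03d}"
            tid = f"S{t.stage}-T{q // 3 + 1:02d}"  # three quadrats per strip point
            records.append(_draw_quadrat(rng, t, qid, tid))
    universe: dict[str, None] = {}
    for t in sorted(config.templates, key=lambda t: t.stage):
        for s in t.species_pool:
            universe.setdefault(s)
    return SurveyTable(records, species_universe=list(universe))
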