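"""End-to-end pipeline: simulate/load -> community -> stages -> coupling ->
multifunctionality -> inference, with a reproducible run manifest.

A single seed fans out to per-module child seeds through
``numpy.random.SeedSequence(seed).generate_state(...) % 2**31`` so each
module can be re-run in isolation with the seed recorded in the manifest.
Any stage failure aborts with a stage-named error and moves partial outputs
to a ``quarantine/`` subdirectory.
"""

from __future__ import annotations

import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as community_mod
from . import coupling as coupling_mod
from . import inference as inference_mod
from . import multifunction as multifunction_mod
from . import stages as stages_mod
from .io import (
    AnalysisConfig,
    FunctionalGroupMap,
    SurveyTable,
    ValidationError,
    read_survey_table,
    write_results,
    write_survey_table,
)
from .simulate import (
    GeneratorConfig,
    default_functional_group_map,
    default_stage_templates,
    generate_survey,
)

__all__ = ["child_seeds", "run_pipeline"]

logger = logging.getLogger(__name__)

#: variables contrasted across recovered stages
CONTRAST_VARIABLES = (
    "sr", "ev", "agb", "bgb", "plant_density", "plant_height",
    "sbd", "sm", "st", "stc", "stn", "stp", "sts",
    "PGI", "SCI", "SNI", "EMF", "D", "toxic_share",
)

#: default predictor set for the relative-importance decomposition
IMPORTANCE_PREDICTORS = (
    "sr", "ev", "sm", "st", "sbd", "stc", "stn", "stp", "sts", "toxic_share",
)

_PLANT_DISTANCE_VARS = ("agb", "bgb", "plant_density", "plant_height", "sr")
_SOIL_DISTANCE_VARS = ("sbd", "sm", "st", "stc", "stn", "stp", "sts")


def child_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-module seeds derived from one run seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _stage_frame(table: SurveyTable, fgmap: FunctionalGroupMap,
                 config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-quadrat analysis frame (+ recovered stage) and stage table."""
    frame = community_mod.analysis_frame(table, fgmap)
    assignment = stages_mod.assign_stages(table, fgmap, config.n_clusters)
    stage_df = assignment.to_frame()
    frame["recovered_stage"] = stage_df["stage"]
    return frame, stage_df


def run_pipeline(
    out_dir: str | Path,
    survey_path: str | Path | None = None,
    generator_config: GeneratorConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    fgmap: FunctionalGroupMap | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full analysis; returns the run manifest.

    Exactly one of ``survey_path`` (read an existing survey CSV) or
    ``generator_config`` (simulate one; ``None`` with no survey path uses
    the default templates) supplies the data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = analysis_config or AnalysisConfig()
    if seed is None:
        seed = config.rng_seed
    gen_seed, mantel_seed, *_ = child_seeds(seed)

    stage_name = "setup"
    try:
        stage_name = "simulate/load"
        if survey_path is not None:
            table = read_survey_table(survey_path, layout="wide")
        else:
            gc = generator_config or GeneratorConfig(
                templates=default_stage_templates(), rng_seed=gen_seed)
            table = generate_survey(gc)
            write_survey_table(table, out_dir / "survey.csv")
            pd.DataFrame(
                {"quadrat_id": [r.quadrat_id for r in table.records],
                 "true_stage": [r.stage for r in table.records]}
            ).to_csv(out_dir / "truth.csv", index=False)
        if fgmap is None:
            fgmap = default_functional_group_map()
        fgmap.check_covers(
            sp for rec in table.records
            for sp, b in rec.species_biomass.items() if b > 0)
        logger.info("%s: %d quadrats, %d species",
                    stage_name, len(table), len(table.species_universe))

        stage_name = "community"
        summ = community_mod.community_summary(table, fgmap)

        stage_name = "stages"
        frame, stage_df = _stage_frame(table, fgmap, config)
        logger.info("stages: %d clusters", stage_df["stage"].nunique())

        stage_name = "coupling"
        missing = [f for f in config.emf_functions if f not in frame.columns]
        if missing:
            raise ValidationError(f"survey lacks EMF function column(s): {missing}")
        coupling_df = coupling_mod.coupling_table(
            frame, spec=config.subsystem_spec, variant=config.coupling_variant)

        stage_name = "multifunction"
        emf_df = multifunction_mod.multifunction_table(
            frame, functions=config.emf_functions,
            index_groups=config.index_groups)

        stage_name = "inference"
        full = frame.join(coupling_df[["S", "P", "C", "T", "D"]]).join(
            emf_df[["PGI", "SCI", "SNI", "EMF"]])
        groups = full["recovered_stage"].to_numpy()

        contrast_rows, tukey_rows = [], []
        for var in CONTRAST_VARIABLES:
            if var not in full.columns:
                continue
            res = inference_mod.anova_tukey(full[var].to_numpy(), groups,
                                            variable=var)
            for grp, row in res.group_stats.iterrows():
                contrast_rows.append({
                    "variable": var, "stage": grp, "mean": row["mean"],
                    "sd": row["sd"], "n": row["n"],
                    "F": res.f_statistic, "p": res.p_value,
                    "letters": res.letters[grp]})
            t = res.tukey.copy()
            t.insert(0, "variable", var)
            tukey_rows.append(t)
        contrasts = pd.DataFrame(contrast_rows)
        tukey = pd.concat(tukey_rows, ignore_index=True)

        reg_rows = []
        pooled = inference_mod.simple_regression(full["D"], full["EMF"])
        reg_rows.append({"scope": "pooled", "x": "D", "y": "EMF",
                         **vars(pooled)})
        for s in sorted(set(groups.tolist())):
            sub = full[full["recovered_stage"] == s]
            if len(sub) >= 3 and np.var(sub["D"]) > 0:
                r = inference_mod.simple_regression(sub["D"], sub["EMF"])
                reg_rows.append({"scope": f"stage_{s}", "x": "D", "y": "EMF",
                                 **vars(r)})
            if len(sub) >= 3 and np.var(sub["toxic_share"]) > 0:
                for yvar in ("D", "EMF"):
                    r = inference_mod.simple_regression(sub["toxic_share"], sub[yvar])
                    reg_rows.append({"scope": f"stage_{s}", "x": "toxic_share",
                                     "y": yvar, **vars(r)})
        regressions = pd.DataFrame(reg_rows)

        d_plant = inference_mod.zscore_euclidean_distance(
            full[list(_PLANT_DISTANCE_VARS)])
        d_soil = inference_mod.zscore_euclidean_distance(
            full[list(_SOIL_DISTANCE_VARS)])
        mres = inference_mod.mantel_test(
            d_plant, d_soil, n_permutations=config.n_permutations,
            seed=mantel_seed)
        mantel = pd.DataFrame([{
            "comparison": "plant_vs_soil", "r": mres.r, "p": mres.p_value,
            "n_permutations": mres.n_permutations, "seed": mantel_seed}])

        corr_cols = ["sr", "ev", "PGI", "SCI", "SNI", "EMF", "D"]
        rmat, pmat, _flagged = inference_mod.correlation_matrix(full[corr_cols])
        correlations = rmat.reset_index(names="variable")

        imp_rows = []
        predictors = [p for p in IMPORTANCE_PREDICTORS if p in full.columns]
        for yvar in ("D", "EMF"):
            imp = inference_mod.lmg_importance(full[predictors], full[yvar])
            for pred, share in imp.shares.items():
                imp_rows.append({"response": yvar, "predictor": pred,
                                 "share": share, "r_squared": imp.r_squared})
        importance = pd.DataFrame(imp_rows)

        stage_name = "write"
        tables = {
            "community": summ.reset_index(),
            "stages": stage_df.reset_index(),
            "coupling": coupling_df.reset_index(),
            "emf": emf_df.reset_index(),
            "contrasts": contrasts,
            "tukey": tukey,
            "regressions": regressions,
            "mantel": mantel,
            "correlations": correlations,
            "importance": importance,
        }
        manifest = write_results(tables, out_dir, config=config, seed=seed)
        manifest["child_seeds"] = {"generator": gen_seed, "mantel": mantel_seed}
        return manifest
    except Exception as exc:
        quarantine = out_dir / "quarantine"
        quarantine.mkdir(exist_ok=True)
        for f in out_dir.iterdir():
            if f.is_file():
                shutil.move(str(f), quarantine / f.name)
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc
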