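import numpy as np
import pytest

from meadowsucc.io import FunctionalGroupMap, QuadratRecord, SurveyTable
from meadowsucc.simulate import (
    GeneratorConfig,
    default_functional_group_map,
    default_stage_templates,
    generate_survey,
)

_COV = dict(bgb=200.0, plant_density=80.0, plant_height=9.0, sbd=1.0,
            sm=27.0, st=11.0, stc=45.0, stn=4.0, stp=0.7, sts=0.8)


def make_record(qid="Q1", species=None, stage=None, **overrides):
    cov = {**_COV, **overrides}
    return QuadratRecord(
        quadrat_id=qid, stage=stage,
        species_biomass=dict(
            species if species is not None
            else {"Kobresia sp01": 3.0, "Poa sp01": 1.0}),
        **cov,
    )


@pytest.fixture(scope="session")
def templates():
    return default_stage_templates()


@pytest.fixture(scope="session")
def fgmap(templates):
    return default_functional_group_map(templates)


@pytest.fixture(scope="session")
def survey(templates):
    """Default-template survey, 30 quadrats per stage, fixed seed."""
    return generate_survey(GeneratorConfig(templates=templates, rng_seed=42))


@pytest.fixture()
def tiny_table():
    recs = [
        make_record("Q1", {"A": 3.0, "B": 1.0}, stage=1),
        make_record("Q2", {"B": 2.0, "C": 2.0}, stage=1, sbd=1.1),
        make_record("Q3", {"C": 5.0}, stage=2, sbd=1.2, stn=3.0),
        make_record("Q4", {"A": 1.0, "C": 1.0}, stage=2, sbd=0.9, stn=5.0),
    ]
    return SurveyTable(recs)


@pytest.fixture()
def tiny_fgmap():
    return FunctionalGroupMap(
        {"A": "sedge", "B": "grass", "C": "toxic_forb"})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
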