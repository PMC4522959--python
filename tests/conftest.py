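import logging

import numpy as np
import pytest

from popsurvey.pipeline import SurveyConfig, run_pipeline
from popsurvey.synthetic import SurveyPlan, generate_survey

logging.getLogger("popsurvey").setLevel(logging.ERROR)


def small_plan() -> SurveyPlan:
    """A scaled-down survey for fast plumbing tests (4 subtypes, 6 genomes)."""
    return SurveyPlan(
        n_subtypes=4, seqs_per_subtype=6, n_genomes=6, n_lineages=2,
        n_dpp=3, n_opb=2, n_acc=3, n_abh=4, n_partial=4, n_propeller_only=2,
        n_twilight=2, n_transferred=6, n_signal=4, n_tm=4, genome_size=24,
    )


def small_config(seed: int = 5) -> SurveyConfig:
    return SurveyConfig(seed=seed, bootstrap_reps=150, calibration_samples=1000)


@pytest.fixture(scope="session")
def small_survey():
    return generate_survey(small_plan(), seed=5)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """(config, rundir, survey, manifest) for the scaled-down survey."""
    rundir = tmp_path_factory.mktemp("small_run")
    config = small_config()
    manifest = run_pipeline(config, rundir, plan=small_plan())
    survey = generate_survey(small_plan(), seed=config.seed)
    return config, rundir, survey, manifest


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """(config, rundir, survey, manifest) for the default (study) survey."""
    rundir = tmp_path_factory.mktemp("full_run")
    config = SurveyConfig(seed=11)
    manifest = run_pipeline(config, rundir, plan=SurveyPlan())
    survey = generate_survey(SurveyPlan(), seed=config.seed)
    return config, rundir, survey, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
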