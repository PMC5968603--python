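import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from plysim import (
    GeneratorConfig,
    RunConfig,
    UpratingRule,
    calibrate_to_benchmarks,
    generate_benchmarks,
    generate_donor_pool,
    generate_population,
    generate_survey,
    impute_economics,
    run_pipeline,
    uprate_profile,
)
from plysim.synthetic import ECON_COLUMNS, PERSON_COLUMNS

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def population(default_cfg) -> pd.DataFrame:
    """Full default-size synthetic population with latent economics."""
    return generate_population(default_cfg)


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    return generate_population(GeneratorConfig(n_records=3000, seed=7))


@pytest.fixture(scope="session")
def imputed_default(default_cfg) -> pd.DataFrame:
    """Default survey imputed from the default donor pool (base-year $)."""
    survey = generate_survey(default_cfg)
    donors = generate_donor_pool(default_cfg)
    imputed, audit = impute_economics(survey, donors, seed=11)
    imputed.attrs["fallback_audit"] = audit
    return imputed


@pytest.fixture(scope="session")
def calibrated_2015(default_cfg, imputed_default) -> pd.DataFrame:
    """Default population uprated to 2015 and calibrated to its benchmarks."""
    bench = generate_benchmarks(default_cfg, [2015])[2015]
    persons = imputed_default.copy()
    persons[ECON_COLUMNS] = uprate_profile(imputed_default[ECON_COLUMNS], UpratingRule(), 2015)
    persons, results = calibrate_to_benchmarks(persons, bench)
    persons.attrs["calibration"] = results
    persons.attrs["benchmark"] = bench
    return persons


@pytest.fixture(scope="session")
def pipeline_results():
    """A full but bootstrap-light pipeline run over the first and last year."""
    cfg = RunConfig(years=(2015, 2030), bootstrap_reps=40, seed=99)
    return run_pipeline(cfg)
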