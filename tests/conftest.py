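import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from cloudprobit.data_model import (assemble_analysis_table, filter_cohort,
                                    link_exposures)
from cloudprobit.probit import ModelSpec
from cloudprobit.sampler import SamplerConfig, run_sampler
from cloudprobit.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant synthetic study with its assembled analysis table."""
    cfg = GeneratorConfig(n_participants=60, seed=42)
    data = generate_dataset(cfg)
    inc = filter_cohort(data["baselines"], data["reports"])
    b = data["baselines"][data["baselines"].participant_id.isin(inc)]
    r = data["reports"][data["reports"].participant_id.isin(inc)]
    p = data["pings"][data["pings"].participant_id.isin(inc)]
    exposures = link_exposures(p, data["stations"], data["observations"])
    table, scaling = assemble_analysis_table(b, r, exposures)
    return {**data, "included": inc, "baselines_inc": b, "reports_inc": r,
            "exposures": exposures, "table": table, "scaling": scaling}


@pytest.fixture(scope="session")
def fitted(small_cohort):
    """A converged-enough fit of the small cohort, reused across tests."""
    table = small_cohort["table"]
    spec = ModelSpec()
    draws = run_sampler(table, spec,
                        SamplerConfig(n_chains=2, n_warmup=400, n_keep=400, seed=9))
    return {"draws": draws, "spec": spec, "table": table,
            "truth": small_cohort["truth"]}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
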