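import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aeikit as ak
from aeikit.aei_quant import usable_aei

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper_like cohort at a fixed seed, with its quantified AEI table."""
    cfg = ak.preset_config("paper_like", seed=7)
    cohort = ak.simulate_cohort(cfg)
    aei = usable_aei(ak.quantify(cohort.peaks, cohort.genotypes, cfg.amplicons))
    return cfg, cohort, aei


@pytest.fixture(scope="session")
def gwas_cohort():
    """One gwas_like cohort (two loci, n=1000) at a fixed seed."""
    cfg = ak.preset_config("gwas_like", seed=11)
    return cfg, ak.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
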