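import pandas as pd
import pytest
from hypothesis import settings

from pawmeth import dm, synthdata as sd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def planted_array():
    """Array experiment with 10% planted effects at |dM| = 3 on 4+4 samples."""
    spec = sd.ArraySimSpec(n_probes=3000, frac_dm=0.1, effect_mean=3.0, seed=1)
    exp, truth, manifest = sd.gen_array_experiment(spec)
    return spec, exp, truth, manifest


@pytest.fixture(scope="session")
def null_array():
    """Array experiment with no planted effect (type-I calibration)."""
    spec = sd.ArraySimSpec(n_probes=2000, frac_dm=0.0, seed=7)
    exp, truth, manifest = sd.gen_array_experiment(spec)
    return spec, exp, truth, manifest


@pytest.fixture(scope="session")
def reference_cohort():
    return sd.reference_cohort(seed=0)


@pytest.fixture()
def tiny_experiment():
    """Hand-sized 100-probe experiment with 10 planted detection failures."""
    spec = sd.ArraySimSpec(
        n_probes=100, frac_detectable=1.0, frac_dm=0.0, seed=11
    )
    exp, truth, _ = sd.gen_array_experiment(spec)
    bad = exp.beta.index[:10]
    detp = exp.detection_p.copy()
    detp.loc[bad, exp.beta.columns[0]] = 0.5  # 1 of 8 samples = 12.5% >= 5%
    return dm.BetaExperiment(exp.beta, detp, exp.bead_count, exp.samples), bad
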