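import numpy as np
import pytest

from metpair import synthetic_cohort as sc
from metpair import ccf_clonality as cc
from metpair import variant_filtering as vf


@pytest.fixture(scope="session")
def signatures():
    return sc.synthetic_signatures(5)


@pytest.fixture(scope="session")
def sim_config():
    return sc.SimConfig()


@pytest.fixture(scope="session")
def mono_patient(sim_config, signatures):
    bundle, truth = sc.simulate_patient(sim_config, seed=101,
                                        signatures=signatures)
    return bundle, truth


@pytest.fixture(scope="session")
def poly_patient(signatures):
    cfg = sc.SimConfig(seeding_mode="polyclonal")
    bundle, truth = sc.simulate_patient(cfg, seed=202, signatures=signatures)
    return bundle, truth


def _fit_patient(bundle, seed=7):
    """Filter a patient's mutations and fit the clone model."""
    purity = {m.sample_id: m.purity for m in bundle.meta if m.role != "normal"}
    kept_p, _ = vf.apply_filters(bundle.mutations_of(bundle.primary_id))
    kept_m, _ = vf.apply_filters(bundle.mutations_of(bundle.metastasis_id))
    model = cc.CloneModel.from_mutations(kept_p + kept_m, purity,
                                         bundle.segments)
    return model, model.fit(seed=seed), kept_p, kept_m


@pytest.fixture(scope="session")
def fit_patient():
    return _fit_patient


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
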