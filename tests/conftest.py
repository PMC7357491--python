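import warnings

import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

import rhizorank as rr

hypothesis_settings.register_profile("derandomized", derandomize=True)
hypothesis_settings.load_profile("derandomized")


@pytest.fixture(autouse=True)
def _quiet_mixedlm():
    """Mixed-model convergence chatter is irrelevant to the assertions."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        warnings.filterwarnings("ignore", module="statsmodels.*")
        yield


@pytest.fixture
def zero_noise_cfg():
    return rr.SyntheticConfig(seed=1).with_noise(0.0)


@pytest.fixture(scope="session")
def zero_noise_study():
    """Deterministic noiseless campaign: estimation must recover the
    configured truths exactly."""
    cfg = rr.SyntheticConfig(seed=1).with_noise(0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, est, rank = rr.run_full_study(cfg)
    return bundle, est, rank


@pytest.fixture(scope="session")
def default_study():
    """One default-noise campaign shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, est, rank = rr.run_full_study(rr.SyntheticConfig(seed=11))
    return bundle, est, rank


def long_rows(records):
    """Helper: AssayTable from terse (strain, cond, unit, rep, t, value) rows."""
    rows = [{"strain": s, "assay": "toy", "condition": c, "unit": u,
             "replicate": r, "time_h": t, "value": v, "value_kind": "od"}
            for s, c, u, r, t, v in records]
    return rr.AssayTable(pd.DataFrame(rows))
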