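import numpy as np
import pytest

from ppgfid import case_params, simulate_beat, simulate_record


@pytest.fixture(scope="session")
def beat_case_iii():
    """Noiseless sampled Case III beat plus its continuous-model truth."""
    return simulate_beat(case_params("III"))


@pytest.fixture(scope="session")
def beats_all_cases():
    return {case: simulate_beat(case_params(case)) for case in ("I", "II", "III")}


@pytest.fixture(scope="session")
def clean_record():
    """One noiseless drift-free record with truth for its single full beat."""
    rec, truths = simulate_record(1, case_params("II"), noise_sd=0.0, drift=(0.0, 0.0), seed=0)
    return rec, truths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
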