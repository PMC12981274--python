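import numpy as np
import pytest

from cdr3bench.binding import assign_effects, calibrate_scale
from cdr3bench.seqsim import default_pwm, one_hot_encode, sample_sequences


@pytest.fixture(scope="session")
def pwm():
    return default_pwm()


@pytest.fixture(scope="session")
def seqs10k(pwm):
    return sample_sequences(pwm, 10_000, seed=1)


@pytest.fixture(scope="session")
def all_columns(seqs10k):
    return one_hot_encode(seqs10k).columns


@pytest.fixture(scope="session")
def calibrated_spec(pwm, all_columns):
    """A standard calibrated effect spec: 5 mains, one pair, strength 8."""
    spec = assign_effects(all_columns, orders=(2,), hierarchy="strong", strength=8.0, seed=3)
    return calibrate_scale(spec, pwm, mc_n=50_000, seed=7)
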