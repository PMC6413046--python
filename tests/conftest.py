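import numpy as np
import pytest

import tripepqsar as tq

#: the seven integrated-matrix outliers reported for the FTC dataset
FTC_OUTLIERS = [181, 183, 182, 134, 151, 153, 188]


@pytest.fixture(scope="session")
def ftc():
    return tq.load_ftc()


@pytest.fixture(scope="session")
def frap():
    return tq.load_frap(drop_inactive=True)


@pytest.fixture(scope="session")
def ftc_integrated(ftc):
    return ftc.encode()


@pytest.fixture(scope="session")
def frap_integrated(frap):
    return frap.encode()


@pytest.fixture(scope="session")
def ftc_cleaned(ftc_integrated):
    """FTC integrated matrix with the seven reported outliers removed."""
    return ftc_integrated.drop_samples(FTC_OUTLIERS)


@pytest.fixture(scope="session")
def small_synth():
    """Small clean synthetic dataset shared by fast unit tests."""
    spec = tq.SyntheticSpec(n_peptides=60, scales=("Z-scale", "VHSE"),
                            n_signal_variables=5, noise_sd=0.2, seed=7)
    return tq.generate(spec)


def loo_q2_max(X, y, max_components=20):
    q2 = tq.cross_validate(X, y, tq.CVScheme(), max_components)
    return float(np.max(q2))
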