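import numpy as np
import pytest

from paneltri import (MoslaParams, REFERENCE_MOSLA, PanelLayout, SampleMoments,
                      mosla_implied_cov)


@pytest.fixture(scope="session")
def layout():
    return PanelLayout(T=3)


@pytest.fixture(scope="session")
def mosla_params():
    """The package's reference spurious-world parameter set."""
    return MoslaParams(n=400, seed=0, **REFERENCE_MOSLA)


@pytest.fixture(scope="session")
def mosla_population_moments(mosla_params):
    """Analytic population covariance of the reference spurious world."""
    cov, names = mosla_implied_cov(mosla_params)
    return SampleMoments(cov=cov, mean=np.zeros(len(names)), n=400, var_names=names)
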