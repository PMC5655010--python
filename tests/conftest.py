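import numpy as np
import pytest

from ricianreg import (
    MCMCConfig,
    NoiseModel,
    PriorSpec,
    SimulationDesign,
    make_multishell_scheme,
    simulate_dti_voxel,
    simulate_regression,
)


def bessel_i_series(nu, x, terms=50):
    """Independent oracle: ascending-series evaluation of I_nu(x)."""
    from scipy.special import gammaln

    k = np.arange(terms)
    logs = (2 * k + nu) * np.log(x / 2.0) - gammaln(k + 1.0) - gammaln(k + nu + 1.0)
    return float(np.sum(np.exp(logs)))


@pytest.fixture
def rician():
    return NoiseModel("rician")


@pytest.fixture
def small_dataset():
    """n=60 Rician regression set with one strong and one null predictor."""
    design = SimulationDesign(n=60, beta=np.array([0.5, 0.0]),
                              alpha=np.array([0.3]), beta0=1.5, alpha0=-1.0,
                              seed=11)
    return simulate_regression(design)


@pytest.fixture
def flat_prior():
    def make(p, q, m_beta0=1.0, m_alpha0=-1.0):
        return PriorSpec(
            m_beta0=m_beta0, s2_beta0=4.0, m_alpha0=m_alpha0, s2_alpha0=4.0,
            Sigma_beta=np.eye(p) if p else np.empty((0, 0)),
            Sigma_alpha=np.eye(q) if q else np.empty((0, 0)),
            c=100.0,
        )

    return make


@pytest.fixture
def dti_voxel():
    """A synthetic anisotropic voxel at moderate SNR with its ground truth."""
    scheme = make_multishell_scheme((16, 16, 16, 16))
    D = np.diag([1.7e-3, 3e-4, 3e-4])
    y, mu, phi = simulate_dti_voxel(D, 1.0, scheme, NoiseModel("rician"),
                                    alpha0=float(np.log(0.0025)), seed=5)
    return {"y": y, "mu": mu, "phi": phi, "scheme": scheme, "D": D, "S0": 1.0}


@pytest.fixture
def quick_cfg():
    return MCMCConfig(n_iter=900, n_burnin=300, seed=7)
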