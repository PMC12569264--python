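import numpy as np
import pytest

from causalfp import CausalSignature, PartitionSpec, simulate_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stable_signature(rng, m=5, n=2, dt=0.72, rho=0.9, q_scale=0.3):
    """Random signature with diag(Q)=0 and spectral radius of (I-Q)^-1 A = rho."""
    Q = rng.normal(0.0, q_scale / np.sqrt(m), (m, m))
    np.fill_diagonal(Q, 0.0)
    A = rng.normal(0.0, 1.0 / np.sqrt(m), (m, m))
    A_hat = np.linalg.solve(np.eye(m) - Q, A)
    A *= rho / np.max(np.abs(np.linalg.eigvals(A_hat)))
    B1 = rng.normal(size=(m, n))
    B2 = rng.normal(size=(m, n))
    return CausalSignature(Q=Q, A=A, B1=B1, B2=B2, dt=dt)


@pytest.fixture
def stable_signature(rng):
    return make_stable_signature(rng)


def simulate_from(sig, rng, T=400, noise_sd=0.0, seed=0):
    U = rng.normal(size=(sig.n, T + 1))
    x0 = rng.normal(size=sig.m)
    return simulate_trajectory(sig, U, x0, noise_sd=noise_sd, seed=seed)


def full_partition(sig):
    return PartitionSpec(
        state_idx=list(range(sig.m)), input_idx=list(range(sig.m, sig.m + sig.n))
    )
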