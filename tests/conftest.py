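import numpy as np
import pytest

import hpenet as h


@pytest.fixture(scope="session")
def sparse_var2_truth():
    """A known sparse stable VAR with genuine lag-2 content."""
    A = np.zeros((2, 5, 5))
    np.fill_diagonal(A[0], [0.4, 0.35, 0.45, 0.3, 0.4])
    # off-diagonal couplings: lag-1 and lag-2
    A[0][1, 0] = 0.4
    A[0][2, 1] = -0.4
    A[1][3, 2] = 0.35
    A[1][4, 0] = -0.35
    model = h.VARModel(A=A, Sigma=np.eye(5))
    assert model.is_stable()
    return model


@pytest.fixture(scope="session")
def standardized_session(sparse_var2_truth):
    """A study-length (L = 1440) standardized simulation of the truth."""
    sim = h.simulate_var(sparse_var2_truth, 1440, seed=42)
    return h.standardize(sim)


@pytest.fixture(scope="session")
def bivariate_coupled():
    """X1 white noise, X2(t) = X1(t-1) + w2: the closed-form cTE example."""
    A = np.zeros((1, 2, 2))
    A[0, 1, 0] = 1.0
    return h.VARModel(A=A, Sigma=np.eye(2))
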