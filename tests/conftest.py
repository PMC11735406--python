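import numpy as np
import pytest

from dfine.model import LDMParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stable_ldm(rng, n_x=2, n_a=2):
    """A random LDM with stable dynamics and well-conditioned noise."""
    A = rng.normal(0, 0.4, (n_x, n_x))
    A *= 0.9 / max(1.0, np.abs(np.linalg.eigvals(A)).max())
    C = rng.normal(0, 1, (n_a, n_x))
    Wm = rng.normal(0, 0.6, (n_x, n_x))
    Rm = rng.normal(0, 0.6, (n_a, n_a))
    return LDMParams(
        A=A, W=Wm @ Wm.T + 0.2 * np.eye(n_x), C=C,
        R=Rm @ Rm.T + 0.2 * np.eye(n_a),
        mu0=rng.normal(0, 1, n_x), Lambda0=0.5 * np.eye(n_x),
    )


def joint_gaussian_conditional(ldm, a_seq, upto=None):
    """Brute-force oracle: condition the full joint Gaussian of x_{1:T} on a_{1:k}.

    Builds the exact joint covariance of states and manifold observations and
    returns the conditional mean of all states given observations up to `upto`
    (inclusive, 0-based; default all).
    """
    T, n_a = a_seq.shape
    n_x = ldm.A.shape[0]
    means = [ldm.mu0]
    Ps = [ldm.Lambda0]
    for _ in range(1, T):
        means.append(ldm.A @ means[-1])
        Ps.append(ldm.A @ Ps[-1] @ ldm.A.T + ldm.W)
    mean_x = np.concatenate(means)
    cov_x = np.zeros((n_x * T, n_x * T))
    for t in range(T):
        for s in range(t, T):
            blk = Ps[t] @ np.linalg.matrix_power(ldm.A, s - t).T
            cov_x[t * n_x:(t + 1) * n_x, s * n_x:(s + 1) * n_x] = blk
            cov_x[s * n_x:(s + 1) * n_x, t * n_x:(t + 1) * n_x] = blk.T
    Cb = np.kron(np.eye(T), ldm.C)
    mean_a = Cb @ mean_x
    cov_aa = Cb @ cov_x @ Cb.T + np.kron(np.eye(T), ldm.R)
    cov_xa = cov_x @ Cb.T
    k = T if upto is None else upto + 1
    m = k * n_a
    sol = np.linalg.solve(cov_aa[:m, :m], a_seq.ravel()[:m] - mean_a[:m])
    cond = mean_x + cov_xa[:, :m] @ sol
    return cond.reshape(T, n_x)
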