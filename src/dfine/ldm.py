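"""Exact linear-Gaussian inference on the (x, a) layer.

Kalman filtering, Rauch-Tung-Striebel smoothing and k-step-ahead prediction,
all tolerant of missing observations: at a masked timestep the measurement
update is skipped and the filter carries the one-step prediction forward, so
no values are ever imputed.

Covariance updates use the Joseph stabilized form with explicit
symmetrization; innovation covariances are inverted via Cholesky with a small
jitter fallback. Time is indexed 1..T in the docstrings (matching y_{1:T});
storage is 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .exceptions import DataError, InvalidModelError
from .model import LDMParams

__all__ = ["FilterResult", "SmoothResult", "kalman_filter", "kalman_smoother",
           "k_step_predict"]

_JITTER = 1e-9


@dataclass
class FilterResult:
    """Forward-pass posteriors: x_{t|t}, P_{t|t} and predictions x_{t|t-1}, P_{t|t-1}."""

    x_filt: np.ndarray    # (T, n_x)
    P_filt: np.ndarray    # (T, n_x, n_x)
    x_pred: np.ndarray    # (T, n_x), x_{t|t-1} with x_{1|0} = mu0
    P_pred: np.ndarray    # (T, n_x, n_x)
    mask: np.ndarray      # (T,) bool, True = observed
    innovations: np.ndarray | None = None  # (T, n_a), NaN at masked steps

    @property
    def T(self) -> int:
        return self.x_filt.shape[0]


@dataclass
class SmoothResult:
    """Backward-pass posteriors x_{t|T} and derived manifold factors."""

    x_smooth: np.ndarray   # (T, n_x)
    P_smooth: np.ndarray   # (T, n_x, n_x)
    a_smooth: np.ndarray   # (T, n_a) = C x_{t|T}
    a_filt: np.ndarray     # (T, n_a) = C x_{t|t}


def _sym(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2


def _chol_solve(S: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve S X = B for symmetric PD S, adding jitter on Cholesky failure."""
    try:
        c = sla.cho_factor(S, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        warnings.warn("innovation covariance not PD; adding jitter", stacklevel=2)
        c = sla.cho_factor(S + _JITTER * np.eye(S.shape[0]), lower=True,
                           check_finite=False)
    return sla.cho_solve(c, B, check_finite=False)


def _validate_ldm(ldm: LDMParams) -> None:
    for name in ("W", "R"):
        M = getattr(ldm, name)
        if not np.allclose(M, M.T, atol=1e-9):
            raise InvalidModelError(f"{name} must be symmetric")
        if np.linalg.eigvalsh(_sym(M)).min() < -1e-9:
            raise InvalidModelError(f"{name} must be PSD")


def kalman_filter(ldm: LDMParams, a_seq: np.ndarray,
                  mask: np.ndarray | None = None,
                  init_mean: np.ndarray | None = None,
                  init_cov: np.ndarray | None = None) -> FilterResult:
    """Kalman filter over the noisy manifold-factor sequence a_seq (T, n_a).

    mask[t] = False marks a missing observation: the update is skipped there
    and x_{t|t} = x_{t|t-1}. `init_mean`/`init_cov` override (mu0, Lambda0),
    which makes streaming in chunks bit-identical to batch processing.
    """
    _validate_ldm(ldm)
    a_seq = np.asarray(a_seq, dtype=np.float64)
    if a_seq.ndim != 2 or a_seq.shape[1] != ldm.n_a:
        raise ValueError(f"a_seq must be (T, {ldm.n_a}), got {a_seq.shape}")
    T = a_seq.shape[0]
    if mask is None:
        mask = np.ones(T, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (T,):
        raise ValueError(f"mask must have shape ({T},), got {mask.shape}")
    if np.isnan(a_seq[mask]).any():
        raise DataError("NaN in observed entries of a_seq")

    A, W, C, R = ldm.A, ldm.W, ldm.C, ldm.R
    n_x, n_a = ldm.n_x, ldm.n_a
    I = np.eye(n_x)
    x_p = (ldm.mu0 if init_mean is None else np.asarray(init_mean, float)).copy()
    P_p = _sym((ldm.Lambda0 if init_cov is None else np.asarray(init_cov, float)).copy())

    x_filt = np.empty((T, n_x)); P_filt = np.empty((T, n_x, n_x))
    x_pred = np.empty((T, n_x)); P_pred = np.empty((T, n_x, n_x))
    innov = np.full((T, n_a), np.nan)
    for t in range(T):
        x_pred[t], P_pred[t] = x_p, P_p
        if mask[t]:
            S = _sym(C @ P_p @ C.T + R)
            K = _chol_solve(S, C @ P_p).T          # P C^T S^{-1}
            e = a_seq[t] - C @ x_p
            innov[t] = e
            x_f = x_p + K @ e
            IKC = I - K @ C
            P_f = _sym(IKC @ P_p @ IKC.T + K @ R @ K.T)   # Joseph form
        else:
            x_f, P_f = x_p, P_p
        x_filt[t], P_filt[t] = x_f, P_f
        x_p = A @ x_f
        P_p = _sym(A @ P_f @ A.T + W)
    return FilterResult(x_filt=x_filt, P_filt=P_filt, x_pred=x_pred,
                        P_pred=P_pred, mask=mask, innovations=innov)


def kalman_smoother(ldm: LDMParams, filt: FilterResult) -> SmoothResult:
    """Rauch-Tung-Striebel backward pass over a FilterResult.

    For T = 1 the smoother coincides with the filter. a_smooth = C x_{t|T}.
    """
    A, C = ldm.A, ldm.C
    T, n_x = filt.T, ldm.n_x
    x_s = np.empty((T, n_x)); P_s = np.empty((T, n_x, n_x))
    x_s[-1], P_s[-1] = filt.x_filt[-1], filt.P_filt[-1]
    for t in range(T - 2, -1, -1):
        P_f = filt.P_filt[t]
        P_next_pred = _sym(A @ P_f @ A.T + ldm.W)
        try:
            J = _chol_solve(P_next_pred, A @ P_f).T   # P_f A^T P_pred^{-1}
        except np.linalg.LinAlgError:
            warnings.warn("singular predicted covariance in smoother; regularizing",
                          stacklevel=2)
            J = P_f @ A.T @ np.linalg.pinv(P_next_pred)
        x_s[t] = filt.x_filt[t] + J @ (x_s[t + 1] - A @ filt.x_filt[t])
        P_s[t] = _sym(P_f + J @ (P_s[t + 1] - P_next_pred) @ J.T)
    return SmoothResult(x_smooth=x_s, P_smooth=P_s,
                        a_smooth=x_s @ C.T, a_filt=filt.x_filt @ C.T)


def k_step_predict(ldm: LDMParams, filt: FilterResult, k: int) -> np.ndarray:
    """Manifold-factor predictions a_{t+k|t} = C A^k x_{t|t} for t = 1..T-k."""
    if not (1 <= k <= filt.T - 1):
        raise ValueError(f"k must be in [1, T-1] = [1, {filt.T - 1}], got {k}")
    Ak = np.linalg.matrix_power(ldm.A, k)
    return filt.x_filt[: filt.T - k] @ (ldm.C @ Ak).T
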