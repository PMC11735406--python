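"""End-to-end inference: encoder -> Kalman recursion -> manifold factors ->
neural reconstruction / future prediction / behaviour decoding.

The same trained model serves causal filtering and non-causal smoothing. At
masked (missing) timesteps the encoder is never evaluated and the recursion
uses pure forward prediction -- no zero-imputation. Results are defined at
every timestep, including masked ones, which is the data-imputation path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import MissingComponentError
from .ldm import FilterResult, kalman_filter, kalman_smoother
from .model import DFINEModel

__all__ = ["InferenceResult", "infer_latents", "predict_one_step",
           "reconstruct_neural", "predict_behavior"]


@dataclass
class InferenceResult:
    """Latent and observation estimates for one sequence.

    x, a are x_{t|t}, a_{t|t} in filter mode and x_{t|T}, a_{t|T} in smooth
    mode; y_hat = f_theta(a) in the original observation units. dt carries the
    step size as metadata; the core is unit-agnostic.
    """

    mode: str
    x: np.ndarray
    a: np.ndarray
    y_hat: np.ndarray
    mask: np.ndarray
    filter_result: FilterResult
    y_next: np.ndarray | None = None
    dt: float = 0.05


def infer_latents(model: DFINEModel, y: np.ndarray,
                  mask: np.ndarray | None = None, mode: str = "smooth",
                  dt: float = 0.05) -> InferenceResult:
    """Infer latent factors from raw observations y (T, n_y).

    y is z-scored internally with the model's training statistics. The encoder
    runs at observed timesteps only; masked steps are bridged by the Kalman
    predictor.
    """
    if mode not in ("filter", "smooth"):
        raise ValueError(f"mode must be 'filter' or 'smooth', got {mode!r}")
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 2 or y.shape[1] != model.dims.n_y:
        raise ValueError(f"y must be (T, {model.dims.n_y}), got {y.shape}")
    T = y.shape[0]
    if mask is None:
        mask = np.ones(T, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() and mode == "smooth":
        warnings.warn("all timesteps masked; returning pure-prediction trajectory",
                      stacklevel=2)
    ldm = model.ldm()
    yz = model.normalization.apply(y)
    a_hat = np.zeros((T, model.dims.n_a))
    if mask.any():
        a_hat[mask] = model.encoder.forward_np(yz[mask])
    filt = kalman_filter(ldm, a_hat, mask=mask)
    if mode == "filter":
        x = filt.x_filt
        a = x @ ldm.C.T
    else:
        sm = kalman_smoother(ldm, filt)
        x, a = sm.x_smooth, sm.a_smooth
    y_hat = model.normalization.invert(model.decoder.forward_np(a))
    return InferenceResult(mode=mode, x=x, a=a, y_hat=y_hat, mask=mask,
                           filter_result=filt, dt=dt)


def predict_one_step(model: DFINEModel, y: np.ndarray,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Causal one-step-ahead predictions y_{t+1|t} = f_theta(C A x_{t|t}).

    Returns an array of shape (T-1, n_y) aligned with targets y[1:]; the
    prediction at row t depends only on y[0..t].
    """
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("y must be (T, n_y) with T >= 2")
    res = infer_latents(model, y, mask=mask, mode="filter")
    ldm = model.ldm()
    a_next = res.filter_result.x_filt[:-1] @ (ldm.C @ ldm.A).T
    return model.normalization.invert(model.decoder.forward_np(a_next))


def reconstruct_neural(model: DFINEModel, result: InferenceResult) -> np.ndarray:
    """y_hat = f_theta(a) per timestep, defined at masked timesteps too."""
    return model.normalization.invert(model.decoder.forward_np(result.a))


def predict_behavior(model: DFINEModel, result: InferenceResult,
                     regressor=None) -> np.ndarray:
    """Decode behaviour from inferred manifold factors.

    Uses the supervised mapper when present, otherwise an externally fitted
    regressor with a predict() method. Behaviour is never consumed as input.
    """
    if model.mapper is not None:
        return model.mapper.forward_np(result.a)
    if regressor is not None:
        return np.asarray(regressor.predict(result.a))
    raise MissingComponentError(
        "behaviour decoding needs a supervised mapper or an external regressor"
    )
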