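"""End-to-end learning of all model parameters.

The cost is the k-step-ahead prediction error: a single differentiable Kalman
filter pass turns encoder outputs a_hat = f_phi(y) into filtered states
x_{t|t}; predictions y_{t+k|t} = f_theta(C A^k x_{t|t}) are scored against
y_{t+k} for k = 1..K, plus an L2 penalty on the autoencoder weights. In
supervised mode a behaviour term lambda_beh * sum_t MSE(f_gamma(a_{t|t}), z_t)
is added and the mapper weights join the L2 penalty; inference is unchanged.

Training assumes fully observed data; observation masks are honoured at
inference time only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .autodiff import Adam, Tensor, stack
from .exceptions import DataError, MissingComponentError
from .model import DFINEModel, Normalization

__all__ = [
    "TrainingConfig", "TrainHistory", "compute_loss", "compute_supervised_loss",
    "train", "zscore_fit", "zscore_apply", "crossval_split",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the k-step-ahead training problem.

    K is chosen so that K * dt covers at least 100 ms of future; at the 50 ms
    step size this means K = 2-4. lr, epochs, lambda_reg and lambda_beh default
    to 0.02, 200, 0.002 and 20.
    """

    K: int = 2
    lr: float = 0.02
    epochs: int = 200
    lambda_reg: float = 0.002
    lambda_beh: float = 20.0
    batch_len: int = 200
    batch_size: int = 32
    seed: int = 0
    supervised: bool = False
    hidden: tuple[int, ...] = (32, 32, 32)
    learn_initial: bool = True        # whether (mu0, Lambda0) receive gradients
    behavior_from: str = "filtered"   # "filtered" a_{t|t} or "encoder" a_hat_t
    lr_decay: float | None = None     # optional per-epoch multiplicative decay
    checkpoint_every: int | None = None
    calibrate: bool = True            # EM refinement of noise covariances after training

    def __post_init__(self):
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        self.hidden = tuple(self.hidden)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden"] = list(self.hidden)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "TrainingConfig":
        with open(path) as f:
            if path.endswith(".json"):
                return cls.from_dict(json.load(f))
            return cls.from_dict(yaml.safe_load(f))


@dataclass
class TrainHistory:
    """Per-epoch diagnostics."""

    loss: list[float] = field(default_factory=list)
    val_nrmse: list[float] = field(default_factory=list)
    param_norm: list[float] = field(default_factory=list)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame({
            "epoch": np.arange(len(self.loss)),
            "loss": self.loss,
            "val_nrmse": self.val_nrmse if self.val_nrmse else np.nan,
            "param_norm": self.param_norm,
        }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# differentiable filter + loss graph
# ---------------------------------------------------------------------------

def _filtered_states(model: DFINEModel, y_batch: np.ndarray):
    """Run the differentiable Kalman filter on a fully observed batch.

    Returns (X, parts) where X is a (B, T, n_x) Tensor of x_{t|t} and parts
    holds the in-graph A, C and encoder output for reuse by the loss terms.
    """
    B, T, n_y = y_batch.shape
    n_x, n_a = model.dims.n_x, model.dims.n_a
    A, C = model.A, model.C
    W = model.log_w.exp().diag()
    R = model.log_r.exp().diag()
    P = model.log_lambda0.exp().diag()
    I_x = Tensor(np.eye(n_x))

    a_hat = model.encoder.forward(Tensor(y_batch))  # (B, T, n_a)

    # gain recursion is data-independent: compute once, shared by the batch
    gains = []
    for _ in range(T):
        S = C @ P @ C.T + R
        K = P @ C.T @ S.inv()
        gains.append(K)
        P_upd = (I_x - K @ C) @ P
        P_upd = (P_upd + P_upd.T) * 0.5
        P = A @ P_upd @ A.T + W
    x = model.mu0.reshape(1, n_x)
    xs = []
    for t in range(T):
        e = a_hat[:, t] - x @ C.T
        x = x + e @ gains[t].T
        xs.append(x)
        if t < T - 1:
            x = x @ A.T
    X = stack(xs, axis=1)  # (B, T, n_x)
    return X, {"A": A, "C": C, "a_hat": a_hat}


def _prediction_loss(model: DFINEModel, y_batch: np.ndarray, X, parts,
                     K_horizon: int):
    """sum_{k=1..K} sum_t MSE(y_{t+k|t}, y_{t+k}) with MSE over batch and dims."""
    B, T, n_y = y_batch.shape
    A, C = parts["A"], parts["C"]
    loss = None
    Ak = None
    for k in range(1, K_horizon + 1):
        Ak = A if Ak is None else Ak @ A
        a_pred = X[:, : T - k] @ Ak.T @ C.T           # (B, T-k, n_a)
        y_pred = model.decoder.forward(a_pred)        # (B, T-k, n_y)
        err = y_pred - Tensor(y_batch[:, k:])
        term = err.square().mean(axis=0).mean(axis=1).sum()
        loss = term if loss is None else loss + term
    return loss


def _as_batch(batch, attr="y") -> np.ndarray:
    if hasattr(batch, attr):
        arr = getattr(batch, attr)
    elif attr == "y":
        arr = batch
    else:
        raise DataError(f"batch has no '{attr}' data")
    if arr is None:
        raise DataError(f"batch has no '{attr}' data")
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"batch {attr} must be (B, T, n) or (T, n), got {arr.shape}")
    if np.isnan(arr).any():
        raise DataError(f"NaN in training {attr}; training requires fully observed data")
    return arr


def compute_loss(model: DFINEModel, batch, config: TrainingConfig):
    """Unsupervised k-step-ahead prediction loss (a scalar autodiff Tensor)."""
    y = _as_batch(batch, "y")
    if y.shape[1] <= config.K:
        raise ValueError(
            f"segment length T={y.shape[1]} must exceed the horizon K={config.K}"
        )
    X, parts = _filtered_states(model, y)
    loss = _prediction_loss(model, y, X, parts, config.K)
    l2 = model.encoder.l2() + model.decoder.l2()
    return loss + config.lambda_reg * l2


def compute_supervised_loss(model: DFINEModel, batch, config: TrainingConfig):
    """Supervised loss: prediction cost + lambda_beh behaviour MSE + L2 (incl. mapper)."""
    if model.mapper is None:
        raise MissingComponentError("supervised loss requires a model with a mapper")
    y = _as_batch(batch, "y")
    z = _as_batch(batch, "z")
    if z.shape[:2] != y.shape[:2]:
        raise DataError(f"behaviour shape {z.shape} does not match y {y.shape}")
    if y.shape[1] <= config.K:
        raise ValueError(
            f"segment length T={y.shape[1]} must exceed the horizon K={config.K}"
        )
    X, parts = _filtered_states(model, y)
    loss = _prediction_loss(model, y, X, parts, config.K)
    if config.behavior_from == "encoder":
        a_for_z = parts["a_hat"]
    else:
        a_for_z = X @ parts["C"].T
    z_pred = model.mapper.forward(a_for_z)
    beh = (z_pred - Tensor(z)).square().mean(axis=0).mean(axis=1).sum()
    l2 = model.encoder.l2() + model.decoder.l2() + model.mapper.l2()
    return loss + config.lambda_beh * beh + config.lambda_reg * l2


# ---------------------------------------------------------------------------
# z-scoring and cross-validation utilities
# ---------------------------------------------------------------------------

def zscore_fit(data) -> Normalization:
    """Per-dimension mean/sd over all timepoints; zero-variance sd clamped to 1."""
    arr = np.asarray(getattr(data, "y", data), dtype=np.float64)
    flat = arr.reshape(-1, arr.shape[-1])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance dimension(s); sd clamped to 1", stacklevel=2)
        sd = np.where(sd == 0, 1.0, sd)
    return Normalization(mean=mean, sd=sd)


def zscore_apply(data, norm: Normalization) -> np.ndarray:
    arr = np.asarray(getattr(data, "y", data), dtype=np.float64)
    return norm.apply(arr)


def crossval_split(n_trials, n_folds: int = 5, seed: int = 0):
    """Disjoint, exhaustive folds with sizes differing by at most one."""
    if hasattr(n_trials, "n_trials"):
        n_trials = n_trials.n_trials
    elif hasattr(n_trials, "y"):
        n_trials = len(n_trials.y)
    n_trials = int(n_trials)
    if n_trials < n_folds:
        raise ValueError(f"need at least {n_folds} trials, got {n_trials}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    folds = np.array_split(perm, n_folds)
    out = []
    for i in range(n_folds):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(n_folds) if j != i]))
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def _segments(dataset, config: TrainingConfig, with_z: bool):
    """Cut a dataset into equal-length fully observed training segments."""
    y = getattr(dataset, "y", dataset)
    z = getattr(dataset, "z", None) if with_z else None
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 2:  # continuous stream: non-overlapping segments of batch_len
        L = config.batch_len
        n_seg = y.shape[0] // L
        if n_seg == 0:
            raise ValueError("stream shorter than one batch_len segment")
        y = y[: n_seg * L].reshape(n_seg, L, -1)
        if z is not None:
            z = np.asarray(z, float)[: n_seg * L].reshape(n_seg, L, -1)
    else:
        keep = [i for i in range(y.shape[0]) if y.shape[1] >= config.K + 2]
        y = y[keep]
        if z is not None:
            z = np.asarray(z, dtype=np.float64)[keep]
    return y, z


def train(model: DFINEModel, dataset, config: TrainingConfig,
          checkpoint_dir: str | None = None):
    """Mini-batch Adam on the (supervised) k-step-ahead loss.

    `dataset` is a SessionData or an array (n_trials, T, n_y), already z-scored
    with statistics from the training split. Returns (model, TrainHistory).
    With `checkpoint_dir` set, the model is written there every
    `config.checkpoint_every` epochs.
    """
    y_seg, z_seg = _segments(dataset, config, with_z=config.supervised)
    if config.supervised and z_seg is None:
        raise DataError("supervised training requires behaviour data z")
    history = TrainHistory()
    if config.epochs == 0:
        return model, history
    params = model.parameters(learn_initial=config.learn_initial)
    opt = Adam(params, lr=config.lr)
    rng = np.random.default_rng(config.seed)
    n_seg = y_seg.shape[0]
    loss_fn = compute_supervised_loss if config.supervised else compute_loss
    for epoch in range(config.epochs):
        order = rng.permutation(n_seg)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_seg, config.batch_size):
            idx = order[start: start + config.batch_size]
            if config.supervised:
                batch = _SupervisedBatch(y_seg[idx], z_seg[idx])
            else:
                batch = y_seg[idx]
            opt.zero_grad()
            loss = loss_fn(model, batch, config)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; history so far: {history.loss}"
                )
            loss.backward()
            opt.step()
            epoch_loss += lval
            n_batches += 1
        if config.lr_decay is not None:
            opt.lr *= config.lr_decay
        history.loss.append(epoch_loss / max(n_batches, 1))
        history.param_norm.append(
            float(np.sqrt(sum(float((p.data ** 2).sum()) for p in params)))
        )
        if (checkpoint_dir is not None and config.checkpoint_every
                and (epoch + 1) % config.checkpoint_every == 0):
            import pathlib

            d = pathlib.Path(checkpoint_dir)
            d.mkdir(parents=True, exist_ok=True)
            model.save(str(d / f"checkpoint_epoch{epoch + 1:04d}.h5"))
    model.check_stability()
    if config.calibrate:
        calibrate_noise(model, y_seg)
    _estimate_V(model, y_seg)
    return model, history


@dataclass
class _SupervisedBatch:
    y: np.ndarray
    z: np.ndarray


def calibrate_noise(model: DFINEModel, y_trials: np.ndarray, n_iter: int = 8,
                    max_trials: int = 60) -> None:
    """Refine the LDM noise statistics (W, R, mu0, Lambda0) by EM on a_hat.

    The prediction cost constrains the Kalman gains only weakly, which can
    leave the process/observation noise split mis-calibrated; smoothing is
    more sensitive to that split than filtering. With A, C and the
    autoencoder frozen, a few EM iterations on the encoder outputs give the
    maximum-likelihood (diagonal) noise covariances for the linear layer.
    Updates model.log_w / log_r / mu0 / log_lambda0 in place.
    """
    from .ldm import kalman_filter, kalman_smoother
    from .model import LDMParams

    y_trials = np.asarray(y_trials, dtype=np.float64)
    if y_trials.ndim == 2:
        y_trials = y_trials[None]
    y_trials = y_trials[:max_trials]
    ldm = model.ldm()
    A, C = ldm.A, ldm.C
    a_hat = np.stack([model.encoder.forward_np(t) for t in y_trials])
    N, T, n_a = a_hat.shape
    n_x = A.shape[0]
    W, R, mu0, L0 = ldm.W, ldm.R, ldm.mu0, ldm.Lambda0
    for _ in range(n_iter):
        cur = LDMParams(A=A, W=W, C=C, R=R, mu0=mu0, Lambda0=L0)
        S11 = np.zeros((n_x, n_x)); S10 = np.zeros((n_x, n_x)); S00 = np.zeros((n_x, n_x))
        Rsum = np.zeros((n_a, n_a)); mu_acc = np.zeros(n_x); L0_acc = np.zeros((n_x, n_x))
        for i in range(N):
            fr = kalman_filter(cur, a_hat[i])
            sm = kalman_smoother(cur, fr)
            xs, Ps = sm.x_smooth, sm.P_smooth
            Exx = Ps + xs[:, :, None] * xs[:, None, :]
            S11 += Exx[1:].sum(0)
            S00 += Exx[:-1].sum(0)
            for t in range(1, T):
                Pp = A @ fr.P_filt[t - 1] @ A.T + W
                J = np.linalg.solve(Pp, A @ fr.P_filt[t - 1]).T   # P_f A^T Pp^{-1}
                Pcross = Ps[t] @ J.T                              # cov(x_t, x_{t-1} | a)
                S10 += Pcross + np.outer(xs[t], xs[t - 1])
            resid = a_hat[i] - xs @ C.T
            Rsum += resid.T @ resid + C @ Ps.sum(0) @ C.T
            mu_acc += xs[0]
            L0_acc += Ps[0] + np.outer(xs[0] - mu0, xs[0] - mu0)
        W = np.diag(np.diag(S11 - A @ S10.T - S10 @ A.T + A @ S00 @ A.T) / (N * (T - 1)))
        R = np.diag(np.diag(Rsum) / (N * T))
        mu0 = mu_acc / N
        L0 = np.diag(np.diag(L0_acc) / N)
    model.log_w.data = np.log(np.clip(np.diag(W), 1e-10, None))
    model.log_r.data = np.log(np.clip(np.diag(R), 1e-10, None))
    model.mu0.data = mu0
    model.log_lambda0.data = np.log(np.clip(np.diag(L0), 1e-10, None))


def _estimate_V(model: DFINEModel, y_seg: np.ndarray) -> None:
    """Diagonal observation-noise covariance from autoencoder residuals.

    V is not identifiable from the MSE cost; it only matters for generative
    sampling, so it is estimated post hoc on the training split.
    """
    flat = y_seg.reshape(-1, y_seg.shape[-1])
    sub = flat[:: max(1, len(flat) // 20000)]
    recon = model.decoder.forward_np(model.encoder.forward_np(sub))
    model.V = np.diag(np.var(sub - recon, axis=0))
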