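"""The DFINE generative model and its parameter containers.

The model couples a linear-Gaussian latent dynamical system with a nonlinear
manifold embedding:

    x_{t+1} = A x_t + w_t,          w_t ~ N(0, W)      (dynamic latent factors)
    a_t     = C x_t + r_t,          r_t ~ N(0, R)      (manifold latent factors)
    y_t     = f_theta(a_t) + v_t,   v_t ~ N(0, V)      (observations, decoder)

with an encoder MLP f_phi : y -> a used only at inference time to provide the
noisy manifold-factor observations for the Kalman recursion; it is not part of
the generative likelihood. An optional mapper MLP f_gamma : a -> z predicts
behaviour variables and exists only for models trained in supervised mode.

Covariances W, R and Lambda0 are stored through log-diagonal unconstrained
parameters so they remain positive definite at every gradient step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .autodiff import Tensor
from .exceptions import InvalidModelError, MissingComponentError

__all__ = [
    "ModelDims",
    "LDMParams",
    "MLP",
    "DFINEModel",
    "init_model",
    "decode_manifold",
    "encode_observation",
    "map_behavior",
    "sample_generative",
]

CHECKPOINT_VERSION = "1"


@dataclass(frozen=True)
class ModelDims:
    """Dimensions of the latent hierarchy.

    n_y : observation dimension; n_a : manifold latent dimension;
    n_x : dynamic latent dimension (defaults to n_a); n_z : behaviour dimension.
    """

    n_y: int
    n_a: int
    n_x: int | None = None
    n_z: int | None = None

    def __post_init__(self):
        n_x = self.n_x if self.n_x is not None else self.n_a
        object.__setattr__(self, "n_x", n_x)
        for name in ("n_y", "n_a", "n_x"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise InvalidModelError(f"{name} must be a positive integer, got {v!r}")
        if self.n_z is not None and self.n_z <= 0:
            raise InvalidModelError(f"n_z must be positive when given, got {self.n_z}")
        if self.n_a > self.n_y:
            raise InvalidModelError(
                f"manifold dimension n_a={self.n_a} cannot exceed n_y={self.n_y}"
            )


@dataclass
class LDMParams:
    """Concrete linear-dynamical-model parameters (plain numpy arrays)."""

    A: np.ndarray
    W: np.ndarray
    C: np.ndarray
    R: np.ndarray
    mu0: np.ndarray
    Lambda0: np.ndarray

    def validate(self) -> None:
        n_x = self.A.shape[0]
        n_a = self.C.shape[0]
        if self.A.shape != (n_x, n_x) or self.W.shape != (n_x, n_x):
            raise InvalidModelError("A and W must be square n_x x n_x")
        if self.C.shape != (n_a, n_x) or self.R.shape != (n_a, n_a):
            raise InvalidModelError("C must be n_a x n_x and R n_a x n_a")
        for name in ("W", "R", "Lambda0"):
            M = getattr(self, name)
            if not np.allclose(M, M.T, atol=1e-10):
                raise InvalidModelError(f"{name} must be symmetric")
            if np.linalg.eigvalsh((M + M.T) / 2).min() < -1e-10:
                raise InvalidModelError(f"{name} must be positive semi-definite")

    @property
    def n_x(self) -> int:
        return self.A.shape[0]

    @property
    def n_a(self) -> int:
        return self.C.shape[0]


class MLP:
    """A feed-forward network with tanh hidden layers and a linear output layer.

    Parameters live as autodiff Tensors so the same object serves both the
    differentiable training path (`forward`) and the fast numpy inference path
    (`forward_np`).
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 out_scale: float = 1.0):
        self.sizes = list(sizes)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            limit = np.sqrt(6.0 / (n_in + n_out))
            W = rng.uniform(-limit, limit, size=(n_in, n_out))
            if i == len(sizes) - 2:
                W = W * out_scale
            self.weights.append(Tensor(W, requires_grad=True))
            self.biases.append(Tensor(np.zeros(n_out), requires_grad=True))

    @property
    def n_in(self) -> int:
        return self.sizes[0]

    @property
    def n_out(self) -> int:
        return self.sizes[-1]

    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases

    def forward(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < last:
                h = h.tanh()
        return h

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=np.float64)
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W.data + b.data
            if i < last:
                h = np.tanh(h)
        return h

    def l2(self) -> Tensor:
        total = None
        for W in self.weights:
            s = W.square().sum()
            total = s if total is None else total + s
        return total


@dataclass
class Normalization:
    """Per-dimension z-scoring statistics, fit on the training split only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def identity(cls, n: int) -> "Normalization":
        return cls(mean=np.zeros(n), sd=np.ones(n))

    def apply(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.sd

    def invert(self, y: np.ndarray) -> np.ndarray:
        return y * self.sd + self.mean


@dataclass
class DFINEModel:
    """Bundle of LDM parameters, autoencoder networks and optional mapper."""

    dims: ModelDims
    A: Tensor
    C: Tensor
    log_w: Tensor          # log diagonal of W
    log_r: Tensor          # log diagonal of R
    mu0: Tensor
    log_lambda0: Tensor    # log diagonal of Lambda0
    encoder: MLP
    decoder: MLP
    mapper: MLP | None = None
    normalization: Normalization = field(default_factory=lambda: Normalization.identity(1))
    V: np.ndarray | None = None  # decoder observation-noise covariance, post hoc

    def ldm(self) -> LDMParams:
        """Concrete LDM parameters as plain numpy arrays."""
        return LDMParams(
            A=self.A.data.copy(),
            W=np.diag(np.exp(self.log_w.data)),
            C=self.C.data.copy(),
            R=np.diag(np.exp(self.log_r.data)),
            mu0=self.mu0.data.copy(),
            Lambda0=np.diag(np.exp(self.log_lambda0.data)),
        )

    def parameters(self, learn_initial: bool = True) -> list[Tensor]:
        params = [self.A, self.C, self.log_w, self.log_r]
        if learn_initial:
            params += [self.mu0, self.log_lambda0]
        params += self.encoder.parameters() + self.decoder.parameters()
        if self.mapper is not None:
            params += self.mapper.parameters()
        return params

    def check_stability(self) -> float:
        """Spectral radius of A; warns if the learned dynamics are unstable."""
        rho = float(np.abs(np.linalg.eigvals(self.A.data)).max())
        if rho > 1.0:
            warnings.warn(
                f"spectral radius of A is {rho:.3f} > 1; learned dynamics are unstable",
                stacklevel=2,
            )
        return rho

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["n_y"] = self.dims.n_y
            f.attrs["n_a"] = self.dims.n_a
            f.attrs["n_x"] = self.dims.n_x
            f.attrs["n_z"] = -1 if self.dims.n_z is None else self.dims.n_z
            f.attrs["version"] = CHECKPOINT_VERSION
            ldm = self.ldm()
            g = f.create_group("ldm")
            for name in ("A", "W", "C", "R", "mu0", "Lambda0"):
                g.create_dataset(name, data=getattr(ldm, name))
            nets = f.create_group("nets")
            for name, mlp in (("encoder", self.encoder), ("decoder", self.decoder),
                              ("mapper", self.mapper)):
                if mlp is None:
                    continue
                sub = nets.create_group(name)
                sub.attrs["sizes"] = np.asarray(mlp.sizes)
                for i, (W, b) in enumerate(zip(mlp.weights, mlp.biases)):
                    sub.create_dataset(f"W{i}", data=W.data)
                    sub.create_dataset(f"b{i}", data=b.data)
            norm = f.create_group("normalization")
            norm.create_dataset("mean", data=self.normalization.mean)
            norm.create_dataset("sd", data=self.normalization.sd)
            if self.V is not None:
                f.create_dataset("V", data=self.V)

    @classmethod
    def load(cls, path: str) -> "DFINEModel":
        with h5py.File(path, "r") as f:
            n_z = int(f.attrs["n_z"])
            dims = ModelDims(
                n_y=int(f.attrs["n_y"]), n_a=int(f.attrs["n_a"]),
                n_x=int(f.attrs["n_x"]), n_z=None if n_z < 0 else n_z,
            )
            g = f["ldm"]

            def _logdiag(M):
                return np.log(np.clip(np.diag(M), 1e-12, None))

            rng = np.random.default_rng(0)
            model = cls(
                dims=dims,
                A=Tensor(g["A"][()], requires_grad=True),
                C=Tensor(g["C"][()], requires_grad=True),
                log_w=Tensor(_logdiag(g["W"][()]), requires_grad=True),
                log_r=Tensor(_logdiag(g["R"][()]), requires_grad=True),
                mu0=Tensor(g["mu0"][()], requires_grad=True),
                log_lambda0=Tensor(_logdiag(g["Lambda0"][()]), requires_grad=True),
                encoder=MLP([1, 1], rng), decoder=MLP([1, 1], rng),
            )
            for name in ("encoder", "decoder", "mapper"):
                if name not in f["nets"]:
                    continue
                sub = f["nets"][name]
                mlp = MLP(list(sub.attrs["sizes"]), rng)
                for i in range(len(mlp.weights)):
                    mlp.weights[i].data = sub[f"W{i}"][()]
                    mlp.biases[i].data = sub[f"b{i}"][()]
                setattr(model, name, mlp)
            model.normalization = Normalization(
                mean=f["normalization/mean"][()], sd=f["normalization/sd"][()]
            )
            if "V" in f:
                model.V = f["V"][()]
        return model


def init_model(dims: ModelDims, config=None, seed: int = 0,
               hidden: tuple[int, ...] = (32, 32, 32)) -> DFINEModel:
    """Create a freshly initialized model.

    A starts at 0.95 I (stable), C with small random entries, W = 0.1 I,
    R = Lambda0 = I, mu0 = 0. The decoder output layer starts small so an
    untrained model predicts near the data mean (chance-level NRMSE of 1).
    The same seed and config always produce bit-identical parameters.
    """
    if not isinstance(dims, ModelDims):
        dims = ModelDims(*dims)
    if config is not None:
        hidden = tuple(getattr(config, "hidden", hidden))
    rng = np.random.default_rng(seed)
    n_y, n_a, n_x = dims.n_y, dims.n_a, dims.n_x
    encoder = MLP([n_y, *hidden, n_a], rng)
    decoder = MLP([n_a, *hidden, n_y], rng, out_scale=0.1)
    mapper = None
    supervised = bool(getattr(config, "supervised", False)) if config is not None else False
    if supervised:
        if dims.n_z is None:
            raise InvalidModelError("supervised model requires n_z")
        mapper = MLP([n_a, *hidden, dims.n_z], rng)
    model = DFINEModel(
        dims=dims,
        A=Tensor(0.95 * np.eye(n_x), requires_grad=True),
        C=Tensor(rng.normal(0.0, 0.1, size=(n_a, n_x)), requires_grad=True),
        log_w=Tensor(np.full(n_x, np.log(0.1)), requires_grad=True),
        log_r=Tensor(np.zeros(n_a), requires_grad=True),
        mu0=Tensor(np.zeros(n_x), requires_grad=True),
        log_lambda0=Tensor(np.zeros(n_x), requires_grad=True),
        encoder=encoder,
        decoder=decoder,
        mapper=mapper,
        normalization=Normalization.identity(n_y),
    )
    return model


def _check_width(arr: np.ndarray, width: int, what: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != width:
        raise ValueError(f"{what} must have shape (T, {width}), got {arr.shape}")
    return arr


def decode_manifold(model: DFINEModel, a: np.ndarray) -> np.ndarray:
    """Apply the decoder f_theta per timestep; no observation noise is added."""
    a = _check_width(a, model.dims.n_a, "manifold factors")
    return model.decoder.forward_np(a)


def encode_observation(model: DFINEModel, y: np.ndarray) -> np.ndarray:
    """Apply the encoder f_phi per timestep to (already z-scored) observations.

    The result is the static, noisy estimate of the manifold latent factors
    that feeds the Kalman recursion.
    """
    y = _check_width(y, model.dims.n_y, "observations")
    return model.encoder.forward_np(y)


def map_behavior(model: DFINEModel, a: np.ndarray) -> np.ndarray:
    """Apply the behaviour mapper f_gamma per timestep (supervised models only)."""
    if model.mapper is None:
        raise MissingComponentError(
            "model has no behaviour mapper; it was not trained in supervised mode"
        )
    a = _check_width(a, model.dims.n_a, "manifold factors")
    return model.mapper.forward_np(a)


def sample_generative(model: DFINEModel, T: int, n_trials: int = 1,
                      seed: int = 0) -> dict[str, np.ndarray]:
    """Sample (x, a, y) trajectories from the generative model.

    y is returned in the model's observation units (normalization inverted).
    The encoder plays no role here.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    ldm = model.ldm()
    ldm.validate()
    n_x, n_a, n_y = model.dims.n_x, model.dims.n_a, model.dims.n_y
    V = model.V if model.V is not None else np.zeros((n_y, n_y))
    V = np.asarray(V, dtype=np.float64)
    if np.linalg.eigvalsh((V + V.T) / 2).min() < -1e-10:
        raise InvalidModelError("V must be positive semi-definite")
    rng = np.random.default_rng(seed)

    def _chol(M):
        # PSD-safe factor (eigendecomposition handles exactly singular M)
        vals, vecs = np.linalg.eigh((M + M.T) / 2)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))

    Lw, Lr, Lv = _chol(ldm.W), _chol(ldm.R), _chol(V)
    L0 = _chol(ldm.Lambda0)
    x = np.empty((n_trials, T, n_x))
    a = np.empty((n_trials, T, n_a))
    y = np.empty((n_trials, T, n_y))
    for i in range(n_trials):
        xt = ldm.mu0 + L0 @ rng.standard_normal(n_x)
        for t in range(T):
            x[i, t] = xt
            a[i, t] = ldm.C @ xt + Lr @ rng.standard_normal(n_a)
            y[i, t] = model.decoder.forward_np(a[i, t][None])[0] + Lv @ rng.standard_normal(n_y)
            xt = ldm.A @ xt + Lw @ rng.standard_normal(n_x)
    y = model.normalization.invert(y)
    return {"x": x, "a": a, "y": y}
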