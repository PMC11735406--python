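"""Synthetic validation data.

Three families of sessions exercise every stage of the pipeline:

* nonlinear-manifold sessions -- a driven walk (constant per-trial drift plus
  Gaussian jitter) in the intrinsic coordinates of a ring, torus or Swiss-roll
  manifold, embedded in 3-D by the parametric manifold equations and observed
  through a random 40 x 3 emission matrix plus white Gaussian noise
  (250 trials x 200 steps by default);
* stochastic Lorenz sessions -- Euler-integrated Lorenz dynamics
  (sigma=10, rho=28, beta=8/3, dt=0.01) with per-step process noise, a 500-step
  burn-in from a standard-normal start, and the same 40-D noisy emission
  (observation noise variance 1);
* block data-drop masks -- within every 100-step block, round((1-rho)*100)
  whole observation vectors are removed uniformly at random.

The exact manifold parameterizations and driving-walk coefficients are this
package's own concrete choices (documented in docs/methods.md) and are fully
configurable. An unscented Kalman filter over the true generator provides the
true-model one-step-ahead prediction reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import SessionData

__all__ = [
    "ManifoldConfig", "LorenzConfig", "DropConfig", "SimGroundTruth",
    "simulate_manifold_session", "simulate_lorenz_session", "make_observations",
    "apply_data_drop", "UnscentedKalmanFilter", "ukf_one_step_predict",
    "true_model_predictions",
]

_MANIFOLDS = ("ring", "torus", "swiss_roll")

# intrinsic coordinate descriptions: range, whether the coordinate is periodic
# (angles wrap; bounded coordinates reflect at the range ends), the range of
# traversals a single 200-step trial makes, and per-step jitter sds
_INTRINSIC = {
    "ring": {
        "dim": 1, "low": np.array([0.0]), "high": np.array([2 * np.pi]),
        "periodic": np.array([True]),
        "speed": np.array([[0.75, 1.5]]), "jitter_sd": np.array([0.05]),
    },
    "torus": {
        "dim": 2, "low": np.array([0.0, 0.0]),
        "high": np.array([2 * np.pi, 2 * np.pi]),
        "periodic": np.array([True, True]),
        "speed": np.array([[0.75, 1.5], [1.5, 3.0]]),
        "jitter_sd": np.array([0.05, 0.08]),
    },
    "swiss_roll": {
        "dim": 2, "low": np.array([1.5 * np.pi, 0.0]),
        "high": np.array([4.5 * np.pi, 20.0]),
        "periodic": np.array([False, False]),
        "speed": np.array([[0.75, 1.5], [0.5, 1.0]]),
        "jitter_sd": np.array([0.05, 0.15]),
    },
}


def _reflect(s: np.ndarray, low: np.ndarray, high: np.ndarray,
             periodic: np.ndarray) -> np.ndarray:
    """Fold bounded coordinates back into [low, high]; angles pass through."""
    out = np.array(s, dtype=np.float64)
    span = high - low
    bounded = ~periodic
    if bounded.any():
        x = out[..., bounded] - low[bounded]
        x = np.abs(np.mod(x, 2 * span[bounded]) - span[bounded]) * -1 + span[bounded]
        out[..., bounded] = low[bounded] + x
    return out

TORUS_R_MAJOR = 2.0
TORUS_R_MINOR = 0.5
RING_RADIUS = 1.0


def embed_manifold(manifold: str, s: np.ndarray) -> np.ndarray:
    """Map intrinsic coordinates (..., d) onto the manifold in 3-D space."""
    s = np.asarray(s, dtype=np.float64)
    if manifold == "ring":
        u = s[..., 0]
        return np.stack([RING_RADIUS * np.cos(u), RING_RADIUS * np.sin(u),
                         np.zeros_like(u)], axis=-1)
    if manifold == "torus":
        u, v = s[..., 0], s[..., 1]
        w = TORUS_R_MAJOR + TORUS_R_MINOR * np.cos(v)
        return np.stack([w * np.cos(u), w * np.sin(u),
                         TORUS_R_MINOR * np.sin(v)], axis=-1)
    if manifold == "swiss_roll":
        u, h = s[..., 0], s[..., 1]
        return np.stack([u * np.cos(u), h, u * np.sin(u)], axis=-1)
    raise ValueError(f"unknown manifold {manifold!r}; choose from {_MANIFOLDS}")


@dataclass
class ManifoldConfig:
    manifold: str = "ring"
    obs_noise_sd: float | None = None   # None -> 0.4 x RMS signal sd per channel
    n_trials: int = 250
    T: int = 200
    n_y: int = 40
    identity_first3: bool = True
    speed_scale: float = 1.0            # multiplies the per-trial traversal speed
    seed: int = 0

    def __post_init__(self):
        if self.manifold not in _MANIFOLDS:
            raise ValueError(f"unknown manifold {self.manifold!r}; choose from {_MANIFOLDS}")
        if self.identity_first3 and self.n_y < 3:
            raise ValueError("identity_first3 requires n_y >= 3")


@dataclass
class LorenzConfig:
    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    dt: float = 0.01
    q_var: float = 1e-3     # per-step process-noise variance per dimension
    obs_noise_var: float = 1.0
    burn_in: int = 500
    n_trials: int = 750
    T: int = 200
    n_y: int = 40
    identity_first3: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.q_var < 0:
            raise ValueError(f"q_var must be >= 0, got {self.q_var}")


@dataclass
class DropConfig:
    observed_ratio: float = 1.0
    block_len: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.observed_ratio <= 1):
            raise ValueError(
                f"observed_ratio must be in (0, 1], got {self.observed_ratio}"
            )


@dataclass
class SimGroundTruth:
    """Everything needed to score inference and run the true-model oracle."""

    manifold: str | None
    traj3d: np.ndarray                 # (n_trials, T, 3) pre-noise trajectory
    intrinsic: np.ndarray | None       # (n_trials, T, d) local coordinates
    emission: np.ndarray               # (n_y, 3)
    obs_noise_sd: float
    velocities: np.ndarray | None = None  # (n_trials, d) per-step drift
    jitter_sd: np.ndarray | None = None
    lorenz: "LorenzConfig | None" = None

    def trial_generator(self, i: int) -> "_ManifoldTrialModel":
        """True-model state-space description of trial i, for the UKF oracle."""
        if self.manifold is None:
            raise ValueError("trial_generator is defined for manifold sessions")
        return _ManifoldTrialModel(
            manifold=self.manifold, velocity=self.velocities[i],
            jitter_sd=self.jitter_sd, init_state=self.intrinsic[i, 0],
            emission=self.emission, obs_noise_sd=self.obs_noise_sd,
        )


@dataclass
class _ManifoldTrialModel:
    """Analytic transition/observation functions of one simulated trial."""

    manifold: str
    velocity: np.ndarray
    jitter_sd: np.ndarray
    init_state: np.ndarray
    emission: np.ndarray
    obs_noise_sd: float

    def state_transition(self, s: np.ndarray) -> np.ndarray:
        info = _INTRINSIC[self.manifold]
        return _reflect(s + self.velocity, info["low"], info["high"],
                        info["periodic"])

    def observation(self, s: np.ndarray) -> np.ndarray:
        return embed_manifold(self.manifold, s) @ self.emission.T

    @property
    def Q(self) -> np.ndarray:
        return np.diag(self.jitter_sd**2)

    @property
    def R_obs(self) -> np.ndarray:
        n_y = self.emission.shape[0]
        return self.obs_noise_sd**2 * np.eye(n_y)

    @property
    def init_mean(self) -> np.ndarray:
        return self.init_state.astype(float)

    @property
    def init_cov(self) -> np.ndarray:
        return 1e-9 * np.eye(len(self.init_state))

    # unit-scale sigma spread: with a near-zero spread the filter linearizes
    # locally and can jump between Swiss-roll whorls when observation noise is
    # comparable to the whorl separation; spreading sigma points at the true
    # covariance scale captures the embedding curvature and stays locked on
    ukf_params = {"alpha": 1.0}


def make_observations(traj3d: np.ndarray, emission: np.ndarray | int,
                      noise_sd: float, identity_first3: bool = True,
                      rng: np.random.Generator | None = None,
                      n_y: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """40-D observations y = E traj + white noise; returns (y, E).

    `emission` may be a ready (n_y, 3) matrix or an integer seed from which a
    random one is drawn (remaining rows N(0, 1/3) so channels have roughly
    unit gain). With identity_first3 the first three rows of E are the
    identity, so the first three observation dims equal the 3-D trajectory
    before noise.
    """
    traj3d = np.asarray(traj3d, dtype=np.float64)
    if traj3d.shape[-1] != 3:
        raise ValueError(f"traj3d must have width 3, got {traj3d.shape}")
    if isinstance(emission, (int, np.integer)):
        erng = np.random.default_rng(int(emission))
        E = erng.normal(0.0, np.sqrt(1.0 / 3.0), size=(n_y, 3))
    else:
        E = np.array(emission, dtype=np.float64)
        n_y = E.shape[0]
    if identity_first3:
        E[:3] = np.eye(3)
    y = traj3d @ E.T
    if noise_sd > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return y, E


def simulate_manifold_session(config: ManifoldConfig) -> tuple[SessionData, SimGroundTruth]:
    """A driven walk in intrinsic coordinates, embedded and observed in 40-D.

    Each trial drifts at a constant random velocity (roughly one traversal or
    revolution of each intrinsic coordinate per trial, random direction) with
    small Gaussian jitter, so a single trial sweeps the manifold; bounded
    coordinates reflect at their range ends, angles wrap.
    """
    rng = np.random.default_rng(config.seed)
    info = _INTRINSIC[config.manifold]
    d = info["dim"]
    n, T = config.n_trials, config.T
    span = info["high"] - info["low"]
    starts = rng.uniform(info["low"], info["high"], size=(n, d))
    traversals = rng.uniform(info["speed"][:, 0], info["speed"][:, 1], size=(n, d))
    signs = rng.choice([-1.0, 1.0], size=(n, d))
    velocities = config.speed_scale * signs * traversals * span / T
    jitter_sd = info["jitter_sd"]
    s = np.empty((n, T, d))
    s[:, 0] = starts
    noise = rng.normal(0.0, 1.0, size=(n, T - 1, d)) * jitter_sd
    for t in range(1, T):
        stepped = _reflect(s[:, t - 1] + velocities, info["low"], info["high"],
                           info["periodic"])
        s[:, t] = stepped + noise[:, t - 1]
    traj3d = embed_manifold(config.manifold, s)
    if config.obs_noise_sd is None:
        signal_sd = float(np.sqrt(np.mean(traj3d.reshape(-1, 3).var(axis=0))))
        noise_sd = 0.4 * signal_sd
    else:
        noise_sd = float(config.obs_noise_sd)
    E_seed = int(rng.integers(2**31 - 1))
    y, E = make_observations(traj3d, E_seed, 0.0, config.identity_first3,
                             n_y=config.n_y)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    session = SessionData(y=y, dt=0.05)
    truth = SimGroundTruth(
        manifold=config.manifold, traj3d=traj3d, intrinsic=s, emission=E,
        obs_noise_sd=noise_sd, velocities=velocities, jitter_sd=jitter_sd,
    )
    return session, truth


def lorenz_derivative(s: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    x1, x2, x3 = s[..., 0], s[..., 1], s[..., 2]
    return np.stack([sigma * (x2 - x1), rho * x1 - x1 * x3 - x2,
                     x1 * x2 - beta * x3], axis=-1)


def simulate_lorenz_session(config: LorenzConfig) -> tuple[SessionData, SimGroundTruth]:
    """Stochastic Lorenz trajectories observed through a random 40-D emission.

    Euler steps s += f(s) dt + q with q ~ N(0, q_var I) applied after a
    noiseless 500-step burn-in from a standard-normal initial state.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_trials, config.T
    s = rng.standard_normal((n, 3))
    for _ in range(config.burn_in):
        s = s + lorenz_derivative(s, config.sigma, config.rho, config.beta) * config.dt
    traj = np.empty((n, T, 3))
    q_sd = np.sqrt(config.q_var)
    for t in range(T):
        traj[:, t] = s
        s = s + lorenz_derivative(s, config.sigma, config.rho, config.beta) * config.dt
        if q_sd > 0:
            s = s + rng.normal(0.0, q_sd, size=s.shape)
    E_seed = int(rng.integers(2**31 - 1))
    y, E = make_observations(traj, E_seed, 0.0, config.identity_first3,
                             n_y=config.n_y)
    obs_sd = float(np.sqrt(config.obs_noise_var))
    if obs_sd > 0:
        y = y + rng.normal(0.0, obs_sd, size=y.shape)
    session = SessionData(y=y, dt=0.05)
    truth = SimGroundTruth(manifold=None, traj3d=traj, intrinsic=None,
                           emission=E, obs_noise_sd=obs_sd, lorenz=config)
    return session, truth


def apply_data_drop(session, drop: DropConfig) -> np.ndarray:
    """Boolean observation mask with block-wise uniform drops.

    Within every consecutive block of `block_len` timesteps, exactly
    round((1 - rho) * block_len) whole observation vectors are masked (the
    final partial block is dropped pro rata). Accepts a SessionData, a
    (n_trials, T, n_y) array, or an integer T; returns a (n_trials, T) or (T,)
    mask.
    """
    y = getattr(session, "y", session)
    if isinstance(y, (int, np.integer)):
        shape: tuple[int, ...] = (int(y),)
    else:
        y = np.asarray(y)
        shape = y.shape[:-1] if y.ndim >= 2 else y.shape
    rng = np.random.default_rng(drop.seed)
    flat = np.ones((int(np.prod(shape[:-1], dtype=int)), shape[-1]), dtype=bool)
    T = shape[-1]
    L = drop.block_len
    for i in range(flat.shape[0]):
        for start in range(0, T, L):
            block = min(L, T - start)
            n_drop = int(round((1 - drop.observed_ratio) * block))
            if n_drop > 0:
                idx = rng.choice(block, size=n_drop, replace=False)
                flat[i, start + idx] = False
    return flat.reshape(shape)


class UnscentedKalmanFilter:
    """Sigma-point filter for additive-noise nonlinear state-space models.

    Standard unscented transform with 2n+1 sigma points (alpha=1e-3, beta=2,
    kappa=0 by default), exact for linear transition/observation maps.
    """

    def __init__(self, state_transition, observation, Q, R,
                 alpha: float = 1e-3, beta: float = 2.0, kappa: float = 0.0):
        self.f = state_transition
        self.g = observation
        self.Q = np.asarray(Q, dtype=np.float64)
        self.R = np.asarray(R, dtype=np.float64)
        self.alpha, self.beta, self.kappa = alpha, beta, kappa

    def _sigma_points(self, mean: np.ndarray, cov: np.ndarray):
        n = len(mean)
        lam = self.alpha**2 * (n + self.kappa) - n
        try:
            L = np.linalg.cholesky((n + lam) * cov)
        except np.linalg.LinAlgError:
            warnings.warn("sigma-point covariance not PD; adding jitter", stacklevel=2)
            L = np.linalg.cholesky((n + lam) * cov + 1e-9 * np.eye(n))
        pts = np.concatenate([[mean], mean + L.T, mean - L.T], axis=0)
        wm = np.full(2 * n + 1, 1.0 / (2 * (n + lam)))
        wc = wm.copy()
        wm[0] = lam / (n + lam)
        wc[0] = lam / (n + lam) + (1 - self.alpha**2 + self.beta)
        return pts, wm, wc

    @staticmethod
    def _moments(pts, wm, wc, mean_ref=None):
        mean = wm @ pts
        dev = pts - (mean if mean_ref is None else mean_ref)
        cov = (dev * wc[:, None]).T @ dev
        return mean, cov

    def filter(self, y: np.ndarray, init_mean: np.ndarray, init_cov: np.ndarray):
        """Run the filter; returns (state means x_{t|t}, one-step obs predictions).

        y_pred[t] is the predicted observation y_{t|t-1}; y_pred[0] uses the
        initial state distribution.
        """
        y = np.asarray(y, dtype=np.float64)
        T = y.shape[0]
        m = np.asarray(init_mean, dtype=np.float64).copy()
        P = np.asarray(init_cov, dtype=np.float64).copy()
        n = len(m)
        x_filt = np.empty((T, n))
        y_pred = np.empty((T, y.shape[1]))
        for t in range(T):
            if t > 0:
                pts, wm, wc = self._sigma_points(m, P)
                fp = self.f(pts)
                m, P = self._moments(fp, wm, wc)
                P = (P + P.T) / 2 + self.Q
            # observation prediction and update
            pts, wm, wc = self._sigma_points(m, P)
            gp = self.g(pts)
            y_hat = wm @ gp
            dev_y = gp - y_hat
            S = (dev_y * wc[:, None]).T @ dev_y + self.R
            dev_x = pts - m
            Cxy = (dev_x * wc[:, None]).T @ dev_y
            y_pred[t] = y_hat
            K = np.linalg.solve(S.T, Cxy.T).T
            m = m + K @ (y[t] - y_hat)
            P = P - K @ S @ K.T
            P = (P + P.T) / 2
            x_filt[t] = m
        return x_filt, y_pred


def ukf_one_step_predict(true_generator, y: np.ndarray) -> np.ndarray:
    """One-step-ahead observation predictions of the true model via the UKF.

    `true_generator` exposes state_transition, observation, Q, R_obs,
    init_mean and init_cov (and optionally ukf_params overriding the sigma
    scaling). Returns y_{t|t-1} for the whole sequence (row 0 uses the initial
    state distribution).
    """
    ukf = UnscentedKalmanFilter(true_generator.state_transition,
                                true_generator.observation,
                                true_generator.Q, true_generator.R_obs,
                                **getattr(true_generator, "ukf_params", {}))
    _, y_pred = ukf.filter(y, true_generator.init_mean, true_generator.init_cov)
    return y_pred


def true_model_predictions(truth: SimGroundTruth, session, trial_indices) -> np.ndarray:
    """Stacked UKF one-step predictions for the given trials of a manifold session."""
    y = getattr(session, "y", session)
    preds = np.empty((len(trial_indices), y.shape[1], y.shape[2]))
    for j, i in enumerate(trial_indices):
        preds[j] = ukf_one_step_predict(truth.trial_generator(int(i)), y[i])
    return preds
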