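"""Evaluation metrics and protocols.

NRMSE is the per-dimension root-sum-squared error divided by the
root-sum-squared deviation from the dimension mean, averaged over dimensions;
the per-dimension mean predictor therefore scores exactly 1 (chance) and a
perfect predictor 0. Behaviour decoding follows the cross-validated
conventions: an MLP regressor from smoothed latents for continuous behaviour
(Pearson CC) and one-vs-one Gaussian-kernel SVMs on length-normalized
latent-trajectory features for discrete classes (mean ROC-AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .inference import infer_latents, predict_one_step
from .model import DFINEModel
from .simulate import DropConfig, apply_data_drop

__all__ = [
    "MetricReport", "nrmse", "nrmse_trials", "pearson_cc", "one_step_eval",
    "behavior_regression_eval", "classification_features", "classification_auc",
    "drop_robustness_curve", "lorenz_recovery_cc",
]


@dataclass
class MetricReport:
    """Labelled scalar metrics with provenance (session, fold)."""

    rows: list[dict] = field(default_factory=list)

    def add(self, metric: str, value: float, session: str = "", fold: int = -1,
            **extra) -> None:
        self.rows.append({"session": session, "fold": fold, "metric": metric,
                          "value": float(value), **extra})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def mean(self, metric: str, **filters) -> float:
        df = self.to_frame()
        df = df[df.metric == metric]
        for k, v in filters.items():
            df = df[df[k] == v]
        return float(df.value.mean())

    def confidence_bound(self, metric: str, level: float = 0.95,
                         method: str = "normal", n_boot: int = 2000,
                         seed: int = 0) -> tuple[float, float]:
        """CI of the mean across rows of this metric.

        method="normal" uses the normal approximation; "bootstrap" the
        percentile bootstrap over rows.
        """
        vals = self.to_frame().query("metric == @metric").value.to_numpy()
        m = vals.mean()
        if method == "bootstrap":
            rng = np.random.default_rng(seed)
            boots = rng.choice(vals, size=(n_boot, len(vals))).mean(axis=1)
            lo, hi = np.quantile(boots, [0.5 - level / 2, 0.5 + level / 2])
            return float(lo), float(hi)
        from scipy import stats

        half = stats.norm.ppf(0.5 + level / 2) * vals.std(ddof=1) / np.sqrt(len(vals))
        return m - half, m + half

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def nrmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean over dimensions of sqrt(sum(err^2)) / sqrt(sum((y - mean)^2)).

    Constant dimensions (zero denominator) are skipped with a warning.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    if y_true.ndim == 1:
        y_true, y_pred = y_true[:, None], y_pred[:, None]
    num = np.sqrt(np.sum((y_true - y_pred) ** 2, axis=0))
    den = np.sqrt(np.sum((y_true - y_true.mean(axis=0)) ** 2, axis=0))
    ok = den > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} constant dimension(s) skipped in NRMSE",
                      stacklevel=2)
    if not ok.any():
        raise ValueError("all dimensions constant; NRMSE undefined")
    return float(np.mean(num[ok] / den[ok]))


def nrmse_trials(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean NRMSE across trials of stacked (n_trials, T, d) arrays."""
    return float(np.mean([nrmse(t, p) for t, p in zip(y_true, y_pred)]))


def pearson_cc(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation; multivariate inputs average the per-dimension CC."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.shape[0] < 2:
        raise ValueError("inputs must share shape with length >= 2")
    if u.ndim == 1:
        u, v = u[:, None], v[:, None]
    ccs = []
    for d in range(u.shape[1]):
        su, sv = u[:, d].std(), v[:, d].std()
        if su == 0 or sv == 0:
            raise ValueError("constant input; correlation undefined")
        ccs.append(np.corrcoef(u[:, d], v[:, d])[0, 1])
    return float(np.mean(ccs))


def one_step_eval(model: DFINEModel, test_sessions, session_names=None) -> MetricReport:
    """One-step-ahead prediction accuracy on held-out trials.

    Each session is an array (n_trials, T, n_y) or SessionData; reports
    per-trial NRMSE (simulation convention) and CC (neural-data convention),
    aggregated per session.
    """
    if not isinstance(test_sessions, (list, tuple)):
        test_sessions = [test_sessions]
    report = MetricReport()
    for s_idx, sess in enumerate(test_sessions):
        y = getattr(sess, "y", sess)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 2:
            y = y[None]
        name = str(s_idx) if session_names is None else session_names[s_idx]
        vals_nrmse, vals_cc = [], []
        for trial in y:
            pred = predict_one_step(model, trial)
            vals_nrmse.append(nrmse(trial[1:], pred))
            vals_cc.append(pearson_cc(trial[1:], pred))
        report.add("one_step_nrmse", np.mean(vals_nrmse), session=name)
        report.add("one_step_cc", np.mean(vals_cc), session=name)
    return report


def _default_regressor(seed: int = 0):
    from sklearn.neural_network import MLPRegressor

    return MLPRegressor(hidden_layer_sizes=(64, 64), activation="tanh",
                        solver="adam", max_iter=800, random_state=seed)


def behavior_regression_eval(latents_train, z_train, latents_test, z_test,
                             regressor=None, seed: int = 0) -> float:
    """Fit a nonlinear regressor latents -> behaviour on train; CC on test."""
    Xtr = np.asarray(latents_train, float).reshape(-1, np.shape(latents_train)[-1])
    Xte = np.asarray(latents_test, float).reshape(-1, np.shape(latents_test)[-1])
    ztr = np.asarray(z_train, float).reshape(len(Xtr), -1)
    zte = np.asarray(z_test, float).reshape(len(Xte), -1)
    if Xtr is Xte or (len(Xtr) == len(Xte) and np.shares_memory(Xtr, Xte)):
        raise AssertionError("train and test latents share memory (fold leakage)")
    reg = _default_regressor(seed) if regressor is None else regressor
    reg.fit(Xtr, ztr if ztr.shape[1] > 1 else ztr.ravel())
    pred = np.asarray(reg.predict(Xte)).reshape(len(Xte), -1)
    return pearson_cc(zte, pred)


def classification_features(latent_trajectory: np.ndarray,
                            n_interp: int = 400, n_samples: int = 10) -> np.ndarray:
    """Fixed-length features from a variable-length latent trajectory.

    The trajectory is linearly interpolated to `n_interp` datapoints and every
    (n_interp/n_samples)-th point is kept (1-based indices 40, 80, ..., 400 at
    the defaults), then flattened to length n_samples * n_latent.
    """
    traj = np.asarray(latent_trajectory, dtype=np.float64)
    if traj.ndim == 1:
        traj = traj[:, None]
    if traj.shape[0] < 2:
        raise ValueError("trial must have length >= 2")
    T, d = traj.shape
    grid = np.linspace(0, T - 1, n_interp)
    interp = np.stack([np.interp(grid, np.arange(T), traj[:, j]) for j in range(d)],
                      axis=1)
    step = n_interp // n_samples
    sampled = interp[step - 1:: step][:n_samples]
    return sampled.ravel()


def classification_auc(features: np.ndarray, labels: np.ndarray,
                       train_idx=None, test_idx=None, seed: int = 0) -> float:
    """Mean ROC-AUC over all one-vs-one Gaussian-kernel SVM problems.

    The kernel width for each binary problem is picked by inner
    cross-validation on the training fold. Without explicit fold indices a
    seeded stratified split is used. Class pairs missing from a fold are
    skipped with a warning.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import GridSearchCV, train_test_split
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if train_idx is None:
        train_idx, test_idx = train_test_split(
            np.arange(len(y)), test_size=0.25, random_state=seed, stratify=y)
    aucs = []
    for c1, c2 in combinations(classes, 2):
        tr = [i for i in train_idx if y[i] in (c1, c2)]
        te = [i for i in test_idx if y[i] in (c1, c2)]
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            warnings.warn(f"class pair ({c1}, {c2}) absent from a fold; skipped",
                          stacklevel=2)
            continue
        svc = GridSearchCV(SVC(kernel="rbf"),
                           {"gamma": ["scale", 0.01, 0.1, 1.0]}, cv=3)
        svc.fit(X[tr], (y[tr] == c2).astype(int))
        score = svc.decision_function(X[te])
        aucs.append(roc_auc_score((y[te] == c2).astype(int), score))
    return float(np.mean(aucs))


def drop_robustness_curve(model: DFINEModel, session, truth=None,
                          ratios=(0.05, 0.1, 0.2, 0.5, 1.0),
                          modes=("filter", "smooth"), seed: int = 0,
                          metric: str = "trajectory_nrmse") -> MetricReport:
    """Inference accuracy as a function of the observed datapoint ratio.

    The model is trained on fully observed data; drops are applied at test
    time only. With simulation ground truth the metric is the NRMSE between
    the inferred manifold trajectory (decoded y_hat, first 3 dims) and the
    true 3-D trajectory; otherwise the reconstruction NRMSE against y itself.
    """
    y = getattr(session, "y", session)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 2:
        y = y[None]
    traj = None
    if truth is not None:
        traj = truth.traj3d if hasattr(truth, "traj3d") else np.asarray(truth)
        if traj.ndim == 2:
            traj = traj[None]
    report = MetricReport()
    for rho in ratios:
        mask = apply_data_drop(y, DropConfig(observed_ratio=rho, seed=seed))
        for mode in modes:
            vals = []
            for i, trial in enumerate(y):
                res = infer_latents(model, trial, mask=mask[i], mode=mode)
                if traj is not None:
                    vals.append(nrmse(traj[i], res.y_hat[:, : traj.shape[-1]]))
                else:
                    vals.append(nrmse(trial, res.y_hat))
            report.add(metric, np.mean(vals), fold=-1, mode=mode, ratio=rho)
    return report


def lorenz_recovery_cc(inferred_train, true_train, inferred_test, true_test,
                       ridge: float = 0.0) -> float:
    """CC of true Lorenz latents reconstructed by a linear map fit on train.

    The linear projection absorbs rotation/scaling indeterminacy of the
    learned latent space. Rank-deficient fits fall back to ridge-regularized
    least squares with a warning.
    """
    Xtr = np.asarray(inferred_train, float).reshape(-1, np.shape(inferred_train)[-1])
    Xte = np.asarray(inferred_test, float).reshape(-1, np.shape(inferred_test)[-1])
    Str = np.asarray(true_train, float).reshape(len(Xtr), -1)
    Ste = np.asarray(true_test, float).reshape(len(Xte), -1)
    Xtr1 = np.hstack([Xtr, np.ones((len(Xtr), 1))])
    Xte1 = np.hstack([Xte, np.ones((len(Xte), 1))])
    if ridge == 0.0 and np.linalg.matrix_rank(Xtr1) < Xtr1.shape[1]:
        warnings.warn("rank-deficient latent design; using ridge-regularized fit",
                      stacklevel=2)
        ridge = 1e-6
    if ridge > 0:
        G = Xtr1.T @ Xtr1 + ridge * np.eye(Xtr1.shape[1])
        B = np.linalg.solve(G, Xtr1.T @ Str)
    else:
        B, *_ = np.linalg.lstsq(Xtr1, Str, rcond=None)
    return pearson_cc(Ste, Xte1 @ B)
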