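"""Session container, file formats and preprocessing.

The HDF5 session layout is /y (float64), /mask (uint8), /z, /labels,
/trial_lengths, with attributes {dt, n_y, n_z, created, seed}. Ragged trials
are stored padded with the per-trial lengths index. CSV is supported for
simple continuous single-stream data with a header time,ch1..chN.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

__all__ = ["SessionData", "read_session", "write_session", "smooth_firing_rates"]


@dataclass
class SessionData:
    """Trials or a continuous stream of multivariate observations.

    y is (n_trials, T, n_y) for trial data or (T, n_y) for a single stream;
    mask matches y's time axes (True = observed); z holds optional behaviour
    with the same leading shape; trial_lengths indexes ragged trials stored
    padded.
    """

    y: np.ndarray
    mask: np.ndarray | None = None
    z: np.ndarray | None = None
    labels: np.ndarray | None = None
    trial_lengths: np.ndarray | None = None
    dt: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.ndim not in (2, 3):
            raise DataError(f"y must be (T, n_y) or (n_trials, T, n_y), got {self.y.shape}")
        t_shape = self.y.shape[:-1]
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != t_shape:
                raise FormatError(
                    f"mask shape {self.mask.shape} does not match time axes {t_shape}"
                )
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=np.float64)
            if self.z.shape[:-1] != t_shape:
                raise FormatError(
                    f"behaviour shape {self.z.shape} does not match time axes {t_shape}"
                )
        obs = self.y if self.mask is None else self.y[self.mask]
        if np.isnan(obs).any():
            raise DataError("NaN found in observed entries of y")

    @property
    def n_trials(self) -> int:
        return 1 if self.y.ndim == 2 else self.y.shape[0]

    @property
    def n_y(self) -> int:
        return self.y.shape[-1]

    def effective_mask(self) -> np.ndarray:
        if self.mask is not None:
            return self.mask
        return np.ones(self.y.shape[:-1], dtype=bool)

    def trials(self):
        """Iterate (y_i, mask_i, z_i) with padding stripped via trial_lengths."""
        if self.y.ndim == 2:
            yield self.y, self.mask, self.z
            return
        for i in range(self.y.shape[0]):
            L = self.y.shape[1] if self.trial_lengths is None else int(self.trial_lengths[i])
            yield (self.y[i, :L],
                   None if self.mask is None else self.mask[i, :L],
                   None if self.z is None else self.z[i, :L])

    def subset(self, indices) -> "SessionData":
        """Trial subset (for cross-validation folds)."""
        if self.y.ndim == 2:
            raise ValueError("subset applies to trial-structured sessions")
        idx = np.asarray(indices)
        return SessionData(
            y=self.y[idx],
            mask=None if self.mask is None else self.mask[idx],
            z=None if self.z is None else self.z[idx],
            labels=None if self.labels is None else self.labels[idx],
            trial_lengths=None if self.trial_lengths is None else self.trial_lengths[idx],
            dt=self.dt, seed=self.seed,
        )


def write_session(data: SessionData, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("y", data=data.y)
        if data.mask is not None:
            f.create_dataset("mask", data=data.mask.astype(np.uint8))
        if data.z is not None:
            f.create_dataset("z", data=data.z)
        if data.labels is not None:
            labels = np.asarray(data.labels)
            if labels.dtype.kind in "UO":
                labels = labels.astype("S")
            f.create_dataset("labels", data=labels)
        if data.trial_lengths is not None:
            f.create_dataset("trial_lengths", data=np.asarray(data.trial_lengths, dtype=np.int64))
        f.attrs["dt"] = data.dt
        f.attrs["n_y"] = data.n_y
        f.attrs["n_z"] = -1 if data.z is None else data.z.shape[-1]
        f.attrs["created"] = datetime.datetime.now().isoformat()
        if data.seed is not None:
            f.attrs["seed"] = data.seed


def read_session(path: str) -> SessionData:
    """Read a session from HDF5 (or CSV for a continuous single stream)."""
    if path.endswith(".csv"):
        return _read_csv(path)
    with h5py.File(path, "r") as f:
        if "y" not in f:
            raise FormatError(f"{path}: missing required dataset /y")
        kwargs = dict(
            y=f["y"][()],
            mask=f["mask"][()].astype(bool) if "mask" in f else None,
            z=f["z"][()] if "z" in f else None,
            trial_lengths=f["trial_lengths"][()] if "trial_lengths" in f else None,
            dt=float(f.attrs.get("dt", 0.05)),
        )
        if "labels" in f:
            labels = f["labels"][()]
            if labels.dtype.kind == "S":
                labels = labels.astype(str)
            kwargs["labels"] = labels
        if "seed" in f.attrs:
            kwargs["seed"] = int(f.attrs["seed"])
    return SessionData(**kwargs)


def _read_csv(path: str) -> SessionData:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: CSV needs a time column plus channels")
    time_col = df.columns[0]
    t = df[time_col].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.05
    y = df.drop(columns=[time_col]).to_numpy(dtype=float)
    return SessionData(y=y, dt=dt)


def smooth_firing_rates(spike_counts: np.ndarray, bin_ms: float = 10.0,
                        kernel_sd_ms: float = 30.0, step_ms: float = 50.0,
                        truncate_sd: float = 4.0) -> np.ndarray:
    """Causal Gaussian smoothing of spike counts, then downsampling.

    Counts arrive in `bin_ms` bins; a one-sided (past-only) Gaussian kernel
    with `kernel_sd_ms` standard deviation, truncated at `truncate_sd` sds and
    renormalized to unit mass over its causal support, is applied per channel;
    every (step_ms / bin_ms)-th sample is kept, so the output rate at each
    50 ms step depends only on spikes up to that time.
    """
    counts = np.asarray(spike_counts, dtype=np.float64)
    if counts.ndim == 1:
        counts = counts[:, None]
    if (counts < 0).any():
        raise DataError("spike counts must be non-negative")
    sd_bins = kernel_sd_ms / bin_ms
    half = int(np.ceil(truncate_sd * sd_bins))
    lags = np.arange(half + 1)          # 0 = current bin, positive = past
    kernel = np.exp(-0.5 * (lags / sd_bins) ** 2)
    kernel /= kernel.sum()
    T = counts.shape[0]
    smoothed = np.zeros_like(counts)
    for lag, w in zip(lags, kernel):
        if lag == 0:
            smoothed += w * counts
        else:
            smoothed[lag:] += w * counts[:-lag]
        # leading edge: kernel mass renormalized over available past
    norm = np.minimum(np.cumsum(kernel), 1.0)[np.minimum(np.arange(T), half)]
    smoothed /= norm[:, None]
    step = int(round(step_ms / bin_ms))
    out = smoothed[step - 1:: step]
    return out
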