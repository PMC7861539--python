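"""Per-epoch early-warning features of the probed LFP.

After each probing pulse a 400 ms post-stimulus epoch is cut from each
population's LFP.  From every epoch the pipeline computes the classical
critical-slowing-down indicators — variance, skewness, kurtosis and lag-1
autocorrelation — plus the mutual information between the two populations'
epochs as a synchrony measure.  Each per-epoch feature series is then
smoothed with a moving-average filter of order 20.

Conventions: moments use the 1/n (biased) normalization; kurtosis is the
Pearson ratio m4/m2^2 (a Gaussian gives 3), so rank-based downstream
statistics are unaffected by the excess-kurtosis shift.  Mutual information
is the plug-in histogram estimate with equal-width bins over each epoch's
own range, in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimulationResult

__all__ = [
    "EpochMatrix",
    "FeatureSeries",
    "FEATURE_NAMES",
    "extract_epochs",
    "moment_features",
    "lag1_autocorrelation",
    "mutual_information",
    "smooth",
    "compute_features",
]

FEATURE_NAMES = ("variance", "skewness", "kurtosis", "lag1_ac", "mutual_information")

DEFAULT_WINDOW_S = 0.400
DEFAULT_MA_ORDER = 20
DEFAULT_MI_BINS = 16


@dataclass
class EpochMatrix:
    """Post-stimulus LFP windows: ``epochs[pop]`` has shape (n_epochs, n_samples)."""

    epochs: np.ndarray        #: (2, n_epochs, window_len)
    onset_times: np.ndarray   #: (n_epochs,) epoch start times (s)
    dt: float


@dataclass
class FeatureSeries:
    """Per-epoch feature values and their smoothed variants.

    ``values[feature]`` has shape (2, n_epochs) for per-population features
    and (n_epochs,) for mutual information.
    """

    values: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray]
    epoch_times: np.ndarray
    param_values: np.ndarray | None = None  #: ramped parameter at epoch onsets

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: epoch_time_s, population, feature, raw_value, smoothed_value."""
        rows = []
        for name in FEATURE_NAMES:
            raw, sm = self.values[name], self.smoothed[name]
            if raw.ndim == 1:
                pops, raws, sms = [0], [raw], [sm]
            else:
                pops, raws, sms = [1, 2], list(raw), list(sm)
            for pop, r, s in zip(pops, raws, sms):
                rows.append(pd.DataFrame({
                    "epoch_time_s": self.epoch_times,
                    "population": pop,
                    "feature": name,
                    "raw_value": r,
                    "smoothed_value": s,
                }))
        return pd.concat(rows, ignore_index=True)


def extract_epochs(result: SimulationResult, window_s: float = DEFAULT_WINDOW_S) -> EpochMatrix:
    """Cut one post-stimulus window per pulse onset from both LFP traces.

    Epochs start at the onset sample; windows that would run past the end of
    the trace are dropped.  Passive (zero-amplitude) runs use the same
    virtual pulse schedule, so probed and passive feature series are aligned.
    """
    onsets = result.stim_onsets[0]
    if len(onsets) == 0:
        raise ValueError("no stimulus onsets available for epoch extraction")
    dt = result.dt
    diffs = np.diff(onsets)
    if len(diffs) and window_s > diffs.min():
        raise ValueError("epoch window must not exceed the stimulation period")
    win = int(np.floor(window_s / dt))
    idx = np.searchsorted(result.time, onsets - 1e-9)
    idx = idx[idx + win <= result.lfp.shape[1]]
    eps = np.stack([
        np.stack([result.lfp[p, i:i + win] for i in idx]) for p in range(2)
    ])
    return EpochMatrix(epochs=eps, onset_times=result.time[idx], dt=dt)


def moment_features(epoch) -> tuple[float, float, float]:
    """(variance, skewness, kurtosis) of one sample window.

    Variance uses 1/n normalization; skewness is m3/m2^(3/2); kurtosis is
    Pearson's m4/m2^2.  A zero-variance window yields variance 0 and NaN for
    the standardized moments.
    """
    x = np.asarray(epoch, dtype=float)
    if x.size < 4:
        raise ValueError("moment features need at least 4 samples")
    d = x - x.mean()
    m2 = np.mean(d ** 2)
    if m2 == 0.0:
        return 0.0, np.nan, np.nan
    m3 = np.mean(d ** 3)
    m4 = np.mean(d ** 4)
    return float(m2), float(m3 / m2 ** 1.5), float(m4 / m2 ** 2)


def lag1_autocorrelation(epoch) -> float:
    """Sample lag-1 autocorrelation r1 = sum d_t d_{t+1} / sum d_t^2, in [-1, 1]."""
    x = np.asarray(epoch, dtype=float)
    if x.size < 3:
        raise ValueError("lag-1 autocorrelation needs at least 3 samples")
    d = x - x.mean()
    denom = np.dot(d, d)
    if denom == 0.0:
        return np.nan
    return float(np.dot(d[:-1], d[1:]) / denom)


def mutual_information(epoch1, epoch2, n_bins: int = DEFAULT_MI_BINS) -> float:
    """Plug-in histogram mutual information between two equal-length epochs, in bits.

    Each epoch is discretized into ``n_bins`` equal-width bins over its own
    range.  A constant epoch carries no information: MI is 0.
    """
    x = np.asarray(epoch1, dtype=float)
    y = np.asarray(epoch2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("epochs must have equal length")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))


def smooth(series, order: int = DEFAULT_MA_ORDER, centered: bool = False) -> np.ndarray:
    """Moving-average filter over a per-epoch feature series.

    Default alignment is causal: each output is the mean of the last
    ``order`` available values (shorter prefixes average what exists), which
    is the natural choice for forecasting.  NaN entries are ignored.
    ``centered=True`` uses a symmetric window instead.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    x = np.asarray(series, dtype=float)
    s = pd.Series(x)
    if centered:
        return s.rolling(order, min_periods=1, center=True).mean().to_numpy()
    return s.rolling(order, min_periods=1).mean().to_numpy()


def compute_features(result: SimulationResult, *, window_s: float = DEFAULT_WINDOW_S,
                     ma_order: int = DEFAULT_MA_ORDER, mi_bins: int = DEFAULT_MI_BINS,
                     centered: bool = False) -> FeatureSeries:
    """Full feature pipeline: epoch extraction, per-epoch features, smoothing."""
    em = extract_epochs(result, window_s)
    n = em.epochs.shape[1]
    var = np.empty((2, n))
    skw = np.empty((2, n))
    kur = np.empty((2, n))
    ac1 = np.empty((2, n))
    mi = np.empty(n)
    for k in range(n):
        for p in range(2):
            var[p, k], skw[p, k], kur[p, k] = moment_features(em.epochs[p, k])
            ac1[p, k] = lag1_autocorrelation(em.epochs[p, k])
        mi[k] = mutual_information(em.epochs[0, k], em.epochs[1, k], mi_bins)

    values = {"variance": var, "skewness": skw, "kurtosis": kur,
              "lag1_ac": ac1, "mutual_information": mi}
    smoothed = {
        name: (np.stack([smooth(v[p], ma_order, centered) for p in range(2)])
               if v.ndim == 2 else smooth(v, ma_order, centered))
        for name, v in values.items()
    }

    param_values = None
    if result.param_name:
        pos = np.searchsorted(result.time, em.onset_times - 1e-9)
        param_values = result.param_trace[pos]
    return FeatureSeries(values=values, smoothed=smoothed,
                         epoch_times=em.onset_times, param_values=param_values)
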