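"""Probing-efficiency scoring and the stimulus-amplitude sweep.

The forecasting value of a feature is scored as the Spearman rank
correlation between its smoothed per-epoch series and the ramped parameter
evaluated at the epoch onsets: a feature that tracks the slow drift toward
the ictal threshold earns |rho| near 1, an uninformative one near 0.

The amplitude sweep repeats this over a grid of probing amplitudes
(0 = passive observation up to 200 APs/s in steps of 20 by default) with
several independent realizations per amplitude, then compares each
amplitude's rho distribution against the passive baseline with Tukey's HSD.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import features as feat
from .protocol import ModelSetting, StimulusProtocol
from .simulate import IntegrationSpec, IntegrationDivergedError, integrate

__all__ = [
    "SweepResult",
    "spearman_rho",
    "realization_seed",
    "run_realization",
    "run_amplitude_sweep",
    "tukey_hsd_vs_passive",
]

log = logging.getLogger(__name__)

DEFAULT_AMPLITUDES = tuple(range(0, 201, 20))
DEFAULT_N_REALIZATIONS = 15


def spearman_rho(feature_series, parameter_series) -> float:
    """Spearman's rank correlation between a feature series and the ramp.

    Both series are ranked (ties get average ranks) and the Pearson
    correlation of the ranks is returned.  Missing (NaN) pairs are dropped
    first; an all-tied series has no defined ranking direction and yields
    NaN.
    """
    x = np.asarray(feature_series, dtype=float)
    y = np.asarray(parameter_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


def realization_seed(base_seed: int, setting_name: str, amplitude: float, realization: int) -> int:
    """Deterministic per-cell seed; distinct across amplitudes and realizations."""
    key = f"{base_seed}|{setting_name}|{amplitude:g}|{realization}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


@dataclass
class SweepResult:
    """Per-(amplitude, realization) correlation table plus significance flags."""

    correlations: pd.DataFrame  #: setting, feature, population, amplitude, realization, seed, rho
    significance: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: setting, feature, population, amplitude, significant_vs_passive, p_adj

    def rho_groups(self, feature: str, population: int) -> dict[float, np.ndarray]:
        """Per-amplitude arrays of rho for one (feature, population)."""
        df = self.correlations
        sel = df[(df.feature == feature) & (df.population == population)]
        return {amp: g.rho.to_numpy() for amp, g in sel.groupby("amplitude")}


def run_realization(setting: ModelSetting, amplitude: float, seed: int, *,
                    duration: float = 2000.0, dt: float = 0.00195,
                    feature_kwargs: dict | None = None) -> pd.DataFrame:
    """One simulation + feature extraction + rho for every feature/population."""
    stim = StimulusProtocol(amplitude=amplitude, targets=setting.stim_targets)
    spec = IntegrationSpec(dt=dt, duration=duration, seed=seed)
    result = integrate(setting, stim, spec)
    fs = feat.compute_features(result, **(feature_kwargs or {}))
    if fs.param_values is None:
        raise ValueError("setting has no ramp; nothing to correlate against")

    rows = []
    for name in feat.FEATURE_NAMES:
        sm = fs.smoothed[name]
        if sm.ndim == 1:
            pops = [(0, sm)]
        else:
            pops = [(1, sm[0]), (2, sm[1])]
        for pop, series in pops:
            rho = spearman_rho(series, fs.param_values)
            rows.append({"setting": setting.name, "feature": name, "population": pop,
                         "amplitude": amplitude, "seed": seed, "rho": rho})
    return pd.DataFrame(rows)


def run_amplitude_sweep(setting: ModelSetting, amplitudes=DEFAULT_AMPLITUDES,
                        n_realizations: int = DEFAULT_N_REALIZATIONS, base_seed: int = 0, *,
                        duration: float = 2000.0, dt: float = 0.00195,
                        alpha: float = 0.05,
                        feature_kwargs: dict | None = None) -> SweepResult:
    """Sweep probing amplitude, scoring rho for every feature over realizations.

    Each (amplitude, realization) cell gets its own deterministically derived
    seed, so the whole sweep is reproducible from ``base_seed``.  Diverged
    integrations are logged and excluded.
    """
    amplitudes = list(amplitudes)
    if 0 not in amplitudes:
        raise ValueError("amplitude grid must include 0 (the passive baseline)")
    frames = []
    for amp in amplitudes:
        for k in range(n_realizations):
            seed = realization_seed(base_seed, setting.name, amp, k)
            try:
                df = run_realization(setting, amp, seed, duration=duration, dt=dt,
                                     feature_kwargs=feature_kwargs)
            except IntegrationDivergedError as err:
                log.warning("amplitude %g realization %d diverged: %s", amp, k, err)
                continue
            df["realization"] = k
            frames.append(df)
    corr = pd.concat(frames, ignore_index=True)

    sig_rows = []
    for (name, pop), grp in corr.groupby(["feature", "population"]):
        groups = {amp: g.rho.dropna().to_numpy() for amp, g in grp.groupby("amplitude")}
        groups = {a: v for a, v in groups.items() if len(v) >= 2}
        if len(groups) < 2 or 0 not in groups:
            continue
        flags = tukey_hsd_vs_passive(groups, alpha=alpha)
        for amp, (sig, p_adj) in flags.items():
            sig_rows.append({"setting": setting.name, "feature": name, "population": pop,
                             "amplitude": amp, "significant_vs_passive": sig, "p_adj": p_adj})
    return SweepResult(correlations=corr, significance=pd.DataFrame(sig_rows))


def tukey_hsd_vs_passive(groups: dict[float, np.ndarray], alpha: float = 0.05,
                         baseline: float = 0.0) -> dict[float, tuple[bool, float]]:
    """Tukey HSD of each amplitude group against the passive (amplitude-0) group.

    All-pairs Tukey HSD is computed (the Tukey–Kramer adjustment applies
    automatically for unequal group sizes); returned flags cover only the
    comparisons against the baseline group.

    Returns
    -------
    dict
        amplitude -> (significant at ``alpha``, adjusted p-value).
    """
    amps = sorted(groups)
    if len(amps) < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    if baseline not in groups:
        raise ValueError("baseline group missing")
    for a in amps:
        if len(groups[a]) < 2:
            raise ValueError("each group needs at least 2 values")
    res = stats.tukey_hsd(*[np.asarray(groups[a], float) for a in amps])
    i0 = amps.index(baseline)
    out = {}
    for j, amp in enumerate(amps):
        if amp == baseline:
            continue
        p = float(res.pvalue[i0, j])
        out[amp] = (p < alpha, p)
    return out
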