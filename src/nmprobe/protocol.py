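"""Probing-stimulus trains, parameter ramps, and named experimental settings.

The probing paradigm injects brief rectangular pulses of afferent
action-potential density into the pyramidal-cell input of one or both
populations: pulses of width 10 ms and amplitude ``E_stim`` (APs/s) every
2 s, i.e. a 0.5 Hz train far below entrainment frequencies.

A simulation is driven toward (or across) the ictal threshold by linearly
ramping exactly one parameter over the run: the excitatory gain ``A_1``, the
slow inhibitory gain ``B_1``, or the inter-population coupling ``K``.  The
named settings pair a ramp with a stimulation laterality:

========  ===============  ==================  ====================
name      ramp             stimulated          scenario
========  ===============  ==================  ====================
I-A       A1 2.5 -> 4.6    population 2        probe the healthy side
I-B       B1 45 -> 30      population 2        probe the healthy side
I-K       K  0.0 -> 0.5    population 2        probe one side
II-A      A1 2.5 -> 4.6    both                bilateral probing
II-B      B1 45 -> 30      both                bilateral probing
II-K      K  0.0 -> 0.5    both                bilateral probing
S-A       A1 2.5 -> 4.6    population 1        probe the ictogenic side
S-B       B1 45 -> 30      population 1        probe the ictogenic side
========  ===============  ==================  ====================
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import CoupledModelConfig

__all__ = [
    "StimulusProtocol",
    "ParameterRamp",
    "ModelSetting",
    "SETTING_NAMES",
    "stimulus_value",
    "ramp_value",
    "build_setting",
]

RAMPABLE = ("A1", "B1", "K")


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic rectangular probing-pulse train in pulse-density units."""

    amplitude: float = 0.0        #: E_stim, APs/s
    pulse_width: float = 0.010    #: s
    period: float = 2.0           #: s
    targets: tuple[int, ...] = (1, 2)  #: stimulated populations (1-based)
    start_time: float = 2.0       #: s; first pulse onset

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be >= 0")
        if not (0 < self.pulse_width < self.period):
            raise ValueError("require 0 < pulse_width < period")
        if any(t not in (1, 2) for t in self.targets):
            raise ValueError("targets must be a subset of {1, 2}")

    def onset_times(self, duration: float):
        """Pulse onset times in [start_time, duration)."""
        import numpy as np

        n = int(np.floor((duration - self.start_time) / self.period)) + 1
        times = self.start_time + self.period * np.arange(max(n, 0))
        return times[times < duration]


@dataclass(frozen=True)
class ParameterRamp:
    """Linear shift of one model parameter over a time window, clamped outside."""

    parameter: str
    start_value: float
    end_value: float
    t_start: float = 0.0
    t_end: float = 2000.0

    def __post_init__(self) -> None:
        if self.parameter not in RAMPABLE:
            raise ValueError(f"ramped parameter must be one of {RAMPABLE}")
        if not self.t_start < self.t_end:
            raise ValueError("require t_start < t_end")


@dataclass(frozen=True)
class ModelSetting:
    """A named experimental condition: base parameters + ramp + stimulation targets."""

    name: str
    config: CoupledModelConfig
    ramp: ParameterRamp | None
    stim_targets: tuple[int, ...]


def stimulus_value(t: float, protocol: StimulusProtocol, population: int) -> float:
    """Stimulus pulse density s_i(t) in APs/s for one population at time t."""
    if t < 0:
        raise ValueError("time must be >= 0")
    if population not in protocol.targets:
        return 0.0
    phase = t - protocol.start_time
    if phase < 0:
        return 0.0
    return protocol.amplitude if (phase % protocol.period) < protocol.pulse_width else 0.0


def ramp_value(t: float, ramp: ParameterRamp) -> float:
    """Ramped parameter value at time t (linear between endpoints, clamped outside)."""
    if t < 0:
        raise ValueError("time must be >= 0")
    if t <= ramp.t_start:
        return ramp.start_value
    if t >= ramp.t_end:
        return ramp.end_value
    frac = (t - ramp.t_start) / (ramp.t_end - ramp.t_start)
    return ramp.start_value + frac * (ramp.end_value - ramp.start_value)


# (ramp parameter, start, end, stimulated populations)
_REGISTRY: dict[str, tuple[str, float, float, tuple[int, ...]]] = {
    "I-A": ("A1", 2.5, 4.6, (2,)),
    "I-B": ("B1", 45.0, 30.0, (2,)),
    "I-K": ("K", 0.0, 0.5, (2,)),
    "II-A": ("A1", 2.5, 4.6, (1, 2)),
    "II-B": ("B1", 45.0, 30.0, (1, 2)),
    "II-K": ("K", 0.0, 0.5, (1, 2)),
    "S-A": ("A1", 2.5, 4.6, (1,)),
    "S-B": ("B1", 45.0, 30.0, (1,)),
}

SETTING_NAMES = tuple(_REGISTRY)


def build_setting(
    name: str,
    *,
    ramp_start: float | None = None,
    ramp_end: float | None = None,
    t_start: float = 0.0,
    t_end: float = 2000.0,
    config: CoupledModelConfig | None = None,
) -> ModelSetting:
    """Construct a registered model setting, optionally overriding the ramp.

    Parameters not touched by the ramp keep their defaults.  For the B-ramp
    settings the non-ramped population keeps ``B_2 = 40``; the ramp overrides
    ``B_1`` during integration, so the base ``B_1`` value is immaterial.

    Raises
    ------
    KeyError
        If ``name`` is not registered; the message lists valid names.
    """
    if name not in _REGISTRY:
        raise KeyError(f"unknown model setting {name!r}; valid names: {', '.join(_REGISTRY)}")
    param, lo, hi, targets = _REGISTRY[name]
    if ramp_start is not None:
        lo = ramp_start
    if ramp_end is not None:
        hi = ramp_end
    cfg = config if config is not None else CoupledModelConfig()
    if param == "K":
        # base K is replaced by the ramp each step; start it at the ramp origin
        cfg = replace(cfg, K=lo)
    ramp = ParameterRamp(parameter=param, start_value=lo, end_value=hi,
                         t_start=t_start, t_end=t_end)
    return ModelSetting(name=name, config=cfg, ramp=ramp, stim_targets=targets)


# Ramps that push each scenario past the ictal threshold, for the pro-ictal
# safety test.  The A ramp 4.30 -> 4.95 is the documented pro-ictal window;
# the B and K extensions are package choices that verifiably cross the
# sustained-discharge threshold.
PROICTAL_RAMPS: dict[str, tuple[float, float]] = {
    "A": (4.30, 4.95),
    "B": (45.0, 25.0),
    "K": (0.0, 0.8),
}


def build_proictal_setting(name: str, *, t_end: float = 2000.0) -> ModelSetting:
    """A registered setting with its ramp extended beyond the ictal threshold."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown model setting {name!r}; valid names: {', '.join(_REGISTRY)}")
    kind = _REGISTRY[name][0][0].replace("A1", "A").replace("B1", "B")[0]
    lo, hi = PROICTAL_RAMPS[kind]
    return build_setting(name, ramp_start=lo, ramp_end=hi, t_end=t_end)
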