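"""Euler–Maruyama integration of the coupled stochastic delayed system.

The system is integrated on a fixed grid (default step 1.95 ms, i.e. a
512 Hz sampling rate).  At each step an independent Gaussian pulse density
``p_i ~ N(mu, sigma)`` is drawn per population and held constant over the
step, the ramped parameter is evaluated at the current time, the partner's
delayed excitatory PSP state is read from the recorded trajectory
(``round(tau_d / dt)`` steps back, zeros before the delay horizon), and the
state advances by one explicit Euler step.  The hot loop is JIT-compiled
with numba.

Noise convention: drawing one ``N(mu, sigma)`` pulse-density value per step
treats ``p_i(t)`` as a piecewise-constant input signal, which makes the
effective noise power depend on the step size.  This is the convention of
the model lineage and the default here; set ``noise_mode="sqrt_dt"`` to
scale the fluctuations by ``1/sqrt(dt)`` instead, which recovers the formal
Euler–Maruyama diffusion scaling and makes noise power step-size invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import NoiseSpec, N_STATE
from .protocol import ModelSetting, StimulusProtocol, stimulus_value, ramp_value

__all__ = [
    "IntegrationSpec",
    "SimulationResult",
    "IntegrationDivergedError",
    "integrate",
    "noise_stream",
]


class IntegrationDivergedError(RuntimeError):
    """The state became non-finite during integration."""

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(f"integration diverged at step {step} (t = {time:.3f} s)")


@dataclass(frozen=True)
class IntegrationSpec:
    """Numerical parameters of one simulation run."""

    dt: float = 0.00195      #: step size (s); 1.95 ms = 512 Hz sampling
    duration: float = 2000.0  #: simulated time (s)
    seed: int = 0             #: RNG seed; (seed, config) fixes the output bit-for-bit
    record_states: bool = False
    noise_mode: str = "per_sample"  #: "per_sample" or "sqrt_dt"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise_mode not in ("per_sample", "sqrt_dt"):
            raise ValueError("noise_mode must be 'per_sample' or 'sqrt_dt'")

    @property
    def n_steps(self) -> int:
        return int(np.floor(self.duration / self.dt))


@dataclass
class SimulationResult:
    """Recorded output of one integration run."""

    time: np.ndarray           #: sample times (s), length n_steps
    lfp: np.ndarray            #: (2, n_steps) LFP traces (mV)
    stim_onsets: tuple[np.ndarray, np.ndarray]  #: grid-aligned pulse onset times per population
    param_trace: np.ndarray    #: ramped-parameter value at each sample
    param_name: str
    seed: int
    dt: float
    states: np.ndarray | None = None  #: optional (n_steps, 20) full state traces
    setting_name: str = ""

    def to_frame(self):
        """Tidy per-sample table: time_s, lfp1_mV, lfp2_mV, param_value, stim1, stim2."""
        import pandas as pd

        stim1 = np.zeros(len(self.time), dtype=int)
        stim2 = np.zeros(len(self.time), dtype=int)
        stim1[np.searchsorted(self.time, self.stim_onsets[0])] = 1
        stim2[np.searchsorted(self.time, self.stim_onsets[1])] = 1
        return pd.DataFrame({
            "time_s": self.time,
            "lfp1_mV": self.lfp[0],
            "lfp2_mV": self.lfp[1],
            "param_value": self.param_trace,
            "stim1": stim1,
            "stim2": stim2,
        })

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["seed"] = self.seed
            f.attrs["dt"] = self.dt
            f.attrs["param_name"] = self.param_name
            f.attrs["setting_name"] = self.setting_name
            f.create_dataset("time", data=self.time)
            f.create_dataset("lfp", data=self.lfp)
            f.create_dataset("param_trace", data=self.param_trace)
            f.create_dataset("stim_onsets_1", data=self.stim_onsets[0])
            f.create_dataset("stim_onsets_2", data=self.stim_onsets[1])
            if self.states is not None:
                f.create_dataset("states", data=self.states)

    @classmethod
    def load_hdf5(cls, path) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                time=f["time"][:],
                lfp=f["lfp"][:],
                stim_onsets=(f["stim_onsets_1"][:], f["stim_onsets_2"][:]),
                param_trace=f["param_trace"][:],
                param_name=str(f.attrs["param_name"]),
                seed=int(f.attrs["seed"]),
                dt=float(f.attrs["dt"]),
                states=f["states"][:] if "states" in f else None,
                setting_name=str(f.attrs["setting_name"]),
            )


def noise_stream(spec: NoiseSpec, seed, n_steps: int) -> np.ndarray:
    """I.i.d. N(mu, sigma) pulse-density sequence, one value per step."""
    if n_steps <= 0:
        raise ValueError("n_steps must be > 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    return rng.normal(spec.mu, spec.sigma, n_steps)


@njit(cache=True)
def _sig(v, v0, e0, r):
    return 2.0 * e0 / (1.0 + np.exp(r * (v0 - v)))


@njit(cache=True)
def _em_loop(n_steps, dt, lag, p1, p2, s1, s2, ramp, param_code,
             pp1, pp2, K0, lfp_coupling, record_states):
    """Explicit Euler loop.  pp = [A,B,G,a,b,g,C1..C7,v0,e0,r] per population.

    Returns (lfp (2, n), y1 history (2, n), states or empty, diverged_step).
    """
    y = np.zeros(N_STATE)
    lfp = np.zeros((2, n_steps))
    hist = np.zeros((2, n_steps))  # y_{i,1} trajectory, source of delayed coupling
    states = np.zeros((n_steps, N_STATE)) if record_states else np.zeros((0, N_STATE))
    dy = np.zeros(N_STATE)
    A = np.array([pp1[0], pp2[0]])
    B = np.array([pp1[1], pp2[1]])
    G = np.array([pp1[2], pp2[2]])
    diverged = -1

    for n in range(n_steps):
        K = K0
        if param_code == 0:
            A[0] = ramp[n]
        elif param_code == 1:
            B[0] = ramp[n]
        elif param_code == 2:
            K = ramp[n]

        if n >= lag and lag >= 0:
            d1 = hist[1, n - lag]  # partner of population 1 is population 2
            d2 = hist[0, n - lag]
        else:
            d1 = 0.0
            d2 = 0.0

        for i in range(2):
            pp = pp1 if i == 0 else pp2
            off = 10 * i
            a, b, g = pp[3], pp[4], pp[5]
            C1, C2, C3, C4, C5, C6, C7 = pp[6], pp[7], pp[8], pp[9], pp[10], pp[11], pp[12]
            v0, e0, r = pp[13], pp[14], pp[15]
            dpart = d1 if i == 0 else d2
            p = p1[n] if i == 0 else p2[n]
            s = s1[n] if i == 0 else s2[n]

            y0, y1_, y2, y3, y4 = y[off], y[off + 1], y[off + 2], y[off + 3], y[off + 4]
            y5, y6, y7, y8, y9 = y[off + 5], y[off + 6], y[off + 7], y[off + 8], y[off + 9]

            v_pyr = K * dpart + y1_ - y2 - y3
            lfp[i, n] = v_pyr if lfp_coupling else (y1_ - y2 - y3)
            hist[i, n] = y1_
            if record_states:
                for k in range(N_STATE):
                    states[n, k] = y[k]

            dy[off] = y5
            dy[off + 5] = A[i] * a * _sig(v_pyr, v0, e0, r) - 2.0 * a * y5 - a * a * y0
            dy[off + 1] = y6
            dy[off + 6] = (A[i] * a * (s + p + C2 * _sig(C1 * y0, v0, e0, r))
                           - 2.0 * a * y6 - a * a * y1_)
            dy[off + 2] = y7
            dy[off + 7] = B[i] * b * C4 * _sig(C3 * y0, v0, e0, r) - 2.0 * b * y7 - b * b * y2
            dy[off + 3] = y8
            dy[off + 8] = (G[i] * g * C7 * _sig(C5 * y0 - C6 * y4, v0, e0, r)
                           - 2.0 * g * y8 - g * g * y3)
            dy[off + 4] = y9
            dy[off + 9] = B[i] * b * _sig(C3 * y0, v0, e0, r) - 2.0 * b * y9 - b * b * y4

        ok = True
        for k in range(N_STATE):
            y[k] = y[k] + dt * dy[k]
            if not np.isfinite(y[k]):
                ok = False
        if not ok:
            diverged = n
            break

    return lfp, hist, states, diverged


def _pack(pp) -> np.ndarray:
    return np.array([pp.A, pp.B, pp.G, pp.a, pp.b, pp.g,
                     pp.C1, pp.C2, pp.C3, pp.C4, pp.C5, pp.C6, pp.C7,
                     pp.v0, pp.e0, pp.r])


def integrate(setting: ModelSetting, stim: StimulusProtocol,
              spec: IntegrationSpec) -> SimulationResult:
    """Integrate one model setting under a probing protocol.

    Identical ``(setting, stim, spec)`` inputs yield bit-identical results.

    Raises
    ------
    IntegrationDivergedError
        If the state becomes non-finite (parameter blow-up).
    """
    cfg = setting.config
    n_steps = spec.n_steps
    dt = spec.dt
    g_max = max(cfg.params_1.g, cfg.params_2.g)
    if dt >= 2.0 / g_max:
        warnings.warn(
            f"dt = {dt} exceeds the explicit-Euler stability bound 2/g = {2.0 / g_max:.4g} "
            "for the fastest synaptic block", stacklevel=2)

    t = dt * np.arange(n_steps)

    # per-population noise: independent child streams of the run seed
    ss = np.random.SeedSequence(spec.seed)
    child1, child2 = ss.spawn(2)
    scale = 1.0 / np.sqrt(dt) if spec.noise_mode == "sqrt_dt" else 1.0
    p1 = cfg.noise_1.mu + scale * (noise_stream(NoiseSpec(0.0, cfg.noise_1.sigma), child1, n_steps))
    p2 = cfg.noise_2.mu + scale * (noise_stream(NoiseSpec(0.0, cfg.noise_2.sigma), child2, n_steps))

    # stimulus trains evaluated on the grid
    s1 = np.array([stimulus_value(ti, stim, 1) for ti in t]) if 1 in stim.targets \
        else np.zeros(n_steps)
    s2 = np.array([stimulus_value(ti, stim, 2) for ti in t]) if 2 in stim.targets \
        else np.zeros(n_steps)

    # ramped parameter evaluated on the grid
    if setting.ramp is not None:
        ramp_arr = np.array([ramp_value(ti, setting.ramp) for ti in t])
        param_code = {"A1": 0, "B1": 1, "K": 2}[setting.ramp.parameter]
        param_name = setting.ramp.parameter
    else:
        ramp_arr = np.zeros(n_steps)
        param_code = -1
        param_name = ""

    lag = int(round(cfg.tau_d / dt))
    lfp, _hist, states, diverged = _em_loop(
        n_steps, dt, lag, p1, p2, s1, s2, ramp_arr, param_code,
        _pack(cfg.params_1), _pack(cfg.params_2), cfg.K,
        cfg.lfp_includes_coupling, spec.record_states)
    if diverged >= 0:
        raise IntegrationDivergedError(diverged, diverged * dt)

    # grid-aligned pulse onset times: first stimulated sample of each pulse
    sched = stim.onset_times(spec.duration)
    idx = np.ceil(sched / dt - 1e-9).astype(int)
    idx = idx[idx < n_steps]
    onsets = t[idx]

    return SimulationResult(
        time=t,
        lfp=lfp,
        stim_onsets=(onsets if 1 in stim.targets else onsets.copy(),
                     onsets if 2 in stim.targets else onsets.copy()),
        param_trace=ramp_arr if setting.ramp is not None else np.full(n_steps, np.nan),
        param_name=param_name,
        seed=spec.seed,
        dt=dt,
        states=states if spec.record_states else None,
        setting_name=setting.name,
    )
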