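"""Coupled two-population Wendling neural mass model.

Each population lumps the CA1 circuit into four interacting neural masses:
pyramidal cells, excitatory interneurons (a self-feedback loop on the
pyramidal cells), slow dendrite-projecting inhibitory interneurons, and fast
soma-projecting inhibitory interneurons.  Every synaptic pathway is a
second-order linear "pulse to wave" filter (impulse response
``h(t) = G * w * t * exp(-w*t)`` with gain ``G`` in mV and rate ``w`` in 1/s)
and every mass converts its mean membrane potential to a firing density via
the asymmetric sigmoid "wave to pulse" function.

Two such populations are coupled bidirectionally through their pyramidal
cells with a dimensionless gain ``K`` and a pure transmission delay
``tau_d``, representing inter-hemispheric hippocampal coupling.

State layout: each population carries ten scalars ``y0..y9``, where
``(y0..y4)`` are post-synaptic potentials in mV and ``(y5..y9)`` their time
derivatives in mV/s.  The full coupled state is the 20-vector
``[y_{1,0}..y_{1,9}, y_{2,0}..y_{2,9}]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PopulationParams",
    "NoiseSpec",
    "CoupledModelConfig",
    "N_STATE",
    "sigmoid",
    "derivatives",
    "lfp_output",
    "psp_block_rhs",
    "psp_impulse_response",
]

#: number of scalars in the coupled state vector (10 per population)
N_STATE = 20


@dataclass(frozen=True)
class PopulationParams:
    """Fixed parameters of a single Wendling population.

    Defaults correspond to the normal-background operating point of the
    coupled model.
    """

    A: float = 4.0    #: excitatory synaptic gain (mV)
    B: float = 40.0   #: slow dendritic inhibitory gain (mV)
    G: float = 20.0   #: fast somatic inhibitory gain (mV)
    a: float = 100.0  #: excitatory time constant (1/s)
    b: float = 50.0   #: slow inhibitory time constant (1/s)
    g: float = 350.0  #: fast inhibitory time constant (1/s)
    C1: float = 135.0          #: pyramidal -> excitatory interneuron contacts
    C2: float = 0.8 * 135.0    #: excitatory interneuron -> pyramidal contacts
    C3: float = 0.25 * 135.0   #: pyramidal -> slow inhibitory contacts
    C4: float = 0.25 * 135.0   #: slow inhibitory -> pyramidal contacts
    C5: float = 0.1 * 135.0    #: pyramidal -> fast inhibitory contacts
    C6: float = 0.1 * 135.0    #: slow -> fast inhibitory contacts
    C7: float = 0.8 * 135.0    #: fast inhibitory -> pyramidal contacts
    v0: float = 6.0   #: sigmoid half-activation potential (mV)
    e0: float = 2.5   #: half of the maximal firing density (1/s)
    r: float = 0.56   #: sigmoid steepness (1/mV)

    def __post_init__(self) -> None:
        for name in ("a", "b", "g", "e0", "r", "C1", "C2", "C3", "C4", "C5", "C6", "C7"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PopulationParams.{name} must be > 0")

    def with_(self, **kwargs) -> "PopulationParams":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian pulse-density input to the pyramidal cells.

    ``mu`` and ``sigma`` are the mean and standard deviation of the afferent
    action-potential density, in APs/s.
    """

    mu: float = 90.0
    sigma: float = 1.3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("NoiseSpec.sigma must be >= 0")


@dataclass(frozen=True)
class CoupledModelConfig:
    """Complete parameterization of the two-population coupled system.

    Coupling is bidirectional and symmetric (``K_12 = K_21 = K``) with a
    pure delay ``tau_d`` on the inter-population pathway.  ``lfp_includes_coupling``
    selects whether the recorded LFP contains the delayed partner
    contribution (the full membrane potential driving pyramidal firing) or
    only the local PSP balance.
    """

    params_1: PopulationParams = field(default_factory=PopulationParams)
    params_2: PopulationParams = field(default_factory=PopulationParams)
    K: float = 0.3
    tau_d: float = 0.010
    noise_1: NoiseSpec = field(default_factory=NoiseSpec)
    noise_2: NoiseSpec = field(default_factory=NoiseSpec)
    lfp_includes_coupling: bool = True

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("coupling gain K must be >= 0")
        if self.tau_d < 0:
            raise ValueError("coupling delay tau_d must be >= 0")


def sigmoid(v, params: PopulationParams = PopulationParams()):
    """Wave-to-pulse function: mean membrane potential (mV) -> firing density (APs/s).

    ``S(v) = 2*e0 / (1 + exp(r*(v0 - v)))``; strictly increasing, bounded in
    ``(0, 2*e0)``, with ``S(v0) = e0`` exactly.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid: membrane potential must be finite")
    out = 2.0 * params.e0 / (1.0 + np.exp(params.r * (params.v0 - v)))
    return float(out) if out.ndim == 0 else out


def psp_block_rhs(position: float, velocity: float, drive: float,
                  gain: float, rate: float) -> tuple[float, float]:
    """One second-order "pulse to wave" synaptic filter.

    Converts an incoming pulse density ``drive`` (APs/s) to a post-synaptic
    potential: ``y'' = gain*rate*drive - 2*rate*y' - rate^2 * y``, the state-space
    form of the impulse response ``h(t) = gain * rate * t * exp(-rate*t)``
    (peak ``gain/e`` at ``t = 1/rate``).

    Returns ``(dy/dt, dv/dt)`` for the (position, velocity) pair.
    """
    return velocity, gain * rate * drive - 2.0 * rate * velocity - rate * rate * position


def psp_impulse_response(t, gain: float, rate: float):
    """Closed-form impulse response ``gain * rate * t * exp(-rate*t)`` of one filter."""
    t = np.asarray(t, dtype=float)
    return gain * rate * t * np.exp(-rate * t)


def _population_derivs(y, dy, off, p, s, delayed_partner_y1, K, pp: PopulationParams):
    """Right-hand side for one population; writes into ``dy[off:off+10]``."""
    A, B, G, a, b, g = pp.A, pp.B, pp.G, pp.a, pp.b, pp.g
    y0, y1, y2, y3, y4 = y[off + 0], y[off + 1], y[off + 2], y[off + 3], y[off + 4]
    y5, y6, y7, y8, y9 = y[off + 5], y[off + 6], y[off + 7], y[off + 8], y[off + 9]

    v_pyr = K * delayed_partner_y1 + y1 - y2 - y3
    # five synaptic filters per population: pyramidal drive, external input,
    # slow inhibition, fast inhibition, slow inhibition onto fast interneurons
    dy[off + 0], dy[off + 5] = psp_block_rhs(y0, y5, sigmoid(v_pyr, pp), A, a)
    dy[off + 1], dy[off + 6] = psp_block_rhs(
        y1, y6, s + p + pp.C2 * sigmoid(pp.C1 * y0, pp), A, a)
    dy[off + 2], dy[off + 7] = psp_block_rhs(y2, y7, pp.C4 * sigmoid(pp.C3 * y0, pp), B, b)
    dy[off + 3], dy[off + 8] = psp_block_rhs(
        y3, y8, pp.C7 * sigmoid(pp.C5 * y0 - pp.C6 * y4, pp), G, g)
    dy[off + 4], dy[off + 9] = psp_block_rhs(y4, y9, sigmoid(pp.C3 * y0, pp), B, b)


def derivatives(state, p, s, delayed_y1, config: CoupledModelConfig):
    """Time-derivative of the coupled 20-dimensional state.

    Parameters
    ----------
    state
        Length-20 coupled state vector.
    p
        Pair of noise pulse densities ``(p_1, p_2)`` in APs/s.
    s
        Pair of stimulus pulse densities ``(s_1, s_2)`` in APs/s.
    delayed_y1
        Pair ``(y_{2,1}(t - tau_d), y_{1,1}(t - tau_d))``: for each
        population, the *partner's* delayed excitatory PSP state.
    config
        Coupled model parameters.

    Returns
    -------
    numpy.ndarray
        Length-20 derivative vector.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},)")
    inputs = np.concatenate([y, np.asarray(p, float), np.asarray(s, float),
                             np.asarray(delayed_y1, float)])
    if not np.all(np.isfinite(inputs)):
        raise ValueError("derivatives: all inputs must be finite")

    dy = np.empty(N_STATE)
    _population_derivs(y, dy, 0, p[0], s[0], delayed_y1[0], config.K, config.params_1)
    _population_derivs(y, dy, 10, p[1], s[1], delayed_y1[1], config.K, config.params_2)
    return dy


def lfp_output(state, delayed_y1, config: CoupledModelConfig):
    """Per-population LFP (mV): the mean membrane potential of the pyramidal cells.

    ``LFP_i = K * y_{j,1}(t - tau_d) + y_{i,1} - y_{i,2} - y_{i,3}``; the
    delayed coupling term is dropped when ``config.lfp_includes_coupling`` is
    False.
    """
    y = np.asarray(state, dtype=float)
    K = config.K if config.lfp_includes_coupling else 0.0
    lfp1 = K * delayed_y1[0] + y[1] - y[2] - y[3]
    lfp2 = K * delayed_y1[1] + y[11] - y[12] - y[13]
    return np.array([lfp1, lfp2])
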