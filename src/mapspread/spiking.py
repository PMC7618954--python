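"""Conductance-based leaky integrate-and-fire dynamics.

Point neurons with an after-hyperpolarisation (AHP) conductance and three
synaptic channels (AMPA, GABA, NMDA).  The membrane equation is integrated
with forward Euler; conductances are dimensionless multiples of the leak
conductance (printed in nS), so synaptic currents g·(V−V_rev) carry units of
nS·mV = pA.

These functions are the reference, unit-testable form of the dynamics; the
full-network runs use the compiled engine in :mod:`mapspread._engine`, which
is cross-checked against this module in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NumericalInstabilityError(RuntimeError):
    """Raised when a state variable becomes non-finite during integration."""


@dataclass(frozen=True)
class NeuronParams:
    """Membrane, refractory and channel constants.

    Time constants in ms, potentials in mV, conductances in nS.
    """

    tau_m: float = 30.0
    V_rest: float = -65.0
    V_th: float = -50.0
    V_AMPA: float = 0.0
    V_NMDA: float = 0.0
    V_GABA: float = -80.0
    V_AHP: float = -80.0
    tau_ref_E: float = 5.0
    tau_ref_I: float = 2.5
    tau_AHP: float = 100.0
    A_AHP: float = 5.0
    tau_AMPA: float = 5.0
    tau_GABA: float = 10.0
    tau_NMDA: float = 150.0
    # leak conductance (nS): the membrane equation's conductances are
    # dimensionless multiples of leak, so printed nS weights are divided
    # by g_leak where they enter the voltage dynamics
    g_leak: float = 7.0
    # coupling of the slow NMDA channel relative to AMPA: an excitatory
    # spike through weight w increments g_AMPA by w and g_NMDA by
    # nmda_mix * w.  External (sensory/background) synapses carry the
    # full printed NMDA coupling, which is what lets a 0.5 nS probe
    # drive its assembly to high rates against the AHP; recurrent
    # synapses use an attenuated mix, because at full recurrent NMDA
    # coupling the 150 ms channel carries ~30x the AMPA charge and the
    # recurrent loop has no balanced regime at the printed weights.
    nmda_mix: float = 0.1
    nmda_mix_input: float = 1.0
    # whether inhibitory neurons carry the AHP adaptation current.
    # Fast-spiking interneurons show little spike-frequency adaptation;
    # adapting inhibition lets the whole network lock into AHP-paced
    # population bursts, so adaptation is excitatory-only by default
    ahp_inhibitory: bool = False
    # membrane integrator: "exp" (exponential Euler: exact for conductances
    # frozen within a step, unconditionally stable) or "euler" (forward
    # Euler, which becomes unstable once total conductance approaches
    # 2 tau_m/dt and is only suitable for low-conductance regimes)
    integrator: str = "exp"

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_ref_E", "tau_ref_I", "tau_AHP",
                     "tau_AMPA", "tau_GABA", "tau_NMDA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.V_GABA == self.V_AHP <= self.V_rest < self.V_th
                < self.V_AMPA == self.V_NMDA):
            raise ValueError("reversal potentials violate "
                             "V_GABA=V_AHP<=V_rest<V_th<V_AMPA=V_NMDA")


@dataclass
class PopulationState:
    """Per-neuron dynamical state: potential, conductances, refractoriness."""

    V: np.ndarray
    g_AHP: np.ndarray
    g_AMPA: np.ndarray
    g_GABA: np.ndarray
    g_NMDA: np.ndarray
    refractory_remaining: np.ndarray

    @classmethod
    def resting(cls, n: int, params: NeuronParams) -> "PopulationState":
        z = lambda: np.zeros(n)
        return cls(V=np.full(n, params.V_rest), g_AHP=z(), g_AMPA=z(),
                   g_GABA=z(), g_NMDA=z(), refractory_remaining=z())

    @property
    def n(self) -> int:
        return self.V.shape[0]


def integrate_membrane(
    state: PopulationState,
    params: NeuronParams,
    is_excitatory: np.ndarray,
    dt: float,
    step: int = 0,
) -> np.ndarray:
    """Advance the membrane potential one Euler step; return the spike vector.

    Non-refractory neurons follow
    ``tau_m dV/dt = (V_rest - V) + sum_X g_X (V_X - V)``; a neuron crossing
    threshold emits a spike, is reset to ``V_rest`` and clamped there for the
    refractory time of its class.  ``refractory_remaining`` is decremented by
    ``dt`` first, so a neuron whose clamp expires this step resumes
    integrating immediately.

    Parameters
    ----------
    is_excitatory : bool array
        Chooses the refractory time per neuron (5 ms E, 2.5 ms I).
    step : int
        Only used to label a numerical-instability error.

    Returns
    -------
    spikes : bool array, True where a spike was emitted this step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params
    ref = state.refractory_remaining
    clamped = ref > 0.0
    ref[clamped] -= dt
    state.V[clamped] = p.V_rest

    free = ~clamped
    V = state.V
    if params.integrator == "exp":
        g_tot = (1.0 + state.g_AHP + state.g_AMPA + state.g_GABA
                 + state.g_NMDA)
        V_inf = (p.V_rest + state.g_AHP * p.V_AHP + state.g_AMPA * p.V_AMPA
                 + state.g_GABA * p.V_GABA + state.g_NMDA * p.V_NMDA) / g_tot
        decay = np.exp(-g_tot * (dt / p.tau_m))
        V_new = V_inf + (V - V_inf) * decay
        V[free] = V_new[free]
    else:
        dV = (
            (p.V_rest - V)
            + state.g_AHP * (p.V_AHP - V)
            + state.g_AMPA * (p.V_AMPA - V)
            + state.g_GABA * (p.V_GABA - V)
            + state.g_NMDA * (p.V_NMDA - V)
        ) * (dt / p.tau_m)
        V[free] += dV[free]
        # the exact solution can never leave the reversal-potential range;
        # clamping removes the overshoot a stiff Euler step would produce
        np.maximum(V, p.V_GABA, out=V)

    if not np.all(np.isfinite(V)):
        bad = int(np.flatnonzero(~np.isfinite(V))[0])
        raise NumericalInstabilityError(
            f"non-finite membrane potential at neuron {bad}, step {step}")

    spikes = (V >= p.V_th) & free
    V[spikes] = p.V_rest
    ref[spikes & is_excitatory] = p.tau_ref_E
    ref[spikes & ~is_excitatory] = p.tau_ref_I
    return spikes


def update_ahp(
    state: PopulationState,
    spikes: np.ndarray,
    params: NeuronParams,
    dt: float,
) -> None:
    """Decay g_AHP with tau_AHP and add A_AHP per postsynaptic spike."""
    g = state.g_AHP
    g -= g * (dt / params.tau_AHP)
    g[spikes] += params.A_AHP
    assert np.all(g >= 0.0), "AHP conductance went negative"


def update_conductance(
    g: np.ndarray,
    tau_X: float,
    presyn_spikes: np.ndarray,
    weights: np.ndarray,
    dt: float,
) -> np.ndarray:
    """One Euler step of a synaptic conductance channel.

    ``g`` decays with ``tau_X``; each presynaptic spike from neuron j adds
    its weight ``weights[j, :]`` to the targets.  ``weights`` has shape
    (n_pre, n_post); a spike in a bin of width dt contributes its full
    increment at the end of the bin.
    """
    if weights.shape[0] != presyn_spikes.shape[0]:
        raise ValueError(
            f"weights rows ({weights.shape[0]}) do not match spike vector "
            f"length ({presyn_spikes.shape[0]})")
    if np.any(weights < 0):
        raise ValueError("synaptic weights must be non-negative")
    g = g - g * (dt / tau_X)
    if presyn_spikes.any():
        g = g + weights[presyn_spikes].sum(axis=0)
    return g


def poisson_spikes(
    rate_hz: float,
    n_neurons: int,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Bernoulli(rate·dt) spike indicators for one step.

    ``dt`` in ms.  Valid only in the sparse-firing regime rate·dt << 1.
    """
    p = rate_hz * dt * 1e-3
    if p >= 1.0:
        raise ValueError(f"rate*dt = {p} >= 1; decrease dt or rate")
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    return rng.random(n_neurons) < p
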