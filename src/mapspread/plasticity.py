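"""Co-dependent excitatory and inhibitory plasticity.

Weight changes depend jointly on spike timing (via exponential traces of the
pre- and postsynaptic spike trains) and on the local excitatory and
inhibitory synaptic currents (low-pass filtered NMDA and GABA currents).
Excitatory changes are multiplicatively gated by ``exp[-(I/I*)^gamma]``, so
strong inhibition freezes excitatory learning; the inhibitory rule pushes the
filtered E/I current ratio toward the balance point alpha.

Current traces are kept per postsynaptic neuron: E is the filtered magnitude
of the total NMDA current (inward current counted positive), I the filtered
total GABA current.  Each neuron carries one trace per role (pre-side trace
of its own spikes, post-side traces of its own spikes); the synapse-level
rules read the appropriate neuron's trace.

The model prose and the printed trace equations disagree on which spike
train drives which trace; the prose pairing (presynaptic traces driven by
presynaptic spikes) is the default, and ``as_printed=True`` reproduces the
literal printed pairing, which swaps the pre/post roles of the traces inside
the weight updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PlasticityParams:
    """Learning rates, gate constants and trace time constants (ms)."""

    A_LTP: float = 3e-4
    A_LTD: float = 3e-5
    A_het: float = 1.5e-8
    I_star: float = 200.0
    gamma: float = 3.0
    tau_plus: float = 16.8
    tau_minus: float = 33.7
    tau_yE: float = 100.0
    A_ISP: float = 1e-3
    # E/I balance point: the inhibitory rule's fixed point is I = E/alpha
    # in trace units.  The default E_star/I_star holds the baseline
    # inhibitory trace at I* (gate e^-1) while the excitatory trace sits
    # at its stationary level E_star
    alpha: float = 16.8
    tau_STDP: float = 20.0
    tau_E_curr: float = 10.0
    tau_I_curr: float = 100.0
    as_printed: bool = False
    w_max: float = np.inf
    # one-shot calibration constants: raw currents (conductance x driving
    # force) are divided by these before entering the traces, chosen so
    # the balanced baseline sits at (E_star, I_star) -- the point where
    # excitatory weights are stationary and the gate is half-engaged
    current_scale: float = 1.0
    current_scale_I: float = 1.0

    @property
    def E_star(self) -> float:
        """Heterosynaptic fixed point of the excitatory trace.

        At E = E_star the expected potentiation A_LTP·x̄·E and
        heterosynaptic depression A_het·ȳE·E² cancel for equal pre/post
        rates (x̄/ȳE = tau_plus/tau_yE), independently of the gate, so
        excitatory weights neither grow nor shrink on average.
        """
        return self.A_LTP * self.tau_plus / (self.A_het * self.tau_yE)

    def __post_init__(self) -> None:
        for name in ("A_LTP", "A_LTD", "A_het", "A_ISP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_plus", "tau_minus", "tau_yE", "tau_STDP",
                     "tau_E_curr", "tau_I_curr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class CurrentTraces:
    """Filtered NMDA (E) and GABA (I) current per excitatory neuron, in pA."""

    E_trace: np.ndarray
    I_trace: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "CurrentTraces":
        return cls(np.zeros(n), np.zeros(n))


@dataclass
class SynapticTraces:
    """Per-neuron spike traces feeding the plasticity rules.

    x_plus, y_minus, y_E, y_isp are indexed by excitatory neuron; x_isp by
    inhibitory neuron.  Each is an exponentially filtered record of that
    neuron's own spike train (unit increment per spike).
    """

    x_plus: np.ndarray
    y_minus: np.ndarray
    y_E: np.ndarray
    x_isp: np.ndarray
    y_isp: np.ndarray

    @classmethod
    def zeros(cls, n_exc: int, n_inh: int) -> "SynapticTraces":
        return cls(np.zeros(n_exc), np.zeros(n_exc), np.zeros(n_exc),
                   np.zeros(n_inh), np.zeros(n_exc))


def inhibitory_gate(I_trace_value, I_star: float, gamma: float):
    """Multiplicative gate exp[-(I/I*)^gamma] on excitatory weight changes.

    Equals 1 at I=0, e^-1 at I=I*, and decays super-exponentially beyond:
    high inhibitory current shuts excitatory plasticity down.
    """
    I = np.asarray(I_trace_value, dtype=float)
    out = np.exp(-((I / I_star) ** gamma))
    return float(out) if np.isscalar(I_trace_value) else out


def update_current_traces(
    traces: CurrentTraces,
    nmda_current_magnitude: np.ndarray,
    gaba_current: np.ndarray,
    params: PlasticityParams,
    dt: float,
) -> None:
    """Low-pass filter the per-neuron NMDA and GABA currents (Euler step).

    ``nmda_current_magnitude`` is the positive magnitude of the total inward
    NMDA current, g_NMDA·(V_NMDA−V); ``gaba_current`` is the outward GABA
    current g_GABA·(V−V_GABA).  Both are >= 0 away from pathological
    overshoot; the traces are clipped at 0 to honour the sign convention.
    """
    traces.E_trace += (nmda_current_magnitude / params.current_scale
                       - traces.E_trace) * (dt / params.tau_E_curr)
    traces.I_trace += (gaba_current / params.current_scale_I
                       - traces.I_trace) * (dt / params.tau_I_curr)
    np.maximum(traces.E_trace, 0.0, out=traces.E_trace)
    np.maximum(traces.I_trace, 0.0, out=traces.I_trace)
    if np.any(traces.E_trace < 0) or np.any(traces.I_trace < 0):
        raise AssertionError("current trace went negative")


def update_spike_traces(
    traces: SynapticTraces,
    exc_spikes: np.ndarray,
    inh_spikes: np.ndarray,
    params: PlasticityParams,
    dt: float,
) -> None:
    """Decay all spike traces and add unit increments for this step's spikes.

    Every trace records its own neuron's spikes; the pre/post pairing is
    applied where the traces are *used* (see apply_* below), so this update
    is identical under either drive-term convention.
    """
    traces.x_plus -= traces.x_plus * (dt / params.tau_plus)
    traces.y_minus -= traces.y_minus * (dt / params.tau_minus)
    traces.y_E -= traces.y_E * (dt / params.tau_yE)
    traces.x_isp -= traces.x_isp * (dt / params.tau_STDP)
    traces.y_isp -= traces.y_isp * (dt / params.tau_STDP)
    traces.x_plus[exc_spikes] += 1.0
    traces.y_minus[exc_spikes] += 1.0
    traces.y_E[exc_spikes] += 1.0
    traces.y_isp[exc_spikes] += 1.0
    traces.x_isp[inh_spikes] += 1.0


def apply_excitatory_plasticity(
    w_EE: np.ndarray,
    mask: np.ndarray,
    traces: SynapticTraces,
    currents: CurrentTraces,
    exc_spikes: np.ndarray,
    params: PlasticityParams,
) -> np.ndarray:
    """Event-driven co-dependent update of E->E weights (dense form).

    ``w_EE[j, k]`` is the weight from presynaptic neuron j to postsynaptic
    neuron k; ``mask`` marks existing synapses.  Per synapse,

        dw = [A_LTP x+_pre S_post E_post - A_LTD y-_post S_pre w
              - A_het yE_post S_post E_post^2] · exp[-(I_post/I*)^gamma]

    with the S terms equal to 1/dt inside spike bins, so each spike event
    contributes the bracketed amount once.  Traces are read *before* their
    increment for this step's spikes (no self-pairing), and weights are
    clipped at 0 (and at w_max if finite).
    """
    p = params
    gate = inhibitory_gate(currents.I_trace, p.I_star, p.gamma)
    pre_spk = exc_spikes.astype(float)
    post_spk = pre_spk
    if p.as_printed:
        # printed pairing: LTP trace is the postsynaptic neuron's tau_+
        # trace, LTD trace is the presynaptic neuron's tau_- trace
        ltp = p.A_LTP * np.outer(post_spk, traces.x_plus * currents.E_trace)
        ltd = p.A_LTD * (traces.y_minus * pre_spk)[:, None] * w_EE
    else:
        ltp = p.A_LTP * np.outer(traces.x_plus, post_spk * currents.E_trace)
        ltd = p.A_LTD * pre_spk[:, None] * (traces.y_minus[None, :] * w_EE)
    het = p.A_het * (post_spk * traces.y_E * currents.E_trace ** 2)[None, :]
    dw = (ltp - ltd - het) * gate
    if not np.all(np.isfinite(dw)):
        raise RuntimeError(
            "non-finite excitatory weight change; gate range "
            f"[{gate.min()}, {gate.max()}], E range "
            f"[{currents.E_trace.min()}, {currents.E_trace.max()}]")
    out = np.clip(w_EE + dw * mask, 0.0, p.w_max)
    return out


def apply_inhibitory_plasticity(
    w_IE: np.ndarray,
    mask: np.ndarray,
    traces: SynapticTraces,
    currents: CurrentTraces,
    inh_spikes: np.ndarray,
    exc_spikes: np.ndarray,
    params: PlasticityParams,
) -> np.ndarray:
    """Event-driven co-dependent update of I->E weights (dense form).

    Per synapse j (inhibitory) onto post (excitatory),

        dw = A_ISP (E_post/I*) ((E_post - alpha I_post)/I*)
             · (x_pre S_post + y_post S_pre)

    a symmetric spike-pair rule whose sign is set by the deviation of the
    filtered currents from balance: above balance (E > alpha I) inhibition
    strengthens, below it weakens.  The current factors are expressed in
    units of I* so the printed learning rate produces nS-scale steps.
    Weights are clipped at 0.
    """
    p = params
    drive = p.A_ISP * (currents.E_trace / p.I_star) * (
        (currents.E_trace - p.alpha * currents.I_trace) / p.I_star)
    pre_spk = inh_spikes.astype(float)
    post_spk = exc_spikes.astype(float)
    if p.as_printed:
        pair = (np.outer(np.ones_like(pre_spk), post_spk * traces.y_isp)
                + np.outer(pre_spk * traces.x_isp, np.ones_like(post_spk)))
    else:
        pair = (np.outer(traces.x_isp, post_spk)
                + np.outer(pre_spk, traces.y_isp))
    dw = drive[None, :] * pair
    if not np.all(np.isfinite(dw)):
        raise RuntimeError("non-finite inhibitory weight change")
    return np.maximum(w_IE + dw * mask, 0.0)
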