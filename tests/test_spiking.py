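"""Unit checks of the membrane, conductance and spike-train primitives."""

import numpy as np
import pytest

from mapspread.spiking import (
    NeuronParams, NumericalInstabilityError, PopulationState,
    integrate_membrane, poisson_spikes, update_ahp, update_conductance,
)

P_EULER = NeuronParams(integrator="euler")
DT = 0.1


def _state(n=1, **over):
    st = PopulationState.resting(n, P_EULER)
    for k, v in over.items():
        getattr(st, k)[:] = v
    return st


def test_resting_network_is_a_fixed_point():
    st = _state(5)
    exc = np.ones(5, bool)
    for _ in range(100):
        spikes = integrate_membrane(st, P_EULER, exc, DT)
        assert not spikes.any()
    assert np.allclose(st.V, P_EULER.V_rest)


@pytest.mark.parametrize("integrator", ["euler", "exp"])
@pytest.mark.parametrize("g", [0.2, 1.0, 3.0])
def test_constant_conductance_converges_to_closed_form(integrator, g):
    # dV/dt = 0 gives V_inf = (V_rest + g V_X) / (1 + g); a GABA
    # conductance keeps the trajectory below threshold
    p = NeuronParams(integrator=integrator)
    st = _state(1, g_GABA=g)
    exc = np.ones(1, bool)
    for _ in range(int(10 * p.tau_m / DT)):
        st.g_GABA[:] = g  # hold constant
        integrate_membrane(st, p, exc, DT)
    v_inf = (p.V_rest + g * p.V_GABA) / (1 + g)
    assert st.V[0] == pytest.approx(v_inf, abs=0.05)


def test_threshold_crossing_resets_and_clamps_5ms():
    st = _state(1)
    st.V[:] = P_EULER.V_th + 1.0
    exc = np.ones(1, bool)
    spikes = integrate_membrane(st, P_EULER, exc, DT)
    assert spikes[0]
    assert st.V[0] == P_EULER.V_rest
    # clamped at rest for tau_ref_E = 5 ms even under strong drive
    n_clamped = 0
    for _ in range(100):
        st.g_AMPA[:] = 50.0
        s = integrate_membrane(st, P_EULER, exc, DT)
        if st.V[0] == P_EULER.V_rest and not s[0]:
            n_clamped += 1
        else:
            break
    assert n_clamped == pytest.approx(50, abs=1)  # 5 ms / 0.1 ms


def test_refractory_time_shorter_for_inhibitory_class():
    st = _state(1)
    st.V[:] = P_EULER.V_th + 1.0
    inh = np.zeros(1, bool)
    integrate_membrane(st, P_EULER, inh, DT)
    assert st.refractory_remaining[0] == pytest.approx(P_EULER.tau_ref_I)


def test_relaxation_to_rest_within_five_tau_m():
    st = _state(1)
    st.V[:] = -51.0
    exc = np.ones(1, bool)
    for _ in range(int(5 * P_EULER.tau_m / DT)):
        integrate_membrane(st, P_EULER, exc, DT)
    assert abs(st.V[0] - P_EULER.V_rest) < 0.1


def test_nonfinite_state_raises_with_neuron_index():
    st = _state(3)
    st.g_AMPA[1] = np.inf
    with pytest.raises(NumericalInstabilityError, match="neuron 1"):
        integrate_membrane(st, P_EULER, np.ones(3, bool), DT, step=7)


def test_euler_halving_dt_is_first_order_accurate():
    # free membrane from a displaced start over 100 ms
    def run(dt):
        p = NeuronParams(integrator="euler")
        st = _state(1)
        st.V[:] = -55.0
        for _ in range(int(100.0 / dt)):
            integrate_membrane(st, p, np.ones(1, bool), dt)
        return st.V[0]

    exact = P_EULER.V_rest + (-55.0 - P_EULER.V_rest) * np.exp(
        -100.0 / P_EULER.tau_m)
    err_dt = abs(run(0.1) - exact)
    err_half = abs(run(0.05) - exact)
    assert err_half < 0.6 * err_dt


def test_ahp_decay_closed_form():
    st = _state(1)
    spk = np.zeros(1, bool)
    # no spikes: zero stays zero
    update_ahp(st, spk, P_EULER, DT)
    assert st.g_AHP[0] == 0.0
    # one spike, then decay for 100 ms -> 5 e^-1
    st.g_AHP[:] = 0.0
    spk[:] = True
    update_ahp(st, spk, P_EULER, DT)
    spk[:] = False
    for _ in range(1000):
        update_ahp(st, spk, P_EULER, DT)
    assert st.g_AHP[0] == pytest.approx(5 * np.exp(-1), rel=1e-2)


def test_ahp_superposition_of_two_spikes():
    st = _state(1)
    spk = np.ones(1, bool)
    update_ahp(st, spk, P_EULER, DT)
    spk[:] = False
    for _ in range(500):  # 50 ms
        update_ahp(st, spk, P_EULER, DT)
    spk[:] = True
    update_ahp(st, spk, P_EULER, DT)
    assert st.g_AHP[0] == pytest.approx(5 * (1 + np.exp(-0.5)), rel=1e-2)


def test_conductance_jump_and_half_life():
    g = np.zeros(1)
    w = np.array([[0.25]])
    g = update_conductance(g, 5.0, np.array([True]), w, DT)
    assert g[0] == pytest.approx(0.25)
    for _ in range(int(round(5 * np.log(2) / DT))):
        g = update_conductance(g, 5.0, np.array([False]), w, DT)
    assert g[0] == pytest.approx(0.125, rel=2e-2)


def test_conductance_linearity_of_simultaneous_spikes():
    g = np.zeros(1)
    w = np.array([[0.1], [0.3]])
    g = update_conductance(g, 5.0, np.array([True, True]), w, DT)
    assert g[0] == pytest.approx(0.4)


def test_conductance_shape_mismatch_raises():
    with pytest.raises(ValueError, match="spike vector"):
        update_conductance(np.zeros(2), 5.0, np.array([True]),
                           np.zeros((2, 2)), DT)


def test_poisson_rate_zero_and_parameter_guard(rng):
    assert not poisson_spikes(0.0, 100, DT, rng).any()
    with pytest.raises(ValueError):
        poisson_spikes(1e7, 10, DT, rng)


def test_poisson_count_statistics(rng):
    # 1 Hz x 100 neurons x 10 s: mean 1000, sd sqrt(1000)
    total = sum(poisson_spikes(1.0, 100, DT, rng).sum()
                for _ in range(100000))
    assert abs(total - 1000) < 3 * np.sqrt(1000)


def test_poisson_expected_count_at_stimulus_rate(rng):
    # 2.5 Hz x 100 neurons x 3.3 s -> mean 825
    n_steps = int(3.3e3 / DT)
    total = sum(poisson_spikes(2.5, 100, DT, rng).sum()
                for _ in range(n_steps))
    assert abs(total - 825) < 3 * np.sqrt(825)


def test_invalid_neuron_params_rejected():
    with pytest.raises(ValueError):
        NeuronParams(tau_m=-1.0)
    with pytest.raises(ValueError):
        NeuronParams(V_rest=-40.0)  # above threshold
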