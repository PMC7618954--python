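"""Unit checks of the co-dependent plasticity rules and their traces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapspread.plasticity import (
    CurrentTraces, PlasticityParams, SynapticTraces,
    apply_excitatory_plasticity, apply_inhibitory_plasticity,
    inhibitory_gate, update_current_traces, update_spike_traces,
)

DT = 0.1
PP = PlasticityParams()


def test_gate_closed_forms():
    assert inhibitory_gate(0.0, 200.0, 3.0) == pytest.approx(1.0)
    assert inhibitory_gate(200.0, 200.0, 3.0) == pytest.approx(np.exp(-1))
    assert inhibitory_gate(400.0, 200.0, 3.0) == pytest.approx(
        np.exp(-8), rel=1e-9)


@given(st.floats(min_value=0.0, max_value=1e4),
       st.floats(min_value=0.0, max_value=1e4))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_gate_is_monotone_decreasing(a, b):
    lo, hi = sorted((a, b))
    assert inhibitory_gate(hi, 200.0, 3.0) <= inhibitory_gate(lo, 200.0, 3.0)


def test_current_traces_decay_to_zero_when_silent():
    tr = CurrentTraces(np.array([5.0]), np.array([7.0]))
    for _ in range(20000):
        update_current_traces(tr, np.zeros(1), np.zeros(1), PP, DT)
    assert tr.E_trace[0] < 1e-6 and tr.I_trace[0] < 1e-6


def test_current_trace_steady_state_matches_input():
    tr = CurrentTraces.zeros(1)
    for _ in range(20000):
        update_current_traces(tr, np.full(1, 42.0), np.full(1, 17.0), PP, DT)
    assert tr.E_trace[0] == pytest.approx(42.0, rel=1e-3)
    assert tr.I_trace[0] == pytest.approx(17.0, rel=1e-3)


def test_inhibitory_trace_first_order_rise():
    tr = CurrentTraces.zeros(1)
    t_ms = 100.0  # one tau_I
    for _ in range(int(t_ms / DT)):
        update_current_traces(tr, np.zeros(1), np.ones(1), PP, DT)
    assert tr.I_trace[0] == pytest.approx(1 - np.exp(-1), rel=2e-2)


def test_spike_trace_decay_time_constants():
    tr = SynapticTraces.zeros(1, 1)
    spk = np.ones(1, bool)
    update_spike_traces(tr, spk, spk, PP, DT)
    assert tr.x_plus[0] == tr.y_minus[0] == 1.0  # both incremented
    no = np.zeros(1, bool)
    for _ in range(168):  # 16.8 ms = tau_plus
        update_spike_traces(tr, no, no, PP, DT)
    assert tr.x_plus[0] == pytest.approx(np.exp(-1), rel=1e-2)


def _dense_setup(n=2):
    w = np.full((n, n), 0.25)
    mask = np.ones((n, n), bool)
    traces = SynapticTraces.zeros(n, n)
    currents = CurrentTraces(np.full(n, 300.0), np.full(n, 100.0))
    return w, mask, traces, currents


def test_no_spikes_leaves_excitatory_weights_unchanged():
    w, mask, tr, cur = _dense_setup()
    out = apply_excitatory_plasticity(w, mask, tr, cur,
                                      np.zeros(2, bool), PP)
    assert np.array_equal(out, w)


def test_strong_inhibition_suppresses_changes_below_1e3():
    w, mask, tr, cur = _dense_setup()
    tr.x_plus[:] = 1.0
    spikes = np.array([False, True])
    open_cur = CurrentTraces(cur.E_trace.copy(), np.zeros(2))
    dw_open = apply_excitatory_plasticity(w, mask, tr, open_cur, spikes,
                                          PP) - w
    closed_cur = CurrentTraces(cur.E_trace.copy(), np.full(2, 400.0))
    dw_closed = apply_excitatory_plasticity(w, mask, tr, closed_cur,
                                            spikes, PP) - w
    assert np.abs(dw_closed).max() < 1e-3 * np.abs(dw_open).max()


def test_term_by_term_structure_of_excitatory_rule():
    # isolated post spike with zero x_plus and y_E: no change
    w, mask, tr, cur = _dense_setup()
    out = apply_excitatory_plasticity(w, mask, tr, cur,
                                      np.array([False, True]), PP)
    assert np.allclose(out, w)
    # isolated pre spike with y_minus > 0: pure depression, scaled by w
    tr.y_minus[:] = 2.0
    out = apply_excitatory_plasticity(w, mask, tr, cur,
                                      np.array([True, False]), PP)
    gate = inhibitory_gate(cur.I_trace[1], PP.I_star, PP.gamma)
    expected = 0.25 * (1 - PP.A_LTD * 2.0 * gate)
    assert out[0, 1] == pytest.approx(expected)
    assert out[1, 0] == 0.25  # no presynaptic spike on that row


def test_inhibitory_rule_balance_fixed_point_and_sign():
    w = np.full((1, 2), 0.31)
    mask = np.ones((1, 2), bool)
    tr = SynapticTraces.zeros(2, 1)
    tr.x_isp[:] = 1.0
    tr.y_isp[:] = 1.0
    both = (np.ones(1, bool), np.ones(2, bool))
    # E = 0: no change regardless of spiking
    cur = CurrentTraces(np.zeros(2), np.full(2, 100.0))
    out = apply_inhibitory_plasticity(w, mask, tr, cur, *both, params=PP)
    assert np.array_equal(out, w)
    # E = alpha I exactly: balance fixed point
    cur = CurrentTraces(np.full(2, PP.alpha * 100.0), np.full(2, 100.0))
    out = apply_inhibitory_plasticity(w, mask, tr, cur, *both, params=PP)
    assert np.allclose(out, w)
    # E above balance with coincident spikes: inhibition strengthens
    cur = CurrentTraces(np.full(2, PP.alpha * 150.0), np.full(2, 100.0))
    out = apply_inhibitory_plasticity(w, mask, tr, cur, *both, params=PP)
    assert np.all(out > w)


def test_invalid_plasticity_params_rejected():
    with pytest.raises(ValueError):
        PlasticityParams(gamma=0.5)
    with pytest.raises(ValueError):
        PlasticityParams(A_LTP=-1e-4)


def test_e_star_is_the_potentiation_depression_crossover():
    # at E = E_star the LTP and heterosynaptic terms cancel for equal
    # pre/post rates (x/yE ratio = tau_plus/tau_yE)
    E = PP.E_star
    r = 5.0
    x_bar = r * PP.tau_plus * 1e-3
    yE_bar = r * PP.tau_yE * 1e-3
    ltp = PP.A_LTP * x_bar * E
    het = PP.A_het * yE_bar * E ** 2
    assert ltp == pytest.approx(het, rel=1e-9)
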