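"""Compiled network integration engine.

``run_stage`` advances the full recurrent network (neurons, Poisson inputs,
conductances, plasticity traces and plastic weights) for a fixed number of
Euler steps inside a single numba-compiled loop.  Spike propagation uses a
one-step (dt) synaptic delay; plasticity is event-driven at spike bins and
reads traces *before* their increment for the current step's spikes, so a
spike never pairs with itself.

``reference_run`` mirrors the same step ordering with the plain-NumPy
operations from :mod:`mapspread.spiking` and :mod:`mapspread.plasticity`
on dense matrices.  It exists to pin the compiled loop to the documented
dynamics: for a deterministic stimulus (no Poisson input) the two paths
agree to machine precision, which the test suite asserts.

Step ordering (both paths):
  1. decay all conductances (AMPA, GABA, NMDA, AHP);
  2. draw Poisson input spikes and add their weights (AMPA+NMDA);
  3. propagate the previous step's recurrent spikes into conductances;
  4. low-pass filter the NMDA/GABA currents (using pre-update V);
  5. membrane Euler step, threshold, reset, refractory clamp, AHP increment;
  6. decay spike traces, apply event-driven weight updates, then increment
     traces for this step's spikes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import plasticity as pl
from . import spiking as sp

STATUS_OK = 0
STATUS_RASTER_OVERFLOW = 1
STATUS_NONFINITE = 2


@njit(cache=True)
def run_stage(
    n_steps, dt, N_E, N_I,
    # neuron constants
    tau_m, V_rest, V_th, V_GABA,
    tau_ref_E, tau_ref_I, tau_AHP, A_AHP, tau_AMPA, tau_GABA, tau_NMDA,
    g_leak, nmda_mix, nmda_mix_input, ahp_inhibitory, exp_integrator,
    # plasticity constants
    plastic_on, as_printed,
    A_LTP, A_LTD, A_het, I_star, gamma_, A_ISP, alpha,
    tau_plus, tau_minus, tau_yE, tau_STDP, tau_E_curr, tau_I_curr, w_max,
    current_scale, current_scale_I,
    # mutable state
    V, g_ahp, g_ampa, g_gaba, g_nmda, ref,
    E_tr, I_tr, x_plus, y_minus, y_E, x_isp, y_isp, prev_spk,
    # recurrent connectivity (CSR by presynaptic neuron; weights mutable)
    rec_indptr, rec_post, rec_w,
    # incoming plastic synapse lists per excitatory postsynaptic neuron
    eein_indptr, eein_pre, eein_sidx,
    iein_indptr, iein_pre, iein_sidx,
    # Poisson inputs (CSR by input neuron)
    in_p, in_indptr, in_post, in_w,
    # recording
    bin_steps, e_counts, i_counts,
    raster_on, r_step, r_id,
    seed,
):
    np.random.seed(seed)
    N = N_E + N_I
    inv_gl = 1.0 / g_leak
    nmda_gl = nmda_mix / g_leak
    nmda_in_gl = nmda_mix_input / g_leak
    n_in = in_p.shape[0]
    cap = r_step.shape[0]
    nr = 0
    status = STATUS_OK
    new_spk = np.zeros(N, np.bool_)

    d_ampa = dt / tau_AMPA
    d_gaba = dt / tau_GABA
    d_nmda = dt / tau_NMDA
    d_ahp = dt / tau_AHP

    for t in range(n_steps):
        b = t // bin_steps

        # 1. conductance decay
        for n in range(N):
            g_ampa[n] -= g_ampa[n] * d_ampa
            g_gaba[n] -= g_gaba[n] * d_gaba
            g_nmda[n] -= g_nmda[n] * d_nmda
            g_ahp[n] -= g_ahp[n] * d_ahp

        # 2. Poisson inputs (excitatory: AMPA + NMDA)
        for i in range(n_in):
            if in_p[i] > 0.0 and np.random.random() < in_p[i]:
                for s in range(in_indptr[i], in_indptr[i + 1]):
                    p_ = in_post[s]
                    g_ampa[p_] += in_w[s] * inv_gl
                    g_nmda[p_] += in_w[s] * nmda_in_gl
                if raster_on:
                    if nr < cap:
                        r_step[nr] = t
                        r_id[nr] = N + i
                        nr += 1
                    else:
                        status = STATUS_RASTER_OVERFLOW

        # 3. recurrent propagation (one-step delay)
        for n in range(N):
            if prev_spk[n]:
                if n < N_E:
                    for s in range(rec_indptr[n], rec_indptr[n + 1]):
                        p_ = rec_post[s]
                        g_ampa[p_] += rec_w[s] * inv_gl
                        g_nmda[p_] += rec_w[s] * nmda_gl
                else:
                    for s in range(rec_indptr[n], rec_indptr[n + 1]):
                        g_gaba[rec_post[s]] += rec_w[s] * inv_gl

        # 4. current traces (excitatory neurons only; V_NMDA = 0)
        for n in range(N_E):
            nm = -g_nmda[n] * V[n] / current_scale
            if nm < 0.0:
                nm = 0.0
            gb = g_gaba[n] * (V[n] - V_GABA) / current_scale_I
            if gb < 0.0:
                gb = 0.0
            E_tr[n] += (nm - E_tr[n]) * dt / tau_E_curr
            I_tr[n] += (gb - I_tr[n]) * dt / tau_I_curr

        # 5. membrane update and spike handling
        for n in range(N):
            if ref[n] > 0.0:
                ref[n] -= dt
                V[n] = V_rest
                new_spk[n] = False
            else:
                v = V[n]
                if exp_integrator:
                    g_tot = (1.0 + g_ahp[n] + g_ampa[n] + g_gaba[n]
                             + g_nmda[n])
                    v_inf = (V_rest + (g_ahp[n] + g_gaba[n]) * V_GABA) / g_tot
                    v = v_inf + (v - v_inf) * np.exp(-g_tot * dt / tau_m)
                else:
                    v += (
                        (V_rest - v)
                        + g_ahp[n] * (V_GABA - v)   # V_AHP = V_GABA
                        + g_ampa[n] * (0.0 - v)
                        + g_gaba[n] * (V_GABA - v)
                        + g_nmda[n] * (0.0 - v)
                    ) * dt / tau_m
                    if v < V_GABA:
                        # a forward-Euler step cannot physically overshoot
                        # the lowest reversal potential
                        v = V_GABA
                if not np.isfinite(v):
                    return nr, STATUS_NONFINITE, n, t
                if v >= V_th:
                    V[n] = V_rest
                    ref[n] = tau_ref_E if n < N_E else tau_ref_I
                    new_spk[n] = True
                    if n < N_E or ahp_inhibitory:
                        g_ahp[n] += A_AHP * inv_gl
                    if n < N_E:
                        e_counts[b, n] += 1
                    else:
                        i_counts[b] += 1
                    if raster_on:
                        if nr < cap:
                            r_step[nr] = t
                            r_id[nr] = n
                            nr += 1
                        else:
                            status = STATUS_RASTER_OVERFLOW
                else:
                    V[n] = v
                    new_spk[n] = False

        # 6. plasticity
        if plastic_on:
            for n in range(N_E):
                x_plus[n] -= x_plus[n] * dt / tau_plus
                y_minus[n] -= y_minus[n] * dt / tau_minus
                y_E[n] -= y_E[n] * dt / tau_yE
                y_isp[n] -= y_isp[n] * dt / tau_STDP
            for n in range(N_I):
                x_isp[n] -= x_isp[n] * dt / tau_STDP

            for n in range(N):
                if not new_spk[n]:
                    continue
                if n < N_E:
                    # presynaptic role: depression of outgoing E->E
                    for s in range(rec_indptr[n], rec_indptr[n + 1]):
                        p_ = rec_post[s]
                        if p_ < N_E:
                            gate = np.exp(-((I_tr[p_] / I_star) ** gamma_))
                            ytr = y_minus[n] if as_printed else y_minus[p_]
                            w = rec_w[s] * (1.0 - A_LTD * ytr * gate)
                            rec_w[s] = w if w > 0.0 else 0.0
                    # postsynaptic role: potentiation + heterosynaptic
                    Et = E_tr[n]
                    gate = np.exp(-((I_tr[n] / I_star) ** gamma_))
                    het = A_het * y_E[n] * Et * Et * gate
                    for s in range(eein_indptr[n], eein_indptr[n + 1]):
                        pre = eein_pre[s]
                        si = eein_sidx[s]
                        xtr = x_plus[n] if as_printed else x_plus[pre]
                        w = rec_w[si] + A_LTP * xtr * Et * gate - het
                        if w < 0.0:
                            w = 0.0
                        elif w > w_max:
                            w = w_max
                        rec_w[si] = w
                    # postsynaptic role: inhibitory rule on incoming I->E
                    drive = A_ISP * (Et / I_star) * (
                        (Et - alpha * I_tr[n]) / I_star)
                    for s in range(iein_indptr[n], iein_indptr[n + 1]):
                        pre_i = iein_pre[s]
                        si = iein_sidx[s]
                        tr = y_isp[n] if as_printed else x_isp[pre_i]
                        w = rec_w[si] + drive * tr
                        rec_w[si] = w if w > 0.0 else 0.0
                else:
                    # inhibitory presynaptic spike: outgoing I->E
                    j = n - N_E
                    for s in range(rec_indptr[n], rec_indptr[n + 1]):
                        p_ = rec_post[s]
                        if p_ < N_E:
                            Et = E_tr[p_]
                            drive = A_ISP * (Et / I_star) * (
                                (Et - alpha * I_tr[p_]) / I_star)
                            tr = x_isp[j] if as_printed else y_isp[p_]
                            w = rec_w[s] + drive * tr
                            rec_w[s] = w if w > 0.0 else 0.0

            for n in range(N_E):
                if new_spk[n]:
                    x_plus[n] += 1.0
                    y_minus[n] += 1.0
                    y_E[n] += 1.0
                    y_isp[n] += 1.0
            for n in range(N_I):
                if new_spk[N_E + n]:
                    x_isp[n] += 1.0

        for n in range(N):
            prev_spk[n] = new_spk[n]

    return nr, status, -1, n_steps


def reference_run(
    n_steps: int,
    dt: float,
    neuron: sp.NeuronParams,
    plast: pl.PlasticityParams,
    state: sp.PopulationState,
    N_E: int,
    W: np.ndarray,
    mask_EE: np.ndarray,
    mask_IE: np.ndarray,
    currents: pl.CurrentTraces,
    traces: pl.SynapticTraces,
    prev_spk: np.ndarray,
    plastic_on: bool = True,
):
    """Dense-matrix reference integration, mirroring ``run_stage`` exactly.

    ``W`` is the full (N, N) weight matrix with presynaptic rows; only the
    E->E and I->E blocks (selected by the masks, expressed in full-matrix
    coordinates) are plastic.  No Poisson inputs are drawn, so the run is
    fully deterministic.  Returns the per-step spike history (n_steps, N).
    """
    N = state.n
    N_I = N - N_E
    gl = neuron.g_leak
    is_exc = np.zeros(N, bool)
    is_exc[:N_E] = True
    no_exc_spk = np.zeros(N_E, bool)
    no_inh_spk = np.zeros(N_I, bool)
    history = np.zeros((n_steps, N), bool)
    for t in range(n_steps):
        pre_E = prev_spk & is_exc
        pre_I = prev_spk & ~is_exc
        w_exc_rows = W[:N_E, :] / gl
        w_inh_rows = W[N_E:, :] / gl
        state.g_AMPA = sp.update_conductance(
            state.g_AMPA, neuron.tau_AMPA, pre_E[:N_E], w_exc_rows, dt)
        state.g_NMDA = sp.update_conductance(
            state.g_NMDA, neuron.tau_NMDA, pre_E[:N_E],
            w_exc_rows * neuron.nmda_mix, dt)
        state.g_GABA = sp.update_conductance(
            state.g_GABA, neuron.tau_GABA, pre_I[N_E:], w_inh_rows, dt)
        state.g_AHP = state.g_AHP - state.g_AHP * (dt / neuron.tau_AHP)

        nmda_mag = np.maximum(-state.g_NMDA[:N_E] * state.V[:N_E], 0.0)
        gaba_cur = np.maximum(
            state.g_GABA[:N_E] * (state.V[:N_E] - neuron.V_GABA), 0.0)
        pl.update_current_traces(currents, nmda_mag, gaba_cur, plast, dt)

        spikes = sp.integrate_membrane(state, neuron, is_exc, dt, step=t)
        ahp_mask = spikes if neuron.ahp_inhibitory else (spikes & is_exc)
        state.g_AHP[ahp_mask] += neuron.A_AHP / gl

        if plastic_on:
            pl.update_spike_traces(traces, no_exc_spk, no_inh_spk, plast, dt)
            W[:N_E, :N_E] = pl.apply_excitatory_plasticity(
                W[:N_E, :N_E], mask_EE[:N_E, :N_E], traces, currents,
                spikes[:N_E], plast)
            W[N_E:, :N_E] = pl.apply_inhibitory_plasticity(
                W[N_E:, :N_E], mask_IE[N_E:, :N_E], traces, currents,
                spikes[N_E:], spikes[:N_E], plast)
            traces.x_plus[spikes[:N_E]] += 1.0
            traces.y_minus[spikes[:N_E]] += 1.0
            traces.y_E[spikes[:N_E]] += 1.0
            traces.y_isp[spikes[:N_E]] += 1.0
            traces.x_isp[spikes[N_E:]] += 1.0

        history[t] = spikes
        prev_spk = spikes
    return history
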