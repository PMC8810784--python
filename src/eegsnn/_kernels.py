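"""Numba-compiled inner loops: ADM level-crossing scan and LIF network stepping.

Both loops are inherently sequential (each step depends on the previous
state), so they are JIT-compiled rather than vectorised.  The LIF step uses
the exact per-step solution of the linear membrane + exponential-current
system (impulses land on step boundaries), so the only discretisation left is
the step-quantisation of threshold crossings.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def adm_scan(x, threshold, dead_samples):
    """Asynchronous delta-modulator scan.

    The reference starts at ``x[0]``.  Whenever the signal rises (falls) by at
    least ``threshold`` from the reference, an UP (DN) event is emitted at
    that sample index and the reference jumps to the current value.  After an
    emission, further emissions are suppressed for ``dead_samples`` samples;
    the reference is only updated again at the first post-refractory emission.

    Returns (up_indices, dn_indices) as int64 arrays.
    """
    n = x.size
    up = np.empty(n, dtype=np.int64)
    dn = np.empty(n, dtype=np.int64)
    n_up = 0
    n_dn = 0
    if n == 0:
        return up[:0], dn[:0]
    ref = x[0]
    next_ok = 0.0
    for i in range(1, n):
        if i < next_ok:
            continue
        d = x[i] - ref
        if d >= threshold:
            up[n_up] = i
            n_up += 1
            ref = x[i]
            next_ok = i + dead_samples
        elif -d >= threshold:
            dn[n_dn] = i
            n_dn += 1
            ref = x[i]
            next_ok = i + dead_samples
    return up[:n_up].copy(), dn[:n_dn].copy()


@njit(cache=True)
def lif_step_loop(
    n_steps,
    # neuron arrays
    alpha,      # exp(-dt/tau_m), per neuron
    v_th,
    v_reset,
    ref_steps,  # refractory period in steps, per neuron (int64)
    i_bias,
    # synapse arrays (weights already carry sign and gain)
    s_post,     # int64 target neuron index
    s_w,        # signed jump applied to the current on a presynaptic event
    s_decay,    # exp(-dt/tau_s)
    s_gamma,    # tau_s / (tau_s - tau_m[post]): exact-map coupling coefficient
    # connectivity: synapse indices grouped by source
    up_syn,
    dn_syn,
    neuron_syn_start,  # CSR over neuron-driven synapses
    neuron_syn_index,
    # input events as step indices (sorted, may repeat)
    up_steps,
    dn_steps,
):
    """Fixed-step LIF network simulation with exponential current synapses.

    Per step: presynaptic events (external ports, then neuron spikes from the
    previous step) add ``s_w`` to the synapse current; the membrane advances
    by the exact solution of ``tau_m dV/dt = -V + i_bias + sum(currents)``
    over one step; crossing ``v_th`` emits a spike, resets to ``v_reset`` and
    holds for the refractory period.

    Returns (spike_neuron_indices, spike_step_indices).
    """
    n_neurons = alpha.size
    n_syn = s_post.size

    v = np.zeros(n_neurons)
    for j in range(n_neurons):
        v[j] = v_reset[j]
    cur = np.zeros(n_syn)
    refr = np.zeros(n_neurons, dtype=np.int64)
    b_start = np.zeros(n_neurons)  # sum of gamma*current at step start
    b_end = np.zeros(n_neurons)    # same after the step's decay

    spiked_prev = np.empty(n_neurons, dtype=np.int64)
    n_prev = 0

    cap = 4096
    out_neuron = np.empty(cap, dtype=np.int64)
    out_step = np.empty(cap, dtype=np.int64)
    n_out = 0

    up_ptr = 0
    dn_ptr = 0

    for step in range(n_steps):
        # external input events scheduled for this step
        nu = 0
        while up_ptr < up_steps.size and up_steps[up_ptr] == step:
            nu += 1
            up_ptr += 1
        if nu > 0:
            for k in range(up_syn.size):
                s = up_syn[k]
                cur[s] += s_w[s] * nu
        nd = 0
        while dn_ptr < dn_steps.size and dn_steps[dn_ptr] == step:
            nd += 1
            dn_ptr += 1
        if nd > 0:
            for k in range(dn_syn.size):
                s = dn_syn[k]
                cur[s] += s_w[s] * nd
        # recurrent events from neurons that fired on the previous step
        for k in range(n_prev):
            j = spiked_prev[k]
            for p in range(neuron_syn_start[j], neuron_syn_start[j + 1]):
                s = neuron_syn_index[p]
                cur[s] += s_w[s]

        # coupling terms and current decay in one pass
        for j in range(n_neurons):
            b_start[j] = 0.0
            b_end[j] = 0.0
        for s in range(n_syn):
            c = cur[s]
            j = s_post[s]
            b_start[j] += s_gamma[s] * c
            c *= s_decay[s]
            cur[s] = c
            b_end[j] += s_gamma[s] * c

        # exact membrane advance and threshold
        n_prev = 0
        for j in range(n_neurons):
            if refr[j] > 0:
                refr[j] -= 1
                v[j] = v_reset[j]
                continue
            v[j] = (v[j] - i_bias[j] - b_start[j]) * alpha[j] + i_bias[j] + b_end[j]
            if v[j] >= v_th[j]:
                v[j] = v_reset[j]
                refr[j] = ref_steps[j]
                spiked_prev[n_prev] = j
                n_prev += 1
                if n_out == cap:
                    cap *= 2
                    tmp_n = np.empty(cap, dtype=np.int64)
                    tmp_s = np.empty(cap, dtype=np.int64)
                    tmp_n[:n_out] = out_neuron
                    tmp_s[:n_out] = out_step
                    out_neuron = tmp_n
                    out_step = tmp_s
                out_neuron[n_out] = j
                out_step[n_out] = step
                n_out += 1

    return out_neuron[:n_out].copy(), out_step[:n_out].copy()


@njit(cache=True)
def lif_membrane_trace(
    n_steps,
    alpha,
    v_th,
    v_reset,
    ref_steps,
    i_bias,
    s_post,
    s_w,
    s_decay,
    s_gamma,
    up_syn,
    dn_syn,
    neuron_syn_start,
    neuron_syn_index,
    up_steps,
    dn_steps,
    trace_neuron,
):
    """Same dynamics as :func:`lif_step_loop` but records one membrane trace."""
    n_neurons = alpha.size
    n_syn = s_post.size
    v = np.zeros(n_neurons)
    for j in range(n_neurons):
        v[j] = v_reset[j]
    cur = np.zeros(n_syn)
    refr = np.zeros(n_neurons, dtype=np.int64)
    b_start = np.zeros(n_neurons)
    b_end = np.zeros(n_neurons)
    spiked_prev = np.empty(n_neurons, dtype=np.int64)
    n_prev = 0
    trace = np.zeros(n_steps)
    up_ptr = 0
    dn_ptr = 0
    for step in range(n_steps):
        nu = 0
        while up_ptr < up_steps.size and up_steps[up_ptr] == step:
            nu += 1
            up_ptr += 1
        if nu > 0:
            for k in range(up_syn.size):
                s = up_syn[k]
                cur[s] += s_w[s] * nu
        nd = 0
        while dn_ptr < dn_steps.size and dn_steps[dn_ptr] == step:
            nd += 1
            dn_ptr += 1
        if nd > 0:
            for k in range(dn_syn.size):
                s = dn_syn[k]
                cur[s] += s_w[s] * nd
        for k in range(n_prev):
            j = spiked_prev[k]
            for p in range(neuron_syn_start[j], neuron_syn_start[j + 1]):
                s = neuron_syn_index[p]
                cur[s] += s_w[s]
        for j in range(n_neurons):
            b_start[j] = 0.0
            b_end[j] = 0.0
        for s in range(n_syn):
            c = cur[s]
            j = s_post[s]
            b_start[j] += s_gamma[s] * c
            c *= s_decay[s]
            cur[s] = c
            b_end[j] += s_gamma[s] * c
        n_prev = 0
        for j in range(n_neurons):
            if refr[j] > 0:
                refr[j] -= 1
                v[j] = v_reset[j]
                continue
            v[j] = (v[j] - i_bias[j] - b_start[j]) * alpha[j] + i_bias[j] + b_end[j]
            if v[j] >= v_th[j]:
                v[j] = v_reset[j]
                refr[j] = ref_steps[j]
                spiked_prev[n_prev] = j
                n_prev += 1
        trace[step] = v[trace_neuron]
    return trace
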