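"""Numba forward-Euler kernel for the gap-junction-coupled inhibitory LIF network.

The gap-junction current on neuron i is -sum_j J_ij * F(V_i - V_j) with F a
linear low-pass filter.  Because F is linear and every filter starts from zero
state, the per-pair filtering is computed equivalently (and ~M/2 times more
cheaply) by filtering each neuron's voltage once, w_i = F(V_i), and forming
the pairwise differences of the filtered signals:

    sum_j J_ij * F(V_i - V_j) = sum_j J_ij * (w_i - w_j)

The filter is realised as cascaded biquad sections (direct form II
transposed) so that a high-order low-pass at a cutoff far below Nyquist stays
numerically stable.
"""

import numpy as np
from numba import njit

#: sanity bound (mV) beyond which the integration is declared divergent
BLOWUP_BOUND = 1.0e3


@njit(cache=True)
def run_lif(v0, n_steps, dt, tau, g_leak, v_rest, v_th, v_reset,
            refrac_steps, g_max, tau_syn, v_inh,
            v_floor, syn_post_idx, syn_post_ptr,
            edge_a, edge_b, g_gap, sos,
            stim_mask, amplitude, period_steps, pulse_steps,
            noise, v_out):
    """Integrate the network; returns (spike_times, spike_ids, n_spikes, blowup).

    ``syn_post_idx``/``syn_post_ptr`` give, in CSR layout, the postsynaptic
    targets of each neuron.  ``edge_a``/``edge_b`` list the undirected gap
    edges.  ``noise`` is a pre-drawn (n_steps, n) array of per-step Gaussian
    current samples.  ``v_out`` is either an (n_steps, n) array to record
    voltages into or an empty (0, 0) array.
    """
    n = v0.shape[0]
    v = v0.copy()
    g_syn = np.zeros(n)
    refrac = np.zeros(n, dtype=np.int64)
    n_edges = edge_a.shape[0]
    n_sec = sos.shape[0]
    z = np.zeros((n, n_sec, 2))
    syn_decay = np.exp(-dt / tau_syn)
    record_v = v_out.shape[0] > 0

    max_spikes = n * (n_steps // max(refrac_steps, 1) + 1)
    spike_times = np.empty(max_spikes)
    spike_ids = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0

    w = np.empty(n)
    i_gap = np.empty(n)
    for k in range(n_steps):
        # low-pass filter each membrane voltage (cascaded biquads, DF2T)
        for i in range(n):
            x = v[i]
            for s in range(n_sec):
                y = sos[s, 0] * x + z[i, s, 0]
                z[i, s, 0] = sos[s, 1] * x - sos[s, 4] * y + z[i, s, 1]
                z[i, s, 1] = sos[s, 2] * x - sos[s, 5] * y
                x = y
            w[i] = x

        for i in range(n):
            i_gap[i] = 0.0
        for e in range(n_edges):
            a = edge_a[e]
            b = edge_b[e]
            d = g_gap * (w[b] - w[a])
            i_gap[a] += d
            i_gap[b] -= d

        in_pulse = (k % period_steps) < pulse_steps

        for i in range(n):
            if record_v:
                v_out[k, i] = v[i]
            if refrac[i] > 0:
                # membrane updates suspended; conductances keep decaying
                refrac[i] -= 1
                g_syn[i] *= syn_decay
                continue
            i_ext = amplitude if (in_pulse and stim_mask[i]) else 0.0
            i_inh = g_syn[i] * (v_inh - v[i])
            v[i] += (dt / tau) * (g_leak * (v_rest - v[i]) + i_inh
                                  + i_gap[i] + i_ext + noise[k, i])
            if v[i] > BLOWUP_BOUND or v[i] < -BLOWUP_BOUND:
                return spike_times[:n_spikes], spike_ids[:n_spikes], n_spikes, True
            if v[i] < v_floor:
                v[i] = v_floor
            g_syn[i] *= syn_decay
            if v[i] > v_th:
                spike_times[n_spikes] = (k + 1) * dt
                spike_ids[n_spikes] = i
                n_spikes += 1
                v[i] = v_reset
                refrac[i] = refrac_steps
                for p in range(syn_post_ptr[i], syn_post_ptr[i + 1]):
                    g_syn[syn_post_idx[p]] += g_max
    return spike_times[:n_spikes], spike_ids[:n_spikes], n_spikes, False
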