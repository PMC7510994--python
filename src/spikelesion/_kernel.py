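"""Numba core for the fixed-timestep network simulation.

One call advances the whole network by ``n_steps`` of size ``dt``.  The design
keeps the per-step cost at O(n) plus O(spike events):

* Membrane integration: explicit forward-Euler loop over neurons (quadratic
  integrate-and-fire with recovery variable and threshold reset).
* Synaptic drive: two per-neuron accumulators (excitatory >= 0, inhibitory
  <= 0) decaying by ``exp(-dt/tau)`` each step.
* Delays: a circular calendar of ``n_slots`` singly-linked event lists; a spike
  on edge ``e`` at step ``t`` enqueues node ``e`` in slot ``(t + delay_e) %
  n_slots``.  Nodes are recycled through a free stack, so memory is bounded by
  the number of in-flight edge events.
* STDP: per-neuron exponentially decaying pre/post traces (emission timing) or
  lazily decayed per-edge arrival traces (arrival timing); all-pairs additive
  updates with hard clipping to [w_min, w_max].

The kernel contains no random numbers: background events are pre-drawn by the
caller and passed as sorted arrays, which makes a run bit-reproducible.
"""

import numpy as np
from numba import njit

# status codes returned by simulate_chunk
OK = 0
QUEUE_FULL = 1
RECORD_FULL = 2
NUMERIC_ERROR = 3

STDP_EMISSION = 0
STDP_ARRIVAL = 1

STIM_IMPULSE = 0
STIM_DECAY = 1


@njit(cache=True, fastmath={"contract", "reassoc", "arcp"})
def simulate_chunk(
    n_steps, step0, dt,
    # neuron state
    v, u, ge, gi, s,
    a, b, c, d,
    # constants
    syn_decay, desens_floor, desens_decay, v_thresh,
    # edges (CSR by pre, plus incoming CSR by post)
    out_ptr, out_edge, in_ptr, in_edge,
    e_pre, e_post, e_w, e_delay, e_is_ee,
    # delay calendar
    head, node_edge, node_next, free_stack, qstate,
    # STDP
    stdp_on, stdp_timing, x_tr, y_tr, stdp_decay, a_plus, a_minus, w_min, w_max,
    etrace, etrace_step, arr_cnt, arr_step,
    # background events (sorted by step, absolute)
    ev_step, ev_nrn, ev_amp, ev_mode, ev_ptr0,
    # recording
    record, spk_step, spk_nrn,
    # scratch
    i_ext, spikers,
):
    n = v.shape[0]
    n_slots = head.shape[0]
    ev_ptr = ev_ptr0
    n_ev = ev_step.shape[0]
    free_top = qstate[0]
    n_rec = 0
    cap = spk_step.shape[0]

    for local in range(n_steps):
        step = step0 + local
        slot = step % n_slots

        # decay synaptic drive, then deliver (so a spike arriving this step
        # contributes its full weight to this step's current)
        for i in range(n):
            ge[i] *= syn_decay
            gi[i] *= syn_decay

        # decay STDP traces up to (and including) this step
        if stdp_on and stdp_timing == STDP_EMISSION:
            for i in range(n):
                x_tr[i] *= stdp_decay
                y_tr[i] *= stdp_decay
        elif stdp_on:
            for i in range(n):
                y_tr[i] *= stdp_decay

        # deliver due edge events
        node = head[slot]
        head[slot] = -1
        while node != -1:
            e = node_edge[node]
            p = e_post[e]
            w = e_w[e]
            if w > 0.0:
                ge[p] += s[p] * w
            else:
                gi[p] += s[p] * w
            if stdp_on and stdp_timing == STDP_ARRIVAL and e_is_ee[e]:
                # lazy decay of the per-edge arrival trace
                gap = step - etrace_step[e]
                etrace[e] *= stdp_decay ** gap
                etrace_step[e] = step
                if arr_step[e] == step:
                    arr_cnt[e] += 1
                else:
                    arr_step[e] = step
                    arr_cnt[e] = 1
                etrace[e] += 1.0
                # depression: this arrival pairs with all earlier post spikes
                nw = e_w[e] - a_minus * y_tr[p]
                e_w[e] = nw if nw > w_min else w_min
            nxt = node_next[node]
            free_top += 1
            free_stack[free_top] = node
            node = nxt

        # background events due this step
        for i in range(n):
            i_ext[i] = 0.0
        while ev_ptr < n_ev and ev_step[ev_ptr] == step:
            nrn = ev_nrn[ev_ptr]
            if ev_mode == STIM_IMPULSE:
                i_ext[nrn] += ev_amp[ev_ptr]
            else:
                ge[nrn] += ev_amp[ev_ptr]
            ev_ptr += 1

        # forward-Euler membrane update, threshold reset, desensitization
        n_spk = 0
        for i in range(n):
            vi = v[i]
            ui = u[i]
            cur = ge[i] + gi[i] + i_ext[i]
            vn = vi + dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + cur)
            un = ui + dt * a[i] * (b[i] * vi - ui)
            if not np.isfinite(vn):
                qstate[0] = free_top
                return NUMERIC_ERROR, n_rec, ev_ptr, step, i
            if vn >= v_thresh:
                v[i] = c[i]
                u[i] = un + d[i]
                s[i] = desens_floor
                spikers[n_spk] = i
                n_spk += 1
            else:
                v[i] = vn
                u[i] = un
                s[i] = 1.0 - (1.0 - s[i]) * desens_decay

        # record + enqueue outgoing spikes
        for k in range(n_spk):
            i = spikers[k]
            if record:
                if n_rec >= cap:
                    qstate[0] = free_top
                    return RECORD_FULL, n_rec, ev_ptr, step, i
                spk_step[n_rec] = step
                spk_nrn[n_rec] = i
                n_rec += 1
            for eptr in range(out_ptr[i], out_ptr[i + 1]):
                e = out_edge[eptr]
                if free_top < 0:
                    qstate[0] = free_top
                    return QUEUE_FULL, n_rec, ev_ptr, step, i
                node = free_stack[free_top]
                free_top -= 1
                tslot = (step + e_delay[e]) % n_slots
                node_edge[node] = e
                node_next[node] = head[tslot]
                head[tslot] = node

        # STDP weight updates for this step's spikes
        if stdp_on and n_spk > 0:
            if stdp_timing == STDP_EMISSION:
                # post traces first so simultaneous pairs fall on the
                # depression branch (delta_t = 0)
                for k in range(n_spk):
                    y_tr[spikers[k]] += 1.0
                for k in range(n_spk):
                    i = spikers[k]
                    for eptr in range(out_ptr[i], out_ptr[i + 1]):
                        e = out_edge[eptr]
                        if e_is_ee[e]:
                            nw = e_w[e] - a_minus * y_tr[e_post[e]]
                            e_w[e] = nw if nw > w_min else w_min
                    for eptr in range(in_ptr[i], in_ptr[i + 1]):
                        e = in_edge[eptr]
                        if e_is_ee[e]:
                            nw = e_w[e] + a_plus * x_tr[e_pre[e]]
                            e_w[e] = nw if nw < w_max else w_max
                for k in range(n_spk):
                    x_tr[spikers[k]] += 1.0
            else:
                for k in range(n_spk):
                    y_tr[spikers[k]] += 1.0
                for k in range(n_spk):
                    i = spikers[k]
                    for eptr in range(in_ptr[i], in_ptr[i + 1]):
                        e = in_edge[eptr]
                        if not e_is_ee[e]:
                            continue
                        gap = step - etrace_step[e]
                        etrace[e] *= stdp_decay ** gap
                        etrace_step[e] = step
                        cnt = arr_cnt[e] if arr_step[e] == step else 0
                        # arrivals at this very step pair at delta_t = 0:
                        # depression, and they were not yet visible to the
                        # arrival-side update above
                        nw = e_w[e] + a_plus * (etrace[e] - cnt) - a_minus * cnt
                        if nw > w_max:
                            nw = w_max
                        elif nw < w_min:
                            nw = w_min
                        e_w[e] = nw

    qstate[0] = free_top
    return OK, n_rec, ev_ptr, step0 + n_steps - 1, -1
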