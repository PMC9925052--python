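"""Numba kernels: single-neuron integration, spatial edge sampling and the
clock-driven network simulation loop.

All kernels use a fixed time step (default 0.1 ms) with an explicit Euler
update for the membrane equations, exact exponential decay for synaptic
conductances, and the exponential term's argument clamped at
(V_detect - V_T) / Delta_T to avoid overflow during the spike upswing.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# argument below which the exponential spike-initiation term is dropped
# (g_L * Delta_T * e^-16 < 1e-6 pA at default parameters)
_EXP_FLOOR = -16.0


@njit(cache=True)
def integrate_single(
    C, g_L, E_L, V_T, Delta_T, a, b, tau_w, E_e, E_i, tau_syn,
    V_detect, V_reset, t_ref,
    drive,            # float64[n_steps] external current per step (pA)
    ev_step,          # int64[:]  event delivery step indices (sorted)
    ev_g,             # float64[:] event peak conductances (nS)
    ev_inh,           # uint8[:]  1 for inhibitory events
    n_steps, dt, V0, w0, record_v,
):
    """Integrate one AdEx neuron; returns (V trace, spike times, ok flag)."""
    V = V0
    w = w0
    g_e = 0.0
    g_i = 0.0
    decay = np.exp(-dt / tau_syn)
    clamp = (V_detect - V_T) / Delta_T
    ref_until = -1.0
    vs = np.empty(n_steps + 1 if record_v else 1)
    vs[0] = V
    ws = np.empty(n_steps + 1 if record_v else 1)
    ws[0] = w
    spikes = np.empty(int(n_steps * dt / t_ref) + 2)
    n_spk = 0
    i_ev = 0
    fail_step = -1
    for i in range(n_steps):
        t = i * dt
        while i_ev < ev_step.size and ev_step[i_ev] == i:
            if ev_inh[i_ev] == 1:
                g_i += ev_g[i_ev]
            else:
                g_e += ev_g[i_ev]
            i_ev += 1
        if t < ref_until:
            V_next = V_reset
        else:
            arg = (V - V_T) / Delta_T
            if arg > clamp:
                arg = clamp
            exp_term = g_L * Delta_T * np.exp(arg) if arg > _EXP_FLOOR else 0.0
            dV = (-g_L * (V - E_L) + exp_term
                  - g_e * (V - E_e) - g_i * (V - E_i) - w + drive[i]) / C
            V_next = V + dt * dV
        w += dt * (a * (V - E_L) - w) / tau_w
        g_e = g_e * decay if g_e > 1e-12 else 0.0
        g_i = g_i * decay if g_i > 1e-12 else 0.0
        V = V_next
        if not np.isfinite(V) or not np.isfinite(w):
            fail_step = i
            break
        if V >= V_detect and t >= ref_until:
            spikes[n_spk] = t + dt
            n_spk += 1
            V = V_reset
            w += b
            ref_until = t + dt + t_ref
        if record_v:
            vs[i + 1] = V
            ws[i + 1] = w
    return vs, ws, spikes[:n_spk], fail_step


@njit(cache=True)
def sample_edges(
    src_x, src_y, src_ids,        # source positions / global ids
    tgt_x, tgt_y, tgt_ids,        # target positions / global ids
    cell_of_tgt_start, cell_tgt,  # CSR grid: cell -> target indices
    n_cells_axis, cell_size, side,
    amplitude, inv_two_sigma2, cutoff2,
    seed,
    out_pre, out_post,            # preallocated int32 output
):
    """Bernoulli edge sampling with p = A * exp(-d^2 / 2 sigma^2), d the
    torus distance. Returns the number of edges written (-1 on overflow)."""
    np.random.seed(seed)
    half = side / 2.0
    cap = out_pre.size
    m = 0
    reach = int(np.ceil(np.sqrt(cutoff2) / cell_size))
    full_scan = 2 * reach + 1 >= n_cells_axis
    for s in range(src_x.size):
        sx = src_x[s]
        sy = src_y[s]
        sid = src_ids[s]
        cx = int(sx / cell_size)
        if cx >= n_cells_axis:
            cx = n_cells_axis - 1
        cy = int(sy / cell_size)
        if cy >= n_cells_axis:
            cy = n_cells_axis - 1
        if full_scan:
            x_lo, x_hi = 0, n_cells_axis - 1
            y_lo, y_hi = 0, n_cells_axis - 1
        else:
            x_lo, x_hi = cx - reach, cx + reach
            y_lo, y_hi = cy - reach, cy + reach
        for gx in range(x_lo, x_hi + 1):
            wx = gx % n_cells_axis
            for gy in range(y_lo, y_hi + 1):
                wy = gy % n_cells_axis
                cell = wx * n_cells_axis + wy
                for k in range(cell_of_tgt_start[cell], cell_of_tgt_start[cell + 1]):
                    j = cell_tgt[k]
                    if tgt_ids[j] == sid:
                        continue  # no autapses
                    dx = abs(tgt_x[j] - sx)
                    if dx > half:
                        dx = side - dx
                    dy = abs(tgt_y[j] - sy)
                    if dy > half:
                        dy = side - dy
                    d2 = dx * dx + dy * dy
                    if d2 > cutoff2:
                        continue
                    r = np.random.random()
                    if r >= amplitude:
                        continue
                    if r < amplitude * np.exp(-d2 * inv_two_sigma2):
                        if m >= cap:
                            return -1
                        out_pre[m] = sid
                        out_post[m] = tgt_ids[j]
                        m += 1
    return m


@njit(cache=True)
def run_network(
    # neuron parameters
    C, g_L, E_L, V_T, Delta_T, a, b, tau_w, E_e, E_i, tau_syn,
    V_detect, V_reset, t_ref,
    # connectivity (CSR by presynaptic neuron)
    indptr, targets, weights, delay_steps, pre_is_inh,
    # noise
    mu_in, sigma_in, refresh_steps,
    # forced spikes (sorted by step) and external conductance events
    forced_step, forced_id,
    ext_step, ext_id, ext_g, ext_inh,
    # schedule
    n_steps, dt, record_from_step, seed,
    # guards
    runaway_frac, spike_cap,
):
    """Clock-driven simulation of the whole network.

    Returns (spike_steps, spike_ids, n_spikes, fail_step, runaway_steps).
    ``n_spikes`` is -1 if ``spike_cap`` was exceeded.
    """
    np.random.seed(seed)
    n = indptr.size - 1
    H = 0
    for k in range(delay_steps.size):
        if delay_steps[k] > H:
            H = delay_steps[k]
    H += 1
    if H < 2:
        H = 2
    buf_e = np.zeros(n * H)
    buf_i = np.zeros(n * H)
    V = np.full(n, E_L)
    w = np.zeros(n)
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    ref_until = np.full(n, -1.0)
    noise = np.zeros(n)
    decay = np.exp(-dt / tau_syn)
    clamp = (V_detect - V_T) / Delta_T
    spk_step = np.empty(spike_cap, dtype=np.int64)
    spk_id = np.empty(spike_cap, dtype=np.int32)
    n_spk = 0
    step_spikes = np.empty(n, dtype=np.int32)
    i_forced = 0
    i_ext = 0
    runaway_limit = int(runaway_frac * n)
    if runaway_limit < 1:
        runaway_limit = 1
    n_runaway = 0
    fail_step = -1
    for i in range(n_steps):
        t = i * dt
        if i % refresh_steps == 0:
            for j in range(n):
                noise[j] = mu_in + sigma_in * np.random.standard_normal()
        while i_ext < ext_step.size and ext_step[i_ext] == i:
            j = ext_id[i_ext]
            if ext_inh[i_ext] == 1:
                g_i[j] += ext_g[i_ext]
            else:
                g_e[j] += ext_g[i_ext]
            i_ext += 1
        slot = i % H
        n_step_spk = 0
        for j in range(n):
            base = j * H + slot
            ge = g_e[j] + buf_e[base]
            gi = g_i[j] + buf_i[base]
            buf_e[base] = 0.0
            buf_i[base] = 0.0
            v = V[j]
            if t < ref_until[j]:
                v_next = V_reset
            else:
                arg = (v - V_T) / Delta_T
                if arg > clamp:
                    arg = clamp
                if arg > _EXP_FLOOR:
                    exp_term = g_L * Delta_T * np.exp(arg)
                else:
                    exp_term = 0.0
                dV = (-g_L * (v - E_L) + exp_term
                      - ge * (v - E_e) - gi * (v - E_i) - w[j] + noise[j]) / C
                v_next = v + dt * dV
            w[j] += dt * (a * (v - E_L) - w[j]) / tau_w
            g_e[j] = ge * decay if ge > 1e-12 else 0.0
            g_i[j] = gi * decay if gi > 1e-12 else 0.0
            if not np.isfinite(v_next):
                fail_step = i
                break
            if v_next >= V_detect and t >= ref_until[j]:
                v_next = V_reset
                w[j] += b
                ref_until[j] = t + dt + t_ref
                step_spikes[n_step_spk] = j
                n_step_spk += 1
            V[j] = v_next
        if fail_step >= 0:
            break
        # forced spikes (voltage pushed above detection threshold -> full
        # spike lifecycle: reset, refractoriness, w increment, delivery)
        while i_forced < forced_step.size and forced_step[i_forced] == i:
            j = forced_id[i_forced]
            V[j] = V_reset
            w[j] += b
            ref_until[j] = t + dt + t_ref
            step_spikes[n_step_spk] = j
            n_step_spk += 1
            i_forced += 1
        if n_step_spk >= runaway_limit:
            n_runaway += 1
        for s in range(n_step_spk):
            j = step_spikes[s]
            if i >= record_from_step:
                if n_spk >= spike_cap:
                    return spk_step, spk_id, -1, fail_step, n_runaway
                spk_step[n_spk] = i
                spk_id[n_spk] = j
                n_spk += 1
            inh = pre_is_inh[j]
            for k in range(indptr[j], indptr[j + 1]):
                tgt = targets[k]
                dest = tgt * H + (i + delay_steps[k]) % H
                if inh == 1:
                    buf_i[dest] += weights[k]
                else:
                    buf_e[dest] += weights[k]
    return spk_step, spk_id, n_spk, fail_step, n_runaway
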