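"""Numba-compiled inner loops for the simulator.

The time-stepped network loop and the event-driven single-synapse loop
live here so the cohort protocols (hundreds of simulated seconds per
network at 1-ms resolution) run in seconds.  Spike pairing uses
exponentially decaying pre/post traces, which is mathematically
identical to all-to-all pair-based STDP: the pre trace accumulates
``exp(-dt/tau_plus)`` factors of all past presynaptic spikes, the post
trace the ``exp(-dt/tau_minus)`` factors of all past postsynaptic
spikes.  Exact pre/post coincidence is assigned to the LTD branch.
"""

import numpy as np
from numba import njit

__all__ = ["single_synapse_trials", "run_network"]


@njit(cache=True)
def _eps(w, ltp, profile, alpha, w_min, w_max):
    """Weight-dependent learning rate; profile 0=AR, 1=SR, 2=hybrid."""
    if profile == 0:
        a = 0.0
    elif profile == 1:
        a = 1.0
    else:
        a = alpha
    ar = (w_max - w) if ltp else (w - w_min)
    lo = w - w_min
    hi = w_max - w
    sr = 2.0 * (lo if lo < hi else hi)
    return a * sr + (1.0 - a) * ar


@njit(cache=True)
def single_synapse_trials(
    duration_ms,
    rate_per_ms,
    seeds,
    k_plus,
    k_minus,
    tau_plus,
    tau_minus,
    profile,
    alpha,
    w_min,
    w_max,
):
    """Final weights of independent single-synapse Poisson-pairing trials.

    Pre and post neurons fire independent homogeneous Poisson trains
    (continuous event times from exponential gaps); each spike applies
    the STDP rule through the opposite trace and the weight is clipped
    after every update.
    """
    n = seeds.size
    out = np.empty(n)
    for tr in range(n):
        np.random.seed(seeds[tr])
        w = w_min + (w_max - w_min) * np.random.random()
        if rate_per_ms > 0.0:
            mean_gap = 1.0 / rate_per_ms
            t_pre = np.random.exponential(mean_gap)
            t_post = np.random.exponential(mean_gap)
            x = 0.0  # pre trace (tau_plus), for LTP at post spikes
            tx = 0.0
            y = 0.0  # post trace (tau_minus), for LTD at pre spikes
            ty = 0.0
            while True:
                if t_pre <= t_post:
                    t = t_pre
                    if t >= duration_ms:
                        break
                    y = y * np.exp(-(t - ty) / tau_minus)
                    ty = t
                    w += _eps(w, False, profile, alpha, w_min, w_max) * k_minus * y
                    if w < w_min:
                        w = w_min
                    elif w > w_max:
                        w = w_max
                    x = x * np.exp(-(t - tx) / tau_plus) + 1.0
                    tx = t
                    t_pre = t + np.random.exponential(mean_gap)
                else:
                    t = t_post
                    if t >= duration_ms:
                        break
                    x = x * np.exp(-(t - tx) / tau_plus)
                    tx = t
                    w += _eps(w, True, profile, alpha, w_min, w_max) * k_plus * x
                    if w < w_min:
                        w = w_min
                    elif w > w_max:
                        w = w_max
                    y = y * np.exp(-(t - ty) / tau_minus) + 1.0
                    ty = t
                    t_post = t + np.random.exponential(mean_gap)
        out[tr] = w
    return out


@njit(cache=True)
def run_network(
    W,
    V,
    g,
    x_pre,
    y_post,
    row_ptr,
    row_idx,
    col_ptr,
    col_idx,
    pre_raster,
    post_forced,
    C,
    g_L,
    E_L,
    E_syn,
    E_th,
    tau_syn,
    c_syn,
    sigma,
    dt,
    k_plus,
    k_minus,
    tau_plus,
    tau_minus,
    profile,
    alpha,
    w_min,
    w_max,
    plastic,
    seed,
):
    """Simulate the feedforward LIF layer over a presynaptic raster.

    ``W`` and the state vectors ``V`` (voltage), ``g`` (conductance),
    ``x_pre`` (LTP pairing trace per input neuron) and ``y_post`` (LTD
    pairing trace per output neuron) are modified in place, so a long
    run may be split into consecutive calls.  Connectivity is given in
    both row-compressed (per presynaptic neuron) and column-compressed
    (per postsynaptic neuron) index form.  One forward-Euler step per
    raster column: both derivatives are evaluated at the previous state,
    then threshold crossing emits a spike and resets the voltage to rest
    within the same step.  ``post_forced`` (empty, or uint8 n_out x T)
    marks externally imposed postsynaptic spikes -- background activity
    that fires the output neuron regardless of its voltage; forced
    spikes reset the voltage and engage STDP exactly like threshold
    spikes.

    Returns the postsynaptic spike raster (uint8, n_out x T).
    """
    n_in, T = pre_raster.shape
    n_out = W.shape[1]
    np.random.seed(seed)

    out = np.zeros((n_out, T), dtype=np.uint8)
    inc = np.zeros(n_out)
    d_plus = np.exp(-dt / tau_plus)
    d_minus = np.exp(-dt / tau_minus)

    for t in range(T):
        if plastic:
            for i in range(n_in):
                x_pre[i] *= d_plus
            for j in range(n_out):
                y_post[j] *= d_minus

        # presynaptic drive of this step
        for j in range(n_out):
            inc[j] = 0.0
        any_pre = False
        for i in range(n_in):
            if pre_raster[i, t] != 0:
                any_pre = True
                for k in range(row_ptr[i], row_ptr[i + 1]):
                    inc[row_idx[k]] += W[i, row_idx[k]]

        # explicit Euler on (g, V) from the previous state, then threshold
        for j in range(n_out):
            gj = g[j]
            g[j] = gj + dt * (-gj / tau_syn + c_syn * inc[j])
            noise = 0.0
            if sigma > 0.0:
                noise = sigma * np.random.standard_normal()
            v0 = V[j]
            v = v0 + (dt / C) * (g_L * (E_L - v0) + gj * (E_syn - v0) + noise)
            if v != v:
                raise ValueError("membrane state is NaN: numerical blow-up")
            if v >= E_th or (post_forced.size > 0 and post_forced[j, t] != 0):
                out[j, t] = 1
                v = E_L
            V[j] = v

        if plastic:
            # LTP: at each postsynaptic spike, pair with all earlier pre spikes
            for j in range(n_out):
                if out[j, t] != 0:
                    for k in range(col_ptr[j], col_ptr[j + 1]):
                        i = col_idx[k]
                        w = W[i, j]
                        w += _eps(w, True, profile, alpha, w_min, w_max) \
                            * k_plus * x_pre[i]
                        if w < w_min:
                            w = w_min
                        elif w > w_max:
                            w = w_max
                        W[i, j] = w
            for j in range(n_out):
                if out[j, t] != 0:
                    y_post[j] += 1.0
            # LTD: at each presynaptic spike, pair with post spikes at <= t
            if any_pre:
                for i in range(n_in):
                    if pre_raster[i, t] != 0:
                        for k in range(row_ptr[i], row_ptr[i + 1]):
                            j = row_idx[k]
                            w = W[i, j]
                            w += _eps(w, False, profile, alpha, w_min, w_max) \
                                * k_minus * y_post[j]
                            if w < w_min:
                                w = w_min
                            elif w > w_max:
                                w = w_max
                            W[i, j] = w
                for i in range(n_in):
                    if pre_raster[i, t] != 0:
                        x_pre[i] += 1.0

    return out
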