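"""Compiled inner loops for tempotron training on one-spike-per-afferent
patterns (the orientation-experiment workload: thousands of cycles over a
fixed stimulus grid of ~10^4 patterns with ~200 afferents each).

The voltage between consecutive input spikes is A exp(-t/tau_m) -
B exp(-t/tau_s); A and B are updated event by event, re-anchored at each
spike time for numerical stability, and the interval maximum is closed
form — the same algorithm as :mod:`latency_readout.tempotron`, asserted
equal to it in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def vmax_single_spike(times, order, w, tm, ts, v0, horizon):
    """(v_max, t_vmax) for a pattern with one spike per afferent.

    ``times`` are the spike times sorted ascending, ``order[k]`` the
    afferent that produced the k-th spike.
    """
    c = tm * ts / (tm - ts)
    A = 0.0
    B = 0.0
    v_max = 0.0
    t_max = -1.0
    n = times.shape[0]
    for k in range(n):
        if k > 0:
            dt = times[k] - times[k - 1]
            A *= math.exp(-dt / tm)
            B *= math.exp(-dt / ts)
        wk = w[order[k]] * v0
        A += wk
        B += wk
        t0 = times[k]
        length = (times[k + 1] - t0) if k + 1 < n else (horizon - t0)
        if length <= 0:
            continue
        v_here = A - B
        if v_here > v_max:
            v_max = v_here
            t_max = t0
        if A != 0.0:
            ratio = (B * tm) / (A * ts)
            if ratio > 0.0:
                s_star = c * math.log(ratio)
                if 0.0 < s_star < length:
                    v = A * math.exp(-s_star / tm) - B * math.exp(-s_star / ts)
                    if v > v_max:
                        v_max = v
                        t_max = t0 + s_star
        v_end = A * math.exp(-length / tm) - B * math.exp(-length / ts)
        if v_end > v_max:
            v_max = v_end
            t_max = t0 + length
    return v_max, t_max


@njit(cache=True)
def grid_error(times, order, w, theta, tm, ts, v0, horizon, labels):
    """Margin-free misclassification count over all patterns."""
    n_err = 0
    for p in range(times.shape[0]):
        v_max, _ = vmax_single_spike(times[p], order[p], w, tm, ts, v0, horizon)
        fired = v_max >= theta
        if fired != (labels[p] == 1):
            n_err += 1
    return n_err


@njit(cache=True)
def train_margin_schedule(
    times,
    order,
    labels,
    margins,
    w,
    theta,
    tm,
    ts,
    v0,
    horizon,
    lambda0,
    decay_scale,
    momentum,
    cycles,
    check_every,
    presentation_order,
):
    """Margin-aware tempotron training with a decaying step size.

    Step size lambda_n = lambda0 / (1 + n / decay_scale), n counting pattern
    presentations.  Every ``check_every`` cycles the margin-free error on
    the full grid is evaluated; training stops early once it reaches zero.

    Returns (converged, cycles_run, final_margin_free_errors).
    """
    n_pat, n_aff = times.shape[0], w.shape[0]
    vel = np.zeros(n_aff)
    n_pres = 0
    for cycle in range(cycles):
        for q in range(n_pat):
            p = presentation_order[q]
            v_max, t_vmax = vmax_single_spike(
                times[p], order[p], w, tm, ts, v0, horizon
            )
            m = margins[p]
            if labels[p] == 1:
                err = v_max < theta * (1.0 + m)
                sign = 1.0
            else:
                err = v_max > theta * (1.0 - m)
                sign = -1.0
            lam = lambda0 / (1.0 + n_pres / decay_scale)
            n_pres += 1
            if not err:
                continue
            # velocity <- momentum * velocity + lambda * gradient (error trials only)
            for i in range(n_aff):
                vel[i] *= momentum
            if t_vmax >= 0.0:
                for k in range(times.shape[1]):
                    t = times[p, k]
                    if t < t_vmax:
                        dtk = t_vmax - t
                        kv = v0 * (math.exp(-dtk / tm) - math.exp(-dtk / ts))
                        vel[order[p, k]] += sign * lam * kv
            for i in range(n_aff):
                w[i] += vel[i]
        if (cycle + 1) % check_every == 0:
            if grid_error(times, order, w, theta, tm, ts, v0, horizon, labels) == 0:
                return True, cycle + 1, 0
    n_err = grid_error(times, order, w, theta, tm, ts, v0, horizon, labels)
    return n_err == 0, cycles, n_err
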