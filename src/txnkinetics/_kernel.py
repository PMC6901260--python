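"""Numba core loop of the transcription-site simulator.

State layout (all arrays owned by the Python-side ``SiteState``):

* nascent polymerases: ``pos``/``paused``/``bfrac``/``pause_cd`` of shape
  (R, K) with R = n_sites * n_copies rows (one row per gene copy) and K slots
  per row; ``npol[r]`` slots are active, ordered by decreasing position
  (index 0 is the polymerase closest to the gene end).  ``bfrac`` is the
  fraction of the MS2 cassette already synthesized at the last bleach (its
  "dark" part).
* retained transcripts: per-site ring buffers ``rd_dead`` (absolute release
  deadline, seconds) and ``rd_bl`` (bleached MS2 fraction) of shape (S, cap),
  with ``ret_head``/``ret_count`` ring pointers and ``ret_bsum`` the running
  sum of bleached fractions (so channel totals are O(1) per site).

Stochastic events are per-step Bernoulli trials with probability rate*dt.
They are realized through geometric skip counters (inverse-CDF draw of the
number of trials to the next success), which is sample-path equivalent to
testing a uniform random number against rate*dt at every step but costs one
RNG draw per event instead of one per step:

* ``pause_cd[r, i]`` counts steps to the next pause entry (while elongating)
  or pause exit (while paused);
* ``init_cd[r]`` counts steps to the next initiation attempt (the attempt is
  lost when the promoter-proximal footprint is occupied, exactly like a
  failed Bernoulli attempt);
* ``term_cd[r]`` counts steps to release for the polymerase at the gene end
  (-1 while no polymerase sits at the end).

With the fixed retention model deadlines enter in nondecreasing order, so
expiry is a pop-from-head; with the exponential model a compacting scan is
used instead.

One simulation step (duration dt):
  1. pause-state update and elongation (clamped to the polymerase ahead
     minus the footprint, and to the gene end),
  2. stochastic termination of the polymerase at the gene end -> retained,
  3. stochastic initiation when the promoter-proximal footprint is clear,
  4. expiry of retained transcripts past their deadline.
"""

import numpy as np
from numba import njit

NEVER = np.int64(1) << np.int64(62)


@njit(cache=True, inline="always")
def _geom(p):
    """Trials to first success of a Bernoulli(p) sequence (>= 1)."""
    if p >= 1.0:
        return np.int64(1)
    if p <= 0.0:
        return NEVER
    u = np.random.random()
    k = np.int64(np.ceil(np.log(1.0 - u) / np.log(1.0 - p)))
    return k if k > 0 else np.int64(1)


@njit(cache=True)
def run_steps(
    seed,
    pos, paused, bfrac, pause_cd, npol, init_cd, term_cd,
    rd_dead, rd_bl, ret_head, ret_count, ret_bsum,
    n_copies, length, foot, ms2_start, ms2_len,
    p_init, p_on, p_off, p_term,
    adv, dt, ret_fixed, ret_mean,
    clock, n_steps,
    sample_steps, out_unb,
    measure_every,
):
    """Advance the whole state by ``n_steps`` steps of ``dt`` seconds.

    Samples per-site *unbleached* MS2 signal into ``out_unb`` at the step
    indices listed in ``sample_steps`` (sorted, 0-based, sampled after the
    update of that step), and accumulates the total MS2 signal (bleached +
    unbleached, summed over all sites) every ``measure_every`` steps for
    steady-state window means.

    Returns (clock, total_signal_sum, n_measured, n_initiations, n_releases,
    n_ring_overflows).
    """
    np.random.seed(seed)
    R, K = pos.shape
    S, cap = rd_dead.shape
    n_init = 0
    n_rel = 0
    n_over = 0
    total_sum = 0.0
    n_meas = 0
    si = 0
    ns_samples = sample_steps.shape[0]
    site_tot = np.empty(S)
    site_unb = np.empty(S)

    for step_i in range(n_steps):
        clock += dt
        for r in range(R):
            n = npol[r]
            # 1. pausing + elongation (leader first; clamp to the one ahead)
            for i in range(n):
                cd = pause_cd[r, i] - 1
                if cd == 0:
                    if paused[r, i]:
                        paused[r, i] = False
                        pause_cd[r, i] = _geom(p_on)
                    else:
                        paused[r, i] = True
                        pause_cd[r, i] = _geom(p_off)
                else:
                    pause_cd[r, i] = cd
                    if not paused[r, i]:
                        p = pos[r, i] + adv
                        if i > 0:
                            lim = pos[r, i - 1] - foot
                            if p > lim:
                                p = lim
                        if p > length:
                            p = length
                        pos[r, i] = p
            # 2. termination of the polymerase at the gene end
            if n > 0 and pos[r, 0] >= length:
                if term_cd[r] < 0:
                    term_cd[r] = _geom(p_term)
                term_cd[r] -= 1
                if term_cd[r] == 0:
                    term_cd[r] = -1
                    s = r // n_copies
                    b = bfrac[r, 0]
                    if ret_count[s] < cap:
                        tail = (ret_head[s] + ret_count[s]) % cap
                        if ret_fixed:
                            rd_dead[s, tail] = clock + ret_mean
                        else:
                            rd_dead[s, tail] = clock - ret_mean * np.log(
                                1.0 - np.random.random()
                            )
                        rd_bl[s, tail] = b
                        ret_count[s] += 1
                        ret_bsum[s] += b
                    else:
                        n_over += 1
                    for i in range(1, n):
                        pos[r, i - 1] = pos[r, i]
                        paused[r, i - 1] = paused[r, i]
                        bfrac[r, i - 1] = bfrac[r, i]
                        pause_cd[r, i - 1] = pause_cd[r, i]
                    n -= 1
                    npol[r] = n
            # 3. initiation when the promoter footprint is clear
            init_cd[r] -= 1
            if init_cd[r] == 0:
                init_cd[r] = _geom(p_init)
                if n < K and (n == 0 or pos[r, n - 1] >= foot):
                    pos[r, n] = 0.0
                    paused[r, n] = False
                    bfrac[r, n] = 0.0
                    pause_cd[r, n] = _geom(p_on)
                    npol[r] = n + 1
                    n_init += 1
        # 4. release of retained transcripts past their deadline
        for s in range(S):
            if ret_fixed:
                while ret_count[s] > 0 and rd_dead[s, ret_head[s]] <= clock:
                    ret_bsum[s] -= rd_bl[s, ret_head[s]]
                    ret_head[s] = (ret_head[s] + 1) % cap
                    ret_count[s] -= 1
                    n_rel += 1
            else:
                cnt = ret_count[s]
                h = ret_head[s]
                w = h
                kept = 0
                for j in range(cnt):
                    idx = (h + j) % cap
                    if rd_dead[s, idx] <= clock:
                        ret_bsum[s] -= rd_bl[s, idx]
                        n_rel += 1
                    else:
                        rd_dead[s, w] = rd_dead[s, idx]
                        rd_bl[s, w] = rd_bl[s, idx]
                        w = (w + 1) % cap
                        kept += 1
                ret_count[s] = kept

        need_sample = si < ns_samples and step_i == sample_steps[si]
        need_meas = measure_every > 0 and (step_i % measure_every) == 0
        if need_sample or need_meas:
            for s in range(S):
                site_tot[s] = float(ret_count[s])
                site_unb[s] = float(ret_count[s]) - ret_bsum[s]
            for r in range(R):
                s = r // n_copies
                for i in range(npol[r]):
                    f = (pos[r, i] - ms2_start) / ms2_len
                    if f < 0.0:
                        f = 0.0
                    elif f > 1.0:
                        f = 1.0
                    site_tot[s] += f
                    site_unb[s] += f - bfrac[r, i]
            if need_meas:
                tt = 0.0
                for s in range(S):
                    tt += site_tot[s]
                total_sum += tt
                n_meas += 1
            if need_sample:
                for s in range(S):
                    out_unb[si, s] = site_unb[s]
                si += 1

    return clock, total_sum, n_meas, n_init, n_rel, n_over
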