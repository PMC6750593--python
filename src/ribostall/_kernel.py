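"""Numba direct-method SSA kernel.

The kernel simulates the same CTMC as the rule set in
:mod:`ribostall.kinetic_model`, over a compressed per-mRNA state that
exploits two structural facts of the model with 3'-5' exonucleolysis
switched off (the default): removed poly(A) residues always form a 3'
suffix (a counter suffices) and exocleaved backbone sites always form a
5' prefix halted by an endocleaved site or a ribosome A site (a prefix
counter plus one endo-site index suffice).

Event selection is the classic two-pass direct method: per-mRNA
propensity totals are cached and only the modified mRNA is rescanned
after each event, so the cost per event is O(ribosomes on one mRNA).
``_scan_mrna`` walks the rule instances of one mRNA in a fixed order;
called with a negative threshold it returns the propensity total,
called with the residual selection threshold it applies the chosen
event in the same walk.
"""

import numpy as np
from numba import njit

# counter indices
I_INIT, I_FULL, I_ABORT, I_TX, I_COLL, I_CLEAVE, I_NPT = range(7)

_BIG = 1 << 60


@njit(cache=False)
def _remove_rib(m, j, nrib, rpos, rhf, rhb):
    n = nrib[m]
    for k in range(j, n - 1):
        rpos[m, k] = rpos[m, k + 1]
        rhf[m, k] = rhf[m, k + 1]
        rhb[m, k] = rhb[m, k + 1]
    nrib[m] = n - 1


@njit(cache=False)
def _scan_mrna(thresh, m, t,
               cap, start_blocked, polyA, exo_front, endo, rec_id,
               nrib, rpos, rhf, rhb,
               death, cnt, ptimes,
               elong, stall,
               k_init, k_term, k_dead, k_decap, k_exo,
               k_ab_no, k_ab_back, k_ab_front, k_ab_both, k_ab_trunc,
               k_cl_no, k_cl_back, k_cl_front, k_cl_both,
               L_m, FP, L_c):
    """thresh < 0: return total propensity of mRNA m.
    thresh >= 0: apply the event at cumulative propensity > thresh and
    return -1.0; returns the (nonnegative) total if the walk fell
    through without selecting, which the driver treats as roundoff."""
    tot = 0.0
    n = nrib[m]
    # --- initiation
    if (k_init > 0.0 and cap[m] == 1 and start_blocked[m] == 0
            and exo_front[m] < 1 and endo[m] != 1
            and (n == 0 or rpos[m, 0] != 1)):
        tot += k_init
        if thresh >= 0.0 and tot > thresh:
            for j in range(n, 0, -1):
                rpos[m, j] = rpos[m, j - 1]
                rhf[m, j] = rhf[m, j - 1]
                rhb[m, j] = rhb[m, j - 1]
            rpos[m, 0] = 1
            rhf[m, 0] = 0
            rhb[m, 0] = 0
            nrib[m] = n + 1
            start_blocked[m] = 1
            cnt[I_INIT] += 1
            return -1.0
    # --- per-ribosome rules, 5' to 3'
    for j in range(n):
        pos = rpos[m, j]
        nxt = rpos[m, j + 1] if j + 1 < n else _BIG
        r_ok = pos > exo_front[m] and pos != endo[m]
        if pos == L_m:
            if k_term > 0.0:
                tot += k_term
                if thresh >= 0.0 and tot > thresh:
                    if rhb[m, j] == 1:
                        rhf[m, j - 1] = 0
                    _remove_rib(m, j, nrib, rpos, rhf, rhb)
                    cnt[I_FULL] += 1
                    if cnt[I_NPT] < ptimes.shape[0]:
                        ptimes[cnt[I_NPT]] = t
                    cnt[I_NPT] += 1
                    return -1.0
        else:
            if (r_ok and nxt > pos + 1
                    and (pos + FP > L_m or nxt > pos + FP)):
                tot += elong[pos - 1]
                if thresh >= 0.0 and tot > thresh:
                    if rhb[m, j] == 1:
                        rhb[m, j] = 0
                        rhf[m, j - 1] = 0
                    if pos == FP - 1:
                        start_blocked[m] = 0
                    rpos[m, j] = pos + 1
                    return -1.0
            if nxt == pos + FP and rhf[m, j] == 0 and rhb[m, j + 1] == 0:
                tot += elong[pos - 1]
                if thresh >= 0.0 and tot > thresh:
                    rhf[m, j] = 1
                    rhb[m, j + 1] = 1
                    cnt[I_COLL] += 1
                    return -1.0
        # abortive termination; QC channels require stall engagement:
        # own A site on a stall codon (no/back), or the front partner
        # stalled (front); both-hit takes either
        self_stall = stall[pos - 1] == 1
        front_stall = rhf[m, j] == 1 and stall[rpos[m, j + 1] - 1] == 1
        ab = 0.0
        if pos == endo[m]:
            ab = k_ab_trunc
        elif r_ok:
            hb = rhb[m, j]
            hf = rhf[m, j]
            if hb == 1 and hf == 1:
                if self_stall or front_stall:
                    ab = k_ab_both
            elif hb == 1:
                if self_stall:
                    ab = k_ab_back
            elif hf == 1:
                if front_stall:
                    ab = k_ab_front
            elif self_stall:
                ab = k_ab_no
        if ab > 0.0:
            tot += ab
            if thresh >= 0.0 and tot > thresh:
                if rhb[m, j] == 1:
                    rhf[m, j - 1] = 0
                if rhf[m, j] == 1:
                    rhb[m, j + 1] = 0
                if pos < FP:
                    # the aborting ribosome was the one covering the
                    # start region; vacate it
                    start_blocked[m] = 0
                _remove_rib(m, j, nrib, rpos, rhf, rhb)
                cnt[I_ABORT] += 1
                return -1.0
        # endonucleolytic cleavage L_c codons 5' of the A site
        if cap[m] == 1 and pos > L_c:
            site = pos - L_c
            if site > exo_front[m] and site != endo[m]:
                # the cut is executed by the stalled ribosome itself
                # (collided interface at the stall)
                cl = 0.0
                hb = rhb[m, j]
                hf = rhf[m, j]
                if hb == 1 and hf == 1:
                    if self_stall:
                        cl = k_cl_both
                elif hb == 1:
                    if self_stall:
                        cl = k_cl_back
                elif hf == 1:
                    if front_stall:
                        cl = k_cl_front
                elif self_stall:
                    cl = k_cl_no
                if cl > 0.0:
                    tot += cl
                    if thresh >= 0.0 and tot > thresh:
                        endo[m] = site
                        cap[m] = 0
                        cnt[I_CLEAVE] += 1
                        return -1.0
    # --- canonical decay
    if polyA[m] > 0 and k_dead > 0.0:
        tot += k_dead
        if thresh >= 0.0 and tot > thresh:
            polyA[m] -= 1
            return -1.0
    if cap[m] == 1 and polyA[m] == 0 and k_decap > 0.0:
        tot += k_decap
        if thresh >= 0.0 and tot > thresh:
            cap[m] = 0
            return -1.0
    if k_exo > 0.0:
        i = exo_front[m] + 1
        if (i <= L_m and i != endo[m] and (i > 1 or cap[m] == 0)
                and (n == 0 or rpos[m, 0] != i)):
            tot += k_exo
            if thresh >= 0.0 and tot > thresh:
                exo_front[m] = i
                if i == 1:
                    death[rec_id[m]] = t
                return -1.0
    return tot


@njit(cache=False)
def run_kernel(seed, duration, max_events,
               k_tx, k_init, k_term, k_dead, k_decap, k_exo,
               k_ab_no, k_ab_back, k_ab_front, k_ab_both, k_ab_trunc,
               k_cl_no, k_cl_back, k_cl_front, k_cl_both,
               elong, stall,
               L_m, L_p, FP, L_c,
               M_cap, REC_cap, PT_cap):
    np.random.seed(seed)
    R_cap = L_m // FP + 2

    cap = np.zeros(M_cap, np.uint8)
    start_blocked = np.zeros(M_cap, np.uint8)
    polyA = np.zeros(M_cap, np.int64)
    exo_front = np.zeros(M_cap, np.int64)
    endo = np.zeros(M_cap, np.int64)
    rec_id = np.zeros(M_cap, np.int64)
    nrib = np.zeros(M_cap, np.int64)
    rpos = np.zeros((M_cap, R_cap), np.int64)
    rhf = np.zeros((M_cap, R_cap), np.uint8)
    rhb = np.zeros((M_cap, R_cap), np.uint8)
    prop = np.zeros(M_cap, np.float64)

    birth = np.full(REC_cap, np.nan)
    death = np.full(REC_cap, np.nan)
    ptimes = np.empty(PT_cap, np.float64)
    cnt = np.zeros(8, np.int64)

    active = np.empty(M_cap, np.int64)
    n_active = 0
    free = np.empty(M_cap, np.int64)
    for s in range(M_cap):
        free[s] = M_cap - 1 - s
    n_free = M_cap

    n_rec = 0
    n_overflow = 0
    t = 0.0
    n_events = 0
    hit_cap = 0
    absorbed_at = -1.0

    def_args = (cap, start_blocked, polyA, exo_front, endo, rec_id,
                nrib, rpos, rhf, rhb, death, cnt, ptimes, elong, stall,
                k_init, k_term, k_dead, k_decap, k_exo,
                k_ab_no, k_ab_back, k_ab_front, k_ab_both, k_ab_trunc,
                k_cl_no, k_cl_back, k_cl_front, k_cl_both,
                L_m, FP, L_c)

    if k_tx == 0.0:
        # single tracked mRNA
        slot = free[n_free - 1]
        n_free -= 1
        cap[slot] = 1
        polyA[slot] = L_p
        rec_id[slot] = n_rec
        birth[n_rec] = 0.0
        n_rec += 1
        active[n_active] = slot
        n_active += 1
        prop[slot] = _scan_mrna(-1.0, slot, t, *def_args)

    while True:
        total = k_tx
        for a in range(n_active):
            total += prop[active[a]]
        if total <= 0.0:
            absorbed_at = t
            break
        dt = -np.log(1.0 - np.random.random()) / total
        if t + dt > duration:
            break
        t += dt
        n_events += 1
        if n_events > max_events:
            hit_cap = 1
            break
        u = np.random.random() * total
        if u < k_tx:
            if n_free > 0 and n_rec < REC_cap:
                slot = free[n_free - 1]
                n_free -= 1
                cap[slot] = 1
                start_blocked[slot] = 0
                polyA[slot] = L_p
                exo_front[slot] = 0
                endo[slot] = 0
                nrib[slot] = 0
                rec_id[slot] = n_rec
                birth[n_rec] = t
                n_rec += 1
                cnt[I_TX] += 1
                active[n_active] = slot
                n_active += 1
                prop[slot] = _scan_mrna(-1.0, slot, t, *def_args)
            else:
                n_overflow += 1
            continue
        u -= k_tx
        ai = 0
        while ai < n_active - 1 and u >= prop[active[ai]]:
            u -= prop[active[ai]]
            ai += 1
        m = active[ai]
        r = _scan_mrna(u, m, t, *def_args)
        if r >= 0.0:
            # float roundoff left the walk unselected; retarget midway
            tot_m = _scan_mrna(-1.0, m, t, *def_args)
            if tot_m > 0.0:
                _scan_mrna(0.5 * tot_m, m, t, *def_args)
        prop[m] = _scan_mrna(-1.0, m, t, *def_args)
        if nrib[m] == 0 and prop[m] <= 0.0:
            # inert mRNA (fully degraded 5' part, bare 3' fragment):
            # retire the slot
            active[ai] = active[n_active - 1]
            n_active -= 1
            free[n_free] = m
            n_free += 1

    n_bound = 0
    for a in range(n_active):
        n_bound += nrib[active[a]]
    n_pt = min(cnt[I_NPT], PT_cap)
    return (cnt, n_rec, birth[:n_rec].copy(), death[:n_rec].copy(),
            n_bound, n_overflow, hit_cap, absorbed_at,
            ptimes[:n_pt].copy(), t)
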