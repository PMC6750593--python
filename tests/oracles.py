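"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result from first principles in a
deliberately naive style, sharing no helper code with the package, so
agreement is meaningful.
"""

import numpy as np

from ribostall.kinetic_model import ENDOCLEAVED, EXOCLEAVED, INTACT


def enumerate_events_oracle(state, params):
    """Re-enumerate enabled rule instances directly from the reaction
    preconditions; returns a multiset of (rule, mrna, rib-or-site,
    propensity) tuples."""
    p = params
    out = []
    if p.k_transcription > 0 and state.n_dna > 0:
        out.append(("TRANSCRIBE", None, None,
                    p.k_transcription * state.n_dna))
    er = p.elongation_rates
    FP = p.footprint

    def stalled(i):  # 1-based codon on a slow codon?
        return (p.n_stall > 0
                and p.stall_start <= i <= p.stall_start + p.n_stall - 1)

    for mi, m in enumerate(state.mrnas):
        occ = {}
        for j, r in enumerate(m.ribosomes):
            occ[r.a_site] = j
        # initiation: cap, start clear, codon 1 free, r1 intact
        if (p.k_init > 0 and m.cap and not m.start_blocked
                and 1 not in occ and m.backbone[0] == INTACT):
            out.append(("INITIATE", mi, None, p.k_init))
        for j, r in enumerate(m.ribosomes):
            i = r.a_site
            if i == p.L_m:
                if p.k_term > 0:
                    out.append(("TERMINATE", mi, j, p.k_term))
            else:
                if (m.backbone[i - 1] == INTACT and er[i - 1] > 0
                        and (i + 1) not in occ
                        and (i + FP > p.L_m or (i + FP) not in occ)):
                    out.append(("ELONGATE", mi, j, er[i - 1]))
                if (i + FP) in occ and er[i - 1] > 0:
                    lead = m.ribosomes[occ[i + FP]]
                    if not r.hit_front and not lead.hit_back:
                        out.append(("COLLIDE", mi, j, er[i - 1]))
            # quality control
            front_stalled = r.hit_front and stalled(
                m.ribosomes[occ[i + FP]].a_site)
            if m.backbone[i - 1] == ENDOCLEAVED:
                if p.k_abort_truncated > 0:
                    out.append(("ABORT_TRUNCATED", mi, j,
                                p.k_abort_truncated))
            elif m.backbone[i - 1] == INTACT:
                hb, hf = r.hit_back, r.hit_front
                if hb and hf and (stalled(i) or front_stalled):
                    k, rule = p.k_abort_both_hit, "ABORT_BOTH"
                elif hb and not hf and stalled(i):
                    k, rule = p.k_abort_back_hit, "ABORT_BACK"
                elif hf and not hb and front_stalled:
                    k, rule = p.k_abort_front_hit, "ABORT_FRONT"
                elif not hb and not hf and stalled(i):
                    k, rule = p.k_abort_no_hit, "ABORT_NO"
                else:
                    k, rule = 0.0, None
                if k > 0:
                    out.append((rule, mi, j, k))
            if m.cap and i > p.L_c and m.backbone[i - 1 - p.L_c] == INTACT:
                hb, hf = r.hit_back, r.hit_front
                if hb and hf and stalled(i):
                    k, rule = p.k_cleave_both_hit, "CLEAVE_BOTH"
                elif hb and not hf and stalled(i):
                    k, rule = p.k_cleave_back_hit, "CLEAVE_BACK"
                elif hf and not hb and front_stalled:
                    k, rule = p.k_cleave_front_hit, "CLEAVE_FRONT"
                elif not hb and not hf and stalled(i):
                    k, rule = p.k_cleave_no_hit, "CLEAVE_NO"
                else:
                    k, rule = 0.0, None
                if k > 0:
                    out.append((rule, mi, j, k))
        # deadenylation: 3'-most intact residue only
        if p.k_deadenylation > 0:
            for jj in range(1, p.L_p + 1):
                if m.polyA[jj - 1] and (jj == p.L_p or not m.polyA[jj]):
                    out.append(("DEADENYLATE", mi, jj, p.k_deadenylation))
        # decapping after complete deadenylation
        if (p.k_decapping > 0 and m.cap
                and (p.L_p == 0 or not m.polyA[0])):
            out.append(("DECAP", mi, None, p.k_decapping))
        # exonucleolysis
        for i in range(1, p.L_m + 1):
            if m.backbone[i - 1] != INTACT or i in occ:
                continue
            if p.k_exo_53 > 0:
                if (i == 1 and not m.cap) or \
                        (i > 1 and m.backbone[i - 2] == EXOCLEAVED):
                    out.append(("EXO53", mi, i, p.k_exo_53))
            if p.k_exo_35 > 0:
                tail_gone = p.L_p == 0 or not m.polyA[0]
                if (i == p.L_m and tail_gone) or \
                        (i < p.L_m and m.backbone[i] == EXOCLEAVED):
                    out.append(("EXO35", mi, i, p.k_exo_35))
    return sorted(out, key=lambda t: (t[0], str(t[1]), str(t[2])))


def scan_windows_oracle(aa_seq, residues, window=10, min_count=6):
    """Naive O(L*window) scan over every offset of a residue string."""
    starts = []
    for s in range(len(aa_seq) - window + 1):
        n = 0
        for c in aa_seq[s:s + window]:
            if c in residues:
                n += 1
        if n >= min_count:
            starts.append(s + 1)
    return starts


def merge_intervals_oracle(intervals):
    """Classic merge of [start, end] integer intervals, abutting counts
    as overlapping."""
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]
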