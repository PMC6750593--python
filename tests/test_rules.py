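"""Rule-level tests: enumeration examples, state updates, invariants,
and equivalence with an independently coded brute-force oracle."""

import numpy as np
import pytest

from ribostall import make_params, translation_only
from ribostall.kinetic_model import (ENDOCLEAVED, Event, RibosomeOnMrna,
                                     apply_event, check_invariants,
                                     enabled_events, fresh_mrna,
                                     initial_state)
from ribostall.engine import run

from oracles import enumerate_events_oracle


def single_mrna_state(params, positions=(), bonds=()):
    st = initial_state(params)
    if not st.mrnas:
        st.mrnas.append(fresh_mrna(params))
        st.n_transcribed += 1
    m = st.mrnas[0]
    m.ribosomes = [RibosomeOnMrna(p) for p in sorted(positions)]
    for j in bonds:
        m.ribosomes[j].hit_front = True
        m.ribosomes[j + 1].hit_back = True
    if any(p <= 9 for p in positions):
        m.start_blocked = True
    return st


class TestEnumeration:
    def test_bare_dna_transcribes_only(self):
        p = make_params("tj", "none")
        st = initial_state(p)
        evs = enabled_events(st, p)
        assert [e.rule for e in evs] == ["TRANSCRIBE"]
        assert evs[0].propensity == pytest.approx(0.001)

    def test_fresh_mrna_initiates_and_deadenylates(self):
        # transcription off: a single tracked mRNA with no ribosomes
        # can only initiate or lose its 3'-most poly(A) residue
        p = make_params("tj", "none", k_transcription=0.0)
        st = initial_state(p)
        evs = sorted(enabled_events(st, p), key=lambda e: e.rule)
        assert [e.rule for e in evs] == ["DEADENYLATE", "INITIATE"]
        dead, init = evs
        assert dead.site == p.L_p and dead.propensity == pytest.approx(0.03)
        assert init.propensity == pytest.approx(p.k_init)

    def test_pair_at_footprint_gap_collides_and_blocks_trailer(self):
        p = translation_only(make_params("tj", "none"))
        st = single_mrna_state(p, positions=(390, 400))
        evs = enabled_events(st, p)
        rules = {(e.rule, e.rib) for e in evs}
        coll = [e for e in evs if e.rule == "COLLIDE"]
        assert len(coll) == 1 and coll[0].rib == 0
        assert coll[0].propensity == pytest.approx(10.0)  # trailer codon
        assert ("ELONGATE", 1) in rules      # leader free to move
        assert ("ELONGATE", 0) not in rules  # trailer sterically blocked

    def test_enumeration_is_pure(self):
        p = translation_only(make_params("csat", "csec", k_a=0.2,
                                         k_cleave=0.01))
        st = single_mrna_state(p, positions=(391, 401), bonds=(0,))
        first = enabled_events(st, p)
        second = enabled_events(st, p)
        assert [(e.rule, e.mrna, e.rib, e.site, e.propensity)
                for e in first] == \
               [(e.rule, e.mrna, e.rib, e.site, e.propensity)
                for e in second]


class TestApply:
    def test_collide_sets_symmetric_bond_without_moving(self):
        p = translation_only(make_params("csat", "none", k_a=0.1))
        st = single_mrna_state(p, positions=(390, 400))
        ev = [e for e in enabled_events(st, p) if e.rule == "COLLIDE"][0]
        apply_event(st, ev)
        trailer, leader = st.mrnas[0].ribosomes
        assert trailer.a_site == 390 and leader.a_site == 400
        assert trailer.hit_front and leader.hit_back
        assert not trailer.hit_back and not leader.hit_front

    def test_elongation_of_back_hit_leader_dissolves_bond(self):
        p = translation_only(make_params("tj", "none"))
        st = single_mrna_state(p, positions=(390, 400), bonds=(0,))
        ev = [e for e in enabled_events(st, p)
              if e.rule == "ELONGATE" and e.rib == 1][0]
        apply_event(st, ev)
        trailer, leader = st.mrnas[0].ribosomes
        assert leader.a_site == 401
        assert not leader.hit_back and not trailer.hit_front

    def test_cleavage_cuts_upstream_and_decaps_keeping_bond(self):
        p = translation_only(make_params("tj", "csec", k_cleave=0.01))
        st = single_mrna_state(p, positions=(396, 406), bonds=(0,))
        m = st.mrnas[0]
        ev = [e for e in enabled_events(st, p)
              if e.rule == "CLEAVE_BACK"][0]
        assert ev.rib == 1 and ev.site == 396
        apply_event(st, ev)
        assert m.backbone[395] == ENDOCLEAVED
        assert not m.cap
        assert m.ribosomes[1].hit_back  # collision bond survives the cut
        check_invariants(st, p)

    def test_abort_within_start_region_vacates_it(self):
        p = translation_only(make_params("tj", "none",
                                         stall_start=5, n_stall=1,
                                         k_abort_no_hit=1.0))
        p = p.replace(k_abort_no_hit=1.0)
        st = single_mrna_state(p, positions=(5,))
        assert st.mrnas[0].start_blocked
        ev = [e for e in enabled_events(st, p) if e.rule == "ABORT_NO"][0]
        apply_event(st, ev)
        assert not st.mrnas[0].start_blocked
        assert st.n_aborted == 1


class TestOracleEquivalence:
    """Event enumeration matches a naive re-derivation of every rule
    precondition, on states sampled by running the reference engine."""

    @pytest.mark.parametrize("abort,cleave,seed", [
        ("tj", "none", 1), ("sat", "none", 2), ("cat", "none", 3),
        ("csat", "none", 4), ("tj", "sec", 5), ("csat", "csec", 6),
    ])
    def test_sampled_states_match_oracle(self, abort, cleave, seed):
        p = make_params(abort, cleave, k_a=0.3, k_cleave=0.02,
                        L_m=40, L_p=4, stall_start=25, n_stall=3,
                        net_stall_rate=0.2, k_init=1.0,
                        k_transcription=0.02, k_deadenylation=0.1,
                        k_decapping=0.05)
        rng = np.random.default_rng(seed)
        from ribostall.kinetic_model import SystemState
        st = initial_state(p)
        for step in range(400):
            evs = enabled_events(st, p)
            got = sorted(
                ((e.rule, e.mrna,
                  e.rib if e.rib is not None else e.site, e.propensity)
                 for e in evs),
                key=lambda t: (t[0], str(t[1]), str(t[2])))
            want = enumerate_events_oracle(st, p)
            assert got == want, f"divergence at step {step}"
            if not evs:
                break
            probs = np.array([e.propensity for e in evs])
            ev = evs[rng.choice(len(evs), p=probs / probs.sum())]
            st.time += rng.exponential(1.0 / probs.sum())
            apply_event(st, ev)
            check_invariants(st, p)


class TestStructuralInvariants:
    def test_invariants_hold_along_high_traffic_run(self):
        p = translation_only(make_params("csat", "csec", k_a=0.5,
                                         k_cleave=0.02, k_init=1.0,
                                         L_m=60, stall_start=41,
                                         n_stall=4, net_stall_rate=0.1))
        tr = run(p, 60.0, 7, engine="reference")
        # conservation of ribosomes over the whole run
        assert tr.n_initiations == (tr.n_full_proteins + tr.n_aborted
                                    + tr.n_bound_final)

    def test_ribosomes_never_share_codons_or_pass(self):
        p = translation_only(make_params("tj", "none", k_init=2.0,
                                         L_m=60, stall_start=41,
                                         n_stall=4))
        st = initial_state(p)
        rng = np.random.default_rng(11)
        for _ in range(2000):
            evs = enabled_events(st, p)
            if not evs:
                break
            probs = np.array([e.propensity for e in evs])
            apply_event(st, evs[rng.choice(len(evs),
                                           p=probs / probs.sum())])
            check_invariants(st, p)
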