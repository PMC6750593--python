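"""State space and reaction rules of the translation/quality-control/decay CTMC.

The state mirrors the agent-based molecule types of the model: an mRNA
carries a cap (present/absent), a start region (clear/blocked), one
backbone site per codon (intact / endocleaved / exocleaved), a poly(A)
tail of removable residues, and a position-ordered set of bound
ribosomes.  A ribosome carries its A-site codon plus two collision
bonds: ``hit_front`` (it ran into a leading ribosome -- it is the
trailing partner) and ``hit_back`` (a trailing ribosome ran into it --
it is the leading partner).

:func:`enabled_events` enumerates every applicable reaction-rule
instance with its propensity; :func:`apply_event` executes one.  The
rules, in brief:

TRANSCRIBE      DNA -> fresh capped mRNA (k_transcription)
INITIATE        capped mRNA, start clear, codon 1 free, r1 intact (k_init)
ELONGATE        A site i -> i+1; needs r_i intact, codon i+1 free and no
                ribosome exactly one footprint ahead; moving off codon 9
                clears the start region; moving dissolves a back bond
TERMINATE       A site at the last codon; makes a full protein
COLLIDE         unbonded pair at exactly footprint distance bonds, at
                the trailing ribosome's elongation rate
DEADENYLATE     3'-most intact poly(A) residue removed (k_deadenylation)
DECAP           after full deadenylation (k_decapping)
EXO53 / EXO35   exonucleolysis of the next backbone site; 5'-3' entry
                needs the cap gone; blocked at A-site codons
ABORT_*         abortive termination, rate by collision state; fires
                only with stall engagement (own A site on a stall
                codon, or -- for the front-hit channels -- a stalled
                front partner); an abort from within the start region
                (A site < footprint) vacates it
ABORT_TRUNCATED ribosome whose A-site backbone is endocleaved leaves at
                a uniform high rate regardless of collision state or
                codon
CLEAVE_*        backbone endocleaved L_c codons 5' of the A site and the
                cap removed, rate by collision state; executed by a
                ribosome whose own A site is on a stall codon; needs
                the cap present, so at most one cleavage per mRNA
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

INTACT, ENDOCLEAVED, EXOCLEAVED = 0, 1, 2

ABORT_RULES = ("ABORT_NO", "ABORT_BACK", "ABORT_FRONT", "ABORT_BOTH",
               "ABORT_TRUNCATED")
CLEAVE_RULES = ("CLEAVE_NO", "CLEAVE_BACK", "CLEAVE_FRONT", "CLEAVE_BOTH")


@dataclass
class RibosomeOnMrna:
    a_site: int
    hit_front: bool = False
    hit_back: bool = False


@dataclass
class Mrna:
    birth_time: float = 0.0
    cap: bool = True
    start_blocked: bool = False
    backbone: np.ndarray | None = None   # uint8[L_m], codes above
    polyA: np.ndarray | None = None      # uint8[L_p], 1 = intact
    ribosomes: list[RibosomeOnMrna] = field(default_factory=list)
    death_time: float | None = None      # first EXO53 event (at site 1)


def fresh_mrna(params: ModelParams, birth_time: float = 0.0) -> Mrna:
    return Mrna(birth_time=birth_time,
                backbone=np.full(params.L_m, INTACT, dtype=np.uint8),
                polyA=np.ones(params.L_p, dtype=np.uint8))


@dataclass
class SystemState:
    time: float = 0.0
    n_dna: int = 1
    mrnas: list[Mrna] = field(default_factory=list)
    # records of mRNAs pruned from the live list: (birth, death-or-None)
    retired: list = field(default_factory=list)
    n_initiations: int = 0
    n_full: int = 0
    n_aborted: int = 0
    n_transcribed: int = 0
    n_collisions: int = 0
    n_cleaved: int = 0


def initial_state(params: ModelParams) -> SystemState:
    """One DNA and no mRNA -- unless transcription is off, in which case
    a single fresh mRNA is tracked (the no-decay sweep configuration)."""
    st = SystemState()
    st._params = params  # lets TRANSCRIBE size new mRNAs correctly
    if params.k_transcription == 0:
        st.mrnas.append(fresh_mrna(params, 0.0))
        st.n_transcribed = 1
    return st


@dataclass(frozen=True)
class Event:
    rule: str
    mrna: int | None = None
    rib: int | None = None
    site: int | None = None
    propensity: float = 0.0


def _abort_channel(rib: RibosomeOnMrna, self_stall: bool,
                   front_stall: bool, p: ModelParams) -> tuple[str, float]:
    """Abort rate by collision state, scoped to stall engagement.

    no/back channels need the ribosome's own A site on a stall codon;
    the front channel needs its front partner stalled (it ran into a
    stalled ribosome); both-hit takes either.
    """
    if rib.hit_back and rib.hit_front:
        k = p.k_abort_both_hit if (self_stall or front_stall) else 0.0
        return "ABORT_BOTH", k
    if rib.hit_back:
        return "ABORT_BACK", p.k_abort_back_hit if self_stall else 0.0
    if rib.hit_front:
        return "ABORT_FRONT", p.k_abort_front_hit if front_stall else 0.0
    return "ABORT_NO", p.k_abort_no_hit if self_stall else 0.0


def _cleave_channel(rib: RibosomeOnMrna, self_stall: bool,
                    front_stall: bool, p: ModelParams) -> tuple[str, float]:
    """Cleavage rate by collision state; the cut is executed by the
    stalled ribosome itself (no/back/both need its own A site on a
    stall codon), so the CSEC hazard does not grow with queue length."""
    if rib.hit_back and rib.hit_front:
        return "CLEAVE_BOTH", p.k_cleave_both_hit if self_stall else 0.0
    if rib.hit_back:
        return "CLEAVE_BACK", p.k_cleave_back_hit if self_stall else 0.0
    if rib.hit_front:
        return "CLEAVE_FRONT", p.k_cleave_front_hit if front_stall else 0.0
    return "CLEAVE_NO", p.k_cleave_no_hit if self_stall else 0.0


def enabled_events(state: SystemState, params: ModelParams) -> list[Event]:
    """Enumerate every enabled rule instance with its propensity.

    A pure function of the state: re-enumerating an untouched state
    yields the same event list.  Zero-propensity instances are omitted.
    """
    p = params
    evs: list[Event] = []
    if p.k_transcription > 0 and state.n_dna > 0:
        evs.append(Event("TRANSCRIBE",
                         propensity=p.k_transcription * state.n_dna))
    er = p.elongation_rates
    stall = p.stall_mask
    FP = p.footprint
    for mi, m in enumerate(state.mrnas):
        bb = m.backbone
        ribs = m.ribosomes
        occupied = {r.a_site for r in ribs}
        if (p.k_init > 0 and m.cap and not m.start_blocked
                and bb[0] == INTACT and 1 not in occupied):
            evs.append(Event("INITIATE", mi, propensity=p.k_init))
        for j, rib in enumerate(ribs):
            pos = rib.a_site
            nxt = ribs[j + 1].a_site if j + 1 < len(ribs) else None
            if pos == p.L_m:
                if p.k_term > 0:
                    evs.append(Event("TERMINATE", mi, j,
                                     propensity=p.k_term))
            else:
                if (bb[pos - 1] == INTACT and er[pos - 1] > 0
                        and (pos + 1) not in occupied
                        and (pos + FP > p.L_m or (pos + FP) not in occupied)):
                    evs.append(Event("ELONGATE", mi, j,
                                     propensity=er[pos - 1]))
                if (nxt == pos + FP and not rib.hit_front
                        and not ribs[j + 1].hit_back and er[pos - 1] > 0):
                    evs.append(Event("COLLIDE", mi, j,
                                     propensity=er[pos - 1]))
            self_stall = bool(stall[pos - 1])
            front_stall = bool(rib.hit_front
                               and stall[ribs[j + 1].a_site - 1])
            if bb[pos - 1] == ENDOCLEAVED:
                if p.k_abort_truncated > 0:
                    evs.append(Event("ABORT_TRUNCATED", mi, j,
                                     propensity=p.k_abort_truncated))
            elif bb[pos - 1] == INTACT:
                rule, k = _abort_channel(rib, self_stall, front_stall, p)
                if k > 0:
                    evs.append(Event(rule, mi, j, propensity=k))
            if m.cap and pos > p.L_c:
                site = pos - p.L_c
                if bb[site - 1] == INTACT:
                    rule, k = _cleave_channel(rib, self_stall,
                                              front_stall, p)
                    if k > 0:
                        evs.append(Event(rule, mi, j, site=site,
                                         propensity=k))
        if p.k_deadenylation > 0:
            pa = m.polyA
            for j in range(p.L_p):
                if pa[j] and (j == p.L_p - 1 or not pa[j + 1]):
                    evs.append(Event("DEADENYLATE", mi, site=j + 1,
                                     propensity=p.k_deadenylation))
        if (p.k_decapping > 0 and m.cap
                and (p.L_p == 0 or not m.polyA[0])):
            evs.append(Event("DECAP", mi, propensity=p.k_decapping))
        if p.k_exo_53 > 0:
            for i in range(1, p.L_m + 1):
                if bb[i - 1] != INTACT:
                    continue
                entry_ok = ((i == 1 and not m.cap)
                            or (i > 1 and bb[i - 2] == EXOCLEAVED))
                if entry_ok and i not in occupied:
                    evs.append(Event("EXO53", mi, site=i,
                                     propensity=p.k_exo_53))
        if p.k_exo_35 > 0:
            tail_gone = p.L_p == 0 or not m.polyA[0]
            for i in range(1, p.L_m + 1):
                if bb[i - 1] != INTACT:
                    continue
                entry_ok = ((i == p.L_m and tail_gone)
                            or (i < p.L_m and bb[i] == EXOCLEAVED))
                if entry_ok and i not in occupied:
                    evs.append(Event("EXO35", mi, site=i,
                                     propensity=p.k_exo_35))
    return evs


def apply_event(state: SystemState, ev: Event) -> SystemState:
    """Execute one enabled event, updating the state in place.

    The event must have been enumerated from this exact state.
    """
    if ev.rule == "TRANSCRIBE":
        state.n_transcribed += 1
        state.mrnas.append(fresh_mrna(_params_of(state), state.time))
        return state
    m = state.mrnas[ev.mrna]
    ribs = m.ribosomes
    if ev.rule == "INITIATE":
        ribs.insert(0, RibosomeOnMrna(1))
        m.start_blocked = True
        state.n_initiations += 1
    elif ev.rule == "ELONGATE":
        rib = ribs[ev.rib]
        if rib.a_site == _params_of(state).footprint - 1:
            m.start_blocked = False
        if rib.hit_back:
            rib.hit_back = False
            ribs[ev.rib - 1].hit_front = False
        rib.a_site += 1
    elif ev.rule == "TERMINATE":
        rib = ribs[ev.rib]
        if rib.hit_back:
            ribs[ev.rib - 1].hit_front = False
        ribs.pop(ev.rib)
        state.n_full += 1
    elif ev.rule == "COLLIDE":
        ribs[ev.rib].hit_front = True
        ribs[ev.rib + 1].hit_back = True
        state.n_collisions += 1
    elif ev.rule in ABORT_RULES:
        rib = ribs[ev.rib]
        if rib.hit_back:
            ribs[ev.rib - 1].hit_front = False
        if rib.hit_front:
            ribs[ev.rib + 1].hit_back = False
        if rib.a_site < _params_of(state).footprint:
            # an abort from within the start region vacates it
            m.start_blocked = False
        ribs.pop(ev.rib)
        state.n_aborted += 1
    elif ev.rule in CLEAVE_RULES:
        m.backbone[ev.site - 1] = ENDOCLEAVED
        m.cap = False
        state.n_cleaved += 1
    elif ev.rule == "DEADENYLATE":
        m.polyA[ev.site - 1] = 0
    elif ev.rule == "DECAP":
        m.cap = False
    elif ev.rule == "EXO53":
        m.backbone[ev.site - 1] = EXOCLEAVED
        if ev.site == 1 and m.death_time is None:
            m.death_time = state.time
    elif ev.rule == "EXO35":
        m.backbone[ev.site - 1] = EXOCLEAVED
    else:
        raise ValueError(f"unknown rule {ev.rule!r}")
    return state


def _params_of(state: SystemState) -> ModelParams:
    # the engine stashes params on the state so TRANSCRIBE can build
    # a correctly sized mRNA without a second argument
    p = getattr(state, "_params", None)
    if p is None:
        raise RuntimeError("state has no attached params; set state._params")
    return p


def check_invariants(state: SystemState, params: ModelParams) -> None:
    """Assert structural invariants; raises AssertionError on violation.

    Bonded pairs sit at exactly footprint distance with symmetric flags;
    ribosome order is strict (no passing, no shared codon); exocleaved
    backbone forms a 5' prefix up to an endocleaved site or A-site
    blockade (when 3'-5' exonucleolysis is off); removed poly(A)
    residues form a 3' suffix; an endocleaved site implies no cap.
    """
    FP = params.footprint
    for m in state.mrnas:
        pos = [r.a_site for r in m.ribosomes]
        assert all(b > a for a, b in zip(pos, pos[1:])), "ribosome order"
        for j, rib in enumerate(m.ribosomes):
            if rib.hit_front:
                assert j + 1 < len(pos) and pos[j + 1] == pos[j] + FP
                assert m.ribosomes[j + 1].hit_back, "asymmetric bond"
            if rib.hit_back:
                assert j > 0 and pos[j - 1] == pos[j] - FP
                assert m.ribosomes[j - 1].hit_front, "asymmetric bond"
        pa = m.polyA
        if params.L_p:
            removed = np.flatnonzero(pa == 0)
            if removed.size:
                assert removed[0] + removed.size == params.L_p, \
                    "poly(A) removal not a 3' suffix"
        if params.k_exo_35 == 0:
            exo = np.flatnonzero(m.backbone == EXOCLEAVED)
            if exo.size:
                assert exo[-1] == exo.size - 1, "exo53 not a 5' prefix"
        if (m.backbone == ENDOCLEAVED).any():
            assert not m.cap, "cap present on endocleaved mRNA"
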