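"""Exact stochastic simulation of the quality-control CTMC.

Two interchangeable engines sample the same chain:

``reference``
    A direct-method loop over the explicit rule set in
    :mod:`ribostall.kinetic_model`; re-enumerates every event each step.
    Slow but transparent; supports event logging and 3'-5'
    exonucleolysis.  Use for small systems and for validating the fast
    path.

``fast``
    The numba kernel in :mod:`ribostall._kernel` with incremental
    per-mRNA propensity updates.  Requires ``k_exo_35 == 0`` (the
    default parameterization).

Both are statistically exact: every jump is drawn from the current total
propensity and the event chosen proportionally to its propensity.  A
given ``(params, duration, seed, engine)`` tuple reproduces the same
trajectory bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, kinetic_model as km
from .params import ModelParams

#: default guard against runaway configurations
MAX_EVENTS_FAST = 500_000_000
MAX_EVENTS_REFERENCE = 5_000_000


class EngineError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Outcome of one SSA run: counters plus per-mRNA birth/death records.

    ``mrna_death`` is NaN for censored mRNAs (alive, or at least not yet
    entered by the 5'-3' exonuclease, at simulation end).  ``n_full_proteins``
    counts normal terminations, ``n_aborted`` premature ones.
    """

    params: ModelParams
    seed: int
    duration: float
    simulated_duration: float
    engine: str
    n_full_proteins: int = 0
    n_aborted: int = 0
    n_initiations: int = 0
    n_transcribed: int = 0
    n_collisions: int = 0
    n_cleaved: int = 0
    n_bound_final: int = 0
    mrna_birth: np.ndarray = field(default_factory=lambda: np.empty(0))
    mrna_death: np.ndarray = field(default_factory=lambda: np.empty(0))
    absorbed_at: float | None = None
    hit_event_cap: bool = False
    n_overflow: int = 0
    protein_times: np.ndarray | None = None
    events: pd.DataFrame | None = None

    @property
    def n_dead(self) -> int:
        return int(np.sum(~np.isnan(self.mrna_death)))

    @property
    def n_censored(self) -> int:
        return int(np.sum(np.isnan(self.mrna_death)))

    @property
    def lifetimes(self) -> np.ndarray:
        """Uncensored mRNA lifetimes (transcription to first 5'-3'
        exonucleolysis), seconds."""
        ok = ~np.isnan(self.mrna_death)
        return self.mrna_death[ok] - self.mrna_birth[ok]


def run(params: ModelParams, duration: float, seed: int,
        track_events: bool = False, engine: str = "auto",
        max_events: int | None = None) -> Trajectory:
    """Simulate the CTMC exactly for ``duration`` seconds.

    If transcription is off the initial state holds one fresh mRNA
    (single-molecule tracking mode); otherwise one DNA template and no
    mRNA.  ``track_events`` logs every event with the total propensity
    it was drawn from (reference engine only).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if engine == "auto":
        engine = "reference" if (track_events or params.k_exo_35 > 0) else "fast"
    if engine == "fast":
        if track_events:
            raise ValueError("event logging needs engine='reference'")
        if params.k_exo_35 > 0:
            raise ValueError("fast engine requires k_exo_35 == 0; "
                             "use engine='reference'")
        return _run_fast(params, duration, seed,
                         max_events or MAX_EVENTS_FAST)
    if engine == "reference":
        return _run_reference(params, duration, seed, track_events,
                              max_events or MAX_EVENTS_REFERENCE)
    raise ValueError(f"unknown engine {engine!r}")


def _run_fast(params: ModelParams, duration: float, seed: int,
              max_events: int) -> Trajectory:
    p = params
    if not (0 <= seed < 2 ** 31):
        raise ValueError("seed must be in [0, 2^31)")
    if p.k_transcription > 0:
        M_cap = 256
        REC_cap = int(p.k_transcription * duration * 3) + 1000
    else:
        M_cap = 1
        REC_cap = 8
    PT_cap = 2_000_000
    (cnt, n_rec, birth, death, n_bound, n_overflow, hit_cap, absorbed,
     ptimes, t_end) = _kernel.run_kernel(
        seed, float(duration), int(max_events),
        p.k_transcription, p.k_init, p.k_term,
        p.k_deadenylation, p.k_decapping, p.k_exo_53,
        p.k_abort_no_hit, p.k_abort_back_hit, p.k_abort_front_hit,
        p.k_abort_both_hit, p.k_abort_truncated,
        p.k_cleave_no_hit, p.k_cleave_back_hit, p.k_cleave_front_hit,
        p.k_cleave_both_hit,
        p.elongation_rates, p.stall_mask.astype(np.uint8),
        p.L_m, p.L_p, p.footprint, p.L_c,
        M_cap, REC_cap, PT_cap)
    simulated = t_end if hit_cap else duration
    return Trajectory(
        params=p, seed=seed, duration=duration,
        simulated_duration=simulated, engine="fast",
        n_full_proteins=int(cnt[_kernel.I_FULL]),
        n_aborted=int(cnt[_kernel.I_ABORT]),
        n_initiations=int(cnt[_kernel.I_INIT]),
        n_transcribed=int(n_rec),
        n_collisions=int(cnt[_kernel.I_COLL]),
        n_cleaved=int(cnt[_kernel.I_CLEAVE]),
        n_bound_final=int(n_bound),
        mrna_birth=birth, mrna_death=death,
        absorbed_at=None if absorbed < 0 else float(absorbed),
        hit_event_cap=bool(hit_cap), n_overflow=int(n_overflow),
        protein_times=ptimes)


def _run_reference(params: ModelParams, duration: float, seed: int,
                   track_events: bool, max_events: int) -> Trajectory:
    rng = np.random.default_rng(seed)
    state = km.initial_state(params)
    log: list[tuple] = []
    absorbed_at = None
    hit_cap = False
    n_events = 0
    protein_times: list[float] = []
    while True:
        evs = km.enabled_events(state, params)
        total = math.fsum(e.propensity for e in evs)
        if total <= 0:
            absorbed_at = state.time
            break
        dt = rng.exponential(1.0 / total)
        if state.time + dt > duration:
            break
        state.time += dt
        n_events += 1
        if n_events > max_events:
            hit_cap = True
            break
        u = rng.random() * total
        acc = 0.0
        chosen = evs[-1]
        for e in evs:
            acc += e.propensity
            if u < acc:
                chosen = e
                break
        if track_events:
            log.append((state.time, chosen.rule, chosen.mrna, total))
        if chosen.rule == "TERMINATE":
            protein_times.append(state.time)
        km.apply_event(state, chosen)
        _prune_inert(state, params, chosen.mrna)

    births = [b for b, _ in state.retired] + \
        [m.birth_time for m in state.mrnas]
    deaths = [d for _, d in state.retired] + \
        [m.death_time for m in state.mrnas]
    birth = np.array(births, dtype=float)
    death = np.array([np.nan if d is None else d for d in deaths],
                     dtype=float)
    traj = Trajectory(
        params=params, seed=seed, duration=duration,
        simulated_duration=state.time if hit_cap else duration,
        engine="reference",
        n_full_proteins=state.n_full, n_aborted=state.n_aborted,
        n_initiations=state.n_initiations,
        n_transcribed=state.n_transcribed,
        n_collisions=state.n_collisions, n_cleaved=state.n_cleaved,
        n_bound_final=sum(len(m.ribosomes) for m in state.mrnas),
        mrna_birth=birth, mrna_death=death,
        absorbed_at=absorbed_at, hit_event_cap=hit_cap,
        protein_times=np.asarray(protein_times))
    if track_events:
        traj.events = pd.DataFrame(
            log, columns=["time", "rule", "mrna", "total_propensity"])
    return traj


def _prune_inert(state: km.SystemState, params: ModelParams,
                 mi: int | None) -> None:
    """Drop the touched mRNA when it has become inert (ribosome-free
    with no enabled events: a fully degraded 5' part plus an
    undegradable 3' fragment); keeps enumeration cheap.  Its
    (birth, death) record moves to ``state.retired``."""
    if mi is None or mi >= len(state.mrnas):
        return
    m = state.mrnas[mi]
    if not m.ribosomes and not _mrna_has_events(m, params):
        state.retired.append((m.birth_time, m.death_time))
        del state.mrnas[mi]


def _mrna_has_events(m: km.Mrna, params: ModelParams) -> bool:
    sub = km.SystemState(n_dna=0, mrnas=[m])
    sub._params = params
    return len(km.enabled_events(sub, params)) > 0


def replicate_seeds(base_seed: int, n_reps: int) -> np.ndarray:
    """Deterministic replicate seeds below 2^31 derived from one base."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n_reps, dtype=np.uint32)
            & np.uint32(0x7FFFFFFF)).astype(np.int64)


def run_replicates(params: ModelParams, duration: float, n_reps: int,
                   base_seed: int, engine: str = "auto") -> pd.DataFrame:
    """Independent replicate runs; one row per replicate.

    Columns: seed, psr (full proteins / simulated time), counters,
    lifetime_mean / lifetime_sd over uncensored mRNAs (NaN if none),
    n_dead, n_censored.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rows = []
    for rep, seed in enumerate(replicate_seeds(base_seed, n_reps)):
        tr = run(params, duration, int(seed), engine=engine)
        lt = tr.lifetimes
        rows.append(dict(
            rep=rep, seed=int(seed),
            psr=tr.n_full_proteins / tr.simulated_duration,
            n_full=tr.n_full_proteins, n_aborted=tr.n_aborted,
            n_initiations=tr.n_initiations,
            n_transcribed=tr.n_transcribed,
            n_collisions=tr.n_collisions, n_cleaved=tr.n_cleaved,
            lifetime_mean=float(np.mean(lt)) if lt.size else np.nan,
            lifetime_sd=float(np.std(lt, ddof=1)) if lt.size > 1 else np.nan,
            n_dead=tr.n_dead, n_censored=tr.n_censored))
    return pd.DataFrame(rows)


def summarize_replicates(reps: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error across replicates for each observable."""
    num = reps.drop(columns=["rep", "seed"])
    mean = num.mean()
    se = num.std(ddof=1) / np.sqrt(len(reps))
    return pd.DataFrame({"mean": mean, "se": se})
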