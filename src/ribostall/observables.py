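"""Headline observables and initiation-rate sweeps.

The two quantities the simulations are read out through:

* protein synthesis rate (PSR): full proteins produced per second of
  biological time, per simulated system;
* mean mRNA lifetime: transcription to the first 5'-3' exonucleolysis
  event, averaged over uncensored mRNAs.

:func:`sweep` scans a grid of initiation rates for one abort/cleave
preset.  Abortive-termination sweeps track a single undegradable mRNA
(transcription and decay off); cleavage sweeps keep transcription and
canonical decay on so lifetime is defined, and PSR is then per system
(the transcription rate maintains a small steady-state mRNA pool).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory, run, run_replicates
from .params import ModelParams, make_params, translation_only


def protein_synthesis_rate(traj: Trajectory) -> float:
    """Full proteins per second of simulated biological time."""
    if traj.simulated_duration <= 0:
        raise ValueError("trajectory has no simulated time")
    return traj.n_full_proteins / traj.simulated_duration


@dataclass(frozen=True)
class LifetimeStats:
    mean: float
    sd: float
    n_dead: int
    n_censored: int


def mrna_lifetime_stats(traj: Trajectory) -> LifetimeStats:
    """Lifetime statistics over uncensored mRNAs.

    Raises ValueError when no mRNA death was observed; censored mRNAs
    are counted but excluded from the mean.
    """
    lt = traj.lifetimes
    if lt.size == 0:
        raise ValueError("no mRNA deaths observed (all censored)")
    sd = float(np.std(lt, ddof=1)) if lt.size > 1 else 0.0
    return LifetimeStats(float(np.mean(lt)), sd, traj.n_dead,
                         traj.n_censored)


def _cell_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([base_seed, index])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def sweep(abort_model: str, cleave_model: str, k_init_grid,
          *, k_a: float = 0.5, k_cleave: float = 0.001,
          duration: float = 1e5, n_reps: int = 4, base_seed: int = 0,
          overrides: dict | None = None, single_mrna: bool | None = None,
          engine: str = "auto") -> pd.DataFrame:
    """PSR and lifetime versus initiation rate for one model preset.

    One row per grid point with replicate means and standard errors.
    ``single_mrna`` defaults to True for pure abort presets
    (cleave_model == "none"): transcription and decay are switched off
    and one mRNA is tracked.  A failing grid cell is flagged in the
    ``failed`` column rather than aborting the sweep.
    """
    grid = list(k_init_grid)
    if not grid:
        raise ValueError("k_init_grid must be nonempty")
    if single_mrna is None:
        single_mrna = cleave_model == "none"
    rows = []
    for idx, k_init in enumerate(grid):
        params = make_params(abort_model, cleave_model, k_a=k_a,
                             k_cleave=k_cleave, k_init=float(k_init),
                             **(overrides or {}))
        if single_mrna:
            params = translation_only(params)
        row = dict(abort_model=abort_model, cleave_model=cleave_model,
                   k_init=float(k_init), k_a=k_a, k_cleave=k_cleave,
                   n_stall=params.n_stall,
                   net_stall_rate=params.net_stall_rate,
                   n_reps=n_reps, base_seed=base_seed,
                   cell_seed=_cell_seed(base_seed, idx), failed=False)
        try:
            reps = run_replicates(params, duration, n_reps,
                                  row["cell_seed"], engine=engine)
            row["psr_mean"] = reps["psr"].mean()
            row["psr_se"] = reps["psr"].std(ddof=1) / np.sqrt(n_reps)
            lt = reps["lifetime_mean"].dropna()
            if len(lt):
                row["lifetime_mean"] = lt.mean()
                row["lifetime_se"] = (lt.std(ddof=1) / np.sqrt(len(lt))
                                      if len(lt) > 1 else np.nan)
            else:
                row["lifetime_mean"] = np.nan
                row["lifetime_se"] = np.nan
            row["n_dead_total"] = int(reps["n_dead"].sum())
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            row.update(psr_mean=np.nan, psr_se=np.nan,
                       lifetime_mean=np.nan, lifetime_se=np.nan,
                       n_dead_total=0, failed=True, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
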