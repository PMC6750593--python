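"""Rate constants, lattice geometry and model presets for the quality-control CTMC.

The simulated system couples three processes on each mRNA:

* canonical translation -- initiation, codon-by-codon elongation with
  hard-core exclusion (footprint 10 codons), termination;
* ribosome quality control at an elongation stall -- abortive termination
  of ribosomes and/or endonucleolytic cleavage of the mRNA backbone,
  each with rates conditioned on the ribosome's collision state;
* canonical mRNA decay -- 3'-5' deadenylation of the poly(A) tail,
  decapping, then 5'-3' exonucleolysis.

A :class:`ModelParams` instance holds every rate constant and length.
Presets (:func:`make_params`) encode which abort/cleave channels are
switched on:

========  ===========================================================
TJ        traffic jam: no abortive termination at all
SAT       simple abort: no-hit and back-hit channels share one rate
CAT       collide-and-abort: the trailing (front-hit) ribosome aborts
CSAT      collision-stimulated abort: the leading (back-hit) ribosome aborts
SEC       simple cleavage: no-hit and back-hit cleavage share one rate
CSEC      collision-stimulated cleavage: only back-hit ribosomes cleave
========  ===========================================================
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

ABORT_MODELS = ("tj", "sat", "cat", "csat")
CLEAVE_MODELS = ("none", "sec", "csec")

#: Ribosome footprint on the mRNA, codons.
FOOTPRINT = 10

_RATE_FIELDS = (
    "k_transcription", "k_init", "k_elong_default", "k_term",
    "k_deadenylation", "k_decapping", "k_exo_53", "k_exo_35",
    "k_abort_no_hit", "k_abort_back_hit", "k_abort_front_hit",
    "k_abort_both_hit", "k_abort_truncated",
    "k_cleave_no_hit", "k_cleave_back_hit", "k_cleave_front_hit",
    "k_cleave_both_hit", "net_stall_rate",
)


class ParameterError(ValueError):
    """Raised for invalid rate constants or lattice geometry."""


def stall_profile(L_m: int, stall_start: int, n_stall: int,
                  net_rate: float, k_default: float) -> np.ndarray:
    """Per-codon elongation rates (1-based codon i at index i-1).

    Each of the ``n_stall`` consecutive slow codons gets rate
    ``n_stall * net_rate`` so that the summed mean dwell time across the
    stall is ``1/net_rate`` regardless of how many codons encode it.
    """
    if L_m < 1:
        raise ParameterError(f"L_m must be positive, got {L_m}")
    rates = np.full(L_m, float(k_default))
    if n_stall == 0:
        return rates
    if n_stall < 0:
        raise ParameterError(f"n_stall must be >= 0, got {n_stall}")
    if not (1 <= stall_start and stall_start + n_stall - 1 <= L_m):
        raise ParameterError(
            f"stall window [{stall_start}, {stall_start + n_stall - 1}] "
            f"outside coding region [1, {L_m}]")
    rates[stall_start - 1:stall_start + n_stall - 1] = n_stall * net_rate
    return rates


@dataclass(frozen=True)
class ModelParams:
    """All rate constants (1/s) and lengths of the CTMC.

    ``elongation_rates`` is derived from the stall geometry.  Abort and
    cleave channels act only with stall engagement: the ribosome's own
    A site on a stall codon, or (front-hit abort) a stalled front
    partner -- stacked ribosomes deeper in a queue are not quality-
    control substrates.
    """

    k_transcription: float = 0.001
    k_init: float = 0.1
    k_elong_default: float = 10.0
    k_term: float = 1.0
    k_deadenylation: float = 0.03
    k_decapping: float = 0.01
    k_exo_53: float = 1.0
    k_exo_35: float = 0.0
    k_abort_no_hit: float = 0.0
    k_abort_back_hit: float = 0.0
    k_abort_front_hit: float = 0.0
    k_abort_both_hit: float = 0.0
    k_abort_truncated: float = 1.0
    k_cleave_no_hit: float = 0.0
    k_cleave_back_hit: float = 0.0
    k_cleave_front_hit: float = 0.0
    k_cleave_both_hit: float = 0.0
    L_m: int = 650
    L_p: int = 60
    footprint: int = FOOTPRINT
    L_c: int = 10
    stall_start: int = 401
    n_stall: int = 6
    net_stall_rate: float = 0.1

    def __post_init__(self):
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        if self.L_m < self.footprint:
            raise ParameterError(
                f"L_m ({self.L_m}) must be >= footprint ({self.footprint})")
        if self.L_p < 0:
            raise ParameterError(f"L_p must be >= 0, got {self.L_p}")
        if self.footprint < 1:
            raise ParameterError("footprint must be >= 1")
        if self.L_c < 1:
            raise ParameterError("L_c must be >= 1")
        # validates the stall window
        stall_profile(self.L_m, self.stall_start, self.n_stall,
                      self.net_stall_rate, self.k_elong_default)

    @property
    def elongation_rates(self) -> np.ndarray:
        """Per-codon elongation rate vector, index i-1 for codon i."""
        return stall_profile(self.L_m, self.stall_start, self.n_stall,
                             self.net_stall_rate, self.k_elong_default)

    @property
    def stall_mask(self) -> np.ndarray:
        """Boolean vector marking the slow codons (no-hit QC substrate)."""
        mask = np.zeros(self.L_m, dtype=bool)
        if self.n_stall > 0:
            mask[self.stall_start - 1:self.stall_start + self.n_stall - 1] = True
        return mask

    def replace(self, **overrides) -> "ModelParams":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_params(abort_model: str = "tj", cleave_model: str = "none",
                k_a: float = 0.5, k_cleave: float = 0.001,
                **overrides) -> ModelParams:
    """Build a :class:`ModelParams` from an abort/cleave preset pair.

    ``k_a`` is the shared nonzero abortive-termination rate of the SAT /
    CAT / CSAT presets; ``k_cleave`` the shared cleavage rate of SEC /
    CSEC.  Rates not named by a preset are zero.  ``overrides`` are
    applied last and may set any :class:`ModelParams` field.
    """
    abort_model = abort_model.lower()
    cleave_model = cleave_model.lower()
    if abort_model not in ABORT_MODELS:
        raise ParameterError(f"unknown abort model {abort_model!r}; "
                             f"choose from {ABORT_MODELS}")
    if cleave_model not in CLEAVE_MODELS:
        raise ParameterError(f"unknown cleave model {cleave_model!r}; "
                             f"choose from {CLEAVE_MODELS}")
    if abort_model != "tj" and k_a <= 0:
        raise ParameterError(f"preset {abort_model} requires k_a > 0")
    if cleave_model != "none" and k_cleave <= 0:
        raise ParameterError(f"preset {cleave_model} requires k_cleave > 0")

    kw: dict = {}
    if abort_model == "sat":
        kw.update(k_abort_no_hit=k_a, k_abort_back_hit=k_a)
    elif abort_model == "cat":
        kw.update(k_abort_front_hit=k_a, k_abort_both_hit=k_a)
    elif abort_model == "csat":
        kw.update(k_abort_back_hit=k_a, k_abort_both_hit=k_a)
    if cleave_model == "sec":
        kw.update(k_cleave_no_hit=k_cleave, k_cleave_back_hit=k_cleave)
    elif cleave_model == "csec":
        kw.update(k_cleave_back_hit=k_cleave, k_cleave_both_hit=k_cleave)
    kw.update(overrides)
    return ModelParams(**kw)


def translation_only(params: ModelParams) -> ModelParams:
    """Single tracked mRNA, no turnover: transcription and decay off.

    This is the configuration of the abortive-termination sweeps, where
    the mRNA decay rate is set to zero and one initial mRNA is followed.
    """
    return params.replace(k_transcription=0.0, k_deadenylation=0.0)


def params_from_config(path) -> ModelParams:
    """Load parameters from a flat YAML/JSON mapping.

    Keys are ModelParams field names, optionally plus ``abort_model``,
    ``cleave_model``, ``k_a`` and ``k_cleave`` preset selectors.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} must be a flat mapping")
    abort_model = raw.pop("abort_model", "tj")
    cleave_model = raw.pop("cleave_model", "none")
    k_a = raw.pop("k_a", 0.5)
    k_cleave = raw.pop("k_cleave", 0.001)
    unknown = set(raw) - {f.name for f in dataclasses.fields(ModelParams)}
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    return make_params(abort_model, cleave_model, k_a=k_a,
                       k_cleave=k_cleave, **raw)
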