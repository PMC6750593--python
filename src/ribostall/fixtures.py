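"""Synthetic ground-truth data for the analysis modules.

Each generator is deterministic under (seed, parameters) and returns
the generated data together with a truth record, so every analysis
module can be tested round-trip without external downloads:

* :func:`synth_cds_set` -- coding sequences with implanted
  stall-encoding windows at known codon coordinates;
* :func:`synth_te_tables` -- rpkm tables for two gene groups with a
  known mean log2 TE offset, plus optional coverage tracks carrying a
  ribosome-density bump at a known offset into the stall window;
* :func:`synth_barcode_reads` -- paired cDNA/gDNA read sets for a
  barcoded reporter pool with known per-reporter abundance ratios.

The background residue alphabet of the CDS generator excludes every
residue any scanning rule counts (K, R, P, E, D), so qualifying windows
exist exactly where they were implanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode_quant import BARCODE_LEN
from .stall_scan import RULES, WINDOW_CODONS

# codons by residue, standard code; background avoids all rule residues
_CODON = {
    "K": "AAG", "R": "AGA", "P": "CCA", "E": "GAA", "D": "GAT",
    "A": "GCT", "C": "TGT", "F": "TTC", "G": "GGT", "H": "CAC",
    "I": "ATT", "L": "TTG", "M": "ATG", "N": "AAC", "Q": "CAA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAC",
}
_BACKGROUND_AA = sorted(set(_CODON) - set("KRPED"))

#: rule residues placed at window offsets 0..4 and 9, so that only the
#: implanted offset itself contains all six and qualifies
_IMPLANT_OFFSETS = (0, 1, 2, 3, 4, 9)


@dataclass
class FixtureTruth:
    seed: int
    params: dict
    stall_regions: dict = field(default_factory=dict)   # gene -> start codon
    te_offset: float | None = None
    group_of: dict = field(default_factory=dict)        # gene -> group
    ratios: dict = field(default_factory=dict)          # reporter -> ratio
    bump_offset_nt: int | None = None


def synth_cds_set(n_genes: int = 10, length_range=(120, 400),
                  stall_prob: float = 0.5, rule_mix=("kr6of10", "p6of10"),
                  seed: int = 0) -> tuple[pd.DataFrame, FixtureTruth]:
    """CDS set with at most one implanted stall window per gene.

    Returns a DataFrame (gene, seq, status) and the truth mapping each
    stall-carrying gene to its window start codon.  Genes are long
    enough to hold one window; the implant satisfies its rule with
    exactly six matching residues arranged so no shifted window also
    qualifies.
    """
    if not 0 <= stall_prob <= 1:
        raise ValueError("stall_prob must be in [0, 1]")
    lo, hi = length_range
    if lo < WINDOW_CODONS:
        raise ValueError(f"genes must be >= {WINDOW_CODONS} codons")
    rng = np.random.default_rng(seed)
    rows = []
    truth = FixtureTruth(seed=seed, params=dict(
        n_genes=n_genes, length_range=tuple(length_range),
        stall_prob=stall_prob, rule_mix=tuple(rule_mix)))
    for g in range(n_genes):
        gene = f"g{g:04d}"
        n_codons = int(rng.integers(lo, hi + 1))
        aa = list(rng.choice(_BACKGROUND_AA, size=n_codons))
        if rng.random() < stall_prob:
            rule = rule_mix[int(rng.integers(len(rule_mix)))]
            residues = sorted(RULES[rule])
            start = int(rng.integers(1, n_codons - WINDOW_CODONS + 2))
            for off in _IMPLANT_OFFSETS:
                aa[start - 1 + off] = residues[int(rng.integers(len(residues)))]
            truth.stall_regions[gene] = start
        rows.append(dict(gene=gene,
                         seq="".join(_CODON[a] for a in aa),
                         status=""))
    return pd.DataFrame(rows), truth


def synth_te_tables(n_stall: int = 1000, n_free: int = 3500,
                    te_offset: float = 0.23, dispersion: float = 0.5,
                    mean_rpkm: float = 50.0, seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.DataFrame, FixtureTruth]:
    """rpkm tables for two gene groups with a mean log2 TE offset.

    RNA rpkm is log-normal around ``mean_rpkm``; ribo rpkm follows the
    per-gene log2 TE drawn Normal(mu_group, dispersion) with the stall
    group's mean lower by ``te_offset``.  Returns (ribo, rna, truth);
    both tables carry a ``stall`` column for grouping.
    """
    rng = np.random.default_rng(seed)
    genes = [f"s{i:05d}" for i in range(n_stall)] + \
            [f"c{i:05d}" for i in range(n_free)]
    stall = np.array([True] * n_stall + [False] * n_free)
    rna = mean_rpkm * rng.lognormal(0.0, 0.8, size=len(genes))
    mu = np.where(stall, -te_offset, 0.0)
    log2_te = rng.normal(mu, dispersion)
    ribo = rna * 2.0 ** log2_te
    rna_df = pd.DataFrame({"gene": genes, "rpkm": rna, "stall": stall})
    ribo_df = pd.DataFrame({"gene": genes, "rpkm": ribo, "stall": stall})
    truth = FixtureTruth(seed=seed, te_offset=te_offset,
                         params=dict(n_stall=n_stall, n_free=n_free,
                                     dispersion=dispersion,
                                     mean_rpkm=mean_rpkm),
                         group_of=dict(zip(genes, stall)))
    return ribo_df, rna_df, truth


def synth_coverage_tracks(n_genes: int = 50, n_codons: int = 300,
                          stall_start: int = 150, bump_offset_nt: int = 24,
                          bump_amplitude: float = 3.0, base_depth: float = 2.0,
                          bump_sd_nt: float = 3.0, seed: int = 0):
    """Poisson coverage tracks with a Gaussian ribosome-density bump.

    The bump is centered ``bump_offset_nt`` nucleotides into the stall
    window (whose first nucleotide is 3*(stall_start-1)+1); amplitude 0
    gives flat tracks.  Returns (tracks, regions, truth): ``regions``
    is the metagene input table (transcript, start_nt).
    """
    rng = np.random.default_rng(seed)
    start_nt = 3 * (stall_start - 1) + 1
    n_nt = 3 * n_codons
    pos = np.arange(1, n_nt + 1)
    center = start_nt + bump_offset_nt - 1
    shape = 1.0 + bump_amplitude * np.exp(
        -0.5 * ((pos - center) / bump_sd_nt) ** 2)
    tracks = {}
    for g in range(n_genes):
        gene = f"g{g:04d}"
        tracks[gene] = rng.poisson(base_depth * shape)
    regions = pd.DataFrame({"transcript": list(tracks),
                            "start_nt": start_nt})
    truth = FixtureTruth(seed=seed, bump_offset_nt=bump_offset_nt,
                         params=dict(n_genes=n_genes, n_codons=n_codons,
                                     stall_start=stall_start,
                                     bump_amplitude=bump_amplitude,
                                     base_depth=base_depth))
    return tracks, regions, truth


_READ_LEN = 50
_FLANK5 = "ACGTGACATAACTAATTACATGAC"  # constant context 5' of the barcode


def synth_barcode_design(n_reporters: int = 2, n_barcodes: int = 4,
                         seed: int = 0) -> pd.DataFrame:
    """Unique random 8-nt barcodes, ``n_barcodes`` per reporter; all
    reporters share one median-normalization group."""
    rng = np.random.default_rng(seed)
    barcodes = set()
    while len(barcodes) < n_reporters * n_barcodes:
        barcodes.add("".join(rng.choice(list("ACGT"), size=BARCODE_LEN)))
    barcodes = sorted(barcodes)
    rows = []
    for r in range(n_reporters):
        for b in range(n_barcodes):
            rows.append(dict(barcode=barcodes[r * n_barcodes + b],
                             reporter=f"rep{r:02d}", group="pool"))
    return pd.DataFrame(rows)


def synth_barcode_reads(design: pd.DataFrame, ratios: dict[str, float],
                        depth: int = 100_000, seed: int = 0,
                        offset: int = len(_FLANK5)):
    """Paired cDNA/gDNA read sets with known abundance ratios.

    gDNA reads are multinomial-uniform over barcodes; cDNA reads follow
    probabilities proportional to ratio x gDNA share.  Reads are
    ``_READ_LEN`` nt with the barcode at ``offset``.  Returns
    (cdna_reads, gdna_reads, truth).
    """
    rng = np.random.default_rng(seed)
    bcs = list(design["barcode"])
    rep = list(design["reporter"])
    for r in set(rep):
        if r not in ratios:
            raise ValueError(f"no ratio for reporter {r!r}")
        if ratios[r] <= 0:
            raise ValueError("ratios must be > 0")
    g_p = np.full(len(bcs), 1.0 / len(bcs))
    g_counts = rng.multinomial(depth, g_p)
    weights = np.array([ratios[r] for r in rep]) * g_p
    c_counts = rng.multinomial(depth, weights / weights.sum())

    def build(counts):
        reads = []
        for bc, n in zip(bcs, counts):
            stem = _FLANK5[:offset].rjust(offset, "A")
            tail_len = _READ_LEN - offset - BARCODE_LEN
            read = stem + bc + "T" * tail_len
            reads.extend([read] * int(n))
        rng.shuffle(reads)
        return reads

    truth = FixtureTruth(seed=seed, ratios=dict(ratios),
                         params=dict(depth=depth, offset=offset))
    return build(c_counts), build(g_counts), truth


def write_fastq(reads, path):
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i}\n{r}\n+\n{'I' * len(r)}\n")
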