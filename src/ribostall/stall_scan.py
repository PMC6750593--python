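"""Scanning coding sequences for stall-encoding windows.

A stall-encoding sequence is a 10-codon window whose translation
contains at least 6 lysine/arginine residues (polybasic tract) or at
least 6 prolines; acidic windows (>= 6 glutamate/aspartate) serve as
the matched negative control.  Every window offset is scanned (stride
one codon) and overlapping or abutting qualifying windows are collapsed
into maximal stall regions reported by their first window's start
codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

WINDOW_CODONS = 10
MIN_MATCHES = 6

RULES = {
    "kr6of10": frozenset("KR"),
    "p6of10": frozenset("P"),
    "ed6of10": frozenset("ED"),
}
#: the stall definition is the union of the polybasic and polyproline rules
STALL_RULES = ("kr6of10", "p6of10")


class CdsError(ValueError):
    pass


@dataclass(frozen=True)
class StallWindow:
    gene: str
    start: int          # 1-based codon index of the window's first codon
    rule: str
    count: int          # matched residues within the window (>= 6)
    length: int = WINDOW_CODONS


def translate_codons(seq: str, gene: str = "") -> str:
    """Residue string, one letter per codon; ambiguous codons become X."""
    seq = str(seq).upper().replace("U", "T")
    if len(seq) % 3:
        raise CdsError(f"CDS length not a multiple of 3"
                       f"{' for gene ' + gene if gene else ''}")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if set(codon) - set("ACGT"):
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def scan_windows(cds: str, rule: str, gene: str = "") -> list[StallWindow]:
    """All qualifying 10-codon windows of one CDS, in coordinate order."""
    residues = RULES[rule]
    aa = translate_codons(cds, gene)
    hits = np.fromiter((r in residues for r in aa), dtype=np.int64,
                       count=len(aa))
    out = []
    if len(aa) < WINDOW_CODONS:
        return out
    csum = np.concatenate([[0], np.cumsum(hits)])
    counts = csum[WINDOW_CODONS:] - csum[:-WINDOW_CODONS]
    for i in np.flatnonzero(counts >= MIN_MATCHES):
        out.append(StallWindow(gene, int(i) + 1, rule, int(counts[i])))
    return out


def scan_stall_windows(cds: str, gene: str = "") -> list[StallWindow]:
    """Union of the KR and P rules, sorted by start codon."""
    wins = [w for r in STALL_RULES for w in scan_windows(cds, r, gene)]
    return sorted(wins, key=lambda w: (w.start, w.rule))


def collapse_windows(windows: list[StallWindow]) -> list[dict]:
    """Merge overlapping/abutting windows of one gene into regions.

    Returns [{gene, start, end, n_windows}] with ``start`` the first
    window's start codon and ``end`` the last covered codon.
    """
    regions: list[dict] = []
    for w in sorted(windows, key=lambda w: w.start):
        end = w.start + w.length - 1
        if regions and w.start <= regions[-1]["end"] + 1 \
                and w.gene == regions[-1]["gene"]:
            regions[-1]["end"] = max(regions[-1]["end"], end)
            regions[-1]["n_windows"] += 1
        else:
            regions.append(dict(gene=w.gene, start=w.start, end=end,
                                n_windows=1))
    return regions


def annotate_cds_set(records, rule: str = "stall") -> pd.DataFrame:
    """Per-gene stall annotation of a CDS collection.

    ``records`` yields (gene_id, sequence, status) triples; genes whose
    status contains "Dubious" are excluded, duplicated ids raise, and
    CDSs whose length is not a multiple of 3 are reported in the
    ``rejected`` column attribute.  ``rule`` is one of the RULES keys or
    "stall" for the KR|P union.  The result has one row per retained
    gene with ``n_windows``, ``n_regions`` and ``first_start`` (NaN when
    no region).
    """
    seen = set()
    rows = []
    rejected = []
    for gene, seq, status in records:
        if gene in seen:
            raise CdsError(f"duplicate gene id {gene!r}")
        seen.add(gene)
        if status and "dubious" in str(status).lower():
            continue
        try:
            wins = (scan_stall_windows(seq, gene) if rule == "stall"
                    else scan_windows(seq, rule, gene))
        except CdsError:
            rejected.append(gene)
            continue
        regions = collapse_windows(wins)
        rows.append(dict(
            gene=gene, n_codons=len(seq) // 3, n_windows=len(wins),
            n_regions=len(regions),
            first_start=regions[0]["start"] if regions else np.nan,
            region_starts=";".join(str(r["start"]) for r in regions)))
    df = pd.DataFrame(rows, columns=["gene", "n_codons", "n_windows",
                                     "n_regions", "first_start",
                                     "region_starts"])
    df.attrs["rejected"] = rejected
    df.attrs["n_genes_with_region"] = int((df["n_regions"] > 0).sum()) \
        if len(df) else 0
    return df


def median_first_stall(table: pd.DataFrame) -> float:
    """Median start codon of the first stall region over stall-containing
    genes (the control-region boundary for upstream-TE analysis)."""
    starts = table.loc[table["n_regions"] > 0, "first_start"]
    if starts.empty:
        raise CdsError("no stall-containing genes")
    return float(starts.median())


def read_cds_fasta(path):
    """Yield (gene, seq, status) from a CDS FASTA; any 'Dubious' token in
    the header is taken as the gene status."""
    for rec in SeqIO.parse(str(path), "fasta"):
        status = "Dubious" if "dubious" in rec.description.lower() else ""
        yield rec.id, str(rec.seq), status


def windows_to_bed(windows: list[StallWindow]) -> pd.DataFrame:
    """0-based half-open nucleotide coordinates on the CDS."""
    return pd.DataFrame(
        [dict(chrom=w.gene, start=3 * (w.start - 1),
              end=3 * (w.start - 1 + w.length), name=w.rule,
              score=w.count) for w in windows])
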