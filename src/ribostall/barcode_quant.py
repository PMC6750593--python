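"""Pooled-reporter mRNA quantification from 3' UTR barcodes.

Each reporter is tagged with a few unique 8-nt barcodes.  Sequencing
the same amplicon from cDNA and from genomic DNA gives, per barcode, a
cDNA/gDNA count ratio proportional to the reporter's steady-state mRNA
level per gene copy.  Barcodes below a count threshold in either assay
are discarded; per-reporter levels are the mean log2 ratio over
retained barcodes and are median-normalized within each group of 5'
UTR variants sharing a coding-sequence insert.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO

BARCODE_LEN = 8
MIN_COUNT = 100


class DesignError(ValueError):
    pass


def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    required = {"barcode", "reporter", "group"}
    missing = required - set(design.columns)
    if missing:
        raise DesignError(f"design table missing columns {sorted(missing)}")
    if design["barcode"].duplicated().any():
        dups = design.loc[design["barcode"].duplicated(), "barcode"]
        raise DesignError(f"duplicate barcodes in design: {list(dups)}")
    bad = design.loc[design["barcode"].str.len() != BARCODE_LEN, "barcode"]
    if len(bad):
        raise DesignError(f"barcodes must be {BARCODE_LEN} nt: {list(bad)}")
    return design


def count_barcodes(reads, design: pd.DataFrame,
                   offset: int = 0) -> tuple[pd.Series, int]:
    """Exact-match barcode counts at a fixed in-read offset.

    ``reads`` is an iterable of read sequences (strings).  Returns a
    Series indexed by barcode (every design barcode present, zeros
    included) and the number of unmatched reads.  No error correction:
    a single mismatch leaves a read unmatched.
    """
    design = _check_design(design)
    counts = {b: 0 for b in design["barcode"]}
    unmatched = 0
    end = offset + BARCODE_LEN
    for read in reads:
        bc = str(read)[offset:end]
        if bc in counts:
            counts[bc] += 1
        else:
            unmatched += 1
    return pd.Series(counts, name="count"), unmatched


def reads_from_fastq(path):
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq)


def mrna_levels(cdna_counts: pd.Series, gdna_counts: pd.Series,
                design: pd.DataFrame,
                min_count: int = MIN_COUNT) -> pd.DataFrame:
    """Median-normalized per-reporter mRNA levels (log2 cDNA/gDNA).

    Per barcode passing ``min_count`` in BOTH assays the level is
    log2(cDNA/gDNA); per reporter the mean and standard error over its
    retained barcodes (SE defined for >= 2 barcodes); the group median
    of reporter means is then subtracted within each ``group`` (the 5'
    UTR variant set of one insert).  Reporters with zero retained
    barcodes appear with n_barcodes == 0 and NaN levels rather than
    silently as zero.
    """
    design = _check_design(design)
    per_bc = design.copy()
    per_bc["cdna"] = per_bc["barcode"].map(cdna_counts).fillna(0).astype(int)
    per_bc["gdna"] = per_bc["barcode"].map(gdna_counts).fillna(0).astype(int)
    per_bc["retained"] = ((per_bc["cdna"] >= min_count)
                          & (per_bc["gdna"] >= min_count))
    kept = per_bc[per_bc["retained"]].copy()
    kept["log2_ratio"] = np.log2(kept["cdna"] / kept["gdna"])

    rows = []
    for (reporter, group), sub in per_bc.groupby(["reporter", "group"],
                                                 sort=False):
        vals = kept.loc[kept["reporter"] == reporter, "log2_ratio"]
        n = len(vals)
        rows.append(dict(
            reporter=reporter, group=group, n_barcodes=n,
            level=vals.mean() if n else np.nan,
            se=vals.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan))
    levels = pd.DataFrame(rows)
    med = levels.groupby("group")["level"].transform("median")
    levels["level_norm"] = levels["level"] - med
    levels["level_norm_linear"] = 2.0 ** levels["level_norm"]
    return levels
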