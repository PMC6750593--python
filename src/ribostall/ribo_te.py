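"""Ribosome-profiling summaries: P-site coverage, metagene density
around stall windows, and translation efficiency (TE).

TE -- the ratio of ribosome-footprint rpkm to RNA-seq rpkm -- proxies
the initiation rate of an mRNA.  The analyses here compare TE between
stall-containing and stall-free gene groups, optionally restricted to
the mRNA region 5' of the (first) stall so that ribosome loss past the
stall cannot depress the footprint signal, with control genes truncated
at the median stall location of the stall-containing group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: footprint reads report the decoded codon at their 13th nucleotide
PSITE_OFFSET = 12

MIN_RPKM = 5.0
MIN_REGION_READS = 100
CONTROL_BOUNDARY_CODONS = 215
WINDOW_NORM_LEN = 150


def psite_coverage(alignments: pd.DataFrame,
                   transcript_lengths: dict[str, int]
                   ) -> tuple[dict[str, np.ndarray], int]:
    """Per-nucleotide P-site coverage tracks from 5'-aligned reads.

    ``alignments`` needs columns transcript, pos (1-based 5' end) and
    optionally length; each read adds one count at pos + 12.  Reads
    whose assigned position falls outside the transcript are dropped
    and tallied in the returned drop count.
    """
    tracks = {t: np.zeros(int(n), dtype=np.int64)
              for t, n in transcript_lengths.items()}
    dropped = 0
    for t, pos in zip(alignments["transcript"], alignments["pos"]):
        track = tracks.get(t)
        p = int(pos) + PSITE_OFFSET
        if track is None or not (1 <= p <= track.size):
            dropped += 1
            continue
        track[p - 1] += 1
    return tracks, dropped


def metagene_profile(tracks: dict[str, np.ndarray],
                     regions: pd.DataFrame, flank: int = 60,
                     window_norm_len: int = WINDOW_NORM_LEN) -> pd.DataFrame:
    """Mean within-window-normalized coverage around region starts.

    ``regions`` has columns transcript and start_nt (1-based first
    nucleotide of the stall window).  Each window spans
    ``window_norm_len`` nucleotides beginning ``flank`` nt upstream of
    the region start; its coverage is divided by its own mean, then
    averaged position-wise across windows.  The offset axis puts the
    window's first nucleotide at +1.  Windows not fully inside their
    transcript, or with zero mean coverage, are excluded.
    """
    if window_norm_len <= flank:
        raise ValueError("window_norm_len must exceed flank")
    profiles = []
    for t, start in zip(regions["transcript"], regions["start_nt"]):
        track = tracks.get(t)
        if track is None:
            continue
        lo = int(start) - flank          # 1-based first nt of the span
        hi = lo + window_norm_len - 1
        if lo < 1 or hi > track.size:
            continue
        win = track[lo - 1:hi].astype(float)
        mu = win.mean()
        if mu == 0:
            continue
        profiles.append(win / mu)
    if not profiles:
        raise ValueError("no usable windows for metagene profile")
    mat = np.vstack(profiles)
    offsets = np.arange(-flank + 1, window_norm_len - flank + 1)
    return pd.DataFrame({"offset": offsets,
                         "mean_density": mat.mean(axis=0),
                         "n_windows": mat.shape[0]})


def compute_te(ribo_rpkm: pd.DataFrame, rna_rpkm: pd.DataFrame,
               min_rpkm: float = MIN_RPKM) -> pd.DataFrame:
    """TE = ribo rpkm / rna rpkm for genes >= min_rpkm in both samples.

    Inputs are two-column tables (gene, rpkm); rpkm values supplied by
    the source are used verbatim.
    """
    ribo = ribo_rpkm.rename(columns={ribo_rpkm.columns[1]: "ribo"})
    rna = rna_rpkm.rename(columns={rna_rpkm.columns[1]: "rna"})
    df = ribo.merge(rna, on=ribo.columns[0])
    df = df[(df["ribo"] >= min_rpkm) & (df["rna"] >= min_rpkm)].copy()
    df["te"] = df["ribo"] / df["rna"]
    df["log2_te"] = np.log2(df["te"])
    return df.reset_index(drop=True)


def te_upstream(tracks_ribo: dict[str, np.ndarray],
                tracks_rna: dict[str, np.ndarray],
                boundaries: dict[str, int],
                min_reads: int = MIN_REGION_READS,
                control_boundary: int = CONTROL_BOUNDARY_CODONS
                ) -> pd.DataFrame:
    """TE restricted to the region 5' of each gene's stall.

    ``boundaries`` maps stall-containing genes to the start codon of
    their first stall region; genes absent from it are controls and are
    truncated at ``control_boundary`` codons (the median stall location
    of stall-containing mRNAs).  The region is CDS nucleotides
    1 .. 3*(boundary-1); genes with fewer than ``min_reads`` reads in
    the region of either assay are excluded.
    """
    rows = []
    for gene, ribo in tracks_ribo.items():
        rna = tracks_rna.get(gene)
        if rna is None:
            continue
        stall = gene in boundaries
        boundary = boundaries[gene] if stall else control_boundary
        if boundary <= 1:
            continue  # no upstream region to measure
        n_nt = 3 * (int(boundary) - 1)
        n_nt = min(n_nt, ribo.size, rna.size)
        r_sum = int(ribo[:n_nt].sum())
        m_sum = int(rna[:n_nt].sum())
        if r_sum < min_reads or m_sum < min_reads:
            continue
        rows.append(dict(gene=gene, ribo=r_sum, rna=m_sum,
                         te=r_sum / m_sum, log2_te=np.log2(r_sum / m_sum),
                         stall=stall, boundary=int(boundary)))
    return pd.DataFrame(rows, columns=["gene", "ribo", "rna", "te",
                                       "log2_te", "stall", "boundary"])


def compare_te_groups(te: pd.DataFrame, stall_col: str = "stall",
                      use_median: bool = False) -> tuple[float, float]:
    """Delta log2 TE between stall-free and stall-containing genes.

    Returns (delta, p) where delta = mean log2 TE(no stall) - mean
    log2 TE(stall) (medians instead when ``use_median``) and p is the
    two-sided Wilcoxon rank-sum p-value.  A positive delta means
    stall-containing genes are translated less efficiently.
    """
    g_stall = te.loc[te[stall_col].astype(bool), "log2_te"].to_numpy()
    g_free = te.loc[~te[stall_col].astype(bool), "log2_te"].to_numpy()
    if g_stall.size == 0 or g_free.size == 0:
        raise ValueError("both gene groups must be nonempty")
    agg = np.median if use_median else np.mean
    delta = float(agg(g_free) - agg(g_stall))
    p = float(stats.ranksums(g_free, g_stall).pvalue)
    return delta, p


def read_rpkm_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       names=["gene", "rpkm"], header=0)


def read_alignment_table(path) -> pd.DataFrame:
    """transcript / pos / length TSV of 5'-aligned reads."""
    return pd.read_csv(path, sep="\t", comment="#")
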