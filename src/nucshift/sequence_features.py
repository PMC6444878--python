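"""Sequence composition around nucleosome dyads and summits.

Nucleosomal DNA favors two anti-phased dinucleotide classes: the flexible
W|W class {AA, AT, TA, TT} and the stiff S class {GC, CG} (optionally the
full {GG, GC, CG, CC}). Profiles report, per strand-oriented offset from the
dyad, the fraction of sites whose dinucleotide at that offset belongs to the
class. Positional k-mer matrices count k-mer starts in fixed windows around
summits, row-normalized and z-scored to show positional bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel

__all__ = [
    "CompositionProfile",
    "KmerPositionMatrix",
    "WW_SET",
    "SS_SET",
    "SS_SET_FULL",
    "revcomp",
    "dinucleotide_profile",
    "kmer_positional_counts",
    "annotate_genic",
]

WW_SET = frozenset({"AA", "AT", "TA", "TT"})
SS_SET = frozenset({"GC", "CG"})
SS_SET_FULL = frozenset({"GG", "GC", "CG", "CC"})

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(slots=True)
class CompositionProfile:
    offsets: np.ndarray
    ww_freq: np.ndarray
    ss_freq: np.ndarray
    n_sites: int
    n_dropped: int = 0


@dataclass(slots=True)
class KmerPositionMatrix:
    k: int
    window: int
    flank: int
    bin_left_edges: np.ndarray
    counts: pd.DataFrame  # rows: k-mers, columns: bin left edges
    zscores: pd.DataFrame  # per-k-mer frequency z-scored across bins


def _oriented_window(seq: str, center: int, strand: str, flank: int, extra: int) -> str | None:
    """Sequence of oriented offsets -flank .. +flank+extra-1 around center.

    For - strand sites the window is reverse-complemented so that increasing
    offsets run downstream in site orientation. Returns None when the window
    leaves the chromosome.
    """
    lo = center - flank - (extra - 1 if strand == "-" else 0)
    hi = center + flank + (extra if strand == "+" else 1)
    if lo < 0 or hi > len(seq):
        return None
    window = seq[lo:hi]
    return revcomp(window) if strand == "-" else window


def dinucleotide_profile(
    genome: Mapping[str, str],
    sites: Sequence[tuple[str, int, str]],
    flank: int = 250,
    ss_set: frozenset[str] | set[str] = SS_SET,
    ww_set: frozenset[str] | set[str] = WW_SET,
) -> CompositionProfile:
    """Per-offset W|W and S dinucleotide frequencies around dyads.

    ``sites`` are (chrom, dyad position, strand). At oriented offset o the
    dinucleotide starts at dyad+o; sites with ambiguity codes at an offset
    are excluded from that offset's denominator. Sites whose window leaves
    the chromosome are dropped entirely and counted.
    """
    if not sites:
        raise ValueError("empty site set")
    offsets = np.arange(-flank, flank + 1)
    ww_hits = np.zeros(offsets.size, dtype=np.int64)
    ss_hits = np.zeros(offsets.size, dtype=np.int64)
    valid = np.zeros(offsets.size, dtype=np.int64)
    used = 0
    dropped = 0
    for chrom, pos, strand in sites:
        seq = genome.get(chrom)
        if seq is None:
            dropped += 1
            continue
        window = _oriented_window(seq, pos, strand, flank, extra=2)
        if window is None:
            dropped += 1
            continue
        used += 1
        for i in range(offsets.size):
            dinuc = window[i : i + 2]
            if any(b not in "ACGT" for b in dinuc):
                continue
            valid[i] += 1
            if dinuc in ww_set:
                ww_hits[i] += 1
            elif dinuc in ss_set:
                ss_hits[i] += 1
    if used == 0:
        raise ValueError("no usable sites (all windows truncated)")
    with np.errstate(invalid="ignore"):
        ww = np.where(valid > 0, ww_hits / np.maximum(valid, 1), np.nan)
        ss = np.where(valid > 0, ss_hits / np.maximum(valid, 1), np.nan)
    return CompositionProfile(offsets, ww, ss, n_sites=used, n_dropped=dropped)


def kmer_positional_counts(
    genome: Mapping[str, str],
    summits: Sequence[tuple[str, int, str]],
    k: int = 6,
    window: int = 10,
    flank: int = 130,
) -> KmerPositionMatrix:
    """Count k-mer starts per window bin around summits, strand-oriented.

    Bins of ``window`` bp tile [-flank, +flank); a k-mer belongs to the bin
    of its start offset. k-mers containing non-ACGT characters are skipped.
    Rows are normalized to frequencies then z-scored across bins.
    """
    if flank % window != 0:
        raise ValueError("flank must be a multiple of window")
    edges = np.arange(-flank, flank, window)
    n_bins = edges.size
    counts: dict[str, np.ndarray] = {}
    for chrom, pos, strand in summits:
        seq = genome.get(chrom)
        if seq is None:
            continue
        win = _oriented_window(seq, pos, strand, flank, extra=k)
        if win is None:
            continue
        for i in range(2 * flank):
            kmer = win[i : i + k]
            if len(kmer) < k or any(b not in "ACGT" for b in kmer):
                continue
            b = i // window
            if b >= n_bins:
                break
            if kmer not in counts:
                counts[kmer] = np.zeros(n_bins, dtype=np.int64)
            counts[kmer][b] += 1
    kmers = sorted(counts)
    mat = pd.DataFrame(
        np.vstack([counts[m] for m in kmers]) if kmers else np.zeros((0, n_bins), dtype=np.int64),
        index=kmers,
        columns=edges,
    )
    if kmers:
        freq = mat.div(mat.sum(axis=1).replace(0, 1), axis=0)
        sd = freq.std(axis=1, ddof=0).replace(0, 1)
        z = freq.sub(freq.mean(axis=1), axis=0).div(sd, axis=0)
    else:
        z = mat.astype(float)
    return KmerPositionMatrix(k, window, flank, edges, mat, z)


def annotate_genic(
    positions: Sequence[tuple[str, int]],
    genes: Sequence[GeneModel],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 100,
) -> list[str]:
    """Label positions as promoter, gene body, or intergenic.

    The promoter covers [TSS - upstream, TSS + downstream] in gene
    orientation (inclusive); the gene body is the rest of the TSS-TES span.
    Promoter wins on overlap.
    """
    promoters: dict[str, list[tuple[int, int]]] = {}
    bodies: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.strand == "+":
            p = (g.tss - promoter_upstream, g.tss + promoter_downstream)
        else:
            p = (g.tss - promoter_downstream, g.tss + promoter_upstream)
        promoters.setdefault(g.chrom, []).append(p)
        bodies.setdefault(g.chrom, []).append((min(g.tss, g.tes), max(g.tss, g.tes)))
    labels = []
    for chrom, pos in positions:
        if any(lo <= pos <= hi for lo, hi in promoters.get(chrom, [])):
            labels.append("promoter")
        elif any(lo <= pos <= hi for lo, hi in bodies.get(chrom, [])):
            labels.append("gene body")
        else:
            labels.append("intergenic")
    return labels
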