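"""Cross-condition nucleosome matching, +1/-1 role assignment, shift
classification, and phasing/spacing statistics.

Two nucleosome calls from different conditions are considered the same
nucleosome ("overlapping") when their fixed 147-bp footprints intersect,
i.e. the summits are at most 146 bp apart. The *variance* of a matched pair
is the absolute summit-to-summit distance; region variance averages these
over all pairs in a region. Shifts are oriented by the gene strand
(positive = downstream) and stratified into the bins
0, 1-9, 10-50, 51-100, 101-150, 151-200 bp; larger shifts are excluded and
counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io_formats import GeneModel
from .nucleosome_calls import NucleosomeCall
from .occupancy import Profile1D

__all__ = [
    "NucleosomePair",
    "ShiftLabel",
    "RegionVariance",
    "PhasingReport",
    "SHIFT_BINS",
    "OVERLAP_MAX",
    "SECONDARY_MAX",
    "assign_flanking_nucleosomes",
    "pair_nucleosomes",
    "region_variance",
    "classify_shift",
    "shift_bin",
    "gene_shift_table",
    "spacing_distances",
    "phasing_metrics",
    "uniformness",
]

OVERLAP_MAX = 146  # footprints intersect iff |summit_B - summit_A| <= 146
SECONDARY_MAX = 200  # nearest-summit fallback cap for role-slot matches
SHIFT_BINS = ("0", "1-9", "10-50", "51-100", "101-150", "151-200")
_BIN_EDGES = ((0, 0), (1, 9), (10, 50), (51, 100), (101, 150), (151, 200))


@dataclass(slots=True)
class NucleosomePair:
    call_a: NucleosomeCall
    call_b: NucleosomeCall

    @property
    def shift_genomic(self) -> int:
        return self.call_b.summit - self.call_a.summit

    def shift_oriented(self, strand: str) -> int:
        return self.shift_genomic if strand == "+" else -self.shift_genomic


@dataclass(frozen=True, slots=True)
class ShiftLabel:
    bin: str  # one of SHIFT_BINS or "excluded"
    direction: str  # upstream | downstream | none


@dataclass(frozen=True, slots=True)
class RegionVariance:
    region: str
    mean_pair_distance: float
    n_pairs: int


@dataclass(slots=True)
class PhasingReport:
    profile: Profile1D
    ndr_depth: float | None
    plus1_offset: int | None
    plus1_prominence: float | None
    peak_offsets: list[int]
    estimated_period: float | None
    decay_monotone: bool
    canonical: bool


def assign_flanking_nucleosomes(
    calls: Sequence[NucleosomeCall],
    genes: Sequence[GeneModel],
    window: int = 1000,
) -> dict[str, tuple[NucleosomeCall | None, NucleosomeCall | None]]:
    """Per gene, the -1 and +1 nucleosome calls relative to the TSS.

    +1 is the call with the smallest gene-oriented downstream distance from
    the TSS (summit at or downstream of the TSS); -1 the smallest strictly
    upstream distance. Either slot is None when no call lies within
    ``window`` bp.
    """
    by_chrom: dict[str, np.ndarray] = {}
    calls_by_chrom: dict[str, list[NucleosomeCall]] = {}
    for c in calls:
        calls_by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cs in calls_by_chrom.items():
        cs.sort(key=lambda c: c.summit)
        by_chrom[chrom] = np.array([c.summit for c in cs], dtype=np.int64)

    out: dict[str, tuple[NucleosomeCall | None, NucleosomeCall | None]] = {}
    for gene in genes:
        summits = by_chrom.get(gene.chrom)
        if summits is None or summits.size == 0:
            out[gene.gene_id] = (None, None)
            continue
        cs = calls_by_chrom[gene.chrom]
        d = (summits - gene.tss) * gene.orient  # oriented distance, >0 downstream
        down = np.flatnonzero((d >= 0) & (d <= window))
        up = np.flatnonzero((d < 0) & (d >= -window))
        plus1 = cs[int(down[np.argmin(d[down])])] if down.size else None
        minus1 = cs[int(up[np.argmax(d[up])])] if up.size else None
        out[gene.gene_id] = (minus1, plus1)
    return out


def pair_nucleosomes(
    calls_a: Sequence[NucleosomeCall],
    calls_b: Sequence[NucleosomeCall],
    max_distance: int = OVERLAP_MAX,
) -> tuple[list[NucleosomePair], list[NucleosomeCall], list[NucleosomeCall]]:
    """One-to-one matching of footprint-overlapping calls across conditions.

    Candidate pairs (footprints overlap by >= 1 bp, i.e. summit distance
    <= ``max_distance``) are accepted greedily by ascending |shift|, ties
    broken by leftmost A summit then leftmost B summit, each call in at most
    one pair. Returns (pairs, unpaired A calls, unpaired B calls).
    """
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, c in enumerate(calls_b):
        b_by_chrom.setdefault(c.chrom, []).append((c.summit, j))
    for v in b_by_chrom.values():
        v.sort()

    candidates: list[tuple[int, int, int, int, int]] = []
    for i, ca in enumerate(calls_a):
        blist = b_by_chrom.get(ca.chrom, [])
        summits = [s for s, _ in blist]
        lo = np.searchsorted(summits, ca.summit - max_distance, side="left")
        hi = np.searchsorted(summits, ca.summit + max_distance, side="right")
        for s, j in blist[lo:hi]:
            candidates.append((abs(s - ca.summit), ca.summit, s, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[NucleosomePair] = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(NucleosomePair(calls_a[i], calls_b[j]))
    unpaired_a = [c for i, c in enumerate(calls_a) if i not in used_a]
    unpaired_b = [c for j, c in enumerate(calls_b) if j not in used_b]
    return pairs, unpaired_a, unpaired_b


def region_variance(pairs: Sequence[NucleosomePair], region: str = "") -> RegionVariance | None:
    """Mean absolute summit distance over pairs; None when no pairs."""
    if not pairs:
        return None
    distances = [abs(p.shift_genomic) for p in pairs]
    return RegionVariance(region, float(np.mean(distances)), len(pairs))


def shift_bin(distance: int) -> str:
    """Bin |oriented shift| into 0, 1-9, 10-50, 51-100, 101-150, 151-200."""
    d = abs(int(distance))
    for name, (lo, hi) in zip(SHIFT_BINS, _BIN_EDGES):
        if lo <= d <= hi:
            return name
    return "excluded"


def classify_shift(shift_oriented: int) -> ShiftLabel:
    """Label a gene-oriented shift by bin and direction.

    direction is downstream for positive oriented shifts, upstream for
    negative, none for 0; |shift| > 200 bp is excluded.
    """
    b = shift_bin(shift_oriented)
    if b == "excluded":
        direction = "none"
    elif shift_oriented > 0:
        direction = "downstream"
    elif shift_oriented < 0:
        direction = "upstream"
    else:
        direction = "none"
    return ShiftLabel(b, direction)


def gene_shift_table(
    calls_a: Sequence[NucleosomeCall],
    calls_b: Sequence[NucleosomeCall],
    genes: Sequence[GeneModel],
    window: int = 1000,
) -> pd.DataFrame:
    """Per-gene +1/-1 shift classification between two conditions.

    Roles are assigned on the control (A) calls; each role call is matched to
    its footprint-overlapping partner from the one-to-one pairing, with a
    nearest-summit fallback within 200 bp for shifts beyond single-footprint
    overlap. Columns: gene, role, strand, summit_a, summit_b, shift_genomic,
    shift_oriented, bin, direction.
    """
    pairs, _, _ = pair_nucleosomes(calls_a, calls_b)
    pair_by_a: dict[tuple[str, int], NucleosomePair] = {
        (p.call_a.chrom, p.call_a.summit): p for p in pairs
    }
    # occupancy of the A partner per B call: a B call whose mass is already
    # explained by a matched A call of similar occupancy is not a fallback
    # candidate, while a merged (two-nucleosome) B call carries surplus mass
    partner_occ: dict[tuple[str, int], float] = {
        (p.call_b.chrom, p.call_b.summit): p.call_a.occupancy for p in pairs
    }
    all_b: dict[str, list[tuple[int, float]]] = {}
    for c in calls_b:
        all_b.setdefault(c.chrom, []).append((c.summit, c.occupancy))
    for v in all_b.values():
        v.sort()

    roles = assign_flanking_nucleosomes(calls_a, genes, window=window)
    rows = []
    for gene in genes:
        minus1, plus1 = roles[gene.gene_id]
        for role, call in ((-1, minus1), (1, plus1)):
            if call is None:
                continue
            partner_summit: int | None = None
            pair = pair_by_a.get((call.chrom, call.summit))
            if pair is not None:
                partner_summit = pair.call_b.summit
            else:
                # secondary match within 200 bp for this gene's role slot:
                # footprint overlap fails for 147-200 bp shifts, and a merged
                # call may already be paired to the neighboring role. Eligible
                # candidates must carry unexplained occupancy (surplus over
                # their matched A partner) comparable to the query call.
                best: tuple[int, int] | None = None
                for summit, b_occ in all_b.get(call.chrom, []):
                    dist = abs(summit - call.summit)
                    if dist > SECONDARY_MAX:
                        continue
                    surplus = b_occ - partner_occ.get((call.chrom, summit), 0.0)
                    if surplus < 0.3 * call.occupancy:
                        continue
                    if best is None or dist < best[0]:
                        best = (dist, summit)
                if best is not None:
                    partner_summit = best[1]
            if partner_summit is None:
                continue
            shift_genomic = partner_summit - call.summit
            shift_oriented = shift_genomic * gene.orient
            label = classify_shift(shift_oriented)
            rows.append(
                {
                    "gene": gene.gene_id,
                    "chrom": gene.chrom,
                    "role": role,
                    "strand": gene.strand,
                    "summit_a": call.summit,
                    "summit_b": partner_summit,
                    "shift_genomic": shift_genomic,
                    "shift_oriented": shift_oriented,
                    "bin": label.bin,
                    "direction": label.direction,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "role", "strand", "summit_a", "summit_b",
            "shift_genomic", "shift_oriented", "bin", "direction",
        ],
    )


def spacing_distances(calls: Sequence[NucleosomeCall]) -> np.ndarray:
    """Adjacent summit-to-summit distances along each chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c.summit)
    dists: list[int] = []
    for summits in by_chrom.values():
        summits.sort()
        dists.extend(int(b - a) for a, b in zip(summits, summits[1:]))
    return np.asarray(dists, dtype=np.int64)


def spacing_density(distances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(values, density) of the adjacent-distance multiset; density sums to 1."""
    if distances.size == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=float)
    values, counts = np.unique(distances, return_counts=True)
    return values, counts / counts.sum()


def uniformness(distances: np.ndarray) -> dict[str, float] | None:
    """Spacing uniformity summary: mode and IQR of adjacent distances.

    Mode from the 1-bp histogram (smallest value on ties); IQR with the
    linear-interpolation (type-7) quartile convention. A narrower IQR means
    more uniform spacing.
    """
    if distances.size == 0:
        return None
    values, counts = np.unique(distances, return_counts=True)
    mode = float(values[np.argmax(counts)])  # np.unique sorts: ties -> smallest
    q1, q3 = np.percentile(distances, [25, 75])  # linear interpolation = type 7
    return {"mode": mode, "iqr": float(q3 - q1), "n": int(distances.size)}


def phasing_metrics(
    profile: Profile1D,
    expected_spacing_range: tuple[int, int] = (140, 240),
    peak_fraction: float = 0.2,
    ndr_threshold: float = 0.5,
    decay_tolerance: float = 0.05,
) -> PhasingReport:
    """Classify a TSS-oriented profile as canonically phased or not.

    Peaks are local maxima above ``peak_fraction`` of the profile maximum,
    separated by at least the lower bound of the expected spacing. Canonical
    phasing requires a nucleosome-depleted region (profile minimum in
    [-250, +50] below ``ndr_threshold`` of the +1 peak), a +1 peak downstream
    of the TSS, and non-increasing downstream peak amplitudes (within
    ``decay_tolerance`` relative slack). The period estimate is the mean
    successive distance between downstream peaks.
    """
    y = profile.mean_density
    offsets = profile.offsets
    if y.size == 0 or np.all(y == y[0]):
        return PhasingReport(profile, None, None, None, [], None, False, False)
    height = peak_fraction * float(np.max(y))
    min_sep = max(1, int(expected_spacing_range[0]))
    idx, _ = find_peaks(y, height=height, distance=min_sep)
    peak_offsets = [int(offsets[i]) for i in idx]
    downstream = [(o, float(y[np.searchsorted(offsets, o)])) for o in peak_offsets if o > 0]
    if not downstream:
        return PhasingReport(profile, None, None, None, peak_offsets, None, False, False)
    plus1_offset, plus1_height = downstream[0]

    ndr_mask = (offsets >= -250) & (offsets <= 50)
    ndr_min = float(np.min(y[ndr_mask])) if ndr_mask.any() else float(np.min(y))
    ndr_depth = ndr_min / plus1_height if plus1_height > 0 else None

    heights = [h for _, h in downstream]
    decay_monotone = all(
        later <= earlier * (1.0 + decay_tolerance)
        for earlier, later in zip(heights, heights[1:])
    )
    period = (
        float(np.mean(np.diff([o for o, _ in downstream])))
        if len(downstream) >= 2
        else None
    )
    canonical = (
        ndr_depth is not None
        and ndr_depth < ndr_threshold
        and decay_monotone
        and len(downstream) >= 2
    )
    prominence = plus1_height / float(np.mean(y)) if float(np.mean(y)) > 0 else None
    return PhasingReport(
        profile=profile,
        ndr_depth=ndr_depth,
        plus1_offset=plus1_offset,
        plus1_prominence=prominence,
        peak_offsets=peak_offsets,
        estimated_period=period,
        decay_monotone=decay_monotone,
        canonical=canonical,
    )
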