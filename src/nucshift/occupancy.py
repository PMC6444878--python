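"""Per-base occupancy signal, average profiles, heatmaps and 2D length matrices.

The substrate for everything downstream is a per-base track built from
fragment dyads (or footprint coverage), optionally depth-normalized to RPBM
(reads per base per million mapped reads: raw * 1e6 / total_count) and
smoothed with a unit-mass kernel. Profiles around anchors are strand-aware:
windows of minus-strand anchors are mirrored so that positive offsets always
point downstream in gene orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import convolve1d, gaussian_filter1d

from .io_formats import Anchor, Fragment, FragmentSet

__all__ = [
    "OccupancyTrack",
    "TrackSet",
    "Profile1D",
    "Occupancy2D",
    "dyad_density",
    "rpbm_normalize",
    "smooth_track",
    "profile_1d",
    "anchor_heatmap",
    "occupancy_2d",
    "fragment_length_density",
]


@dataclass(slots=True)
class OccupancyTrack:
    """Per-base signal on one chromosome starting at ``origin``."""

    chrom: str
    origin: int
    values: np.ndarray
    units: str = "raw"  # raw | RPBM
    mode: str = "dyad"  # dyad | coverage
    smoothing: float | None = None  # bandwidth in bp, None = unsmoothed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def value_at(self, position: int) -> float:
        i = position - self.origin
        if 0 <= i < self.values.size:
            return float(self.values[i])
        return 0.0


TrackSet = dict[str, OccupancyTrack]


@dataclass(slots=True)
class Profile1D:
    """Strand-oriented mean density on a fixed offset grid around anchors."""

    offsets: np.ndarray
    mean_density: np.ndarray
    n_anchors: int
    units: str = "raw"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.mean_density = np.asarray(self.mean_density, dtype=float)
        if self.offsets.size != self.mean_density.size:
            raise ValueError("offsets and mean_density must have equal length")


@dataclass(slots=True)
class Occupancy2D:
    """Mean dyad density per (fragment-length bin, strand-oriented offset)."""

    offsets: np.ndarray
    length_bins: np.ndarray  # left edges; bin i covers [edge_i, edge_i + bin width)
    length_bin_width: int
    matrix: np.ndarray  # shape (n_length_bins, n_offsets)
    marginal_profile: np.ndarray
    n_anchors: int


def _chrom_sizes(frags: FragmentSet) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for f in frags:
        sizes[f.chrom] = max(sizes.get(f.chrom, 0), f.end)
    return sizes


def dyad_density(
    frags: FragmentSet,
    mode: str = "dyad",
    chrom_sizes: Mapping[str, int] | None = None,
) -> TrackSet:
    """Build raw per-base tracks from fragments.

    ``dyad`` mode adds 1 at each fragment's dyad; ``coverage`` adds 1 over the
    whole footprint [start, end). The genome-wide integral is therefore the
    fragment count (dyad) or the summed fragment length (coverage).
    """
    if mode not in ("dyad", "coverage"):
        raise ValueError(f"unknown mode: {mode}")
    sizes = dict(chrom_sizes) if chrom_sizes else _chrom_sizes(frags)
    arrays = {c: np.zeros(n, dtype=float) for c, n in sizes.items()}
    for f in frags:
        arr = arrays[f.chrom]
        if mode == "dyad":
            arr[f.dyad] += 1.0
        else:
            arr[f.start : f.end] += 1.0
    return {
        c: OccupancyTrack(chrom=c, origin=0, values=v, units="raw", mode=mode)
        for c, v in arrays.items()
    }


def rpbm_normalize(track: OccupancyTrack | TrackSet, total_count: int):
    """Scale raw counts to RPBM: value * 1e6 / total mapped fragments."""
    if total_count <= 0:
        raise ValueError("total_count must be positive for RPBM normalization")
    if isinstance(track, dict):
        return {c: rpbm_normalize(t, total_count) for c, t in track.items()}
    return replace(track, values=track.values * (1e6 / total_count), units="RPBM")


def smooth_track(
    track: OccupancyTrack | TrackSet,
    bandwidth: float,
    kernel: str = "gaussian",
):
    """Convolve with a unit-mass kernel (reflected edges); bandwidth 0 = identity.

    For the gaussian kernel the bandwidth is sigma; for the triangular kernel
    it is the half-width of the support.
    """
    if bandwidth < 0:
        raise ValueError("bandwidth must be non-negative")
    if isinstance(track, dict):
        return {c: smooth_track(t, bandwidth, kernel) for c, t in track.items()}
    if bandwidth == 0:
        return replace(track, smoothing=None)
    if kernel == "gaussian":
        smoothed = gaussian_filter1d(track.values, sigma=bandwidth, mode="reflect")
    elif kernel == "triangular":
        half = int(round(bandwidth))
        taps = np.arange(-half, half + 1, dtype=float)
        weights = 1.0 - np.abs(taps) / (half + 1)
        weights /= weights.sum()
        smoothed = convolve1d(track.values, weights, mode="reflect")
    else:
        raise ValueError(f"unknown kernel: {kernel}")
    return replace(track, values=smoothed, smoothing=float(bandwidth))


def _anchor_window(
    tracks: TrackSet, anchor: Anchor, flank: int
) -> np.ndarray | None:
    """Strand-oriented window of track values; None when truncated/absent."""
    track = tracks.get(anchor.chrom)
    if track is None:
        return None
    lo = anchor.position - flank - track.origin
    hi = anchor.position + flank + 1 - track.origin
    if lo < 0 or hi > track.values.size:
        return None
    window = track.values[lo:hi]
    return window[::-1] if anchor.strand == "-" else window


def profile_1d(
    tracks: TrackSet,
    anchors: Sequence[Anchor],
    flank: int = 1000,
) -> Profile1D:
    """Mean strand-oriented density on offsets -flank..+flank around anchors.

    Anchors whose window leaves the chromosome are dropped (and counted in
    ``n_dropped``) rather than zero-padded, which would bias edge means.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not anchors:
        raise ValueError("no anchors given")
    offsets = np.arange(-flank, flank + 1)
    total = np.zeros(offsets.size, dtype=float)
    used = 0
    dropped = 0
    units = next(iter(tracks.values())).units if tracks else "raw"
    for a in anchors:
        window = _anchor_window(tracks, a, flank)
        if window is None:
            dropped += 1
            continue
        total += window
        used += 1
    if used == 0:
        raise ValueError("no usable anchors (all windows truncated or off-track)")
    return Profile1D(offsets, total / used, n_anchors=used, units=units, n_dropped=dropped)


def anchor_heatmap(
    tracks: TrackSet,
    anchors: Sequence[Anchor],
    flank: int,
    sort_key: Mapping[str, float],
) -> tuple[np.ndarray, list[str]]:
    """Per-anchor rows ordered by ascending sort key (ties by anchor name).

    Returns (matrix, ordered anchor names). Anchors missing a key or with a
    truncated window are dropped. Row means reproduce ``profile_1d`` computed
    on the retained anchors.
    """
    keyed = [a for a in anchors if a.name in sort_key]
    rows: list[tuple[float, str, np.ndarray]] = []
    for a in keyed:
        window = _anchor_window(tracks, a, flank)
        if window is None:
            continue
        rows.append((float(sort_key[a.name]), a.name, window))
    rows.sort(key=lambda r: (r[0], r[1]))
    if not rows:
        return np.zeros((0, 2 * flank + 1)), []
    matrix = np.vstack([r[2] for r in rows])
    return matrix, [r[1] for r in rows]


def occupancy_2d(
    frags: FragmentSet,
    anchors: Sequence[Anchor],
    flank: int,
    length_range: tuple[int, int] = (100, 250),
    length_bin: int = 1,
    chrom_sizes: Mapping[str, int] | None = None,
) -> Occupancy2D:
    """Mean dyad counts per (fragment length bin, strand-oriented offset).

    Cell (L, o) is the mean over retained anchors of the number of fragment
    dyads at oriented offset o whose length falls in bin L. Column sums over
    the length axis reproduce the 1D profile of the same length-filtered
    fragment set on the same anchors.
    """
    lo, hi = length_range
    if hi < lo:
        raise ValueError("empty length_range")
    if length_bin < 1:
        raise ValueError("length_bin must be >= 1")
    edges = np.arange(lo, hi + 1, length_bin)
    n_bins = edges.size
    offsets = np.arange(-flank, flank + 1)
    matrix = np.zeros((n_bins, offsets.size), dtype=float)

    # per-chrom sorted dyads with lengths for fast window queries
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chrom_max: dict[str, int] = dict(chrom_sizes) if chrom_sizes else {}
    if not chrom_max:
        for f in frags:
            chrom_max[f.chrom] = max(chrom_max.get(f.chrom, 0), f.end)
    tmp: dict[str, list[tuple[int, int]]] = {}
    for f in frags:
        if lo <= f.length <= hi:
            tmp.setdefault(f.chrom, []).append((f.dyad, f.length))
    for c, pairs in tmp.items():
        pairs.sort()
        d = np.array([p[0] for p in pairs], dtype=np.int64)
        l = np.array([p[1] for p in pairs], dtype=np.int64)
        by_chrom[c] = (d, l)

    used = 0
    for a in anchors:
        extent = chrom_max.get(a.chrom, 0)
        if a.position - flank < 0 or a.position + flank + 1 > extent:
            continue
        used += 1
        if a.chrom not in by_chrom:
            continue
        dyads, lens = by_chrom[a.chrom]
        i0 = np.searchsorted(dyads, a.position - flank, side="left")
        i1 = np.searchsorted(dyads, a.position + flank, side="right")
        off = dyads[i0:i1] - a.position
        if a.strand == "-":
            off = -off
        bins = (lens[i0:i1] - lo) // length_bin
        np.add.at(matrix, (bins, off + flank), 1.0)
    if used == 0:
        raise ValueError("no usable anchors for occupancy_2d")
    matrix /= used
    return Occupancy2D(
        offsets=offsets,
        length_bins=edges,
        length_bin_width=length_bin,
        matrix=matrix,
        marginal_profile=matrix.sum(axis=0),
        n_anchors=used,
    )


def fragment_length_density(frags: FragmentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-length counts and a density summing to 1.

    Returns (lengths, counts, density) over the observed length support.
    """
    if len(frags) == 0:
        raise ValueError("empty fragment set")
    lens = frags.lengths()
    lengths, counts = np.unique(lens, return_counts=True)
    density = counts / counts.sum()
    return lengths, counts, density
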