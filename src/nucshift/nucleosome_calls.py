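"""Nucleosome calling, fuzziness scoring, and the cross-condition
positional-difference track.

Calls are summits of the smoothed dyad density: strict local maxima above an
occupancy floor, retained greedily by descending occupancy subject to a
minimum summit-to-summit distance. The footprint is fixed at 147 bp
(summit +/- 73), the length of DNA wrapped around the histone octamer.
Fuzziness is the sample standard deviation of the supporting dyads, the
standard positional-dispersion companion of the call.

The positional-difference statistic compares windowed dyad counts between two
conditions per base with a library-size-scaled two-sided Poisson test. The
sign convention follows the occupancy ordering: when the treatment (B) signal
exceeds control (A), the score is -log10 p; otherwise +log10 p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import FragmentSet
from .occupancy import OccupancyTrack, TrackSet

__all__ = [
    "NucleosomeCall",
    "FOOTPRINT_HALF",
    "filter_canonical",
    "call_nucleosomes",
    "call_fuzziness",
    "positional_difference",
]

FOOTPRINT_HALF = 73  # 147-bp footprint: summit +/- 73


@dataclass(slots=True)
class NucleosomeCall:
    chrom: str
    summit: int
    start: int
    end: int
    occupancy: float
    fuzziness: float | None
    sample_label: str

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside footprint [{self.start}, {self.end})"
            )
        if self.occupancy <= 0:
            raise ValueError("call occupancy must be positive")


def filter_canonical(frags: FragmentSet, lo: int = 140, hi: int = 180) -> FragmentSet:
    """Keep fragments with lo <= length <= hi (canonical mononucleosomes).

    ``total_count`` is preserved from the input so RPBM stays comparable.
    """
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    kept = [f for f in frags if lo <= f.length <= hi]
    return FragmentSet(frags.sample_label, kept, frags.total_count)


def _strict_local_maxima(values: np.ndarray) -> np.ndarray:
    """Summit candidates: points (or constant plateaus) above both flanks.

    A run of equal values counts as one summit at its left end when the run
    is strictly higher than the values on both sides; exact plateaus arise in
    degenerate noise-free signal where two dyad clusters are symmetric.
    """
    if values.size < 3:
        return np.array([], dtype=int)
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.size]))  # run i is [starts_i, ends_i)
    out = []
    for s, e in zip(starts, ends):
        if s == 0 or e == values.size:
            continue  # runs touching the edges have no outer flank
        if values[s] > values[s - 1] and values[s] > values[e]:
            out.append(s)
    return np.asarray(out, dtype=int)


def call_nucleosomes(
    tracks: OccupancyTrack | TrackSet,
    min_occupancy: float,
    min_summit_distance: int = 120,
    frags: FragmentSet | None = None,
    sample_label: str | None = None,
) -> list[NucleosomeCall]:
    """Call nucleosomes from a smoothed occupancy track.

    Summits are strict local maxima with value >= min_occupancy; retained
    greedily by descending occupancy (ties broken leftmost) such that any two
    kept summits are >= min_summit_distance apart. When ``frags`` is given,
    fuzziness is computed from the dyads inside each footprint.
    """
    if isinstance(tracks, OccupancyTrack):
        tracks = {tracks.chrom: tracks}
    dyads_by_chrom = frags.dyads_by_chrom() if frags is not None else {}
    calls: list[NucleosomeCall] = []
    for chrom in sorted(tracks):
        track = tracks[chrom]
        if track.smoothing is None:
            warnings.warn(
                f"calling nucleosomes on an unsmoothed track ({chrom})", stacklevel=2
            )
        idx = _strict_local_maxima(track.values)
        idx = idx[track.values[idx] >= min_occupancy]
        if idx.size == 0:
            continue
        # greedy by descending occupancy, ties leftmost
        order = np.lexsort((idx, -track.values[idx]))
        kept: list[int] = []
        for i in order:
            pos = int(idx[i])
            if all(abs(pos - k) >= min_summit_distance for k in kept):
                kept.append(pos)
        kept.sort()
        chrom_len = track.origin + track.values.size
        chrom_dyads = dyads_by_chrom.get(chrom)
        label = sample_label or (frags.sample_label if frags is not None else "sample")
        for pos in kept:
            summit = pos + track.origin
            start = max(0, summit - FOOTPRINT_HALF)
            end = min(chrom_len, summit + FOOTPRINT_HALF + 1)
            fuzz = None
            if chrom_dyads is not None:
                lo = np.searchsorted(chrom_dyads, start, side="left")
                hi = np.searchsorted(chrom_dyads, end, side="left")
                support = chrom_dyads[lo:hi]
                if support.size >= 2:
                    fuzz = float(np.std(support, ddof=1))
            calls.append(
                NucleosomeCall(
                    chrom=chrom,
                    summit=summit,
                    start=start,
                    end=end,
                    occupancy=float(track.values[pos]),
                    fuzziness=fuzz,
                    sample_label=label,
                )
            )
    return calls


def call_fuzziness(call: NucleosomeCall, frags: FragmentSet) -> float | None:
    """Sample standard deviation (bp) of dyads inside the call footprint.

    Returns None (missing) when fewer than two supporting dyads exist.
    """
    dyads = [f.dyad for f in frags if f.chrom == call.chrom and call.start <= f.dyad < call.end]
    if len(dyads) < 2:
        return None
    return float(np.std(np.asarray(dyads, dtype=float), ddof=1))


def poisson_two_sided_p(observed: int, mean: float) -> float:
    """Two-sided Poisson test: 2 * min(P(X <= obs), P(X >= obs)), capped at 1."""
    lower = stats.poisson.cdf(observed, mean)
    upper = stats.poisson.sf(observed - 1, mean)
    return float(min(1.0, 2.0 * min(lower, upper)))


def positional_difference(
    track_a: OccupancyTrack,
    track_b: OccupancyTrack,
    total_a: int,
    total_b: int,
    window: int = 147,
) -> OccupancyTrack:
    """Signed per-base -log10 p track comparing windowed dyad counts.

    Counts are summed over a centered ``window`` at each base and given a
    pseudocount of 1 on both sides. The larger depth-scaled count is tested
    two-sided against the Poisson expectation derived from the smaller side
    after library-size scaling; fixing the direction this way makes the track
    exactly antisymmetric under swapping the samples. Scaled B > scaled A
    scores -log10 p (treatment gain), the reverse +log10 p, exact ties 0.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    if track_a.chrom != track_b.chrom or track_a.origin != track_b.origin or (
        track_a.values.size != track_b.values.size
    ):
        raise ValueError("tracks must cover the same chromosome extent")
    kernel = np.ones(window)
    wa = np.convolve(track_a.values, kernel, mode="same")
    wb = np.convolve(track_b.values, kernel, mode="same")
    a = np.rint(wa).astype(np.int64) + 1
    b = np.rint(wb).astype(np.int64) + 1

    # vectorize over unique (a, b) pairs: windowed integer counts repeat heavily
    pairs = np.stack([a, b], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    ua, ub = uniq[:, 0], uniq[:, 1]
    scaled_a = ua / total_a
    scaled_b = ub / total_b
    # canonical direction: the larger depth-scaled count is tested against the
    # expectation derived from the smaller side, so swapping the two samples
    # flips only the sign (exact antisymmetry)
    b_high = scaled_b >= scaled_a
    obs = np.where(b_high, ub, ua)
    mean = np.where(b_high, ua * (total_b / total_a), ub * (total_a / total_b))
    lower = stats.poisson.cdf(obs, mean)
    upper = stats.poisson.sf(obs - 1, mean)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    with np.errstate(divide="ignore"):
        mag = -np.log10(p)
    uscore = np.where(
        scaled_b > scaled_a, -mag, np.where(scaled_b < scaled_a, mag, 0.0)
    )
    scores = uscore[inverse]
    return OccupancyTrack(
        chrom=track_a.chrom,
        origin=track_a.origin,
        values=scores,
        units="signed_log10p",
        mode="diff",
    )
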