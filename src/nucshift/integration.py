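"""Integration of nucleosome shift groups with external signal densities,
differential expression, and factor binding.

Signal densities over regions are RPBM-quantified (tag count scaled to a
million mapped tags) and compared between groups with two-sample
Kolmogorov-Smirnov tests; group summaries use type-7 quartiles. Association
tables report per shift group the fraction of up/down differentially
expressed member genes and the fraction of nucleosomes whose summit falls in
a bound region, with fold enrichment relative to the stable (0-bp shift)
reference group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DERecord, FragmentSet

__all__ = [
    "SignalQuant",
    "GroupComparison",
    "quantify_signal",
    "ks_compare",
    "group_summary",
    "de_shift_association",
    "binding_enrichment",
    "POOLED_BINS",
]

POOLED_BINS = ("10-50", "51-100", "101-150", "151-200")  # the 10-200 bp aggregate


@dataclass(frozen=True, slots=True)
class SignalQuant:
    region: tuple[str, int, int]
    count: int
    rpbm: float
    log2_rpbm: float


@dataclass(frozen=True, slots=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    ks_statistic: float
    p_value: float
    method: str  # asymptotic | exact


def quantify_signal(
    tags: FragmentSet,
    regions: Sequence[tuple[str, int, int]],
    pseudocount: float = 1.0,
    per_base: bool = False,
) -> list[SignalQuant]:
    """RPBM density of tag dyads over regions.

    A tag counts toward a region when its dyad lies in [start, end).
    rpbm = count * 1e6 / total tags (divided additionally by region length
    when ``per_base``); log2_rpbm = log2(rpbm + pseudocount).
    """
    if tags.total_count <= 0:
        raise ValueError("total tag count must be positive")
    dyads = tags.dyads_by_chrom()
    out = []
    for chrom, start, end in regions:
        if end <= start:
            raise ValueError(f"zero-length region: {chrom}:{start}-{end}")
        pos = dyads.get(chrom)
        if pos is None:
            count = 0
        else:
            count = int(
                np.searchsorted(pos, end, side="left")
                - np.searchsorted(pos, start, side="left")
            )
        rpbm = count * 1e6 / tags.total_count
        if per_base:
            rpbm /= end - start
        out.append(
            SignalQuant((chrom, start, end), count, rpbm, math.log2(rpbm + pseudocount))
        )
    return out


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS D via the pooled-grid ECDF difference (handles ties)."""
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    exact_max_n: int = 10,
) -> GroupComparison:
    """Two-sided two-sample Kolmogorov-Smirnov comparison.

    Uses the asymptotic Kolmogorov distribution for large samples and an
    exhaustive permutation enumeration (valid under ties) when both samples
    have at most ``exact_max_n`` observations.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d_obs = _ks_statistic(a, b)
    if a.size <= exact_max_n and b.size <= exact_max_n:
        pooled = np.concatenate([a, b])
        n = a.size
        total = 0
        ge = 0
        for idx in combinations(range(pooled.size), n):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(idx)] = True
            d = _ks_statistic(pooled[mask], pooled[~mask])
            total += 1
            if d >= d_obs - 1e-12:
                ge += 1
        p = ge / total
        method = "exact"
    else:
        p = float(stats.ks_2samp(a, b, method="asymp").pvalue)
        method = "asymptotic"
    return GroupComparison(label_a, label_b, int(a.size), int(b.size), d_obs, min(1.0, p), method)


def group_summary(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group five-number summary (type-7 quartiles) and count."""
    rows = []
    for group, values in values_by_group.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            rows.append(
                {"group": group, "n": 0, "min": np.nan, "q1": np.nan,
                 "median": np.nan, "q3": np.nan, "max": np.nan}
            )
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation = type 7
        rows.append(
            {"group": group, "n": int(v.size), "min": float(v.min()), "q1": float(q1),
             "median": float(med), "q3": float(q3), "max": float(v.max())}
        )
    return pd.DataFrame(rows, columns=["group", "n", "min", "q1", "median", "q3", "max"])


def de_shift_association(
    groups: Mapping[str, Sequence[str]],
    de_records: Sequence[DERecord],
    pooled_label: str = "10-200",
) -> pd.DataFrame:
    """Fraction of up/down DE genes per shift group, plus the 10-200 pool.

    Genes absent from the DE table count as unchanged (reported in
    ``n_missing``). The pooled row aggregates the members of the 10-50
    through 151-200 bins.
    """
    status = {r.gene_id: r.status for r in de_records}
    rows = []

    def _row(label: str, members: Sequence[str]) -> dict | None:
        if not members:
            return None
        n = len(members)
        up = sum(1 for g in members if status.get(g) == "up")
        down = sum(1 for g in members if status.get(g) == "down")
        missing = sum(1 for g in members if g not in status)
        return {
            "group": label, "n": n, "fraction_up": up / n,
            "fraction_down": down / n, "n_missing": missing,
        }

    for label, members in groups.items():
        r = _row(label, list(members))
        if r is not None:
            rows.append(r)
    pooled: list[str] = []
    for b in POOLED_BINS:
        pooled.extend(groups.get(b, []))
    r = _row(pooled_label, pooled)
    if r is not None:
        rows.append(r)
    return pd.DataFrame(rows, columns=["group", "n", "fraction_up", "fraction_down", "n_missing"])


def binding_enrichment(
    groups: Mapping[str, Sequence[tuple[str, int]]],
    bound_regions: Sequence[tuple[str, int, int]],
    reference_group: str = "0",
    mode: str = "summit",
) -> pd.DataFrame:
    """Fraction of bound nucleosomes per group and fold vs the stable group.

    ``groups`` maps group label to nucleosome summits (chrom, position). A
    nucleosome is bound when its summit lies in a bound region ([start, end));
    ``mode='footprint'`` instead requires its 147-bp footprint to overlap one.
    Fold is fraction(group) / fraction(reference); missing when the reference
    fraction is 0.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in bound_regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    for v in by_chrom.values():
        v.sort()

    def _bound(chrom: str, pos: int) -> bool:
        if mode == "summit":
            lo, hi = pos, pos + 1
        else:
            lo, hi = pos - 73, pos + 74
        return any(s < hi and lo < e for s, e in by_chrom.get(chrom, []))

    fractions: dict[str, tuple[float, int]] = {}
    for label, summits in groups.items():
        summits = list(summits)
        if not summits:
            fractions[label] = (np.nan, 0)
            continue
        bound = sum(1 for chrom, pos in summits if _bound(chrom, pos))
        fractions[label] = (bound / len(summits), len(summits))
    ref_frac = fractions.get(reference_group, (np.nan, 0))[0]
    rows = []
    for label, (frac, n) in fractions.items():
        if np.isnan(frac) or np.isnan(ref_frac) or ref_frac == 0:
            fold = np.nan
        else:
            fold = frac / ref_frac
        rows.append({"group": label, "n": n, "fraction_bound": frac, "fold_vs_reference": fold})
    return pd.DataFrame(rows, columns=["group", "n", "fraction_bound", "fold_vs_reference"])
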