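"""Reference synthetic studies: ground-truth recovery of programmed shifts
and caller accuracy, computed fully in memory.

These drive validation and the reproducibility script. The default
conditions are the package's study conditions: 200 genes on one chromosome,
190-bp spacing, 150-bp NDR, 50 fragments per nucleosome, 10-bp dyad jitter,
147 +/- 12 bp fragment lengths, +1 shifts of 30/75/125/175 bp half
downstream, half upstream.
"""

from __future__ import annotations

import numpy as np

from . import nucleosome_calls as nc
from . import occupancy as occ
from . import shift_analysis as sa
from . import synthetic as syn
from .io_formats import FragmentSet
from .pipeline import RunConfig

__all__ = ["build_study_model", "call_condition", "shift_recovery_study", "caller_accuracy_study"]


def build_study_model(cfg: RunConfig, fraction_shifted: float = 1.0) -> syn.GenomeModel:
    """Simulate the study genome and program +1 shifts across all bins.

    Genes are assigned round-robin to the (delta, direction) combinations of
    ``cfg.shift_deltas`` x {downstream, upstream}.
    """
    model = syn.simulate_genome(
        n_genes=cfg.n_genes,
        chrom_len=cfg.resolved_chrom_len(),
        gc_fraction=cfg.gc_fraction,
        ndr_width=cfg.ndr_width,
        spacing=cfg.spacing,
        n_nucs_per_side=cfg.n_nucs_per_side,
        seed=cfg.seed,
        ndr_offset=cfg.ndr_offset,
        footprint_gc=cfg.footprint_gc or None,
    )
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [g.gene_id for g in model.genes]
    n_shift = int(round(fraction_shifted * len(gene_ids)))
    shifted = list(rng.permutation(gene_ids)[:n_shift])
    combos = [(d, dr) for d in cfg.shift_deltas for dr in ("downstream", "upstream")]
    programs = [
        syn.ShiftProgram(1, direction, delta, tuple(shifted[i :: len(combos)]))
        for i, (delta, direction) in enumerate(combos)
        if shifted[i :: len(combos)]
    ]
    return syn.program_shifts(model, programs)


def call_condition(
    model: syn.GenomeModel,
    condition: str,
    cfg: RunConfig,
    depth: int | None = None,
    jitter: float | None = None,
    len_sd: float | None = None,
    seed_offset: int = 0,
) -> tuple[list[nc.NucleosomeCall], FragmentSet]:
    """Sample fragments for one condition and call nucleosomes on them."""
    frags = syn.sample_fragments(
        model,
        condition,
        depth_per_nuc=depth if depth is not None else cfg.depth_per_nuc,
        len_mean=cfg.len_mean,
        len_sd=cfg.len_sd if len_sd is None else len_sd,
        dyad_jitter_sd=cfg.dyad_jitter_sd if jitter is None else jitter,
        seed=cfg.seed + seed_offset,
    )
    canonical = nc.filter_canonical(frags, cfg.canonical_lo, cfg.canonical_hi)
    sizes = {c: len(s) for c, s in model.sequences.items()}
    tracks = occ.dyad_density(canonical, "dyad", chrom_sizes=sizes)
    tracks = occ.rpbm_normalize(tracks, canonical.total_count)
    smoothed = occ.smooth_track(tracks, cfg.smoothing_bandwidth, cfg.smoothing_kernel)
    calls = nc.call_nucleosomes(
        smoothed, cfg.min_occupancy, cfg.min_summit_distance, frags=canonical
    )
    return calls, canonical


def shift_recovery_study(
    seed: int = 1,
    noiseless: bool = False,
    cfg: RunConfig | None = None,
) -> dict[str, float]:
    """Programmed-shift recovery at the study conditions.

    Returns the fraction of programmed genes assigned the correct shift bin,
    the fraction of recovered genes with the correct direction, and the
    fraction recovered at all.
    """
    cfg = cfg or RunConfig()
    cfg.seed = seed
    model = build_study_model(cfg)
    kw = dict(jitter=0.0, len_sd=0.0) if noiseless else {}
    calls_a, _ = call_condition(model, "control", cfg, seed_offset=11, **kw)
    calls_b, _ = call_condition(model, "treatment", cfg, seed_offset=13, **kw)
    table = sa.gene_shift_table(calls_a, calls_b, model.genes, window=cfg.role_window)
    plus1 = table[table["role"] == 1].set_index("gene")

    n_programmed = n_recovered = bin_ok = dir_ok = 0
    for (cond, gid, role), (delta, direction) in model.programmed.items():
        if role != 1:
            continue
        n_programmed += 1
        if gid not in plus1.index:
            continue
        row = plus1.loc[gid]
        n_recovered += 1
        if sa.shift_bin(delta) == row["bin"]:
            bin_ok += 1
        if direction == row["direction"]:
            dir_ok += 1
    return {
        "n_programmed": n_programmed,
        "n_recovered": n_recovered,
        "bin_accuracy": bin_ok / n_programmed if n_programmed else float("nan"),
        "direction_accuracy_recovered": dir_ok / n_recovered if n_recovered else float("nan"),
        "recovered_fraction": n_recovered / n_programmed if n_programmed else float("nan"),
    }


def caller_accuracy_study(seed: int = 1, cfg: RunConfig | None = None) -> dict[str, float]:
    """Noise-free caller accuracy on an unshifted phased-array genome.

    Measures the largest summit-to-truth distance over all truth dyads and
    the number of spurious summits (calls farther than 2 bp from any truth
    dyad) above the occupancy floor.
    """
    cfg = cfg or RunConfig()
    cfg.seed = seed
    model = build_study_model(cfg, fraction_shifted=0.0)
    calls, _ = call_condition(model, "control", cfg, jitter=0.0, len_sd=0.0, seed_offset=11)
    truth = np.sort([pos for (c, g, r), pos in model.truth_dyads.items() if c == "control"])
    summits = np.sort([c.summit for c in calls])
    # distance from each truth dyad to its nearest summit, and vice versa
    idx = np.clip(np.searchsorted(summits, truth), 1, summits.size - 1)
    nearest = np.minimum(np.abs(truth - summits[idx - 1]), np.abs(truth - summits[idx]))
    jdx = np.clip(np.searchsorted(truth, summits), 1, truth.size - 1)
    summit_err = np.minimum(np.abs(summits - truth[jdx - 1]), np.abs(summits - truth[jdx]))
    return {
        "n_truth_dyads": int(truth.size),
        "n_calls": int(summits.size),
        "max_truth_to_summit_bp": float(nearest.max()),
        "n_spurious_summits": int((summit_err > 2).sum()),
    }
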