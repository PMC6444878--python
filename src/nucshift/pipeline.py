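"""End-to-end synthetic study: stage functions, run configuration, manifest.

Stages run in dependency order (simulate -> occupancy -> call -> diff ->
shift -> seqfeat -> integrate). Every stage reads its inputs from and writes
its outputs to the run directory, so a stage can be re-run in isolation once
its dependencies exist. The manifest records a SHA-256 checksum per output;
identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_formats as io
from . import occupancy as occ
from . import nucleosome_calls as nc
from . import shift_analysis as sa
from . import sequence_features as sf
from . import integration as ig
from . import synthetic as syn

__all__ = ["RunConfig", "STAGES", "run_pipeline", "write_manifest"]

STAGES = ("simulate", "occupancy", "call", "diff", "shift", "seqfeat", "integrate")

_STAGE_INPUTS: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "occupancy": ("frags_control.bed", "frags_treatment.bed", "anchors_tss.bed"),
    "call": ("frags_control.bed", "frags_treatment.bed"),
    "diff": ("frags_control.bed", "frags_treatment.bed"),
    "shift": ("calls_control.tsv", "calls_treatment.tsv", "genes.tsv", "anchors_tss.bed"),
    "seqfeat": ("calls_control.tsv", "genome.fa", "genes.tsv"),
    "integrate": ("shift_table.tsv", "de_table.tsv", "signal_tags.bed", "bound_regions.bed"),
}


@dataclass(slots=True)
class RunConfig:
    """All tunable parameters of the synthetic study, with their defaults."""

    # simulation
    n_genes: int = 200
    chrom_len: int = 0  # 0 = auto-size to fit the gene count
    gc_fraction: float = 0.42
    footprint_gc: float = 0.0  # 0 = no footprint G+C elevation
    ndr_width: int = 150
    ndr_offset: int = 100
    spacing: int = 190
    n_nucs_per_side: int = 3
    shift_deltas: tuple[int, ...] = (30, 75, 125, 175)
    fraction_shifted: float = 0.8
    depth_per_nuc: int = 50
    len_mean: float = 147.0
    len_sd: float = 12.0
    dyad_jitter_sd: float = 10.0
    # synthetic associations (bound/DE probabilities per shift status)
    p_bound_shifted: float = 0.6
    p_bound_stable: float = 0.25
    p_de_shifted: float = 0.5
    p_de_stable: float = 0.1
    # analysis
    canonical_lo: int = 140
    canonical_hi: int = 180
    smoothing_bandwidth: float = 20.0
    smoothing_kernel: str = "gaussian"
    min_occupancy: float = 2.0  # RPBM
    min_summit_distance: int = 40
    diff_window: int = 147
    profile_flank: int = 1000
    role_window: int = 1000
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.001
    kmer_k: int = 6
    kmer_window: int = 10
    kmer_flank: int = 130
    dinuc_flank: int = 250
    log2_pseudocount: float = 1.0
    seed: int = 1

    def resolved_chrom_len(self) -> int:
        if self.chrom_len:
            return self.chrom_len
        half_span = self.ndr_offset + self.ndr_width + self.n_nucs_per_side * self.spacing
        return self.n_genes * (2 * half_span + 400 + 200) + 2 * 1200 + 1000

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["shift_deltas"] = list(self.shift_deltas)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "shift_deltas" in data:
            data["shift_deltas"] = tuple(data["shift_deltas"])
        return cls(**data)


# ---------------------------------------------------------------------------
# stage implementations


def _genes_to_tsv(genes: Sequence[io.GeneModel], path: Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "tss": g.tss, "tes": g.tes,
            "rpkm_control": g.rpkm_by_condition.get("control", 0.0),
            "rpkm_treatment": g.rpkm_by_condition.get("treatment", 0.0),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _genes_from_tsv(path: Path) -> list[io.GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        io.GeneModel(
            str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss), int(r.tes),
            {"control": float(r.rpkm_control), "treatment": float(r.rpkm_treatment)},
        )
        for r in df.itertuples(index=False)
    ]


def stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    rng = np.random.default_rng(cfg.seed)
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
    gene_ids = [g.gene_id for g in model.genes]
    n_shift = int(round(cfg.fraction_shifted * len(gene_ids)))
    shifted = list(rng.permutation(gene_ids)[:n_shift])
    combos = [(d, direction) for d in cfg.shift_deltas for direction in ("downstream", "upstream")]
    programs = []
    for i, (delta, direction) in enumerate(combos):
        subset = tuple(shifted[i::len(combos)])
        if subset:
            programs.append(syn.ShiftProgram(1, direction, delta, subset))
    syn.program_shifts(model, programs)

    frags_a = syn.sample_fragments(
        model, "control", cfg.depth_per_nuc, cfg.len_mean, cfg.len_sd,
        cfg.dyad_jitter_sd, seed=cfg.seed + 11,
    )
    frags_b = syn.sample_fragments(
        model, "treatment", cfg.depth_per_nuc, cfg.len_mean, cfg.len_sd,
        cfg.dyad_jitter_sd, seed=cfg.seed + 13,
    )

    shifted_set = set(shifted)
    # synthetic DE table: shifted genes dysregulated more often
    de_rows = []
    for g in model.genes:
        p = cfg.p_de_shifted if g.gene_id in shifted_set else cfg.p_de_stable
        if rng.random() < p:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * rng.uniform(0.7, 3.0)
            fdr = 10 ** rng.uniform(-8, -4)
        else:
            lfc = rng.normal(0.0, 0.15)
            fdr = rng.uniform(0.05, 1.0)
        de_rows.append({"gene_id": g.gene_id, "log2fc": round(float(lfc), 4), "fdr": float(f"{fdr:.3e}")})
    # synthetic bound regions: +1 footprints, bound more often when shifted
    bound_rows = []
    for g in model.genes:
        p = cfg.p_bound_shifted if g.gene_id in shifted_set else cfg.p_bound_stable
        if rng.random() < p:
            dyad = model.truth_dyads[("control", g.gene_id, 1)]
            bound_rows.append((g.chrom, dyad - 73, dyad + 74))
    # synthetic signal tags: promoter-proximal signal, stronger at stable genes
    tag_frags = []
    chrom_len = len(next(iter(model.sequences.values())))
    for g in model.genes:
        n_tags = 30 if g.gene_id not in shifted_set else 12
        dyad = model.truth_dyads[("control", g.gene_id, 1)]
        centers = dyad + np.rint(rng.normal(0, 40, n_tags)).astype(int)
        for c in centers:
            s, e = int(c) - 73, int(c) + 74
            if 0 <= s and e <= chrom_len:
                tag_frags.append(io.Fragment(g.chrom, s, e))

    outputs: list[Path] = []

    def _out(name: str) -> Path:
        p = outdir / name
        outputs.append(p)
        return p

    io.write_genome(model.sequences, _out("genome.fa"))
    io.write_anchors(syn.tss_anchors(model), _out("anchors_tss.bed"))
    _genes_to_tsv(model.genes, _out("genes.tsv"))
    io.write_fragments_bed(frags_a, _out("frags_control.bed"))
    io.write_fragments_bed(frags_b, _out("frags_treatment.bed"))
    syn.export_truth(model, _out("truth.tsv"))
    pd.DataFrame(de_rows).to_csv(_out("de_table.tsv"), sep="\t", index=False)
    with open(_out("bound_regions.bed"), "w") as fh:
        for chrom, s, e in bound_rows:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    io.write_fragments_bed(
        io.FragmentSet("signal", tag_frags, len(tag_frags)), _out("signal_tags.bed")
    )
    return outputs


def _load_canonical(cfg: RunConfig, outdir: Path, condition: str) -> io.FragmentSet:
    frags = io.read_fragments(outdir / f"frags_{condition}.bed", sample_label=condition)
    return nc.filter_canonical(frags, cfg.canonical_lo, cfg.canonical_hi)


def _chrom_sizes_from_genome(outdir: Path) -> dict[str, int] | None:
    fa = outdir / "genome.fa"
    if not fa.exists():
        return None
    return {c: len(s) for c, s in io.read_genome(fa).items()}


def stage_occupancy(cfg: RunConfig, outdir: Path) -> list[Path]:
    anchors = io.read_anchors(outdir / "anchors_tss.bed", "TSS")
    sizes = _chrom_sizes_from_genome(outdir)
    outputs: list[Path] = []
    profile_cols: dict[str, np.ndarray] = {}
    for condition in ("control", "treatment"):
        frags = _load_canonical(cfg, outdir, condition)
        tracks = occ.dyad_density(frags, "dyad", chrom_sizes=sizes)
        tracks = occ.rpbm_normalize(tracks, frags.total_count)
        smoothed = occ.smooth_track(tracks, cfg.smoothing_bandwidth, cfg.smoothing_kernel)
        for chrom, tr in smoothed.items():
            p = outdir / f"track_{condition}_{chrom}.bedgraph"
            io.write_track(tr, p)
            outputs.append(p)
        prof = occ.profile_1d(smoothed, anchors, cfg.profile_flank)
        profile_cols[condition] = prof.mean_density
        lengths, counts, density = occ.fragment_length_density(frags)
        p = outdir / f"fragment_lengths_{condition}.tsv"
        pd.DataFrame({"length": lengths, "count": counts, "density": density}).to_csv(
            p, sep="\t", index=False
        )
        outputs.append(p)
    offsets = np.arange(-cfg.profile_flank, cfg.profile_flank + 1)
    p = outdir / "tss_profile.tsv"
    pd.DataFrame({"offset": offsets, **profile_cols}).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    return outputs


def stage_call(cfg: RunConfig, outdir: Path) -> list[Path]:
    sizes = _chrom_sizes_from_genome(outdir)
    outputs: list[Path] = []
    for condition in ("control", "treatment"):
        frags = _load_canonical(cfg, outdir, condition)
        tracks = occ.dyad_density(frags, "dyad", chrom_sizes=sizes)
        tracks = occ.rpbm_normalize(tracks, frags.total_count)
        smoothed = occ.smooth_track(tracks, cfg.smoothing_bandwidth, cfg.smoothing_kernel)
        calls = nc.call_nucleosomes(
            smoothed, cfg.min_occupancy, cfg.min_summit_distance, frags=frags
        )
        p = outdir / f"calls_{condition}.tsv"
        io.write_nucleosome_calls(calls, p)
        outputs.append(p)
    return outputs


def stage_diff(cfg: RunConfig, outdir: Path) -> list[Path]:
    sizes = _chrom_sizes_from_genome(outdir)
    frags_a = _load_canonical(cfg, outdir, "control")
    frags_b = _load_canonical(cfg, outdir, "treatment")
    tracks_a = occ.dyad_density(frags_a, "dyad", chrom_sizes=sizes)
    tracks_b = occ.dyad_density(frags_b, "dyad", chrom_sizes=sizes)
    outputs: list[Path] = []
    for chrom in sorted(tracks_a):
        diff = nc.positional_difference(
            tracks_a[chrom], tracks_b[chrom],
            frags_a.total_count, frags_b.total_count, cfg.diff_window,
        )
        p = outdir / f"diff_{chrom}.bedgraph"
        io.write_track(diff, p)
        outputs.append(p)
    return outputs


def stage_shift(cfg: RunConfig, outdir: Path) -> list[Path]:
    calls_a = io.read_nucleosome_calls(outdir / "calls_control.tsv")
    calls_b = io.read_nucleosome_calls(outdir / "calls_treatment.tsv")
    genes = _genes_from_tsv(outdir / "genes.tsv")
    table = sa.gene_shift_table(calls_a, calls_b, genes, window=cfg.role_window)
    outputs: list[Path] = []
    p = outdir / "shift_table.tsv"
    table.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    pairs, _, _ = sa.pair_nucleosomes(calls_a, calls_b)
    rv = sa.region_variance(pairs, region="genome")
    spacing_a = sa.spacing_distances(calls_a)
    spacing_b = sa.spacing_distances(calls_b)
    summary = {
        "genome_variance_bp": None if rv is None else rv.mean_pair_distance,
        "n_pairs": 0 if rv is None else rv.n_pairs,
        "spacing_control": sa.uniformness(spacing_a),
        "spacing_treatment": sa.uniformness(spacing_b),
    }

    # phasing per condition over all TSS anchors
    anchors = io.read_anchors(outdir / "anchors_tss.bed", "TSS")
    sizes = _chrom_sizes_from_genome(outdir)
    for condition in ("control", "treatment"):
        frags = _load_canonical(cfg, outdir, condition)
        tracks = occ.dyad_density(frags, "dyad", chrom_sizes=sizes)
        tracks = occ.rpbm_normalize(tracks, frags.total_count)
        smoothed = occ.smooth_track(tracks, cfg.smoothing_bandwidth, cfg.smoothing_kernel)
        prof = occ.profile_1d(smoothed, anchors, cfg.profile_flank)
        report = sa.phasing_metrics(prof, (cfg.spacing - 50, cfg.spacing + 50))
        summary[f"phasing_{condition}"] = {
            "canonical": report.canonical,
            "ndr_depth": report.ndr_depth,
            "plus1_offset": report.plus1_offset,
            "estimated_period": report.estimated_period,
            "decay_monotone": report.decay_monotone,
            "peak_offsets": report.peak_offsets,
        }
    p = outdir / "shift_summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs.append(p)
    return outputs


def stage_seqfeat(cfg: RunConfig, outdir: Path) -> list[Path]:
    genome = io.read_genome(outdir / "genome.fa")
    calls = io.read_nucleosome_calls(outdir / "calls_control.tsv")
    genes = _genes_from_tsv(outdir / "genes.tsv")
    strand_by_chrom: dict[str, str] = {}
    sites = [(c.chrom, c.summit, "+") for c in calls]
    outputs: list[Path] = []

    prof = sf.dinucleotide_profile(genome, sites, flank=cfg.dinuc_flank)
    p = outdir / "dinucleotide_profile.tsv"
    pd.DataFrame(
        {"offset": prof.offsets, "ww_freq": prof.ww_freq, "ss_freq": prof.ss_freq}
    ).to_csv(p, sep="\t", index=False, float_format="%.6g")
    outputs.append(p)

    kmat = sf.kmer_positional_counts(
        genome, sites, k=cfg.kmer_k, window=cfg.kmer_window, flank=cfg.kmer_flank
    )
    p = outdir / "kmer_counts.tsv"
    kmat.counts.to_csv(p, sep="\t", index_label="kmer")
    outputs.append(p)
    p = outdir / "kmer_zscores.tsv"
    kmat.zscores.to_csv(p, sep="\t", index_label="kmer", float_format="%.6g")
    outputs.append(p)

    labels = sf.annotate_genic([(c.chrom, c.summit) for c in calls], genes)
    p = outdir / "genic_annotation.tsv"
    pd.DataFrame(
        {"chrom": [c.chrom for c in calls], "summit": [c.summit for c in calls], "label": labels}
    ).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    return outputs


def stage_integrate(cfg: RunConfig, outdir: Path) -> list[Path]:
    table = pd.read_csv(outdir / "shift_table.tsv", sep="\t")
    plus1 = table[table["role"] == 1]
    de = io.read_de_table(outdir / "de_table.tsv", cfg.fc_threshold, cfg.fdr_threshold)
    tags = io.read_fragments(outdir / "signal_tags.bed", sample_label="signal")
    bound = []
    with open(outdir / "bound_regions.bed") as fh:
        for line in fh:
            if line.strip():
                c, s, e = line.split("\t")[:3]
                bound.append((c, int(s), int(e)))

    groups_genes: dict[str, list[str]] = {b: [] for b in sa.SHIFT_BINS}
    groups_summits: dict[str, list[tuple[str, int]]] = {b: [] for b in sa.SHIFT_BINS}
    # binding and signal are anchored on the control summit: the question is
    # whether the nucleosome (at its control position) carries the mark
    for row in plus1.itertuples(index=False):
        if row.bin in groups_genes:
            groups_genes[row.bin].append(str(row.gene))
            groups_summits[row.bin].append((str(row.chrom), int(row.summit_a)))

    outputs: list[Path] = []
    de_assoc = ig.de_shift_association(groups_genes, de)
    p = outdir / "de_association.tsv"
    de_assoc.to_csv(p, sep="\t", index=False, float_format="%.6g")
    outputs.append(p)

    enrich = ig.binding_enrichment(groups_summits, bound, reference_group="0")
    p = outdir / "binding_enrichment.tsv"
    enrich.to_csv(p, sep="\t", index=False, float_format="%.6g")
    outputs.append(p)

    # signal densities at the +1 footprint per shift group, with KS vs stable
    values_by_group: dict[str, list[float]] = {}
    for label, summits in groups_summits.items():
        regions = [(c, s - 73, s + 74) for c, s in summits]
        if not regions:
            values_by_group[label] = []
            continue
        quants = ig.quantify_signal(tags, regions, pseudocount=cfg.log2_pseudocount)
        values_by_group[label] = [q.log2_rpbm for q in quants]
    summary = ig.group_summary(values_by_group)
    p = outdir / "signal_by_group.tsv"
    summary.to_csv(p, sep="\t", index=False, float_format="%.6g")
    outputs.append(p)

    ks_rows = []
    ref = values_by_group.get("0", [])
    for label in sa.SHIFT_BINS[1:]:
        vals = values_by_group.get(label, [])
        if ref and vals:
            cmp = ig.ks_compare(ref, vals, "0", label)
            ks_rows.append(
                {"group": label, "ks_statistic": cmp.ks_statistic,
                 "p_value": cmp.p_value, "method": cmp.method,
                 "n_ref": cmp.n_a, "n_group": cmp.n_b}
            )
    p = outdir / "ks_vs_stable.tsv"
    pd.DataFrame(
        ks_rows, columns=["group", "ks_statistic", "p_value", "method", "n_ref", "n_group"]
    ).to_csv(p, sep="\t", index=False, float_format="%.6g")
    outputs.append(p)
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "occupancy": stage_occupancy,
    "call": stage_call,
    "diff": stage_diff,
    "shift": stage_shift,
    "seqfeat": stage_seqfeat,
    "integrate": stage_integrate,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    cfg: RunConfig,
    outdir: str | Path,
    stages: Sequence[str] = STAGES,
) -> dict[str, str]:
    """Run the requested stages in dependency order; return the manifest.

    The manifest maps each output file (relative to ``outdir``) to its
    SHA-256 checksum and is also written to ``manifest.json``. A stage whose
    required inputs are missing raises, naming the stage to run first.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGES if s in stages]
    manifest: dict[str, str] = {}
    producers = {
        name: stage for stage, names in {
            "simulate": _STAGE_INPUTS["occupancy"] + ("genes.tsv", "genome.fa", "de_table.tsv",
                                                      "signal_tags.bed", "bound_regions.bed", "truth.tsv"),
            "call": ("calls_control.tsv", "calls_treatment.tsv"),
            "shift": ("shift_table.tsv",),
        }.items() for name in names
    }
    for stage in ordered:
        for req in _STAGE_INPUTS[stage]:
            if not (outdir / req).exists():
                blame = producers.get(req, "simulate")
                raise FileNotFoundError(
                    f"stage '{stage}' requires {req}; run stage '{blame}' first"
                )
        for path in _STAGE_FUNCS[stage](cfg, outdir):
            manifest[path.name] = _sha256(path)
    write_manifest(manifest, outdir / "manifest.json")
    return manifest


def write_manifest(manifest: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(sorted(manifest.items())), fh, indent=2)
        fh.write("\n")
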