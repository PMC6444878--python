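"""Synthetic chromatin: genomes, gene models, ground-truth nucleosome arrays
for two conditions, and sampled paired-end MNase fragments.

The generator emulates the hallmark organization around active promoters: a
nucleosome-depleted region (NDR) upstream of the TSS flanked by a -1
nucleosome, a +1 nucleosome a fixed offset downstream of the TSS, and a
regularly spaced, phased array on both sides. A second condition is derived
from the reference by programmed, gene-oriented dyad shifts of known
magnitude and direction on chosen +1/-1 nucleosomes, which gives every
downstream stage a recoverable ground truth.

Fragment sampling draws, per truth dyad, a configurable number of protected
fragments whose centers are jittered around the dyad and whose lengths are
Gaussian around the mononucleosome length (clamped to [100, 250] bp, the
bounded support of a gel-purified mononucleosome library).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import Anchor, Fragment, FragmentSet, GeneModel

__all__ = [
    "GenomeModel",
    "ShiftProgram",
    "simulate_genome",
    "program_shifts",
    "sample_fragments",
    "export_truth",
    "read_truth",
    "tss_anchors",
]

LEN_CLAMP = (100, 250)


@dataclass(frozen=True, slots=True)
class ShiftProgram:
    """A programmed dyad shift applied to one role on a subset of genes."""

    role: int  # +1 or -1
    direction: str  # upstream | downstream (gene-oriented)
    delta: int  # bp > 0
    gene_subset: tuple[str, ...]
    condition: str = "treatment"

    def __post_init__(self) -> None:
        if self.role not in (1, -1):
            raise ValueError("shift programs target only +1/-1 nucleosomes")
        if self.direction not in ("upstream", "downstream"):
            raise ValueError(f"unknown direction: {self.direction}")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass(slots=True)
class GenomeModel:
    """Synthetic genome, gene annotation, and per-condition truth dyads."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    # (condition, gene_id, role) -> dyad bp; roles are ...,-2,-1,+1,+2,...
    truth_dyads: dict[tuple[str, str, int], int]
    ndr_width: int
    ndr_offset: int
    spacing: int
    seed: int
    conditions: tuple[str, str] = ("control", "treatment")
    # (condition, gene_id, role) -> (applied delta, direction) for programmed shifts
    programmed: dict[tuple[str, str, int], tuple[int, str]] = field(default_factory=dict)

    def roles(self) -> list[int]:
        return sorted({k[2] for k in self.truth_dyads}, key=lambda r: (abs(r), -r))

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def dyads_for(self, condition: str) -> list[tuple[str, int, int, str]]:
        """(chrom, dyad, role, gene_id) for every truth dyad of a condition."""
        out = []
        for (cond, gid, role), pos in self.truth_dyads.items():
            if cond == condition:
                out.append((self.gene(gid).chrom, pos, role, gid))
        return out


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Sequence as a byte array, base probabilities split evenly within AT/GC."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"AGCT", dtype="S1"), size=n, p=probs)


def simulate_genome(
    n_genes: int,
    chrom_len: int,
    gc_fraction: float = 0.42,
    ndr_width: int = 150,
    spacing: int = 190,
    n_nucs_per_side: int = 3,
    seed: int = 0,
    ndr_offset: int = 100,
    footprint_gc: float | None = None,
    chrom: str = "chrS",
    flank: int = 1200,
) -> GenomeModel:
    """Place non-overlapping genes with phased truth nucleosome arrays.

    The reference condition's +1 dyad sits ``ndr_offset`` bp downstream of the
    TSS in gene orientation, successive downstream dyads every ``spacing`` bp;
    the -1 dyad sits ``ndr_width`` bp upstream of the +1 dyad, successive
    upstream dyads every ``spacing`` bp. ``footprint_gc``, when set, raises
    the G+C fraction of the 147-bp window under every reference truth dyad.
    """
    if spacing <= 147:
        raise ValueError("spacing must exceed the 147-bp footprint")
    rng = np.random.default_rng(seed)
    # span of one gene's array on both sides of the TSS, plus breathing room
    half_span = ndr_offset + ndr_width + n_nucs_per_side * spacing
    pitch = 2 * half_span + 400
    required = n_genes * pitch + 2 * flank
    if required > chrom_len:
        raise ValueError(
            f"cannot pack {n_genes} genes into {chrom_len} bp; need >= {required}"
        )
    seq = _random_sequence(rng, chrom_len, gc_fraction)

    genes: list[GeneModel] = []
    truth: dict[tuple[str, str, int], int] = {}
    slack = (chrom_len - required) // max(n_genes, 1)
    cursor = flank
    for i in range(n_genes):
        gid = f"g{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        orient = 1 if strand == "+" else -1
        center = cursor + half_span + int(rng.integers(0, slack + 1))
        tss = center
        gene_len = n_nucs_per_side * spacing + ndr_offset
        tes = tss + orient * gene_len
        rpkm = {"control": float(rng.lognormal(1.0, 1.0)), "treatment": float(rng.lognormal(1.0, 1.0))}
        genes.append(GeneModel(gid, chrom, strand, tss, tes, rpkm))
        plus1 = tss + orient * ndr_offset
        minus1 = plus1 - orient * ndr_width
        for k in range(1, n_nucs_per_side + 1):
            truth[("control", gid, k)] = plus1 + orient * (k - 1) * spacing
            truth[("control", gid, -k)] = minus1 - orient * (k - 1) * spacing
        cursor = center + half_span + 400
    # condition B starts identical; program_shifts perturbs it
    for (cond, gid, role), pos in list(truth.items()):
        truth[("treatment", gid, role)] = pos

    if footprint_gc is not None:
        gc_bases = np.frombuffer(b"GC", dtype="S1")
        at_bases = np.frombuffer(b"AT", dtype="S1")
        for (cond, gid, role), pos in truth.items():
            if cond != "control":
                continue
            lo, hi = max(0, pos - 73), min(chrom_len, pos + 74)
            n = hi - lo
            is_gc = rng.random(n) < footprint_gc
            picks = np.where(
                is_gc,
                gc_bases[rng.integers(0, 2, n)],
                at_bases[rng.integers(0, 2, n)],
            )
            seq[lo:hi] = picks

    return GenomeModel(
        sequences={chrom: seq.tobytes().decode("ascii")},
        genes=genes,
        truth_dyads=truth,
        ndr_width=ndr_width,
        ndr_offset=ndr_offset,
        spacing=spacing,
        seed=seed,
    )


def program_shifts(
    model: GenomeModel,
    programs: Sequence[ShiftProgram],
    co_shift_array: bool = False,
) -> GenomeModel:
    """Apply programmed dyad shifts to the treatment condition's truth.

    ``downstream`` moves the dyad in gene orientation (+ strand: larger
    coordinates), ``upstream`` the reverse. With ``co_shift_array`` the rest
    of the array on the same side co-moves with the focal nucleosome; default
    off so recovery of the focal shift is unambiguous.
    """
    known = {g.gene_id for g in model.genes}
    for prog in programs:
        if prog.delta > model.spacing:
            raise ValueError("delta must not exceed spacing (no array reordering)")
        for gid in prog.gene_subset:
            if gid not in known:
                raise ValueError(f"shift program targets unknown gene: {gid}")
            gene = model.gene(gid)
            sign = gene.orient * (1 if prog.direction == "downstream" else -1)
            roles = [prog.role]
            if co_shift_array:
                side = 1 if prog.role > 0 else -1
                roles = [r for r in model.roles() if r * side > 0]
            for role in roles:
                key = (prog.condition, gid, role)
                model.truth_dyads[key] = model.truth_dyads[key] + sign * prog.delta
            model.programmed[(prog.condition, gid, prog.role)] = (prog.delta, prog.direction)
    return model


def sample_fragments(
    model: GenomeModel,
    condition: str,
    depth_per_nuc: int = 50,
    len_mean: float = 147.0,
    len_sd: float = 12.0,
    dyad_jitter_sd: float = 10.0,
    seed: int = 0,
    clip: bool = False,
) -> FragmentSet:
    """Sample ``depth_per_nuc`` protected fragments per truth dyad.

    Fragment center = dyad + round(N(0, dyad_jitter_sd)); length =
    clamp(round(N(len_mean, len_sd)), 100, 250). Fragments that would extend
    past the chromosome are dropped (or clipped with ``clip=True``);
    total_count is the number of fragments emitted.
    """
    if depth_per_nuc < 1:
        raise ValueError("depth_per_nuc must be >= 1")
    rng = np.random.default_rng(seed)
    fragments: list[Fragment] = []
    entries = sorted(
        (k for k in model.truth_dyads if k[0] == condition),
        key=lambda k: (k[1], k[2]),
    )
    for key in entries:
        pos = model.truth_dyads[key]
        chrom = model.gene(key[1]).chrom
        chrom_len = len(model.sequences[chrom])
        centers = pos + np.rint(rng.normal(0.0, dyad_jitter_sd, depth_per_nuc)).astype(int)
        lens = np.clip(
            np.rint(rng.normal(len_mean, len_sd, depth_per_nuc)).astype(int),
            *LEN_CLAMP,
        )
        starts = centers - (lens - 1) // 2
        ends = starts + lens
        for s, e in zip(starts, ends):
            if s < 0 or e > chrom_len:
                if not clip:
                    continue
                s, e = max(0, int(s)), min(chrom_len, int(e))
                if e - s < 1:
                    continue
            fragments.append(Fragment(chrom, int(s), int(e)))
    return FragmentSet(condition, fragments, len(fragments))


def export_truth(model: GenomeModel, path: str | Path | None = None) -> pd.DataFrame:
    """Truth table: one row per (condition, gene, role) with applied shifts."""
    rows = []
    for (cond, gid, role), pos in sorted(model.truth_dyads.items()):
        delta, direction = model.programmed.get((cond, gid, role), (0, "none"))
        rows.append(
            {
                "condition": cond,
                "gene": gid,
                "role": role,
                "dyad": pos,
                "applied_delta": delta,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows, columns=["condition", "gene", "role", "dyad", "applied_delta", "direction"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def tss_anchors(model: GenomeModel) -> list[Anchor]:
    """TSS anchor per gene, oriented by gene strand."""
    return [
        Anchor(g.chrom, g.tss, g.strand, g.gene_id, "TSS") for g in model.genes
    ]
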