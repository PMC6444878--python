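"""Readers and writers for every external representation the pipeline touches.

All genomic coordinates are 0-based, half-open (BED convention). Anchor
points are single base pairs. The dyad of a fragment is the midpoint of its
inclusive span, ``floor((start + end - 1) / 2)``, which is deterministic for
even fragment lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Fragment",
    "FragmentSet",
    "Anchor",
    "GeneModel",
    "DERecord",
    "dyad",
    "read_fragments",
    "read_anchors",
    "read_genome",
    "write_genome",
    "write_anchors",
    "write_fragments_bed",
    "write_fragments_bedpe",
    "write_track",
    "read_track",
    "write_nucleosome_calls",
    "read_nucleosome_calls",
    "read_de_table",
]

ANCHOR_CLASSES = ("TSS", "DHS", "CTCF", "TF", "other")


@dataclass(frozen=True, slots=True)
class Fragment:
    """One MNase-protected fragment; the atomic observation."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def dyad(self) -> int:
        """Midpoint of the inclusive span; the nucleosome position estimate."""
        return (self.start + self.end - 1) // 2


def dyad(start: int, end: int) -> int:
    """Dyad of the fragment [start, end): floor((start + end - 1) / 2)."""
    return (start + end - 1) // 2


@dataclass(slots=True)
class FragmentSet:
    """An ordered collection of fragments from one sample.

    ``total_count`` is the number of fragments parsed/emitted *before* any
    length filtering, and is the denominator for RPBM normalization so that
    densities stay comparable across length-filter settings.
    """

    sample_label: str
    fragments: list[Fragment]
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count < len(self.fragments):
            raise ValueError(
                f"total_count ({self.total_count}) < retained fragments "
                f"({len(self.fragments)})"
            )

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.fragments], dtype=np.int64)

    def dyads_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted dyad positions per chromosome."""
        out: dict[str, list[int]] = {}
        for f in self.fragments:
            out.setdefault(f.chrom, []).append(f.dyad)
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}

    def dedup(self) -> "FragmentSet":
        """Remove exact-coordinate duplicate fragments (order preserved)."""
        seen: set[tuple[str, int, int]] = set()
        kept: list[Fragment] = []
        for f in self.fragments:
            key = (f.chrom, f.start, f.end)
            if key not in seen:
                seen.add(key)
                kept.append(f)
        return FragmentSet(self.sample_label, kept, self.total_count)


@dataclass(frozen=True, slots=True)
class Anchor:
    """A single-bp genomic anchor point (TSS, DHS, CTCF/TF site)."""

    chrom: str
    position: int
    strand: str = "+"
    name: str = "."
    anchor_class: str = "other"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative anchor position: {self.name} @ {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"anchor strand must be '+' or '-', got {self.strand!r}")


@dataclass(slots=True)
class GeneModel:
    """Gene with TSS/TES and optional per-condition expression (RPKM)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    rpkm_by_condition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")

    def is_active(self, condition: str, rpkm_threshold: float = 1.0) -> bool:
        return self.rpkm_by_condition.get(condition, 0.0) > rpkm_threshold

    @property
    def orient(self) -> int:
        """+1 for + strand, -1 for - strand (gene orientation sign)."""
        return 1 if self.strand == "+" else -1


@dataclass(frozen=True, slots=True)
class DERecord:
    gene_id: str
    log2fc: float
    fdr: float
    status: str  # up | down | unchanged


# ---------------------------------------------------------------------------
# readers


def _parse_bed_fragment(fields: Sequence[str], lineno: int) -> Fragment:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed fragment record at line {lineno}") from exc
    if start >= end:
        raise ValueError(f"start >= end at line {lineno}: {chrom}:{start}-{end}")
    return Fragment(chrom, start, end)


def _parse_bedpe_fragment(fields: Sequence[str], lineno: int) -> Fragment:
    # mates merged to the outer span
    try:
        chrom1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
        chrom2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed BEDPE record at line {lineno}") from exc
    if chrom1 != chrom2:
        raise ValueError(f"inter-chromosomal mate pair at line {lineno}")
    start, end = min(s1, s2), max(e1, e2)
    if start >= end:
        raise ValueError(f"start >= end at line {lineno}: {chrom1}:{start}-{end}")
    return Fragment(chrom1, start, end)


def read_fragments(
    path: str | Path,
    min_len: int | None = None,
    max_len: int | None = None,
    sample_label: str | None = None,
    dedup: bool = False,
) -> FragmentSet:
    """Read fragments from a BED3+ or BEDPE file, with optional length limits.

    BEDPE records (>= 6 columns where columns 4-6 parse as an interval on the
    same chromosome) are merged to the outer span of the two mates.
    ``total_count`` is the number of parsed records before length filtering.
    """
    path = Path(path)
    fragments: list[Fragment] = []
    total = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            # BEDPE when cols 5-6 parse as the second mate's interval; BED6
            # carries name/score/strand there and strand is never an integer
            if len(fields) >= 6 and fields[4].lstrip("-").isdigit() and fields[5].lstrip("-").isdigit():
                frag = _parse_bedpe_fragment(fields, lineno)
            else:
                frag = _parse_bed_fragment(fields, lineno)
            total += 1
            if min_len is not None and frag.length < min_len:
                continue
            if max_len is not None and frag.length > max_len:
                continue
            fragments.append(frag)
    if total == 0:
        raise ValueError(f"empty fragment file: {path}")
    fs = FragmentSet(sample_label or path.stem, fragments, total)
    return fs.dedup() if dedup else fs


def read_anchors(path: str | Path, anchor_class: str = "TSS") -> list[Anchor]:
    """Read anchors from BED6.

    TSS-class anchors take the annotated start site as the point: the start
    field for + strand, ``end - 1`` for - strand. Other classes use the
    interval midpoint and default to + strand when unstranded.
    """
    path = Path(path)
    anchors: list[Anchor] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed anchor at line {lineno}") from exc
            if start < 0:
                raise ValueError(f"negative coordinate at line {lineno}")
            name = fields[3] if len(fields) > 3 else f"anchor{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            if anchor_class == "TSS":
                if strand not in ("+", "-"):
                    raise ValueError(
                        f"TSS anchor missing strand at line {lineno}: {name}"
                    )
                position = start if strand == "+" else end - 1
            else:
                position = (start + end) // 2
                if strand not in ("+", "-"):
                    strand = "+"
            anchors.append(Anchor(chrom, position, strand, name, anchor_class))
    return anchors


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA into a chrom -> uppercase sequence mapping."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome name in FASTA: {rec.id}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def read_de_table(
    path: str | Path,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.001,
) -> list[DERecord]:
    """Read a differential-expression TSV (gene_id, log2fc, fdr) and call status.

    up:   log2fc >= log2(fc_threshold)  and fdr < fdr_threshold
    down: log2fc <= -log2(fc_threshold) and fdr < fdr_threshold
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "fdr"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table missing columns: {required - set(df.columns)}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("fdr values outside [0, 1]")
    lfc_cut = math.log2(fc_threshold)
    records = []
    for row in df.itertuples(index=False):
        if row.fdr < fdr_threshold and row.log2fc >= lfc_cut:
            status = "up"
        elif row.fdr < fdr_threshold and row.log2fc <= -lfc_cut:
            status = "down"
        else:
            status = "unchanged"
        records.append(DERecord(str(row.gene_id), float(row.log2fc), float(row.fdr), status))
    return records


# ---------------------------------------------------------------------------
# writers


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_anchors(anchors: Iterable[Anchor], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(f"{a.chrom}\t{a.position}\t{a.position + 1}\t{a.name}\t0\t{a.strand}\n")


def write_fragments_bed(frags: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def write_fragments_bedpe(frags: FragmentSet, path: str | Path, read_len: int = 36) -> None:
    """Write fragments as BEDPE, synthesizing mate spans at the fragment ends."""
    with open(path, "w") as fh:
        for i, f in enumerate(frags):
            half = min(read_len, f.length)
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.start + half}"
                f"\t{f.chrom}\t{f.end - half}\t{f.end}"
                f"\tfrag{i}\t0\t+\t-\n"
            )


def write_track(
    track: "OccupancyTrack",  # noqa: F821 - forward ref to occupancy module
    path: str | Path,
    emit_zero: bool = True,
) -> None:
    """Write a per-base track as run-length-merged bedGraph (0-based half-open).

    Values are written with round-trip-exact float formatting so read-back
    reproduces them exactly. Zero runs are skipped with ``emit_zero=False``
    (an all-zero track then has an empty body).
    """
    values = np.asarray(track.values, dtype=float)
    with open(path, "w") as fh:
        if values.size == 0:
            return
        # boundaries of constant runs
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            v = float(values[s])
            if v == 0 and not emit_zero:
                continue
            out = int(v) if v.is_integer() else repr(v)
            fh.write(f"{track.chrom}\t{track.origin + s}\t{track.origin + e}\t{out}\n")


def read_track(path: str | Path):
    """Read a single-chromosome bedGraph back into an OccupancyTrack (raw units)."""
    from .occupancy import OccupancyTrack

    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")
            rows.append((c, int(s), int(e), float(v)))
    if not rows:
        raise ValueError(f"empty bedGraph: {path}")
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise ValueError("read_track expects a single-chromosome bedGraph")
    origin = min(r[1] for r in rows)
    extent = max(r[2] for r in rows)
    values = np.zeros(extent - origin, dtype=float)
    for _, s, e, v in rows:
        values[s - origin : e - origin] = v
    return OccupancyTrack(chrom=rows[0][0], origin=origin, values=values, units="raw")


CALL_COLUMNS = ["chrom", "summit", "start", "end", "occupancy", "fuzziness", "sample_label"]


def write_nucleosome_calls(calls, path: str | Path) -> None:
    """Write nucleosome calls as a header-carrying TSV (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fuzz = "NA" if c.fuzziness is None else f"{c.fuzziness:.6g}"
            fh.write(
                f"{c.chrom}\t{c.summit}\t{c.start}\t{c.end}"
                f"\t{c.occupancy:.6g}\t{fuzz}\t{c.sample_label}\n"
            )


def read_nucleosome_calls(path: str | Path):
    from .nucleosome_calls import NucleosomeCall

    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALL_COLUMNS:
            raise ValueError(f"unexpected call-table header: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                chrom, summit, start, end = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
                occupancy = float(fields[4])
                fuzziness = None if fields[5] == "NA" else float(fields[5])
                label = fields[6]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed call record at line {lineno}") from exc
            if not (start <= summit < end):
                raise ValueError(f"summit outside footprint at line {lineno}")
            calls.append(
                NucleosomeCall(
                    chrom=chrom, summit=summit, start=start, end=end,
                    occupancy=occupancy, fuzziness=fuzziness, sample_label=label,
                )
            )
    return calls
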