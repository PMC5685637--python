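"""On-disk formats and genome coordinate conventions.

All internal coordinates are 0-based, half-open.  Conversion to the 1-based
inclusive convention happens only at the GFF3 / report boundaries.  Coverage
is unstranded; strand enters the analysis only through the gene annotation.

Contaminant features (rDNA, tRNA genes, mitochondrial DNA, ...) are handled
as a coverage-level exclusion mask: masked positions are zeroed and flagged so
that depth sums and percentile pools downstream ignore them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq


class BedGraphError(ValueError):
    """Malformed or inconsistent bedGraph input."""


class AnnotationError(ValueError):
    """Malformed gene annotation input."""


@dataclass(frozen=True)
class GenomeLayout:
    """Named reference sequences and their lengths (nt)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("layout needs at least one sequence")
        for name, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"sequence {name!r} has non-positive length {n}")

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def check_interval(self, seq: str, start: int, end: int) -> None:
        if seq not in self.lengths:
            raise ValueError(f"unknown sequence {seq!r}")
        if not (0 <= start <= end <= self.lengths[seq]):
            raise ValueError(
                f"interval {seq}:{start}-{end} outside sequence bounds "
                f"(length {self.lengths[seq]})"
            )


@dataclass
class CoverageTrack:
    """Per-base non-negative coverage for one sample.

    ``mask`` marks excluded positions (True = excluded).  Masked positions
    hold value 0 and are left out of depth sums and percentile pools.
    """

    layout: GenomeLayout
    values: dict[str, np.ndarray]
    label: str = ""
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, n in self.layout.lengths.items():
            v = self.values.get(name)
            if v is None or len(v) != n:
                raise ValueError(f"values for {name!r} missing or wrong length")
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"coverage for {name!r} must be finite and >= 0")
        if not self.mask:
            self.mask = {
                name: np.zeros(n, dtype=bool)
                for name, n in self.layout.lengths.items()
            }

    def total_signal(self) -> float:
        """Sum of coverage over all unmasked positions, genome-wide."""
        return float(
            sum(self.values[s][~self.mask[s]].sum() for s in self.layout.names)
        )


@dataclass(frozen=True)
class Gene:
    """One annotated ORF. ``start``/``end`` are 0-based half-open."""

    gene_id: str
    seq: str
    start: int
    end: int
    strand: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(f"{self.gene_id}: start >= end")
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneAnnotation:
    """Container of ORF records with interval-overlap queries."""

    def __init__(self, genes: list[Gene]):
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate gene identifiers: {dup}")
        self.genes = list(genes)
        self._by_id = {g.gene_id: g for g in genes}
        from intervaltree import IntervalTree

        self._trees: dict[str, "IntervalTree"] = {}
        for g in genes:
            self._trees.setdefault(g.seq, IntervalTree())[g.start : g.end] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def overlapping(self, seq: str, start: int, end: int | None = None) -> list[Gene]:
        """Genes overlapping position ``start`` (or interval [start, end))."""
        tree = self._trees.get(seq)
        if tree is None:
            return []
        if end is None:
            end = start + 1
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))


@dataclass
class ExclusionSet:
    """Genomic intervals (0-based half-open) to mask out of coverage."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self, layout: GenomeLayout) -> None:
        for seq, start, end in self.intervals:
            layout.check_interval(seq, start, end)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path, layout: GenomeLayout, label: str = "") -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a dense track.

    Positions not covered by any interval get value 0.  Overlapping intervals
    are an error — the format is a partition of the axis, and silently adding
    or overwriting would corrupt depth sums.
    """
    values = {s: np.zeros(n) for s, n in layout.lengths.items()}
    per_seq: dict[str, list[tuple[int, int, int]]] = {s: [] for s in layout.names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise BedGraphError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            seq = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedGraphError(f"{path}:{lineno}: {exc}") from None
            if seq not in layout.lengths:
                raise BedGraphError(f"{path}:{lineno}: unknown sequence {seq!r}")
            if start < 0 or end > layout.lengths[seq] or start >= end:
                raise BedGraphError(
                    f"{path}:{lineno}: interval {start}-{end} outside "
                    f"{seq} (length {layout.lengths[seq]}) or empty"
                )
            if value < 0:
                raise BedGraphError(f"{path}:{lineno}: negative coverage {value}")
            per_seq[seq].append((start, end, lineno))
            values[seq][start:end] = value
    for seq, ivs in per_seq.items():
        ivs.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise BedGraphError(
                    f"{path}: overlapping intervals on {seq} "
                    f"(lines {l1} and {l2})"
                )
    return CoverageTrack(layout=layout, values=values, label=label)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a dense track as run-length-encoded bedGraph; zero runs omitted."""
    with open(path, "w") as fh:
        for seq in track.layout.names:
            v = track.values[seq]
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0:
                    continue
                if val == int(val):
                    fh.write(f"{seq}\t{s}\t{e}\t{int(val)}\n")
                else:
                    fh.write(f"{seq}\t{s}\t{e}\t{val:.6g}\n")


def apply_exclusions(track: CoverageTrack, excl: ExclusionSet) -> CoverageTrack:
    """Zero and flag coverage inside excluded intervals (idempotent)."""
    excl.validate(track.layout)
    values = {s: v.copy() for s, v in track.values.items()}
    mask = {s: m.copy() for s, m in track.mask.items()}
    for seq, start, end in excl.intervals:
        values[seq][start:end] = 0.0
        mask[seq][start:end] = True
    return CoverageTrack(
        layout=track.layout, values=values, label=track.label, mask=mask
    )


# ---------------------------------------------------------------------------
# GFF3 / BED / FASTA
# ---------------------------------------------------------------------------

def read_gff3(path, feature_type: str = "gene") -> GeneAnnotation:
    """Load ORF records of ``feature_type`` from a GFF3 file via gffutils."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on duplicates
        raise AnnotationError(f"{path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type(feature_type):
        if "ID" not in feat.attributes:
            raise AnnotationError(
                f"{path}: {feature_type} feature at {feat.seqid}:"
                f"{feat.start}-{feat.end} has no ID attribute"
            )
        if feat.strand not in "+-":
            raise AnnotationError(
                f"{path}: feature {feat.id} has unsupported strand "
                f"{feat.strand!r}"
            )
        name = feat.attributes.get("Name", [""])[0]
        genes.append(
            Gene(
                gene_id=feat.attributes["ID"][0],
                seq=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand,
                name=name,
            )
        )
    return GeneAnnotation(genes)


def write_gff3(annot: GeneAnnotation, path, source: str = "itss") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annot:
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(
                f"{g.seq}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_bed_exclusions(path, layout: GenomeLayout | None = None) -> ExclusionSet:
    """Read a BED(3+) file of excluded features."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
        names=["seq", "start", "end"], dtype={"seq": str},
    )
    excl = ExclusionSet(
        [(r.seq, int(r.start), int(r.end)) for r in df.itertuples()]
    )
    if layout is not None:
        excl.validate(layout)
    return excl


def read_fasta(path) -> dict[str, str]:
    """Genome sequences as upper-case strings keyed by name."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_upstream(
    genome: dict[str, str],
    seq: str,
    anchor: int,
    strand: str,
    length: int = 300,
) -> tuple[str, bool]:
    """The ``length`` nt immediately 5' of ``anchor`` on ``strand``.

    ``anchor`` is a 0-based position; the extracted window excludes the anchor
    base itself.  On the minus strand "upstream" means higher coordinates and
    the sequence is returned reverse-complemented (5'→3' of the transcript).
    Windows running off the sequence end are truncated with a warning; the
    returned flag records truncation.
    """
    if seq not in genome:
        raise ValueError(f"unknown sequence {seq!r}")
    n = len(genome[seq])
    if not (0 <= anchor < n):
        raise ValueError(f"anchor {anchor} outside {seq} (length {n})")
    if strand == "+":
        lo, hi = anchor - length, anchor
        clo, chi = max(lo, 0), hi
        window = genome[seq][clo:chi]
    elif strand == "-":
        lo, hi = anchor + 1, anchor + 1 + length
        clo, chi = lo, min(hi, n)
        window = reverse_complement(genome[seq][clo:chi])
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    truncated = (chi - clo) < length
    if truncated:
        warnings.warn(
            f"upstream window at {seq}:{anchor}({strand}) truncated to "
            f"{chi - clo} nt",
            stacklevel=2,
        )
    return window, truncated


__all__ = [
    "AnnotationError",
    "BedGraphError",
    "CoverageTrack",
    "ExclusionSet",
    "Gene",
    "GeneAnnotation",
    "GenomeLayout",
    "apply_exclusions",
    "extract_upstream",
    "read_bed_exclusions",
    "read_bedgraph",
    "read_fasta",
    "read_gff3",
    "reverse_complement",
    "write_bedgraph",
    "write_fasta",
    "write_gff3",
]
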