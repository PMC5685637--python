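"""Synthetic genomes and coverage tracks with known ground truth.

The generator emulates the data structure the detection pipeline assumes:
every gene carries basal full-length transcription in the control sample;
a chosen subset gains an additional internally initiated transcript in the
test samples (a coverage plateau from an intra-ORF start position to the
gene's 3' end); a second subset acts as TES decoys, losing 3' coverage in the
test samples (a shape change that must be filtered out, not called); and
per-base counts carry negative-binomial noise.

Defaults encode a mid-scale study: a ~1.1 Mb two-chromosome genome carrying
200 genes with log-normally distributed basal depth (median 30x), 20 genes
induced four-fold from an internal start, three test samples, per-base NB
dispersion 1.  A consensus match for the bundled toy MSE matrix is written
into the genome 150 nt 5' of each planted internal TSS, the typical
promoter-proximal placement of the element.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .tracks_io import (
    CoverageTrack,
    ExclusionSet,
    Gene,
    GeneAnnotation,
    GenomeLayout,
    reverse_complement,
    write_bedgraph,
    write_fasta,
    write_gff3,
)

MSE_CONSENSUS = "GACACAAAAATA"  # consensus of the bundled synthetic toy MSE PWM


@dataclass
class SimSpec:
    """Parameters of one simulation; fully determined by ``seed``."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (560_000, 540_000)
    n_genes: int = 200
    gene_length: tuple[int, int] = (1000, 2500)
    intergenic: tuple[int, int] = (2000, 3000)
    # basal depth: log-normal across genes (median exp(mu)), clipped
    basal_log_mu: float = math.log(30.0)
    basal_log_sigma: float = 1.0
    basal_range: tuple[float, float] = (5.0, 400.0)
    # broad condition response (full-length up/down regulation in the test
    # samples, emulating developmental transcriptome remodeling; read totals
    # stay roughly balanced between conditions)
    frac_upregulated: float = 0.28
    up_fold: tuple[float, float] = (1.4, 2.2)
    frac_downregulated: float = 0.30
    down_fold: tuple[float, float] = (0.15, 0.55)
    # internally induced genes
    n_internal: int = 20
    internal_basal: tuple[float, float] = (20.0, 30.0)
    internal_fold: float = 4.0
    internal_offset_frac: tuple[float, float] = (0.3, 0.7)
    internal_margin: int = 180  # min distance of planted TSS from ORF ends
    tss_jitter: int = 5  # per-sample plateau-start jitter (± nt)
    # TES decoys: coverage lost 3' of a planted position in test samples
    n_tes_decoys: int = 0
    decoy_pos_frac: tuple[float, float] = (0.3, 0.7)
    # pervasive low-level background transcription (mean depth, genome-wide)
    background_depth: float = 3.0
    # noise: per-base NB with mean m and var m + m^2/dispersion; None = exact
    nb_dispersion: float | None = 20.0
    n_test: int = 3
    # motif planting
    plant_motif: bool = True
    motif_consensus: str = MSE_CONSENSUS
    motif_gap: int = 150  # nt between motif 3' end and the planted TSS
    # a high-coverage excluded locus (rDNA-like) to exercise masking
    excluded_locus: bool = True
    excluded_length: int = 6000
    excluded_depth: float = 2000.0

    def validate(self) -> None:
        problems = []
        if self.n_internal + self.n_tes_decoys > self.n_genes:
            problems.append("n_internal + n_tes_decoys exceeds n_genes")
        if self.internal_fold < 1:
            problems.append("internal_fold must be >= 1")
        if self.gene_length[0] < 2 * self.internal_margin:
            problems.append("genes too short for the internal-TSS margin")
        if self.tss_jitter < 0:
            problems.append("tss_jitter must be >= 0")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            problems.append("nb_dispersion must be positive or None")
        if problems:
            raise ValueError("invalid SimSpec: " + "; ".join(problems))


@dataclass
class TruthRecord:
    gene_id: str
    seq: str
    start: int
    end: int
    strand: str
    basal: float
    internal: bool = False
    internal_tss: int | None = None  # genomic, 0-based, before jitter
    fold: float | None = None
    tes_decoy: bool = False
    decoy_pos: int | None = None
    motif_pos: int | None = None  # left end of the planted consensus
    regulation_fold: float = 1.0  # full-length expression change in tests


@dataclass
class TruthSet:
    records: list[TruthRecord]

    @property
    def induced(self) -> list[TruthRecord]:
        return [r for r in self.records if r.internal]

    @property
    def decoys(self) -> list[TruthRecord]:
        return [r for r in self.records if r.tes_decoy]

    def __getitem__(self, gene_id: str) -> TruthRecord:
        return next(r for r in self.records if r.gene_id == gene_id)


@dataclass
class SimResult:
    spec: SimSpec
    layout: GenomeLayout
    genome: dict[str, str]
    annotation: GeneAnnotation
    exclusions: ExclusionSet
    control: CoverageTrack
    tests: list[CoverageTrack]
    truth: TruthSet


def _sample_counts(mean: np.ndarray, dispersion: float | None, rng) -> np.ndarray:
    """NB(mean m, dispersion r): var = m + m^2/r.  dispersion=None → exact."""
    if dispersion is None:
        return mean.copy()
    out = np.zeros_like(mean)
    pos = mean > 0
    m = mean[pos]
    p = dispersion / (dispersion + m)
    out[pos] = rng.negative_binomial(dispersion, p)
    return out


def _place_genes(spec: SimSpec, rng) -> list[Gene]:
    genes: list[Gene] = []
    gid = 0
    for ci, clen in enumerate(spec.chrom_lengths):
        seq = f"chrS{ci + 1}"
        cursor = int(rng.integers(spec.intergenic[0], spec.intergenic[1] + 1))
        if ci == 0 and spec.excluded_locus:
            # keep genes clear of the masked high-coverage locus
            cursor += 500 + spec.excluded_length
        while gid < spec.n_genes:
            glen = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
            gap = int(rng.integers(spec.intergenic[0], spec.intergenic[1] + 1))
            if cursor + glen + gap > clen:
                break
            gid += 1
            genes.append(
                Gene(
                    gene_id=f"G{gid:04d}",
                    seq=seq,
                    start=cursor,
                    end=cursor + glen,
                    strand="+" if rng.random() < 0.5 else "-",
                    name=f"SYN{gid}",
                )
            )
            cursor += glen + gap
        if gid >= spec.n_genes:
            break
    if gid < spec.n_genes:
        raise ValueError(
            f"genome too small: placed only {gid} of {spec.n_genes} genes"
        )
    return genes


def simulate(spec: SimSpec) -> SimResult:
    """Generate genome, annotation, exclusions, coverage tracks and truth.

    All randomness derives from ``spec.seed``; the same spec yields
    byte-identical outputs.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_layout, rng_seq, rng_noise = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]
    layout = GenomeLayout(
        {f"chrS{i + 1}": n for i, n in enumerate(spec.chrom_lengths)}
    )
    genes = _place_genes(spec, rng_layout)

    # per-gene basal depth
    basal = np.exp(
        rng_layout.normal(spec.basal_log_mu, spec.basal_log_sigma, len(genes))
    )
    basal = np.clip(basal, *spec.basal_range)

    # choose induced genes and TES decoys (disjoint), among long-enough genes
    eligible = [
        i for i, g in enumerate(genes) if g.length >= 2 * spec.internal_margin
    ]
    picked = rng_layout.choice(
        eligible, size=spec.n_internal + spec.n_tes_decoys, replace=False
    )
    induced_idx = set(int(i) for i in picked[: spec.n_internal])
    decoy_idx = set(int(i) for i in picked[spec.n_internal :])

    # condition-responsive genes (disjoint from the planted classes)
    rest = [i for i in range(len(genes)) if i not in induced_idx and i not in decoy_idx]
    n_up = int(round(spec.frac_upregulated * len(genes)))
    n_down = int(round(spec.frac_downregulated * len(genes)))
    regulated = rng_layout.choice(rest, size=min(n_up + n_down, len(rest)), replace=False)
    up_idx = set(int(i) for i in regulated[:n_up])
    down_idx = set(int(i) for i in regulated[n_up:])

    records: list[TruthRecord] = []
    for i, g in enumerate(genes):
        rec = TruthRecord(
            gene_id=g.gene_id, seq=g.seq, start=g.start, end=g.end,
            strand=g.strand, basal=float(basal[i]),
        )
        if i in induced_idx:
            rec.internal = True
            rec.basal = float(
                rng_layout.uniform(*spec.internal_basal)
            )
            frac = rng_layout.uniform(*spec.internal_offset_frac)
            off = int(round(frac * g.length))
            off = min(max(off, spec.internal_margin), g.length - spec.internal_margin)
            # genomic TSS: offset counted from the biological 5' end of the ORF
            rec.internal_tss = g.start + off if g.strand == "+" else g.end - 1 - off
            rec.fold = spec.internal_fold
        if i in decoy_idx:
            rec.tes_decoy = True
            frac = rng_layout.uniform(*spec.decoy_pos_frac)
            off = int(round(frac * g.length))
            rec.decoy_pos = g.start + off if g.strand == "+" else g.end - 1 - off
        if i in up_idx:
            rec.regulation_fold = float(rng_layout.uniform(*spec.up_fold))
        elif i in down_idx:
            rec.regulation_fold = float(rng_layout.uniform(*spec.down_fold))
        records.append(rec)

    # genome sequence, with planted motif consensus 5' of each true TSS
    genome: dict[str, str] = {}
    for seq, n in layout.lengths.items():
        genome[seq] = "".join(
            np.array(list("ACGT"))[rng_seq.integers(0, 4, n)]
        )
    if spec.plant_motif:
        motif = spec.motif_consensus
        for rec in records:
            if not rec.internal:
                continue
            if rec.strand == "+":
                left = rec.internal_tss - spec.motif_gap - len(motif)
                planted = motif
            else:
                left = rec.internal_tss + spec.motif_gap + 1
                planted = reverse_complement(motif)
            s = genome[rec.seq]
            genome[rec.seq] = s[:left] + planted + s[left + len(motif) :]
            rec.motif_pos = left

    # excluded high-coverage locus at the start of chromosome 1
    excl_intervals: list[tuple[str, int, int]] = []
    if spec.excluded_locus:
        first = layout.names[0]
        excl_intervals.append((first, 500, 500 + spec.excluded_length))
    exclusions = ExclusionSet(excl_intervals)

    # mean coverage profiles
    def base_mean() -> dict[str, np.ndarray]:
        mean = {
            s: np.full(n, spec.background_depth)
            for s, n in layout.lengths.items()
        }
        for rec in records:
            mean[rec.seq][rec.start : rec.end] += rec.basal
        for seq, s0, s1 in excl_intervals:
            mean[seq][s0:s1] += spec.excluded_depth
        return mean

    ctrl_mean = base_mean()
    control = CoverageTrack(
        layout=layout,
        values={
            s: _sample_counts(ctrl_mean[s], spec.nb_dispersion, rng_noise)
            for s in layout.names
        },
        label="control",
    )

    tests: list[CoverageTrack] = []
    for t in range(spec.n_test):
        mean = base_mean()
        for rec in records:
            if rec.regulation_fold != 1.0:
                mean[rec.seq][rec.start : rec.end] += rec.basal * (
                    rec.regulation_fold - 1.0
                )
            if rec.internal:
                jitter = (
                    int(rng_noise.integers(-spec.tss_jitter, spec.tss_jitter + 1))
                    if spec.tss_jitter
                    else 0
                )
                tss = rec.internal_tss + jitter
                extra = rec.basal * (rec.fold - 1.0)
                if rec.strand == "+":
                    mean[rec.seq][tss : rec.end] += extra
                else:
                    mean[rec.seq][rec.start : tss + 1] += extra
            if rec.tes_decoy:
                # transcription of the gene is lost 3' of the decoy position;
                # background transcription remains
                if rec.strand == "+":
                    mean[rec.seq][rec.decoy_pos : rec.end] -= rec.basal
                else:
                    mean[rec.seq][rec.start : rec.decoy_pos + 1] -= rec.basal
        tests.append(
            CoverageTrack(
                layout=layout,
                values={
                    s: _sample_counts(mean[s], spec.nb_dispersion, rng_noise)
                    for s in layout.names
                },
                label=f"test_{t + 1}",
            )
        )

    return SimResult(
        spec=spec,
        layout=layout,
        genome=genome,
        annotation=GeneAnnotation(genes),
        exclusions=exclusions,
        control=control,
        tests=tests,
        truth=TruthSet(records),
    )


def write_outputs(sim: SimResult, outdir) -> dict[str, Path]:
    """Write every artifact the pipeline consumes, plus the truth set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "genes.gff3",
        "exclusions": outdir / "exclude.bed",
        "control": outdir / "control.bedgraph",
        "truth": outdir / "truth.json",
    }
    write_fasta(sim.genome, paths["genome"])
    write_gff3(sim.annotation, paths["annotation"])
    with open(paths["exclusions"], "w") as fh:
        for seq, s0, s1 in sim.exclusions.intervals:
            fh.write(f"{seq}\t{s0}\t{s1}\texcluded\n")
    write_bedgraph(sim.control, paths["control"])
    for t in sim.tests:
        p = outdir / f"{t.label}.bedgraph"
        write_bedgraph(t, p)
        paths[t.label] = p
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"spec": asdict(sim.spec), "genes": [asdict(r) for r in sim.truth.records]},
            fh,
            indent=1,
        )
    return paths


def load_truth(path) -> TruthSet:
    with open(path) as fh:
        payload = json.load(fh)
    return TruthSet([TruthRecord(**rec) for rec in payload["genes"]])


@dataclass
class RecoveryScore:
    n_calls: int
    n_planted: int
    true_positive_calls: int
    recovered_genes: int
    precision: float
    recall: float
    mean_abs_error: float | None  # nt, over true-positive calls
    vacuous_precision: bool = False


def score_against_truth(calls, truth: TruthSet, tolerance: int = 100) -> RecoveryScore:
    """Precision/recall of internal-TSS calls against the planted truth.

    A call is a true positive when its host gene was induced and its
    consensus TSS lies within ``tolerance`` nt of the planted start.  With
    zero calls precision is vacuously 1.0 (flagged).
    """
    planted = {r.gene_id: r for r in truth.induced}
    tp = 0
    recovered = set()
    errors = []
    for call in calls:
        rec = planted.get(call.gene.gene_id)
        if rec is None:
            continue
        err = abs(call.call.tss - rec.internal_tss)
        if err <= tolerance:
            tp += 1
            recovered.add(rec.gene_id)
            errors.append(err)
    n_calls = len(calls)
    vacuous = n_calls == 0
    return RecoveryScore(
        n_calls=n_calls,
        n_planted=len(planted),
        true_positive_calls=tp,
        recovered_genes=len(recovered),
        precision=1.0 if vacuous else tp / n_calls,
        recall=(len(recovered) / len(planted)) if planted else 0.0,
        mean_abs_error=(sum(errors) / len(errors)) if errors else None,
        vacuous_precision=vacuous,
    )


__all__ = [
    "MSE_CONSENSUS",
    "RecoveryScore",
    "SimResult",
    "SimSpec",
    "TruthRecord",
    "TruthSet",
    "load_truth",
    "score_against_truth",
    "simulate",
    "write_outputs",
]
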