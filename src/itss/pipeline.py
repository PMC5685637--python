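"""End-to-end orchestration of the internal-TSS detection flow.

Stages mirror the analytical flowchart: per-sample shape analysis and contig
calling (``scan_sample``/``scan_all``), cross-sample consensus and internal
classification (``call_consensus``), and upstream motif flagging with
enrichment testing (``annotate_motifs``).  ``run_all`` chains the three on
in-memory objects; the CLI drives the same functions from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import contig_caller, consensus_annotator, motif_enrichment, shape_signal
from .config import RunConfig
from .contig_caller import TranscriptContig
from .consensus_annotator import ConsensusCall, InternalTSSCall
from .motif_enrichment import EnrichmentResult, MotifModel
from .tracks_io import (
    CoverageTrack,
    ExclusionSet,
    GeneAnnotation,
    apply_exclusions,
)


@dataclass
class ScanResult:
    contigs: dict[str, list[TranscriptContig]]
    stage_counts: dict[str, dict[str, int]]


@dataclass
class CallResult:
    consensus: list[ConsensusCall]
    internal: list[InternalTSSCall]
    n_clusters: int = 0
    n_discarded: int = 0


@dataclass
class MotifResult:
    internal: list[InternalTSSCall]
    enrichment: dict[str, EnrichmentResult] = field(default_factory=dict)


def scan_sample(
    ctrl: CoverageTrack,
    test: CoverageTrack,
    annot: GeneAnnotation | None,
    config: RunConfig | None = None,
) -> tuple[list[TranscriptContig], dict[str, int]]:
    """Smooth, normalize, window-compare and call contigs for one test sample."""
    cfg = config or RunConfig()
    ctrl_sm = shape_signal.normalized_smoothed(ctrl, cfg.sigma, cfg.kernel_mass)
    test_sm = shape_signal.normalized_smoothed(test, cfg.sigma, cfg.kernel_mass)
    diff = shape_signal.shape_difference(ctrl_sm, test_sm, cfg.window, cfg.step)
    return contig_caller.call_sample(
        ctrl_sm,
        test_sm,
        diff,
        annot,
        sample=test.label,
        tes_flank=cfg.tes_flank,
        rmsd_floor_pct=cfg.rmsd_floor_percentile,
        sum_band=cfg.coverage_sum_band,
        diff_pct=cfg.contig_scan_percentile,
        merge_proximity=cfg.merge_proximity,
        merge_fold=cfg.merge_fold,
    )


def scan_all(
    ctrl: CoverageTrack,
    tests: list[CoverageTrack],
    annot: GeneAnnotation | None,
    excl: ExclusionSet | None = None,
    config: RunConfig | None = None,
) -> ScanResult:
    cfg = config or RunConfig()
    if excl is not None:
        ctrl = apply_exclusions(ctrl, excl)
        tests = [apply_exclusions(t, excl) for t in tests]
    contigs: dict[str, list[TranscriptContig]] = {}
    counts: dict[str, dict[str, int]] = {}
    for i, test in enumerate(tests):
        label = test.label or f"test_{i + 1}"
        ranked, stage = scan_sample(ctrl, test, annot, cfg)
        contigs[label] = ranked
        counts[label] = stage
    return ScanResult(contigs=contigs, stage_counts=counts)


def call_consensus(
    per_sample: dict[str, list[TranscriptContig]],
    annot: GeneAnnotation,
    config: RunConfig | None = None,
) -> CallResult:
    """Cross-sample consensus, filtering, and ORF-internal classification."""
    cfg = config or RunConfig()
    if len(per_sample) < cfg.min_support:
        raise ValueError(
            f"need >= {cfg.min_support} samples; contigs identified in only "
            "one sample are discarded"
        )
    clusters = consensus_annotator.match_across_samples(
        per_sample, proximity=cfg.match_proximity
    )
    consensus = []
    discarded = 0
    for cluster in clusters:
        call = consensus_annotator.build_consensus(
            cluster, max_span=cfg.max_contig, min_support=cfg.min_support
        )
        if call is None:
            discarded += 1
        else:
            consensus.append(call)
    internal = consensus_annotator.classify_internal(
        consensus, annot, min_dist=cfg.internal_margin, rank_cut=cfg.rank_cutoff
    )
    return CallResult(
        consensus=consensus,
        internal=internal,
        n_clusters=len(clusters),
        n_discarded=discarded,
    )


def annotate_motifs(
    internal: list[InternalTSSCall],
    genome: dict[str, str],
    annot: GeneAnnotation,
    mse: MotifModel | None,
    urs1: MotifModel | None = None,
    config: RunConfig | None = None,
) -> MotifResult:
    """Flag MSE/URS1 sites upstream of each call and test enrichment."""
    cfg = config or RunConfig()
    calls = internal
    enrichment: dict[str, EnrichmentResult] = {}
    for attr, motif in (("mse", mse), ("urs1", urs1)):
        if motif is None:
            continue
        calls = motif_enrichment.flag_upstream_sites(
            calls, genome, motif, attr,
            window=cfg.upstream_window, threshold_frac=cfg.motif_threshold,
        )
        k = sum(1 for c in calls if getattr(c, attr))
        bg_k, bg_n = motif_enrichment.background_hit_count(
            annot, genome, motif,
            window=cfg.upstream_window, threshold_frac=cfg.motif_threshold,
        )
        enrichment[motif.name] = motif_enrichment.exact_enrichment(
            k, len(calls), bg_k, bg_n, motif=motif.name
        )
    return MotifResult(internal=calls, enrichment=enrichment)


def run_all(
    ctrl: CoverageTrack,
    tests: list[CoverageTrack],
    annot: GeneAnnotation,
    genome: dict[str, str] | None = None,
    excl: ExclusionSet | None = None,
    mse: MotifModel | None = None,
    urs1: MotifModel | None = None,
    config: RunConfig | None = None,
) -> tuple[ScanResult, CallResult, MotifResult | None]:
    cfg = config or RunConfig()
    scan = scan_all(ctrl, tests, annot, excl, cfg)
    called = call_consensus(scan.contigs, annot, cfg)
    motifs = None
    if genome is not None and mse is not None:
        motifs = annotate_motifs(
            called.internal, genome, annot, mse, urs1, cfg
        )
        called.internal = motifs.internal
    return scan, called, motifs


__all__ = [
    "CallResult",
    "MotifResult",
    "ScanResult",
    "annotate_motifs",
    "call_consensus",
    "run_all",
    "scan_all",
    "scan_sample",
]
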