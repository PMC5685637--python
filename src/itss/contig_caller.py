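"""Peak calling, filtering, and transcript-contig construction for one sample.

Shape-difference peaks mark positions where the test transcriptome departs
from the control: both novel TSSs and novel TESs (3' ends) appear as peaks.
TES-like peaks — greater average coverage in the window immediately 5' of the
peak than immediately 3', in the orientation of transcription — are removed.
The remaining peaks must satisfy three criteria, all strict:

1. shape difference at the peak > median of all shape-difference values;
2. smoothed-coverage sum (control + test) at the peak strictly between the
   median and the 95th percentile of the genome-wide per-position sums;
3. smoothed-coverage difference (test − control) at the peak > the 90th
   percentile of the genome-wide per-position differences.

Each surviving peak seeds a transcript contig: positions 5' and 3' of the
peak are scanned base-by-base while the per-position difference stays at or
above the 90th-percentile threshold; the first sub-threshold position on each
side bounds the contig.  Nearby contigs (5' boundaries < 1 kb apart) of
similar expression (< 3-fold variation in averaged difference) are merged.
Contigs are scored by averaged difference × size and ranked (1 = best).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .shape_signal import ShapeDiffTrack, SmoothedTrack
from .tracks_io import GeneAnnotation

TSS_CANDIDATE = "TSS-candidate"
TES_LIKE = "TES-like"

MERGE_PROXIMITY = 1000
MERGE_FOLD = 3.0


@dataclass
class CandidatePeak:
    seq: str
    position: int  # window anchor (central base of the window), 0-based
    value: float  # shape-difference (RMSD) at the window
    classification: str = TSS_CANDIDATE
    strand: str | None = None  # transcription orientation, if resolvable
    flags: tuple[str, ...] = ()
    failed: tuple[str, ...] = ()  # criteria that rejected the peak


@dataclass(frozen=True)
class ThresholdSet:
    """Genome-wide pools' summary statistics used by the peak filters."""

    rmsd_median: float
    sum_median: float
    sum_p95: float
    diff_p90: float

    def __post_init__(self) -> None:
        for v in (self.rmsd_median, self.sum_median, self.sum_p95, self.diff_p90):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")
        if self.sum_median > self.sum_p95:
            raise ValueError("sum median exceeds its 95th percentile")


@dataclass
class TranscriptContig:
    """A called novel-transcript interval (0-based half-open span)."""

    seq: str
    start: int
    end: int
    strand: str | None
    avg_diff: float
    sample: str = ""
    rank: int = 0
    flags: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def score(self) -> float:
        return self.avg_diff * self.size

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' boundary (genomic position of the TSS)."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def tss(self) -> int:
        return self.five_prime


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def find_peaks(diff: ShapeDiffTrack) -> list[CandidatePeak]:
    """Local maxima of the per-window RMSD series.

    Equal-valued runs (plateaus) collapse to their middle window; a run is a
    peak iff it is strictly above both neighbouring runs.  The first and last
    windows of a sequence are never peaks (one-sided evidence), and peaks in
    windows overlapping the exclusion mask are dropped.
    """
    peaks: list[CandidatePeak] = []
    for seq in diff.layout.names:
        v = diff.values[seq]
        if len(v) < 3:
            continue
        run_starts = np.concatenate(([0], np.flatnonzero(np.diff(v)) + 1))
        run_ends = np.concatenate((run_starts[1:], [len(v)]))
        run_vals = v[run_starts]
        masked = diff.mask_flag[seq]
        half = diff.window // 2
        for i in range(1, len(run_vals) - 1):
            if run_vals[i] > run_vals[i - 1] and run_vals[i] > run_vals[i + 1]:
                mid = (run_starts[i] + run_ends[i] - 1) // 2
                if masked[mid]:
                    continue
                peaks.append(
                    CandidatePeak(
                        seq=seq,
                        position=int(mid * diff.step + half),
                        value=float(run_vals[i]),
                    )
                )
    return peaks


def _flank_mean(v: np.ndarray, lo: int, hi: int) -> float:
    lo, hi = max(lo, 0), min(hi, len(v))
    if hi <= lo:
        return 0.0
    return float(v[lo:hi].mean())


def _is_tes_like(v: np.ndarray, pos: int, strand: str, flank: int) -> bool:
    left = _flank_mean(v, pos - flank, pos)
    right = _flank_mean(v, pos + 1, pos + 1 + flank)
    if strand == "+":
        five, three = left, right
    else:
        five, three = right, left
    return five > three


def classify_tes(
    peak: CandidatePeak,
    test: SmoothedTrack,
    annot: GeneAnnotation | None,
    flank: int = 150,
) -> CandidatePeak:
    """Label a peak TES-like if coverage falls off in transcription direction.

    A TES shows more test coverage immediately 5' of the peak than immediately
    3'.  The orientation comes from the annotated genes overlapping the peak's
    window footprint (the shape change a window reports can sit up to half a
    window from the gene whose transcript produced it); where no gene
    overlaps, both orientations are evaluated and the peak is retained only
    if it is TSS-like in at least one (flagged strand-ambiguous).
    """
    v = test.values[peak.seq]
    half = flank // 2
    genes = (
        annot.overlapping(peak.seq, peak.position - half, peak.position + half + 1)
        if annot
        else []
    )
    strands = sorted({g.strand for g in genes})
    if len(strands) == 1:
        tes = _is_tes_like(v, peak.position, strands[0], flank)
        return replace(
            peak,
            strand=strands[0],
            classification=TES_LIKE if tes else TSS_CANDIDATE,
        )
    flags = peak.flags + ("strand-ambiguous",)
    tes_plus = _is_tes_like(v, peak.position, "+", flank)
    tes_minus = _is_tes_like(v, peak.position, "-", flank)
    if tes_plus and tes_minus:  # unreachable unless flanks tie; defensive
        return replace(peak, classification=TES_LIKE, flags=flags)
    if tes_plus != tes_minus:
        # TSS-like in exactly one orientation: adopt it
        strand = "-" if tes_plus else "+"
        return replace(peak, strand=strand, classification=TSS_CANDIDATE, flags=flags)
    return replace(peak, classification=TSS_CANDIDATE, flags=flags)


# ---------------------------------------------------------------------------
# thresholds and filtering
# ---------------------------------------------------------------------------

def compute_thresholds(
    ctrl: SmoothedTrack,
    test: SmoothedTrack,
    diff: ShapeDiffTrack,
    rmsd_floor_pct: float = 50.0,
    sum_band: tuple[float, float] = (50.0, 95.0),
    diff_pct: float = 90.0,
) -> ThresholdSet:
    """Genome-wide percentile thresholds (linear-interpolation definition).

    Pools are global: all unmasked window RMSD values, and all unmasked
    per-position coverage sums and differences.
    """
    rmsd_pool = np.concatenate(
        [diff.values[s][~diff.mask_flag[s]] for s in diff.layout.names]
    )
    unmasked = {
        s: ~(ctrl.mask[s] | test.mask[s]) for s in ctrl.layout.names
    }
    sum_pool = np.concatenate(
        [(ctrl.values[s] + test.values[s])[unmasked[s]] for s in ctrl.layout.names]
    )
    diff_pool = np.concatenate(
        [(test.values[s] - ctrl.values[s])[unmasked[s]] for s in ctrl.layout.names]
    )
    if rmsd_pool.size == 0 or sum_pool.size == 0:
        raise ValueError("empty threshold pool (everything masked?)")
    return ThresholdSet(
        rmsd_median=float(np.percentile(rmsd_pool, rmsd_floor_pct)),
        sum_median=float(np.percentile(sum_pool, sum_band[0])),
        sum_p95=float(np.percentile(sum_pool, sum_band[1])),
        diff_p90=float(np.percentile(diff_pool, diff_pct)),
    )


def filter_candidates(
    peaks: list[CandidatePeak],
    thresholds: ThresholdSet,
    ctrl: SmoothedTrack,
    test: SmoothedTrack,
) -> list[CandidatePeak]:
    """Apply the three strict criteria; TES-like peaks never survive.

    Every peak comes back annotated with the criteria it failed; the caller
    keeps those with an empty failure list and TSS-candidate classification.
    """
    out = []
    for p in peaks:
        failed: list[str] = []
        if p.classification == TES_LIKE:
            out.append(replace(p, failed=("tes",)))
            continue
        c = ctrl.values[p.seq][p.position]
        t = test.values[p.seq][p.position]
        if not p.value > thresholds.rmsd_median:
            failed.append("rmsd>median")
        s = c + t
        if not (thresholds.sum_median < s < thresholds.sum_p95):
            failed.append("sum-in-band")
        if not (t - c) > thresholds.diff_p90:
            failed.append("diff>p90")
        out.append(replace(p, failed=tuple(failed)))
    return out


def surviving(peaks: list[CandidatePeak]) -> list[CandidatePeak]:
    return [p for p in peaks if not p.failed and p.classification == TSS_CANDIDATE]


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------

def build_contig(
    peak: CandidatePeak,
    ctrl: SmoothedTrack,
    test: SmoothedTrack,
    thresholds: ThresholdSet,
    sample: str = "",
) -> TranscriptContig:
    """Expand a surviving peak into a contig bounded by sub-p90 positions."""
    d = test.values[peak.seq] - ctrl.values[peak.seq]
    thr = thresholds.diff_p90
    n = len(d)
    lo = peak.position
    while lo - 1 >= 0 and d[lo - 1] >= thr:
        lo -= 1
    hi = peak.position
    while hi + 1 < n and d[hi + 1] >= thr:
        hi += 1
    flags = list(peak.flags)
    if lo == 0:
        flags.append("clamped-5p")
    if hi == n - 1:
        flags.append("clamped-3p")
    if lo == hi:
        flags.append("single-base")
    return TranscriptContig(
        seq=peak.seq,
        start=int(lo),
        end=int(hi) + 1,
        strand=peak.strand,
        avg_diff=float(d[lo : hi + 1].mean()),
        sample=sample,
        flags=tuple(flags),
    )


def _strand_compatible(a: str | None, b: str | None) -> bool:
    return a is None or b is None or a == b


def _similar_expression(a: float, b: float, fold: float = MERGE_FOLD) -> bool:
    """Less-than-``fold`` variation; defined only for positive levels."""
    if a <= 0 or b <= 0:
        return False
    return max(a, b) / min(a, b) < fold


def merge_contigs(
    contigs: list[TranscriptContig],
    ctrl: SmoothedTrack,
    test: SmoothedTrack,
    proximity: int = MERGE_PROXIMITY,
    fold: float = MERGE_FOLD,
) -> list[TranscriptContig]:
    """Iteratively merge close, similarly expressed contigs to a fixed point.

    Two contigs merge when their strand-aware 5' boundaries are strictly less
    than ``proximity`` nt apart, their averaged differences vary by strictly
    less than ``fold``, and their strand contexts are compatible.  The merged
    contig spans the union and its averaged difference is recomputed over the
    union span.  Processing runs 5'→3' and repeats until no pair merges.
    """
    work = sorted(contigs, key=lambda c: (c.seq, c.start, c.end))
    changed = True
    while changed:
        changed = False
        out: list[TranscriptContig] = []
        for c in work:
            merged = False
            for i, prev in enumerate(out):
                if prev.seq != c.seq:
                    continue
                if abs(prev.five_prime - c.five_prime) >= proximity:
                    continue
                if not _strand_compatible(prev.strand, c.strand):
                    continue
                if not _similar_expression(prev.avg_diff, c.avg_diff, fold):
                    continue
                start = min(prev.start, c.start)
                end = max(prev.end, c.end)
                d = test.values[c.seq] - ctrl.values[c.seq]
                strand = prev.strand if prev.strand is not None else c.strand
                out[i] = TranscriptContig(
                    seq=c.seq,
                    start=start,
                    end=end,
                    strand=strand,
                    avg_diff=float(d[start:end].mean()),
                    sample=c.sample or prev.sample,
                    flags=tuple(sorted(set(prev.flags + c.flags))),
                )
                merged = True
                changed = True
                break
            if not merged:
                out.append(c)
        work = sorted(out, key=lambda c: (c.seq, c.start, c.end))
    return work


def score_and_rank(contigs: list[TranscriptContig]) -> list[TranscriptContig]:
    """Rank by confidence score (averaged difference × size), 1 = highest.

    Ties break deterministically: score descending, then 5'-most genomic
    coordinate ascending, then sequence name.
    """
    ordered = sorted(contigs, key=lambda c: (-c.score, c.start, c.seq))
    return [replace(c, rank=i + 1) for i, c in enumerate(ordered)]


def call_sample(
    ctrl: SmoothedTrack,
    test: SmoothedTrack,
    diff: ShapeDiffTrack,
    annot: GeneAnnotation | None,
    sample: str = "",
    tes_flank: int = 150,
    rmsd_floor_pct: float = 50.0,
    sum_band: tuple[float, float] = (50.0, 95.0),
    diff_pct: float = 90.0,
    merge_proximity: int = MERGE_PROXIMITY,
    merge_fold: float = MERGE_FOLD,
) -> tuple[list[TranscriptContig], dict[str, int]]:
    """Full single-sample flow: peaks → TES removal → criteria → contigs.

    Returns ranked merged contigs and a stage-count log.
    """
    peaks = find_peaks(diff)
    classified = [classify_tes(p, test, annot, flank=tes_flank) for p in peaks]
    thresholds = compute_thresholds(
        ctrl, test, diff, rmsd_floor_pct=rmsd_floor_pct,
        sum_band=sum_band, diff_pct=diff_pct,
    )
    filtered = filter_candidates(classified, thresholds, ctrl, test)
    kept = surviving(filtered)
    contigs = [build_contig(p, ctrl, test, thresholds, sample=sample) for p in kept]
    merged = merge_contigs(contigs, ctrl, test, proximity=merge_proximity, fold=merge_fold)
    ranked = score_and_rank(merged)
    counts = {
        "peaks": len(peaks),
        "tes_removed": sum(1 for p in classified if p.classification == TES_LIKE),
        "passed_filters": len(kept),
        "contigs": len(contigs),
        "merged": len(ranked),
    }
    return ranked, counts


CONTIG_COLUMNS = [
    "seq", "start", "end", "strand", "tss", "avg_diff", "size", "score",
    "rank", "sample", "flags",
]


def write_contig_table(contigs: list[TranscriptContig], path) -> None:
    """Per-sample contig table (TSV), rank-sorted; coordinates 1-based."""
    with open(path, "w") as fh:
        fh.write("\t".join(CONTIG_COLUMNS) + "\n")
        for c in sorted(contigs, key=lambda c: c.rank):
            fh.write(
                "\t".join(
                    [
                        c.seq, str(c.start + 1), str(c.end),
                        c.strand or ".", str(c.tss + 1),
                        f"{c.avg_diff:.8g}", str(c.size), f"{c.score:.8g}",
                        str(c.rank), c.sample, ",".join(c.flags),
                    ]
                )
                + "\n"
            )


def read_contig_table(path) -> list[TranscriptContig]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"seq": str, "flags": str})
    out = []
    for r in df.itertuples():
        out.append(
            TranscriptContig(
                seq=r.seq,
                start=int(r.start) - 1,
                end=int(r.end),
                strand=None if r.strand == "." else r.strand,
                avg_diff=float(r.avg_diff),
                sample=str(r.sample),
                rank=int(r.rank),
                flags=tuple(str(r.flags).split(","))
                if isinstance(r.flags, str) and r.flags
                else (),
            )
        )
    return out


def write_contig_bed(contigs: list[TranscriptContig], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(contigs, key=lambda c: (c.seq, c.start)):
            fh.write(
                f"{c.seq}\t{c.start}\t{c.end}\tcontig_r{c.rank}\t"
                f"{c.rank}\t{c.strand or '.'}\n"
            )


__all__ = [
    "CandidatePeak",
    "TES_LIKE",
    "TSS_CANDIDATE",
    "ThresholdSet",
    "TranscriptContig",
    "build_contig",
    "call_sample",
    "classify_tes",
    "compute_thresholds",
    "filter_candidates",
    "find_peaks",
    "merge_contigs",
    "score_and_rank",
    "surviving",
]
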