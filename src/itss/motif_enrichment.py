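"""PWM scanning of internal-TSS upstream windows and exact enrichment tests.

A count (or probability) matrix is converted to log-odds weights against a
uniform background with a pseudocount, and sequences are scored on both
strands at every offset.  Sites are called where the relative score — the
fraction of the attainable score range, (score − min)/(max − min) — strictly
exceeds a threshold (0.85 by default).

Enrichment is tested at the gene level (a gene either has ≥1 site in its
window or not) with a two-sided Fisher's exact test: genes with internal
TSSs, scanned 300 nt upstream of the 3' end of the possible TSS range,
against all annotated genes scanned 300 nt upstream of the ORF start.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.stats import fisher_exact

from .consensus_annotator import InternalTSSCall, _round_half_up
from .tracks_io import GeneAnnotation, extract_upstream

BASES = "ACGT"
DEFAULT_THRESHOLD = 0.85
DEFAULT_UPSTREAM = 300
DEFAULT_PSEUDOCOUNT = 0.25


class MotifFormatError(ValueError):
    pass


@dataclass(frozen=True)
class MotifModel:
    """Log-odds position weight matrix over {A,C,G,T}."""

    name: str
    weights: np.ndarray  # shape (L, 4)

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise MotifFormatError("weight matrix must be L x 4")
        if self.weights.shape[0] < 1:
            raise MotifFormatError("motif must have length >= 1")
        if not np.all(np.isfinite(self.weights)):
            raise MotifFormatError("weights must be finite")
        if self.max_score <= self.min_score:
            raise MotifFormatError(
                f"degenerate motif {self.name!r}: score range is zero"
            )

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def relative(self, score: float) -> float:
        return (score - self.min_score) / (self.max_score - self.min_score)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    label: str
    offset: int  # 0-based offset of the site's left end on the given sequence
    strand: str
    score: float
    relative: float


@dataclass(frozen=True)
class EnrichmentResult:
    motif: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    p_value: float

    def table(self) -> list[list[int]]:
        return [
            [self.fg_hits, self.fg_total - self.fg_hits],
            [self.bg_hits, self.bg_total - self.bg_hits],
        ]


def pwm_to_logodds(
    counts: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: float = 0.25,
) -> np.ndarray:
    """Column-normalized counts + pseudocount → natural-log odds weights."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise MotifFormatError("negative counts")
    if pseudocount <= 0 and np.any(counts.sum(axis=1) == 0):
        raise MotifFormatError("zero column requires a positive pseudocount")
    padded = counts + pseudocount
    probs = padded / padded.sum(axis=1, keepdims=True)
    return np.log(probs / background)


def load_pwm(
    path,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: float = 0.25,
) -> MotifModel:
    """Load a JASPAR/pfm count matrix and convert it to log-odds weights."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        try:
            m = bio_motifs.read(fh, "jaspar")
        except Exception as exc:
            raise MotifFormatError(f"{path}: {exc}") from exc
    counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
    name = m.name or Path(str(path)).stem
    return MotifModel(name=name, weights=pwm_to_logodds(counts, pseudocount, background))


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T → 0..3; anything else → 4 (scores as the column minimum)."""
    table = np.full(128, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[codes]


def _scan_strand(codes: np.ndarray, w5: np.ndarray) -> np.ndarray:
    length = w5.shape[0]
    n = len(codes) - length + 1
    scores = np.zeros(n)
    for j in range(length):
        scores += w5[j, codes[j : j + n]]
    return scores


def scan(
    seq: str,
    motif: MotifModel,
    threshold_frac: float = DEFAULT_THRESHOLD,
    label: str = "",
) -> list[MotifHit]:
    """Score every offset on both strands; keep relative score > threshold.

    Offsets of minus-strand hits refer to the left end of the site on the
    given (forward) sequence.  Sequences shorter than the motif yield an
    empty result.
    """
    L = motif.length
    if len(seq) < L:
        import warnings

        warnings.warn(
            f"sequence {label or '<unnamed>'} shorter than motif "
            f"{motif.name} ({len(seq)} < {L})",
            stacklevel=2,
        )
        return []
    w5 = np.hstack([motif.weights, motif.weights.min(axis=1, keepdims=True)])
    codes = _encode(seq)
    # minus strand = scan with the reverse-complemented matrix
    rc = w5[::-1, [3, 2, 1, 0, 4]]
    hits = []
    for strand, weights in (("+", w5), ("-", rc)):
        scores = _scan_strand(codes, weights)
        rel = (scores - motif.min_score) / (motif.max_score - motif.min_score)
        for off in np.flatnonzero(rel > threshold_frac):
            hits.append(
                MotifHit(
                    label=label,
                    offset=int(off),
                    strand=strand,
                    score=float(scores[off]),
                    relative=float(rel[off]),
                )
            )
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def best_hit(seq: str, motif: MotifModel, label: str = "") -> MotifHit | None:
    """Highest-scoring site regardless of threshold (None if seq too short)."""
    all_hits = scan(seq, motif, threshold_frac=-np.inf, label=label)
    if not all_hits:
        return None
    return max(all_hits, key=lambda h: h.score)


# ---------------------------------------------------------------------------
# flagging and enrichment
# ---------------------------------------------------------------------------

def upstream_anchor(call: InternalTSSCall) -> int:
    """Genomic position of the 3'-most possible TSS (mean + range, by strand)."""
    r = _round_half_up(call.call.tss_range)
    if call.gene.strand == "+":
        return call.call.tss + r
    return call.call.tss - r


def flag_upstream_sites(
    calls: list[InternalTSSCall],
    genome: dict[str, str],
    motif: MotifModel,
    attr: str,
    window: int = DEFAULT_UPSTREAM,
    threshold_frac: float = DEFAULT_THRESHOLD,
) -> list[InternalTSSCall]:
    """Set ``attr`` ("mse" or "urs1") per call from its upstream window."""
    out = []
    for call in calls:
        anchor = upstream_anchor(call)
        seq, _trunc = extract_upstream(
            genome, call.gene.seq, anchor, call.gene.strand, window
        )
        hits = scan(seq, motif, threshold_frac, label=call.gene.gene_id)
        out.append(replace(call, **{attr: bool(hits)}))
    return out


def background_hit_count(
    annot: GeneAnnotation,
    genome: dict[str, str],
    motif: MotifModel,
    window: int = DEFAULT_UPSTREAM,
    threshold_frac: float = DEFAULT_THRESHOLD,
) -> tuple[int, int]:
    """Genes whose 300-nt ORF-upstream window holds ≥1 site, over all genes."""
    import warnings

    k = 0
    for gene in annot:
        anchor = gene.start if gene.strand == "+" else gene.end - 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seq, _ = extract_upstream(genome, gene.seq, anchor, gene.strand, window)
            if scan(seq, motif, threshold_frac, label=gene.gene_id):
                k += 1
    return k, len(annot)


def exact_enrichment(k: int, n: int, K: int, N: int, motif: str = "") -> EnrichmentResult:
    """Two-sided Fisher's exact test on gene counts with vs without a site.

    The two-sided p-value sums, at fixed margins, the probabilities of all
    tables no more probable than the observed one.
    """
    if not (0 <= k <= n and 0 <= K <= N and n > 0 and N > 0):
        raise ValueError("invalid enrichment counts")
    _, p = fisher_exact([[k, n - k], [K, N - K]], alternative="two-sided")
    return EnrichmentResult(
        motif=motif, fg_hits=k, fg_total=n, bg_hits=K, bg_total=N,
        p_value=float(p),
    )


__all__ = [
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_THRESHOLD",
    "DEFAULT_UPSTREAM",
    "EnrichmentResult",
    "MotifFormatError",
    "MotifHit",
    "MotifModel",
    "background_hit_count",
    "best_hit",
    "exact_enrichment",
    "flag_upstream_sites",
    "load_pwm",
    "pwm_to_logodds",
    "scan",
    "upstream_anchor",
]
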