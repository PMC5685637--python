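"""Multi-sample consensus calls and ORF-internal TSS classification.

Contigs are called independently in each test sample.  Contigs supported by
only one sample are discarded, as are consensus spans longer than 4 kb (very
long contigs are more likely fusions of neighbouring transcripts than single
novel ones).  A consensus call gets an averaged rank (mean of member ranks),
a TSS position (mean of member TSSs) and a TSS range (maximum deviation of a
member TSS from that mean).

An internal TSS is a consensus call whose TSS lies inside an annotated ORF,
at least 75 nt from both the start and stop codons, with averaged rank ≤ 800.
Offsets are reported strand-aware with the first ORF base as +1, formatted
"+mean±range".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .contig_caller import TranscriptContig, _strand_compatible
from .tracks_io import Gene, GeneAnnotation

MATCH_PROXIMITY = 150  # one analysis window: boundary reproducibility scale
MAX_SPAN = 4000
MIN_SUPPORT = 2
MIN_CODON_DISTANCE = 75
RANK_CUTOFF = 800


@dataclass
class ConsensusCall:
    seq: str
    start: int  # union span, 0-based half-open
    end: int
    strand: str | None
    tss_mean: float
    tss: int  # rounded half-up consensus TSS
    tss_range: float
    avg_rank: float
    samples: tuple[str, ...]
    members: list[TranscriptContig] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.samples)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class InternalTSSCall:
    call: ConsensusCall
    gene: Gene
    offset: int  # +1 = first ORF base, strand-aware
    dist_start: int  # nt from TSS to the start-codon end of the ORF
    dist_stop: int  # nt from TSS to the stop-codon end of the ORF
    ambiguous_host: bool = False
    mse: bool | None = None
    urs1: bool | None = None

    @property
    def location_label(self) -> str:
        return f"+{self.offset}±{_round_half_up(self.call.tss_range)}"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# cross-sample matching
# ---------------------------------------------------------------------------

def match_across_samples(
    per_sample: dict[str, list[TranscriptContig]],
    proximity: int = MATCH_PROXIMITY,
) -> list[list[TranscriptContig]]:
    """Single-linkage clusters of contigs representing the same transcript.

    Two contigs (from different samples, on the same sequence, with
    compatible strand contexts) link when their spans overlap and their
    strand-aware 5' boundaries are strictly less than ``proximity`` nt apart
    (default: one analysis window — two samples' estimates of the same TSS
    agree to within the smoothing/window scale).
    """
    if len(per_sample) < 2:
        raise ValueError("need contig lists from at least 2 samples")
    contigs: list[TranscriptContig] = [
        c for sample in sorted(per_sample) for c in per_sample[sample]
    ]
    parent = list(range(len(contigs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(len(contigs)), key=lambda i: (contigs[i].seq, contigs[i].start))
    for ii, i in enumerate(order):
        a = contigs[i]
        for j in order[ii + 1 :]:
            b = contigs[j]
            if b.seq != a.seq or b.start >= a.end:
                break
            if a.sample == b.sample:
                continue
            if not _strand_compatible(a.strand, b.strand):
                continue
            if abs(a.five_prime - b.five_prime) < proximity:
                union(i, j)
    clusters: dict[int, list[TranscriptContig]] = {}
    for i, c in enumerate(contigs):
        clusters.setdefault(find(i), []).append(c)
    return sorted(
        clusters.values(), key=lambda cl: (cl[0].seq, min(c.start for c in cl))
    )


def build_consensus(
    cluster: list[TranscriptContig],
    max_span: int = MAX_SPAN,
    min_support: int = MIN_SUPPORT,
) -> ConsensusCall | None:
    """Average a cluster into one call; None when discarded."""
    if not cluster:
        raise ValueError("empty cluster")
    samples = tuple(sorted({c.sample for c in cluster}))
    if len(samples) < min_support:
        return None
    start = min(c.start for c in cluster)
    end = max(c.end for c in cluster)
    if end - start > max_span:
        return None
    tsses = [c.five_prime for c in cluster]
    mean = sum(tsses) / len(tsses)
    strands = {c.strand for c in cluster if c.strand is not None}
    return ConsensusCall(
        seq=cluster[0].seq,
        start=start,
        end=end,
        strand=strands.pop() if len(strands) == 1 else None,
        tss_mean=mean,
        tss=_round_half_up(mean),
        tss_range=max(abs(t - mean) for t in tsses),
        avg_rank=sum(c.rank for c in cluster) / len(cluster),
        samples=samples,
        members=sorted(cluster, key=lambda c: (c.sample, c.start)),
    )


# ---------------------------------------------------------------------------
# internal classification
# ---------------------------------------------------------------------------

def _offset_in_orf(tss: int, gene: Gene) -> int:
    """Strand-aware offset of a genomic TSS, first ORF base = +1."""
    if gene.strand == "+":
        return tss - gene.start + 1
    return gene.end - tss


def classify_internal(
    calls: list[ConsensusCall],
    annot: GeneAnnotation,
    min_dist: int = MIN_CODON_DISTANCE,
    rank_cut: float = RANK_CUTOFF,
) -> list[InternalTSSCall]:
    """Keep calls whose consensus TSS is internal to an annotated ORF.

    The host gene is the overlapping ORF on the call's strand when the strand
    is resolvable; otherwise every overlapping ORF is reported with an
    ambiguity flag.  The TSS must sit ≥ ``min_dist`` nt from both the start
    and stop codons (distances counted inclusively from the TSS to the first
    and last ORF base) and the averaged rank must be ≤ ``rank_cut``.
    """
    out: list[InternalTSSCall] = []
    for call in calls:
        if call.avg_rank > rank_cut:
            continue
        hosts = annot.overlapping(call.seq, call.tss)
        if call.strand is not None:
            matched = [g for g in hosts if g.strand == call.strand]
            ambiguous = False
            if matched:
                hosts = matched
            else:
                ambiguous = True
        else:
            ambiguous = len(hosts) > 1
        for gene in hosts:
            offset = _offset_in_orf(call.tss, gene)
            dist_start = offset
            dist_stop = gene.length - offset + 1
            if dist_start < min_dist or dist_stop < min_dist:
                continue
            out.append(
                InternalTSSCall(
                    call=call,
                    gene=gene,
                    offset=offset,
                    dist_start=dist_start,
                    dist_stop=dist_stop,
                    ambiguous_host=ambiguous,
                )
            )
    return sorted(out, key=lambda c: (c.call.avg_rank, c.gene.gene_id))


REPORT_COLUMNS = [
    "orf_id",
    "gene_name",
    "start_location",
    "avg_rank",
    "support",
    "mse",
    "urs1",
    "span",
    "flags",
]


def _yesno(flag: bool | None) -> str:
    if flag is None:
        return "NA"
    return "Yes" if flag else "No"


def write_report(calls: list[InternalTSSCall], path) -> None:
    """Tab-separated internal-TSS report, one row per call, rank-sorted."""
    rows = sorted(calls, key=lambda c: (c.call.avg_rank, c.gene.gene_id))
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for c in rows:
            flags = sorted(set(f for m in c.call.members for f in m.flags))
            if c.ambiguous_host:
                flags.append("ambiguous-host")
            fh.write(
                "\t".join(
                    [
                        c.gene.gene_id,
                        c.gene.name,
                        c.location_label,
                        f"{c.call.avg_rank:.1f}",
                        str(c.call.support),
                        _yesno(c.mse),
                        _yesno(c.urs1),
                        f"{c.call.seq}:{c.call.start}-{c.call.end}",
                        ",".join(flags),
                    ]
                )
                + "\n"
            )


def write_bed(calls: list[ConsensusCall], path) -> None:
    """Consensus contigs as BED6; the score column holds the averaged rank."""
    with open(path, "w") as fh:
        for i, c in enumerate(sorted(calls, key=lambda c: (c.seq, c.start))):
            fh.write(
                f"{c.seq}\t{c.start}\t{c.end}\tconsensus_{i + 1}\t"
                f"{c.avg_rank:.1f}\t{c.strand or '.'}\n"
            )


def calls_to_json(
    consensus: list[ConsensusCall], internal: list[InternalTSSCall], path
) -> None:
    """Persist consensus + internal calls between pipeline stages."""
    import json
    from dataclasses import asdict

    def call_dict(c: ConsensusCall) -> dict:
        d = asdict(c)
        d["members"] = [asdict(m) for m in c.members]
        return d

    payload = {
        "consensus": [call_dict(c) for c in consensus],
        "internal": [
            {
                "call": call_dict(ic.call),
                "gene": asdict(ic.gene),
                "offset": ic.offset,
                "dist_start": ic.dist_start,
                "dist_stop": ic.dist_stop,
                "ambiguous_host": ic.ambiguous_host,
                "mse": ic.mse,
                "urs1": ic.urs1,
            }
            for ic in internal
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def calls_from_json(path) -> tuple[list[ConsensusCall], list[InternalTSSCall]]:
    import json

    with open(path) as fh:
        payload = json.load(fh)

    def call_from(d: dict) -> ConsensusCall:
        members = [TranscriptContig(**{
            k: (tuple(v) if k == "flags" else v) for k, v in m.items()
        }) for m in d.pop("members")]
        d["samples"] = tuple(d["samples"])
        return ConsensusCall(members=members, **d)

    consensus = [call_from(d) for d in payload["consensus"]]
    internal = [
        InternalTSSCall(
            call=call_from(d["call"]),
            gene=Gene(**d["gene"]),
            offset=d["offset"],
            dist_start=d["dist_start"],
            dist_stop=d["dist_stop"],
            ambiguous_host=d["ambiguous_host"],
            mse=d["mse"],
            urs1=d["urs1"],
        )
        for d in payload["internal"]
    ]
    return consensus, internal


__all__ = [
    "ConsensusCall",
    "InternalTSSCall",
    "MATCH_PROXIMITY",
    "MAX_SPAN",
    "MIN_CODON_DISTANCE",
    "MIN_SUPPORT",
    "RANK_CUTOFF",
    "REPORT_COLUMNS",
    "build_consensus",
    "classify_internal",
    "match_across_samples",
    "write_bed",
    "write_report",
]
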