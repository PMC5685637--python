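# Methods

This note documents the model behind `itss`, the choices made where the
procedure left room, what the synthetic data does and does not emulate, and
the known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model

Coverage is treated as an unstranded per-base histogram per sample; strand
enters only through the gene annotation. Internally all coordinates are
0-based half-open; 1-based inclusive conventions appear only at the GFF3 and
report boundaries.

**Smoothing.** Each position's count is spread with a discrete Gaussian
kernel, σ = 50 nt, truncated to its central 99.5% two-sided mass
(half-width ⌈z₀.₉₉₇₅·σ⌉ = 141 nt) and renormalized to unit sum. At sequence
ends the in-bounds part of each source position's kernel is renormalized, so
the per-sequence signal total is preserved exactly and no mass wraps around
or leaks — important on the short sequences used in testing. Tracks are then
divided by the sample's genome-wide unmasked raw coverage sum. Smoothing and
depth normalization commute (both linear); smoothing is applied first.

**Shape difference.** Two normalized smoothed tracks are compared in 150-nt
windows stepped by 5 nt. Within a window both curves are rescaled to unit
area — making the statistic invariant to local expression level — and their
RMSD is the window's shape-difference value. The value is assigned to the
window's **central base**: a window reports a shape change, and the change
sits at its center. (Assigning it to the window's 5'-most base was tried
first and rejected: the downstream "value at the TSS" criteria were then
evaluated 75 nt away from the change point, and asymmetrically by strand —
minus-strand candidate positions landed deep inside the induced region and
failed the coverage-band criterion, plus-strand ones sat on the ramp foot
and failed the difference criterion.)

Windows where either sample sums to zero carry no initiation evidence;
their RMSD is defined as 0 and flagged. Windows overlapping the exclusion
mask are flagged and yield no peaks. Exclusion masking (applied to coverage,
with masked positions removed from all depth sums and percentile pools) is
the coverage-level equivalent of removing contaminant-feature reads before
quantification.

## Peak filtering

Peaks are local maxima of the RMSD series: equal-valued runs collapse to
their middle window, a run counts as a peak only when strictly above both
neighbouring runs, and runs touching the series ends are never peaks
(one-sided evidence). There is no prominence or minimum-separation rule —
the percentile criteria do that work.

**TES removal.** A novel transcript end also produces a shape peak. A peak
with greater mean test coverage in the 150 nt immediately 5' of it than in
the 150 nt immediately 3' (in the transcription orientation) is TES-like
and removed. Orientation comes from annotated genes overlapping the peak's
window footprint (position ± half a window): the transcript producing a
shape change can end up to half a window away from its gene's annotated
span, and the footprint rule lets the 3' ramp just past a gene's end — the
TES of an internal transcript — be correctly attributed and removed. Where
no gene is within reach, both orientations are evaluated and the peak is
kept only if TSS-like in at least one, flagged `strand-ambiguous`. Flank
means are computed on the smoothed test track, consistent with the rest of
the windowed analysis.

**Three criteria, strictly applied.** Surviving peaks must have (1) RMSD
strictly above the median of all window RMSD values, (2) a per-position
smoothed coverage sum (test + control) strictly inside the (median, 95th
percentile) band, and (3) a per-position smoothed difference (test −
control) strictly above the 90th percentile. All pools are genome-wide over
unmasked positions/windows; percentiles use linear interpolation between
order statistics (the numpy default, reproduced independently by the naive
reference). The band's upper bound deliberately excludes the most highly
expressed loci; it is implemented literally.

## Contigs, consensus, internal calls

A surviving peak expands into a contig while the per-position difference
stays at or above the criterion-(3) threshold; the first sub-threshold
position on each side bounds it (clamped, and flagged, at sequence ends).
Contigs whose strand-aware 5' boundaries are < 1000 nt apart and whose mean
differences vary < 3-fold merge (union span, mean recomputed over the
union, iterated 5'→3' to a fixed point — order-independent by test).
Merging and cross-sample matching require compatible strand contexts
(equal, or one side unknown), and the 3-fold similarity ratio is defined
only for positive means: a non-positive mean difference is never "similar".
Score = mean difference × length; rank 1 is the best score, ties broken by
5' coordinate then sequence name.

Cross-sample identity (a rule the procedure needs but the source analysis
never spells out): contigs from different samples cluster by single linkage
when spans overlap and 5' boundaries differ by less than one analysis
window (150 nt). Two samples' estimates of the same TSS agree to within the
smoothing/window scale — observed true-positive spread is ±20 nt — while a
1-kb tolerance (the intra-sample merge constant) admitted enough random
coincidences of noise contigs that null data produced spurious consensus
calls. Clusters need ≥ 2 distinct samples; union spans > 4000 nt are
discarded as likely fusions. Consensus TSS = mean of member TSSs (rounded
half-up), range = maximum deviation from that mean, averaged rank = mean of
member ranks (inclusive cutoff at 800, matching the "top 800" phrasing).

A call is internal when its consensus TSS lies within an ORF, ≥ 75 nt from
both the start- and stop-codon ends (distances counted inclusively from the
TSS to the first/last ORF base) and passes the rank cutoff. The host is the
overlapping ORF on the call's strand; if none matches, all overlapping ORFs
are reported with an ambiguity flag. A TSS inside an annotated intron still
counts as internal to the gene's span. Offsets are reported strand-aware,
first ORF base = +1, formatted `+mean±range`.

## Motif scanning and enrichment

Count/probability matrices (JASPAR format, parsed with Biopython) become
log-odds weights with pseudocount 0.25 per cell against a uniform 0.25
background (natural log; the relative score is base-invariant). Both
strands are scanned at every offset; ambiguous bases score as the column
minimum; a site requires a relative score — (score − min)/(max − min) —
strictly above 0.85. The scanned window is the 300 nt immediately 5' of the
3'-most possible TSS (consensus + range, strand-aware). Enrichment is
counted per gene (≥ 1 site or none) with a two-sided Fisher's exact test
(scipy) against the 300-nt upstream windows of all annotated ORFs; the test
suite cross-checks it against an exhaustive hypergeometric enumeration and
a Monte-Carlo permutation estimate. The bundled `mse_toy`/`urs1_toy`
matrices are synthetic toy profiles (consensus `GACACAAAAATA` and
`TCGGCGGCT`) built so the test suite needs no external motif database; they
are not the curated Ndt80/Ume6 profiles and real analyses should supply
those as input.

## Synthetic data: what it emulates, and what it does not

The generator (`itss.synthetic_data`) emulates the coverage structure the
detection procedure assumes, with full ground truth:

- **Genes**: 200 ORFs of 1–2.5 kb on a two-chromosome ~1.1 Mb genome,
  ≥ 2 kb intergenic spacing (adjacent-gene bleed-through is controlled by
  design, not left to chance), random strands. Basal expression is
  log-normal across genes (median 30×, σ_log = 1.0, clipped to [5, 400]) —
  the coverage-band criterion is only meaningful when expression varies.
- **Background transcription**: a genome-wide mean depth of 3× in every
  sample. Without it most of the genome sits at exactly zero coverage and
  the 90th percentile of the difference pool degenerates to ~0, which makes
  the contig-boundary scan unbounded; pervasive low-level transcription is
  also the realistic regime for a deeply sequenced yeast library.
- **Condition response**: 28% of genes up-regulated 1.4–2.2× and 30%
  down-regulated to 0.15–0.55× in all test samples (read totals roughly
  balanced). This emulates the broad transcriptome remodeling of a
  developmental time course; the genome-wide percentile thresholds
  presuppose it, and it places the difference threshold at the foot of the
  genuinely changed territory rather than inside the noise.
- **Internal initiations**: 20 genes (basal drawn U[20, 30]×, the
  modest-expression population the coverage band targets) gain a plateau of
  basal × (fold − 1), fold = 4, from a planted intra-ORF position (30–70%
  of the ORF, ≥ 180 nt from its ends) to the gene's 3' end, with ±5 nt
  per-sample jitter of the plateau start so the consensus range logic is
  exercised. The toy MSE consensus is written into the genome 150 nt 5' of
  each planted start — typical promoter-proximal placement, and inside the
  300-nt scan window given the known boundary bias (below).
- **TES decoys**: genes that lose their transcription (background remains)
  3' of a planted mid-ORF position in test samples — the confounder the TES
  filter must remove.
- **Noise**: independent per-base negative binomial counts, dispersion
  r = 20 (variance m + m²/20, per-base CV ≈ 29% at 30×), so relative noise
  falls with depth as in real coverage. A `None` dispersion gives exact
  means for construction oracles.

Everything is deterministic given the seed.

Not emulated: UTRs (coverage starts/ends at ORF boundaries), introns,
overlapping or antisense transcription, positional coverage biases
(GC, 3' bias), replicate-to-replicate library effects, and real promoter
sequence composition (the genome is uniform random ACGT). Passing tests
therefore show the pipeline recovers the *coverage-shape* signal it was
designed for under realistic depth, noise, and remodeling — not that it is
robust to every artifact of real libraries; on real data the flags
(`strand-ambiguous`, `clamped-*`, ambiguity) and the genome-browser exports
support the manual review step that the original workflow ends with, which
is deliberately not automated here.

## Numerical and boundary choices

- Percentiles: linear interpolation; pools genome-wide; strict
  inequalities exactly as specified above.
- Consensus TSS rounding: half-up to integer nucleotides.
- Degenerate contigs (single base) are kept but flagged.
- Windows shorter than the sequence are skipped (no partial windows).
- A PWM whose score range is zero is rejected at load time.
- All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning.

## Expected positional bias

The reported TSS is where the smoothed difference crosses the
90th-percentile threshold t walking 5' from the peak. For a step of height
h smoothed with a Gaussian of σ = 50 nt, the deterministic crossing sits
≈ σ·Φ⁻¹(1 − t/h) nt 5' of the true start — between ~35 and ~100 nt for
t/h between 0.25 and 0.02. Under the default simulation this bias is
~50–70 nt (the acceptance script reports the realized mean absolute error),
always 5'-ward, i.e. calls slightly *overestimate* the transcript's extent.
Consumers comparing offsets to orthogonal data (5'-end sequencing, tiling
arrays) should allow for roughly one smoothing σ of slack.

## Known limitations

- A single shared control means a strong noise excursion in the control
  track recurs in every test-vs-control comparison; in data with no real
  signal at all such excursions can reach consensus support. The broad
  condition response in realistic data keeps the difference threshold well
  above this noise floor; fully exchangeable samples are the worst case.
- Genes weakly expressed but strongly induced full-length can surface with
  a mid-ORF 5' boundary when the difference profile crosses the threshold
  patchily — locally indistinguishable from internal initiation; such calls
  are exactly what the end-stage manual review is for.
- The rank-800 cutoff is calibrated to a full-genome contig universe; on
  small toy genomes every contig ranks far below it and the cutoff is
  inert.
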