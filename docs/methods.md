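# Methods

This note documents the models implemented in `drnatss`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and strand conventions

All in-memory coordinates are 0-based half-open; GFF3 and variableStep
wiggle files keep their native 1-based inclusive conventions. Replicons are
linear: windows are truncated at replicon ends, never wrapped. "Upstream"
and "downstream" are always in transcription direction; on the − strand the
first base of the start codon is the feature's rightmost base. The entire
pipeline is strand-mirror invariant: reverse-complementing the genome and
swapping strand labels of all inputs yields coordinate-reflected outputs
(asserted end-to-end in the tests).

## TSS detection

For each growth condition a TEX-treated and an untreated track of read
5′-end counts per strand are compared. A position is a candidate TSS when,
in the treated library,

* height ≥ `min_height` (default 5),
* step factor = height / max(upstream height, ψ) ≥ 2, where the upstream
  neighbour is one base before the position in transcription direction, and
* enrichment factor = height / (untreated height + ψ) ≥ 2,

with pseudocount ψ = 1. At a replicon edge no rise can be demonstrated, so
the missing upstream neighbour counts as the position's own height (step
factor 1) — a flat track yields no calls anywhere.

Heights may be reads-per-million normalized; the pipeline default applies
the thresholds to **raw counts**. A fixed RPM floor translates into a
different raw-read floor for every library and genome size, so it either
passes single stray background reads (small libraries) or swallows weak true
peaks (large ones); a floor of 5 raw reads rejects background coincidences
(1–3 reads) at any scale while the weakest planted peaks (~8 expected
reads) clear it. RPM normalization remains available for reporting and
cross-library comparison.

Candidates within 3 nt on one strand are clustered; the representative is
the member with the maximum height (kept as its own height, not a sum),
ties going to the most upstream position. Calls from different conditions
are merged as a **union** with ±1 nt tolerance — a TSS found convincingly in
any library is kept — and after merging, every treated library's height at
the final position is recorded, so the downstream "most reads" ranking uses
all the data rather than only the libraries in which the site passed the
calling thresholds.

## TSS classification

Each TSS receives every class its position supports:

* upstream-sense assignment for every same-strand gene whose start codon
  lies 0–300 bp downstream (a TSS exactly on the start codon's first base is
  upstream with a 0 nt UTR); per gene, the upstream TSS with the largest
  summed treated height is the pTSS, all others sTSS, height ties resolved
  to the most upstream position;
* iTSS for every same-strand gene containing the position downstream of the
  start codon;
* aTSS for every opposite-strand gene containing the position or whose
  boundary lies within 100 bp (inclusive on both ends);
* oTSS if and only if nothing else applies (exclusive by construction).

Both the 300 bp and 100 bp bounds are inclusive. A TSS ≤300 bp upstream of
two same-strand genes associates with both. The antisense summary counts,
for every aTSS, whether it falls within ±150 bp of the opposite-strand
gene's start codon (5′ terminus) or stop codon (3′ terminus); a TSS near
both termini of a short gene counts once per terminus, and the headline
fraction is the share of aTSS near at least one terminus.

## 5′-UTR annotation and start-codon re-annotation

UTR length is the distance from the TSS to the first base of the start
codon (0 when coincident); leaderless ⇔ ≤8 nt, long ⇔ 50–300 nt. Summary
statistics (median, class fractions, mean GC of long UTRs) are computed over
the combined pTSS+sTSS record set, and are reported **before** the
re-annotation step (which by design removes leaderless records).

The re-annotation screen considers every leaderless p/sTSS record and every
iTSS within 100 nt downstream of its gene's annotated start. In-frame
candidate starts are collected from the annotated start to the end of the
scan window (TSS + 100 nt), stopping at the first in-frame stop; candidates
are ranked ATG before GTG before TTG, nearest first within a codon class.
A candidate is accepted when it has an RBS — a GGDGRD match (or PWM hit)
whose 3′ end sits 4–15 nt upstream of the candidate start, scanned on the
genome because the element may lie upstream of the TSS — **or** when
adopting it lifts the record out of the leaderless class. The OR rule
mirrors treating the RBS as supporting rather than mandatory evidence; at
most one reassignment is accepted per gene. Accepted reassignments move the
CDS start, UTRs and classes are recomputed (an iTSS whose gene start moves
past it becomes that gene's pTSS), and a second round finds nothing further
when alternative starts are unique.

## Promoter motif discovery

Motif discovery is one-occurrence-per-sequence (OOPS) EM over fixed-width
PWMs on the strand-aware −50..TSS windows (51 nt, windows truncated by a
replicon edge are excluded). The E-step computes the posterior over site
offsets under the current PWM against a 0-order background estimated from
the windows; the M-step re-estimates the PWM from posterior-weighted counts
with pseudocount 0.25 per base; iteration stops at ΔlogL < 1e−6 or 200
iterations, and the best of 10 seeded restarts is kept (deterministic given
the seed; the log-likelihood is non-decreasing within a run). Because EM
over promoter windows has near-degenerate column-shifted optima, a phase
polish refits from the best sites shifted by ±1..2 columns and keeps the
highest-likelihood model.

OOPS was chosen over a ZOOPS prior because the windows are
promoter-anchored; the fraction of windows *without* the motif is estimated
post hoc by scanning each window with the learned PWM at a log-odds
threshold of 0.5 × the PWM's maximum score. The factor 0.5 is calibrated to
the generator's motif mutation model: a planted instance with one
substitution loses ~6 of ~13 bits against the sharp learned PWM and must
still count as motif-bearing. Offsets are reported from the motif's 3′-most
base to the TSS; medians are taken over windows with at least one hit,
while hit-less windows still count in the fraction.

Two motifs are discovered per window set: the BRE first — in an AT-rich
genome the purine/C-containing BRE carries more information per column than
the A/T-only TATA-box and dominates the first EM basin — then, after
masking each window's best BRE site with background-sampled bases, the
TATA-box. The labels are confirmed by the offset medians (TATA ≈ 23 bp,
BRE ≈ 33 bp upstream). Default widths: TATA 8, BRE 7, RBS 6.

## Expression analysis

The expression proxy is strand-matched 5′-end reads within the gene body
per kb of gene. This is semi-quantitative: dRNA-seq libraries are enriched
for 5′-terminal sequences, so gene-body 5′-end density tracks transcript
abundance through processing/fragmentation products rather than uniform
coverage. Positions shared by overlapping same-strand genes count for each.

Libraries are normalized by median-of-ratios size factors, standardized to
geometric mean 1 so that normalization is exactly idempotent. The gene
filter generalizes the usual any-zero exclusion: with a uniform sequencing
background no count is ever literally zero, yet genes silent in some
libraries must not enter the median (unequal silent fractions would shift
which quantile the median picks and bias the factors), so the pipeline
excludes genes below the expression-detection threshold in any library.

TU values are exact sums over operon members; singleton genes are their own
TU. Expression bins are computed on the **raw** per-gene-mean scale (TU
value ÷ member count): the "little or no transcription" call is a
raw-background question — the per-gene background floor is ~20 reads/kb at
the default background rate, the default detection threshold is 50 — and
median-of-ratios factors are unreliable for near-quiescent libraries, where
most genes carry only background. Expressed TUs are binned by fold over the
threshold (1×, 10×, 100×, 1000×). Contrasts are log2((b+1)/(a+1)) on
normalized TU values; no dispersion estimation or significance testing is
performed.

## sRNA conservation, ORFs, GC

The conservation value of a query sRNA against a subject sequence is the
number of identical nucleotides in the best local alignment divided by the
query length × 100, retained at ≥40 %. Alignment is affine-gap
Smith–Waterman (match +1, mismatch −1, gap of length k costs −2−(k−1);
scores chosen to approximate identity-driven nucleotide alignment); both
orientations of the subject are searched but the query is never
reverse-complemented, keeping the denominator stable, and gapped columns
count as non-identical. For subjects ≥2 kb an exact-word seed (≥10 nt)
selects the region and a banded Smith–Waterman extends it; below that the
full matrix is computed. The database-dependent e-value filter of a
database search has no pairwise analogue and is replaced by the score/word
gate. The ORF screen reports every sense-frame ORF from a start codon
(ATG/GTG/TTG) to its next in-frame stop, stop excluded from the codon
count; a transcript with no ORF longer than 10 codons is flagged
non-coding.

## The synthetic-data generator

The generator is the package's study system: its defaults are the study
conditions, and passing tests demonstrate recovery of exactly the structure
it plants.

Genome: transcription units of 1–4 genes (probabilities 0.60/0.15/0.15/
0.10), gene bodies 140–280 codons sampled at 42 % GC with in-frame stops
(and, where scrubbing applies, start codons) excluded, intra-operon gaps
20–60 nt, inter-TU gaps ≥120 nt, dedicated 900 nt zones for orphan TSS.
Long-UTR regions are sampled at 48 % GC, other non-coding sequence at 40 %.

TSS and transcripts: one pTSS per TU; a secondary TSS for 30 % of TUs;
internal TSS for 25 % of genes, planted >100 nt from the start codon (so
the re-annotation screen's planted answer set stays exact) and >250 nt from
the gene 3′ end (so an iTSS never doubles as a downstream operon member's
promoter TSS); antisense TSS at 0.6 per gene with exactly 58 % placed
within the ±150 bp terminus windows (offsets kept ≥2 nt clear of the window
boundary so ±1 detection jitter cannot flip the label), the rest >160 bp
from both termini, all rejected if they would double as a sense-strand TSS
of any gene; orphan TSS (0.15 per gene) in isolated intergenic zones. All
planted 5′ ends on one strand are ≥6 nt apart so ±1 nt read jitter can
never bridge two true sites into one cluster.

UTRs: class counts (leaderless ≤8 nt: 14 %; long 50–300 nt: 20 %) are
planted as exact stratified counts over the combined pTSS+sTSS population —
the population the summary statistic is defined on. Mid-length UTRs are a
discretized lognormal (σ = 0.42) clipped to 9–49 nt whose location is
solved so the whole mixture's median equals the configured 16 nt; long
UTRs are lognormal around median 103 clipped to 50–300.

Promoters: BRE (7-mer) and TATA (8-mer) consensus sequences are written
with their 3′ ends 33 and 23 bp upstream of the pTSS for 90 % of TUs, with
one shared N(0, 2) jitter per promoter (shared so the elements never
collide while both medians keep σ = 2) and 3 % per-base substitution.
sTSS windows carry no planted promoter. An RBS hexamer sampled from GGDGRD
is written 4–12 nt (shrunk for short UTRs) upstream of half the start
codons; leaderless genes cannot carry one.

Mis-annotations: a configurable number of leaderless TUs get a GTG start
whose true ATG sits exactly 3 codons downstream with an RBS 10–12 nt
upstream of the ATG (entirely upstream of the GTG); codons 1–2 are free of
start/stop codons. Every *other* gene with a leaderless p/sTSS has
start codons scrubbed from the whole scan window, making "exactly k
reassignments, zero false" a well-defined planted answer.

Expression: each TU draws a lognormal level (μ = 0.5, σ = 0.9, clipped to
0.5–30). Per condition an exact-count random subset of TUs is silent
(S_exp 28 %, S_stat 87 %, P_exp 35 %, PS 28 %; independent draws, so ~2 %
of TUs are silent everywhere and are excluded from the detection ground
truth — a never-transcribed TSS leaves no signal). Two singleton TUs form
the sulfur switch: levels 10 and 10/16 swapped between P_exp and PS
(|log2FC| = 4).

Coverage: treated-library peak reads ~ Poisson(depth × level × class
factor) with depth 40 and class factors pTSS 1.0, sTSS 0.4, iTSS/aTSS 0.5,
oTSS 0.8; each read smears ±1 nt with probability 0.1. Untreated libraries
keep 30 % of primary peaks, carry processing sites (0.3/kb of transcript,
0.75 × depth × level) that leave nothing in treated libraries, and carry
dispersed intra-transcript 5′ ends at 0.4 reads/nt per unit level (0.005 in
treated libraries — TEX degrades most processed 5′ ends). Background is
Poisson 0.02 reads/nt/strand on both strands. All randomness derives from
one seed; outputs are byte-identical across runs.

### What the generator does not emulate

Sequence-composition and ligation biases, RNA degradation kinetics,
transcript 3′ ends and terminators, read-level errors, replicate variance
beyond Poisson, condition-correlated expression programs, and chance motif
look-alikes beyond what random sequence provides. Recovery on this material
shows the algorithms implement their definitions correctly at realistic
signal-to-noise; it does not certify performance on real libraries, where
threshold choices (height, enrichment, detection floor) would need
re-calibration to library depth and background.

## Problem sizes

The shipped analyses and checks use a 200-gene genome (~0.2 Mb, ~350 TSS,
eight libraries) for detection recovery and end-to-end runs, and a 900-gene
genome (~0.9 Mb, ~1,570 TSS) where a statistic needs population size: ≥500
p/sTSS UTR records, ≥300 antisense TSS, ≥500 promoter windows, and 25
planted mis-annotations (a 200-gene genome has only ~18 leaderless TUs,
too few to host 25). Both complete in seconds on one CPU.

## Known limitations

* The p/s split depends on observed read counts: when a gene's true primary
  TSS escapes detection (marginal TEX enrichment in its only active
  condition), its secondary TSS is — correctly, per the definition —
  promoted to primary.
* The re-annotation OR-rule will reassign any leaderless mRNA with *any*
  in-frame downstream alternative start in the window; on real annotations
  this is aggressive and the RBS-required variant may be preferable (both
  are available via configuration).
* Expression values are 5′-end based and semi-quantitative; between-library
  contrasts are only as good as the size factors, which require a shared
  majority of expressed genes above the detection floor.
* The conservation statistic is asymmetric by construction (query-length
  denominator) and is not an e-value-calibrated homology search.
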