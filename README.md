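# drnatss — primary-transcriptome annotation from differential RNA-seq

Differential RNA sequencing (dRNA-seq) maps transcription start sites (TSS)
genome-wide by comparing two cDNA libraries per sample: one treated with a
5′-phosphate-dependent terminator exonuclease (TEX), which degrades processed
RNAs carrying a 5′-monophosphate but spares primary transcripts with their
5′-triphosphate, and one untreated control. Read 5′ ends pile up at the +1
position of each transcript, and a position that is high, rises sharply over
its upstream neighbour, and is TEX-enriched marks a genuine TSS rather than a
processing site.

This package re-implements that analysis for an archaeal (AT-rich,
operon-dense, leaderless-mRNA-rich) genome as a tested, reusable pipeline:

* **TSS detection** from per-strand 5′-end count tracks (variableStep wiggle),
  using three statistics per position — normalized height *h*, step factor
  *h/h(upstream)*, and TEX enrichment *h(TEX+)/(h(TEX−)+ψ)* — with ±1 nt
  clustering and union merging across growth conditions;
* **positional classification** into primary/secondary (sense, ≤300 bp
  upstream of a start codon; the one with most reads is primary), internal
  (inside a gene, sense), antisense (in or within 100 bp of a gene,
  antisense) and orphan TSS, with multi-class membership;
* **5′-UTR annotation**: UTR length (0 = first base of the start codon),
  leaderless (≤8 nt) and long-UTR (50–300 nt) classes, and a start-codon
  re-annotation screen that finds in-frame alternative starts (ATG > GTG >
  TTG) with a Shine–Dalgarno-like RBS (consensus GGDGRD) and re-categorizes
  the affected TSS;
* **promoter motif discovery**: one-occurrence-per-sequence EM over the
  −50..TSS windows recovers the archaeal BRE and TATA-box elements and their
  distance-to-TSS distributions;
* **expression analysis**: per-gene 5′-end reads/kb, median-of-ratios size
  factors, exact per-operon (transcription unit, TU) sums, expression bins,
  log2 fold-change contrasts, top-expressed tables;
* **sRNA features**: the percentage conservation statistic (identical
  nucleotides in the best local alignment ÷ query length × 100, retained at
  ≥40%) on a hand-written affine-gap Smith–Waterman / seeded aligner, an ORF
  screen (>10 codons), and GC content.

Everything runs against a first-class **synthetic-data generator**
(`drnatss.simulate`) that plants all of the above — TSS of every class,
BRE/TATA at median 33/23 bp, a UTR mixture with median 16 nt, 14 %
leaderless and 20 % long UTRs, mis-annotated GTG starts, antisense TSS
concentrated near gene termini (58 % within 150 bp windows), processing
sites suppressed by TEX, and a four-condition expression program — and
records the ground truth, so every stage is tested against known answers.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
200-gene genome (seed 7; reruns are byte-identical) and write their tables
under `results/`:

```
cd analysis
python 01_simulate.py && python 02_detect_tss.py && python 03_classify_tss.py
python 04_annotate_utrs.py && python 05_promoter_motifs.py
python 06_expression.py && python 07_srna_conservation.py
```

Output of the core steps (what the code actually printed):

```
detected 341 TSS (349 expressed planted TSS)
  sensitivity 0.977  precision 1.000 (±1 nt tolerance)
  processing sites mis-called as TSS: 0
341 unique TSS carry 366 class assignments: {'pTSS': 112, 'sTSS': 31,
  'iTSS': 50, 'aTSS': 143, 'oTSS': 30}
aTSS near gene termini: 0.576 (5' 45, 3' 48, of 118)
143 p/sTSS 5'-UTRs: median 17 nt, 14.7% leaderless, 19.6% long (50-300 nt)
start-codon reassignments: 10 (10 planted); after re-annotation: 7.0%
  leaderless (was 14.7%)
TATA: consensus TTTATATA, present in 88.4% of 112 pTSS windows, median 23 bp
BRE:  consensus CGAAAGT,  present in 88.4% of 112 pTSS windows, median 33 bp
fraction of TUs with little or no transcription:
  S_exp 27.6%   S_stat 87.1%   P_exp 35.3%   PS 27.6%
```

Reading: detection recovered 97.7 % of the planted, expressed TSS with no
false calls and rejected every RNA-processing site; the classifier's
per-class counts match the planted ones (a TSS can carry several classes,
hence 366 assignments for 341 sites); the UTR summary reproduces the planted
length mixture; the re-annotation screen recovers exactly the ten planted
GTG→ATG mis-annotations and clears their leaderless labels; the promoter
search recovers both planted elements at their planted consensus and median
offsets; and the expression bins reproduce the planted per-condition silent
fractions.

## Layout

```
src/drnatss/      io, config, simulate, detect, classify, utrs, motifs,
                  expression, srna, pipeline
analysis/         numbered narrative drivers (see worked example)
tests/            unit, property and end-to-end recovery tests
scripts/          acceptance.py
docs/methods.md   models, parameter choices, limitations
```
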