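"""Conservation and coding-potential screen of orphan small transcripts.

Takes the transcripts downstream of orphan TSS as candidate sRNAs, screens
them for ORFs (>10 codons disqualifies a transcript as non-coding) and GC
content, and computes the pairwise conservation statistic — identical
nucleotides in the best local alignment divided by query length × 100,
retained at ≥40% — against synthetic "relative genomes" derived from the
real genome by point mutation at two divergence levels.
"""

import csv

import numpy as np

from common import RESULTS, load_dataset
from drnatss import srna


def mutated_copy(rng, seq, rate):
    out = list(seq)
    for i in rng.choice(len(out), size=int(rate * len(out)), replace=False):
        out[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[i]]
    return "".join(out)


def main():
    annotation, truth, tracks = load_dataset()
    rng = np.random.default_rng(0)
    genome = annotation.sequences["chr"]
    orphans = [t for t in truth.tss if t.intent == "oTSS"]

    rows = []
    for t in orphans:
        lo, hi = t.span
        transcript = annotation.subsequence("chr", lo, hi, t.strand)
        noncoding = srna.is_noncoding(transcript, 10)
        gc = srna.gc_content(transcript)
        for label, rate in (("close_relative", 0.10), ("distant_relative", 0.55)):
            subject = mutated_copy(rng, transcript, rate)
            flanked = (mutated_copy(rng, genome[max(lo - 300, 0):lo], 0.3)
                       + subject + mutated_copy(rng, genome[hi:hi + 300], 0.3))
            r = srna.conservation_value(transcript, flanked,
                                        query_id=t.tss_id, subject_id=label)
            rows.append([t.tss_id, label, len(transcript),
                         f"{gc:.1f}", int(noncoding), r.identical_nt,
                         f"{r.conservation_value:.1f}", int(r.retained)])

    out = RESULTS / "srna_conservation.tsv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["srna", "subject", "length_nt", "gc_pct", "noncoding",
                    "identical_nt", "conservation_pct", "retained"])
        w.writerows(rows)

    close = [float(r[6]) for r in rows if r[1] == "close_relative"]
    far = [float(r[6]) for r in rows if r[1] == "distant_relative"]
    kept = sum(int(r[7]) for r in rows)
    nc = sum(int(r[4]) for r in rows) / 2
    print(f"{len(orphans)} orphan transcripts screened "
          f"({nc:.0f} without ORFs >10 codons)")
    print(f"median conservation: close relative {np.median(close):.1f}%, "
          f"distant relative {np.median(far):.1f}%; "
          f"{kept}/{len(rows)} pairs retained at >=40%")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
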