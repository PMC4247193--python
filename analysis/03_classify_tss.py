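"""Classify detected TSS against the annotation and summarize the classes.

Each TSS gets every class its position supports: primary/secondary (sense,
≤300 bp upstream of a start codon, split by read count), internal (inside a
gene, sense), antisense (in or within 100 bp of a gene, antisense), orphan
(none of these).  Also quantifies the antisense bias toward gene termini
(±150 bp windows around start/stop codons).
"""

import csv

from common import CONFIG, RESULTS, load_dataset
from drnatss import classify, detect, io, pipeline


def main():
    annotation, truth, tracks = load_dataset()
    candidates = detect.detect_tss(tracks, CONFIG.detection)
    records = classify.classify_all(candidates, annotation,
                                    CONFIG.classification)
    io.write_tss_table(records, RESULTS / "tss_master_table.tsv")

    s = classify.category_summary(records)
    with open(RESULTS / "tss_category_summary.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["metric", "value"])
        w.writerow(["unique_tss", s["unique_tss"]])
        w.writerow(["total_assignments", s["total_assignments"]])
        for cls, n in sorted(s["per_class"].items()):
            w.writerow([f"count_{cls}", n])
        for (a, b), n in sorted(s["overlap"].items()):
            if n:
                w.writerow([f"overlap_{a}_{b}", n])

    term = classify.terminus_enrichment(records, annotation,
                                        CONFIG.classification.terminus_window)
    ec = pipeline.evaluate_classification(records, truth)

    print(f"{s['unique_tss']} unique TSS carry {s['total_assignments']} "
          f"class assignments: {s['per_class']}")
    print(f"aTSS near gene termini: {term['near_any_fraction']:.3f} "
          f"(5' {term['near_5prime']}, 3' {term['near_3prime']}, "
          f"of {term['n_atss']})")
    print(f"agreement with planted classes: {ec['agreement']:.4f} "
          f"over {ec['n_compared']} matched TSS")
    print(f"wrote {RESULTS / 'tss_master_table.tsv'}")


if __name__ == "__main__":
    main()
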