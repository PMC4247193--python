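"""Discover the archaeal core-promoter elements upstream of detected TSS.

Runs two-pass one-occurrence-per-sequence EM on the −50..TSS windows of
primary TSS (BRE first — it carries more information in this AT-rich genome
— then the TATA-box after masking), scans all windows with the learned
PWMs, and summarizes motif→TSS distances.  Writes PWM files and the offset
histograms.
"""

import csv

from common import CONFIG, RESULTS, load_dataset
from drnatss import classify, detect, pipeline


def main():
    annotation, truth, tracks = load_dataset()
    candidates = detect.detect_tss(tracks, CONFIG.detection)
    records = classify.classify_all(candidates, annotation,
                                    CONFIG.classification)
    summary = pipeline.promoter_motif_summary(records, annotation, CONFIG,
                                              seed=0)
    with open(RESULTS / "promoter_offsets.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["motif", "offset_3p_to_tss", "count"])
        for name in ("TATA", "BRE"):
            for off, n in summary[name]["summary"].histogram.items():
                w.writerow([name, off, n])
    for name in ("TATA", "BRE"):
        model = summary[name]["model"]
        s = summary[name]["summary"]
        model.to_file(RESULTS / f"pwm_{name}.txt")
        print(f"{name}: consensus {model.consensus}, present in "
              f"{s.fraction_with_hit:.1%} of {s.n_anchors} pTSS windows, "
              f"median {s.median_offset:.0f} bp upstream of the TSS")
    print(f"wrote {RESULTS / 'pwm_TATA.txt'}, {RESULTS / 'pwm_BRE.txt'}, "
          f"{RESULTS / 'promoter_offsets.tsv'}")


if __name__ == "__main__":
    main()
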