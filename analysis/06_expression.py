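"""Gene/TU expression across conditions, expression bins and the sulfur switch.

Quantifies per-gene 5'-end reads per kb from the untreated libraries,
derives median-of-ratios size factors, sums normalized values over operons,
bins TUs by expression (the "little or no transcription" bin uses the raw
per-gene-mean scale), contrasts pyruvate vs sulfur-shift libraries on a
log2 scale, and ranks the top-expressed genes.
"""

from common import CONFIG, RESULTS, load_dataset
from drnatss import expression as ex


def main():
    annotation, truth, tracks = load_dataset()
    untreated = [tracks[(c, False)] for c in truth.conditions]
    raw = ex.count_matrix(untreated, annotation)
    factors = ex.size_factors(raw,
                              min_count=CONFIG.expression.detection_threshold)
    norm = raw / factors
    tu_raw = ex.tu_expression(raw, annotation.operons)
    tu_norm = ex.tu_expression(norm, annotation.operons)

    raw.round(3).to_csv(RESULTS / "gene_expression_raw.tsv", sep="\t")
    tu_norm.round(3).to_csv(RESULTS / "tu_expression_normalized.tsv", sep="\t")
    bins = ex.expression_bins(tu_raw, annotation.operons, CONFIG.expression)
    bins.round(4).to_csv(RESULTS / "expression_bins.tsv", sep="\t")
    con = ex.contrast(tu_norm, "P_exp_noTEX", "PS_noTEX",
                      CONFIG.expression.contrast_pseudocount)
    con.round(3).to_csv(RESULTS / "contrast_P_exp_vs_PS.tsv", sep="\t")

    print("size factors:",
          {k: round(v, 3) for k, v in factors.items()})
    print("fraction of TUs with little or no transcription:")
    for lib in bins.columns:
        print(f"  {lib:<14} {bins.loc['little_or_none', lib]:.1%}")
    swings = con["log2_fold_change"].sort_values()
    print("strongest condition-dependent TUs (log2 PS/P_exp):")
    print(f"  down: {swings.index[0]} {swings.iloc[0]:+.2f}   "
          f"up: {swings.index[-1]} {swings.iloc[-1]:+.2f}")
    top = ex.top_expressed(norm, "P_exp_noTEX", 5)
    print(f"top-5 expressed genes (P_exp): {', '.join(top)}")
    print(f"wrote expression tables under {RESULTS}")


if __name__ == "__main__":
    main()
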