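"""Per-gene and per-transcription-unit expression from 5'-end coverage.

The expression proxy is strand-matched 5'-end read counts within the gene
body, divided by gene length in kb ("average reads per gene").  Libraries
are normalized with median-of-ratios size factors; TU values are exact sums
over operon members (singleton genes are their own TU).  Downstream
summaries: expression bins (with a "little or no transcription" bin below a
detection threshold applied to the TU's per-gene mean), pairwise log2
fold-change contrasts, and ranked top-expressed tables.  No dispersion
modeling or significance testing is done — the readout is semi-quantitative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ExpressionParams
from .io import CoverageTrack, GenomeAnnotation


def gene_counts(track: CoverageTrack, annotation: GenomeAnnotation) -> pd.Series:
    """Per-gene 5'-end reads per kb (raw, strand-matched; positions shared by
    overlapping same-strand genes count for every one of them)."""
    values = {}
    for f in annotation.features:
        arr = track.counts(f.replicon, f.strand)
        total = int(arr[f.start:f.end].sum())
        values[f.locus_tag] = total / (f.length / 1000.0)
    return pd.Series(values, name=track.library_id)


def count_matrix(tracks, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Genes x libraries matrix of per-kb 5'-end counts."""
    cols = [gene_counts(t, annotation) for t in tracks]
    return pd.concat(cols, axis=1)


def size_factors(matrix: pd.DataFrame, min_count: float = 0.0) -> pd.Series:
    """Median-of-ratios normalization factors (the DESeq size-factor scheme).

    factor_j = median over genes of count_gj / geomean_g, computed over genes
    with counts above ``min_count`` in every library, then standardized so
    the factors' geometric mean is 1 — which makes normalization exactly
    idempotent (re-deriving factors from a normalized matrix gives all ones).

    ``min_count`` generalizes the usual any-zero exclusion: with a uniform
    sequencing background no count is ever literally zero, yet genes that are
    silent in some libraries must not enter the median (different silent
    fractions would otherwise shift which quantile the median picks, biasing
    the factors).  Pass the expression-detection threshold for such data.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two libraries")
    nonzero = matrix[(matrix > min_count).all(axis=1)]
    if nonzero.empty:
        raise ValueError("no gene has nonzero counts in every library")
    geomean = np.exp(np.log(nonzero).mean(axis=1))
    factors = nonzero.div(geomean, axis=0).median(axis=0)
    factors /= np.exp(np.log(factors).mean())
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, min_count: float = 0.0) -> pd.DataFrame:
    return matrix / size_factors(matrix, min_count=min_count)


def tu_expression(norm_matrix: pd.DataFrame, operons: dict[str, list[str]]
                  ) -> pd.DataFrame:
    """TU x library matrix: exact sums of member-gene values; genes absent
    from every operon become singleton TUs named by their locus_tag."""
    in_operon = set()
    rows = {}
    for tu, members in sorted(operons.items()):
        missing = [m for m in members if m not in norm_matrix.index]
        if missing:
            raise ValueError(f"operon {tu}: genes missing from matrix: {missing}")
        rows[tu] = norm_matrix.loc[members].sum(axis=0)
        in_operon.update(members)
    for tag in norm_matrix.index:
        if tag not in in_operon:
            rows[tag] = norm_matrix.loc[tag]
    return pd.DataFrame(rows).T.sort_index()


def tu_sizes(operons: dict[str, list[str]], tu_matrix: pd.DataFrame) -> pd.Series:
    sizes = {tu: len(members) for tu, members in operons.items()}
    return pd.Series({tu: sizes.get(tu, 1) for tu in tu_matrix.index})


def expression_bins(tu_matrix: pd.DataFrame, operons: dict[str, list[str]],
                    params: ExpressionParams) -> pd.DataFrame:
    """Fraction of TUs per expression bin per library.

    The silent/expressed call uses the TU's per-gene mean (TU value divided
    by member count) so multi-gene operons are not biased toward "expressed";
    expressed TUs are binned by fold over the detection threshold.  Bin
    fractions sum to 1 per library.

    Pass the *raw* TU matrix: the detection threshold is calibrated against
    the raw per-kb background floor.  Median-of-ratios factors are unreliable
    for near-quiescent libraries (e.g. stationary phase, where most genes
    carry only background), so normalized values would misclassify exactly
    the libraries this summary is about.
    """
    mean_per_gene = tu_matrix.div(tu_sizes(operons, tu_matrix), axis=0)
    t = params.detection_threshold
    edges = [t * f for f in params.fold_bins]
    labels = (["little_or_none"]
              + [f"<{int(f)}x" for f in params.fold_bins[1:]]
              + [f">={int(params.fold_bins[-1])}x"])
    out = {}
    for lib in tu_matrix.columns:
        v = mean_per_gene[lib]
        fractions = []
        prev = -np.inf
        for edge in edges:
            fractions.append(((v >= prev) & (v < edge)).mean())
            prev = edge
        fractions.append((v >= edges[-1]).mean())
        out[lib] = fractions
    return pd.DataFrame(out, index=labels)


def contrast(tu_matrix: pd.DataFrame, library_a: str, library_b: str,
             pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-TU log2((b + pc) / (a + pc)); antisymmetric in (a, b)."""
    for lib in (library_a, library_b):
        if lib not in tu_matrix.columns:
            raise KeyError(f"unknown library {lib!r}")
    a = tu_matrix[library_a] + pseudocount
    b = tu_matrix[library_b] + pseudocount
    return pd.DataFrame({
        "log2_fold_change": np.log2(b / a),
        "mean_expression": (tu_matrix[library_a] + tu_matrix[library_b]) / 2,
    })


def top_expressed(gene_matrix: pd.DataFrame, library: str, n: int) -> list[str]:
    """Top-n locus_tags by expression; ties break alphabetically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    s = gene_matrix[library]
    order = sorted(s.index, key=lambda tag: (-s[tag], tag))
    return order[:n]
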