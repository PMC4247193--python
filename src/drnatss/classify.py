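"""Positional TSS classification against the gene annotation.

Classes (multi-membership allowed):

* pTSS/sTSS — sense strand, 0..max_upstream bp upstream of a gene's start
  codon (distance measured TSS → first base of the start codon; a TSS exactly
  on the start codon's first base is upstream with a 0 nt 5'-UTR).  Per gene,
  the upstream TSS with the most summed treated reads is the pTSS, the rest
  are sTSS; height ties go to the most upstream TSS.
* iTSS — sense strand, inside the gene downstream of the start codon.
* aTSS — antisense strand, inside the gene or within antisense_flank bp of
  either gene boundary (inclusive).
* oTSS — none of the above; exclusive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ClassificationParams
from .detect import TSSCandidate
from .io import FORWARD, GenomeAnnotation

TSS_CLASSES = ("pTSS", "sTSS", "iTSS", "aTSS", "oTSS")


@dataclass
class TSSRecord:
    candidate: TSSCandidate
    assignments: set[tuple[str, str | None]] = field(default_factory=set)
    utr_length: int | None = None

    def classes(self) -> set[str]:
        return {cls for cls, _ in self.assignments}

    def genes_of(self, cls: str) -> set[str]:
        return {tag for c, tag in self.assignments if c == cls and tag}


def _upstream_distance(pos: int, strand: str, gene) -> int:
    """Signed distance TSS → start codon first base along transcription."""
    if strand == FORWARD:
        return gene.start_codon_pos - pos
    return pos - gene.start_codon_pos


def classify_tss(candidate: TSSCandidate, annotation: GenomeAnnotation,
                 params: ClassificationParams) -> set[tuple[str, str | None]]:
    """Provisional assignments for one TSS: 'upstream' (finalized to p/sTSS
    later), iTSS, aTSS; oTSS iff nothing else applies."""
    pos, strand, replicon = candidate.position, candidate.strand, candidate.replicon
    out: set[tuple[str, str | None]] = set()
    for gene in annotation.features:
        if gene.replicon != replicon:
            continue
        inside = gene.start <= pos < gene.end
        if gene.strand == strand:
            d = _upstream_distance(pos, strand, gene)
            if 0 <= d <= params.max_upstream:
                out.add(("upstream", gene.locus_tag))
            elif inside:
                out.add(("iTSS", gene.locus_tag))
        else:
            if (gene.start - params.antisense_flank <= pos
                    < gene.end + params.antisense_flank):
                out.add(("aTSS", gene.locus_tag))
    if not out:
        out.add(("oTSS", None))
    return out


def assign_primary_secondary(records: list[TSSRecord]) -> None:
    """Finalize provisional 'upstream' assignments to pTSS/sTSS in place.

    Exactly one pTSS per gene: the upstream TSS with the maximum summed
    normalized treated height; ties break to the most upstream position in
    transcription direction.
    """
    per_gene: dict[str, list[TSSRecord]] = {}
    for rec in records:
        for cls, tag in list(rec.assignments):
            if cls == "upstream":
                per_gene.setdefault(tag, []).append(rec)
    for tag, group in per_gene.items():
        strand = group[0].candidate.strand

        def rank(rec: TSSRecord):
            pos = rec.candidate.position
            upstreamness = -pos if strand == FORWARD else pos
            return (rec.candidate.total_height, upstreamness)

        primary = max(group, key=rank)
        for rec in group:
            rec.assignments.discard(("upstream", tag))
            rec.assignments.add(("pTSS" if rec is primary else "sTSS", tag))


def classify_all(candidates: list[TSSCandidate], annotation: GenomeAnnotation,
                 params: ClassificationParams) -> list[TSSRecord]:
    records = [TSSRecord(candidate=c, assignments=classify_tss(c, annotation, params))
               for c in candidates]
    assign_primary_secondary(records)
    return records


def category_summary(records: list[TSSRecord]) -> dict:
    """Unique TSS count, per-class assignment counts, pairwise class overlaps."""
    per_class = {cls: 0 for cls in TSS_CLASSES}
    overlap = {(a, b): 0 for a in TSS_CLASSES for b in TSS_CLASSES if a < b}
    total_assignments = 0
    for rec in records:
        classes = sorted(rec.classes())
        for cls, _ in rec.assignments:
            per_class[cls] += 1
            total_assignments += 1
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                overlap[(a, b)] += 1
    return {
        "unique_tss": len(records),
        "per_class": per_class,
        "total_assignments": total_assignments,
        "overlap": overlap,
    }


def terminus_enrichment(records: list[TSSRecord], annotation: GenomeAnnotation,
                        terminus_window: int) -> dict:
    """Positional bias of aTSS around opposite-strand gene termini.

    For every aTSS assignment, the TSS is near the gene's 5' terminus when it
    lies within ±terminus_window of the start codon, and near the 3' terminus
    when within ±terminus_window of the stop codon (a TSS near both termini
    of a short gene counts once per terminus).  The headline fraction is the
    share of unique aTSS near at least one terminus of any of its genes.
    """
    index = annotation.feature_index
    near5 = near3 = 0
    total = 0
    near_any = 0
    for rec in records:
        atss_genes = rec.genes_of("aTSS")
        if not atss_genes:
            continue
        total += 1
        pos = rec.candidate.position
        hit5 = hit3 = False
        for tag in atss_genes:
            gene = index[tag]
            if abs(pos - gene.start_codon_pos) <= terminus_window:
                hit5 = True
            if abs(pos - gene.stop_codon_pos) <= terminus_window:
                hit3 = True
        near5 += hit5
        near3 += hit3
        near_any += hit5 or hit3
    if total == 0:
        return {"n_atss": 0, "near_5prime": 0, "near_3prime": 0,
                "near_any_fraction": float("nan")}
    return {
        "n_atss": total,
        "near_5prime": near5,
        "near_3prime": near3,
        "near_any_fraction": near_any / total,
    }
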