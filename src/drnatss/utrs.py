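"""5'-UTR annotation, leaderless/long-UTR classes, start-codon re-annotation.

A 5'-UTR is the distance (nt) from a p/sTSS to the first base of its gene's
start codon (0 when coincident).  mRNAs are leaderless when the UTR is ≤8 nt
and long-UTR when 50..300 nt.  The re-annotation screen mirrors the dRNA-seq
curation step: for every leaderless mRNA (and every iTSS close to an
annotated start) the downstream window is scanned for an in-frame
alternative start codon; a candidate is accepted when it has a ribosome
binding site at a plausible spacer, or when adopting it moves the mRNA out
of the leaderless class.  Accepted reassignments update the annotation and
the affected TSS are re-categorized.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace

from .classify import TSSRecord, classify_all
from .config import ClassificationParams, UtrParams
from .io import FORWARD, Feature, GenomeAnnotation
from .motifs import match_iupac
from .srna import gc_content

START_CODON_PRIORITY = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class UTRRecord:
    locus_tag: str
    tss_position: int  # 0-based
    tss_class: str  # pTSS or sTSS
    utr_length: int
    leaderless: bool
    long_utr: bool
    utr_gc: float  # percent; nan for zero-length UTRs
    rbs_hit: tuple[int, str] | None = None  # (spacer nt, matched hexamer)


@dataclass
class StartReassignment:
    locus_tag: str
    old_start_pos: int  # 0-based first base of the annotated start codon
    new_start_pos: int
    new_codon: str
    rbs_found: bool
    frame_offset_codons: int
    old_utr: int | None
    new_utr: int | None
    tss_position: int


def utr_length(tss_position: int, strand: str, gene: Feature) -> int:
    """Distance in nt from the TSS to the first base of the start codon."""
    d = (gene.start_codon_pos - tss_position if strand == FORWARD
         else tss_position - gene.start_codon_pos)
    if d < 0:
        raise ValueError(
            f"TSS at {tss_position} lies downstream of {gene.locus_tag} start codon "
            "(internal TSS, not an upstream one)")
    return d


def _utr_sequence(tss_position: int, gene: Feature, ann: GenomeAnnotation) -> str:
    if gene.strand == FORWARD:
        return ann.subsequence(gene.replicon, tss_position, gene.start_codon_pos,
                               FORWARD)
    return ann.subsequence(gene.replicon, gene.start_codon_pos + 1,
                           tss_position + 1, gene.strand)


def build_utr_records(records: list[TSSRecord], annotation: GenomeAnnotation,
                      params: UtrParams) -> list[UTRRecord]:
    """One UTRRecord per (p/sTSS, gene) assignment; fills record.utr_length
    with the pTSS UTR (or the single p/s assignment's UTR)."""
    index = annotation.feature_index
    out: list[UTRRecord] = []
    for rec in records:
        for cls, tag in sorted(rec.assignments):
            if cls not in ("pTSS", "sTSS") or tag is None:
                continue
            gene = index[tag]
            L = utr_length(rec.candidate.position, rec.candidate.strand, gene)
            seq = _utr_sequence(rec.candidate.position, gene, annotation)
            rbs = _find_rbs_in_utr(seq, params)
            out.append(UTRRecord(
                locus_tag=tag, tss_position=rec.candidate.position, tss_class=cls,
                utr_length=L,
                leaderless=L <= params.leaderless_max,
                long_utr=params.long_min <= L <= params.long_max,
                utr_gc=gc_content(seq) if seq else float("nan"),
                rbs_hit=rbs,
            ))
            if cls == "pTSS" or rec.utr_length is None:
                rec.utr_length = L
    return out


def _find_rbs_in_utr(utr_seq: str, params: UtrParams) -> tuple[int, str] | None:
    """GGDGRD-type hexamer whose 3' end sits rbs_spacer_min..max nt upstream
    of the start codon, searched within the UTR sequence itself."""
    w = len(params.rbs_pattern)
    for off in match_iupac(utr_seq, params.rbs_pattern):
        spacer = len(utr_seq) - (off + w)
        if params.rbs_spacer_min <= spacer <= params.rbs_spacer_max:
            return spacer, utr_seq[off:off + w]
    return None


@dataclass
class UTRSummary:
    n: int
    median: float
    leaderless_fraction: float
    long_fraction: float
    long_utr_mean_gc: float


def classify_utrs(utr_records: list[UTRRecord]) -> UTRSummary:
    """Summary statistics over the combined pTSS+sTSS UTR set."""
    if not utr_records:
        raise ValueError("no UTR records")
    lengths = [r.utr_length for r in utr_records]
    long_gc = [r.utr_gc for r in utr_records if r.long_utr and r.utr_gc == r.utr_gc]
    return UTRSummary(
        n=len(lengths),
        median=float(statistics.median(lengths)),
        leaderless_fraction=sum(r.leaderless for r in utr_records) / len(lengths),
        long_fraction=sum(r.long_utr for r in utr_records) / len(lengths),
        long_utr_mean_gc=(sum(long_gc) / len(long_gc)) if long_gc else float("nan"),
    )


# ---------------------------------------------------------------------------
# Start-codon re-annotation


def _codon_at(ann: GenomeAnnotation, gene: Feature, pos: int) -> str:
    """Transcription-oriented codon whose first base is at 0-based pos."""
    if gene.strand == FORWARD:
        return ann.subsequence(gene.replicon, pos, pos + 3, FORWARD)
    return ann.subsequence(gene.replicon, pos - 2, pos + 1, gene.strand)


def _downstream_pos(pos: int, strand: str, offset: int) -> int:
    return pos + offset if strand == FORWARD else pos - offset


def _has_rbs_upstream(ann: GenomeAnnotation, gene: Feature, start_pos: int,
                      params: UtrParams) -> bool:
    """GGDGRD with spacer rbs_spacer_min..max upstream of a candidate start,
    scanned on the genome (the element may lie upstream of the TSS)."""
    span = params.rbs_spacer_max + len(params.rbs_pattern)
    if gene.strand == FORWARD:
        lo = start_pos - span
        if lo < 0:
            lo = 0
        region = ann.subsequence(gene.replicon, lo, start_pos, FORWARD)
    else:
        hi = min(start_pos + 1 + span, ann.replicon_length(gene.replicon))
        region = ann.subsequence(gene.replicon, start_pos + 1, hi, gene.strand)
    w = len(params.rbs_pattern)
    for off in match_iupac(region, params.rbs_pattern):
        spacer = len(region) - (off + w)
        if params.rbs_spacer_min <= spacer <= params.rbs_spacer_max:
            return True
    return False


def reassign_start_codon(gene: Feature, rec: TSSRecord, annotation: GenomeAnnotation,
                         params: UtrParams) -> StartReassignment | None:
    """Screen one (gene, TSS) pair for a better downstream start codon.

    Applies to leaderless p/sTSS records and to iTSS lying within
    ``reassign_window`` nt downstream of the annotated start.  In-frame
    candidate starts are collected from the annotated start (exclusive) to
    the end of the scan window, stopping at the first in-frame stop codon.
    Candidates are ranked ATG before GTG before TTG, nearest first within a
    codon class, and the first one that either carries an RBS at a 4–15 nt
    spacer or lifts the record out of the leaderless class is accepted.
    """
    tss = rec.candidate.position
    strand = gene.strand
    is_leaderless_case = False
    if ("iTSS", gene.locus_tag) in rec.assignments:
        depth = (tss - gene.start_codon_pos if strand == FORWARD
                 else gene.start_codon_pos - tss)
        if not (0 < depth <= params.reassign_window):
            return None
        old_utr = None
    else:
        old_utr = utr_length(tss, strand, gene)
        if old_utr > params.leaderless_max:
            return None
        is_leaderless_case = True

    scan_end = _downstream_pos(tss, strand, params.reassign_window)
    candidates: list[tuple[int, int, str]] = []  # (priority, distance, codon)
    by_pos: dict[tuple[int, int], int] = {}
    offset = 3
    while True:
        pos = _downstream_pos(gene.start_codon_pos, strand, offset)
        if strand == FORWARD:
            if pos + 2 >= gene.end or pos > scan_end:
                break
        else:
            if pos - 2 < gene.start or pos < scan_end:
                break
        codon = _codon_at(annotation, gene, pos)
        if codon in STOP_CODONS:
            break
        if codon in START_CODON_PRIORITY:
            prio = START_CODON_PRIORITY.index(codon)
            candidates.append((prio, offset, codon))
            by_pos[(prio, offset)] = pos
        offset += 3
    for prio, off, codon in sorted(candidates):
        pos = by_pos[(prio, off)]
        moved = (replace(gene, start=pos) if strand == FORWARD
                 else replace(gene, end=pos + 1))
        try:
            new_utr = utr_length(tss, strand, moved)
        except ValueError:  # TSS still internal to the shortened gene
            new_utr = None
        rbs = _has_rbs_upstream(annotation, gene, pos, params)
        escapes = (is_leaderless_case and new_utr is not None
                   and new_utr > params.leaderless_max)
        if rbs or escapes:
            return StartReassignment(
                locus_tag=gene.locus_tag,
                old_start_pos=gene.start_codon_pos,
                new_start_pos=pos,
                new_codon=codon,
                rbs_found=rbs,
                frame_offset_codons=off // 3,
                old_utr=old_utr,
                new_utr=new_utr,
                tss_position=tss,
            )
    return None


def screen_reassignments(records: list[TSSRecord], annotation: GenomeAnnotation,
                         params: UtrParams) -> list[StartReassignment]:
    """Run the re-annotation screen over all eligible (TSS, gene) pairs;
    at most one reassignment per gene (the first eligible TSS wins, scanning
    records in genomic order)."""
    index = annotation.feature_index
    done: set[str] = set()
    out: list[StartReassignment] = []
    ordered = sorted(records, key=lambda r: (r.candidate.replicon,
                                             r.candidate.position))
    for rec in ordered:
        for cls, tag in sorted(rec.assignments):
            if tag is None or tag in done or cls not in ("pTSS", "sTSS", "iTSS"):
                continue
            gene = index[tag]
            if gene.kind != "CDS":
                continue
            r = reassign_start_codon(gene, rec, annotation, params)
            if r is not None:
                out.append(r)
                done.add(tag)
    return out


def apply_reassignments(annotation: GenomeAnnotation,
                        reassignments: list[StartReassignment]) -> GenomeAnnotation:
    """New annotation with CDS starts moved to the accepted codons."""
    moves = {r.locus_tag: r for r in reassignments}
    feats = []
    for f in annotation.features:
        r = moves.get(f.locus_tag)
        if r is None:
            feats.append(f)
        elif f.strand == FORWARD:
            feats.append(replace(f, start=r.new_start_pos))
        else:
            feats.append(replace(f, end=r.new_start_pos + 1))
    return GenomeAnnotation(sequences=annotation.sequences, features=feats,
                            operons=dict(annotation.operons))


def recategorize(records: list[TSSRecord], reassignments: list[StartReassignment],
                 annotation: GenomeAnnotation, class_params: ClassificationParams,
                 utr_params: UtrParams
                 ) -> tuple[list[TSSRecord], list[UTRRecord], GenomeAnnotation, list]:
    """Re-run classification and UTR annotation against the updated starts.

    Returns (records, utr_records, updated_annotation, change_log); with an
    empty reassignment list the records are reproduced unchanged.
    """
    updated = apply_reassignments(annotation, reassignments)
    new_records = classify_all([r.candidate for r in records], updated, class_params)
    new_utrs = build_utr_records(new_records, updated, utr_params)
    old_by_key = {(r.candidate.replicon, r.candidate.position, r.candidate.strand): r
                  for r in records}
    changes = []
    for rec in new_records:
        key = (rec.candidate.replicon, rec.candidate.position, rec.candidate.strand)
        old = old_by_key.get(key)
        if old is not None and old.assignments != rec.assignments:
            changes.append((key, sorted(old.assignments), sorted(rec.assignments)))
    return new_records, new_utrs, updated, changes
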