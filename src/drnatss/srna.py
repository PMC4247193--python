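"""Small-RNA sequence features: pairwise conservation, ORF screen, GC content.

The conservation statistic is the number of identical nucleotides in the
best local alignment of a query sRNA against a subject sequence, divided by
the query length, times 100; values >= 40% are retained by default.  The
aligner is a hand-written affine-gap Smith–Waterman (gap of length k costs
open + (k-1)*extend); for long subjects an exact-word seed-and-extend with a
banded extension stands in for the full matrix, falling back to full dynamic
programming below 2 kb.  Both orientations of the subject are searched; the
query is never reverse-complemented so the denominator is stable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import revcomp

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class AlignParams:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    min_word: int = 10
    retain_threshold: float = 40.0
    full_dp_max_len: int = 2000
    band: int = 24

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")


@dataclass
class Alignment:
    score: int
    identical_nt: int
    aligned_columns: int
    query_span: tuple[int, int]    # 0-based half-open on the query
    subject_span: tuple[int, int]  # on the given subject orientation
    subject_reverse: bool


@dataclass
class ConservationResult:
    query_id: str
    subject_id: str
    identical_nt: int
    query_length: int
    conservation_value: float
    retained: bool


def smith_waterman(query: str, subject: str, params: AlignParams,
                   q_offset: int = 0, s_offset: int = 0) -> Alignment:
    """Full affine-gap local alignment with traceback identity counting."""
    if not query or not subject:
        raise ValueError("empty sequence")
    n, m = len(query), len(subject)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (vertical)
    best, bi, bj = 0.0, 0, 0
    go, ge = params.gap_open, params.gap_extend
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + ge, H[i][j - 1] + go)
            F[i][j] = max(F[i - 1][j] + ge, H[i - 1][j] + go)
            sub = params.match if qi == subject[j - 1] else params.mismatch
            h = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    # traceback from (bi, bj)
    i, j = bi, bj
    ident = cols = 0
    state = "H"
    while i > 0 and j > 0 and H[i][j] > 0:
        if state == "H":
            sub = params.match if query[i - 1] == subject[j - 1] else params.mismatch
            if H[i][j] == H[i - 1][j - 1] + sub:
                cols += 1
                if query[i - 1] == subject[j - 1]:
                    ident += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            elif H[i][j] == F[i][j]:
                state = "F"
            else:  # H == 0, local start
                break
        elif state == "E":
            cols += 1
            if E[i][j] == H[i][j - 1] + go:
                state = "H"
            j -= 1
        else:
            cols += 1
            if F[i][j] == H[i - 1][j] + go:
                state = "H"
            i -= 1
    return Alignment(score=int(best), identical_nt=ident, aligned_columns=cols,
                     query_span=(q_offset + i, q_offset + bi),
                     subject_span=(s_offset + j, s_offset + bj),
                     subject_reverse=False)


def _seed_and_extend(query: str, subject: str, params: AlignParams) -> Alignment:
    """Exact-word seeding (>= min_word) followed by banded SW extension
    around the best seed diagonal."""
    w = params.min_word
    words: dict[str, list[int]] = {}
    for i in range(len(query) - w + 1):
        words.setdefault(query[i:i + w], []).append(i)
    best_seed = None  # (run_length, qpos, spos)
    j = 0
    while j <= len(subject) - w:
        hit = words.get(subject[j:j + w])
        if hit:
            for qpos in hit:
                # extend the exact match greedily to measure the run
                k = w
                while (qpos + k < len(query) and j + k < len(subject)
                       and query[qpos + k] == subject[j + k]):
                    k += 1
                if best_seed is None or k > best_seed[0]:
                    best_seed = (k, qpos, j)
        j += 1
    if best_seed is None:
        return Alignment(0, 0, 0, (0, 0), (0, 0), False)
    run, qpos, spos = best_seed
    pad = params.band + len(query)
    s_lo = max(0, spos - qpos - pad)
    s_hi = min(len(subject), spos + (len(query) - qpos) + pad)
    return smith_waterman(query, subject[s_lo:s_hi], params, s_offset=s_lo)


def local_align(query: str, subject: str, params: AlignParams | None = None
                ) -> Alignment:
    """Best local alignment of query against either orientation of subject."""
    params = params or AlignParams()
    for name, s in (("query", query), ("subject", subject)):
        if not s:
            raise ValueError(f"empty {name} sequence")
        if set(s) - set("ACGT"):
            raise ValueError(f"{name} contains non-ACGT characters")
    results = []
    for rev, subj in ((False, subject), (True, revcomp(subject))):
        if len(query) < params.full_dp_max_len and len(subj) < params.full_dp_max_len:
            aln = smith_waterman(query, subj, params)
        else:
            aln = _seed_and_extend(query, subj, params)
        aln.subject_reverse = rev
        results.append(aln)
    return max(results, key=lambda a: (a.score, a.identical_nt))


def conservation_from_counts(identical_nt: int, query_length: int,
                             retain_threshold: float = 40.0
                             ) -> tuple[float, bool]:
    if query_length <= 0:
        raise ValueError("zero-length query")
    value = identical_nt / query_length * 100.0
    return value, value >= retain_threshold


def conservation_value(query: str, subject: str, params: AlignParams | None = None,
                       query_id: str = "query", subject_id: str = "subject"
                       ) -> ConservationResult:
    """Percentage conservation of a query sRNA in a subject sequence:
    identical nucleotides in the best local alignment / query length x 100;
    retained at >= retain_threshold.  Gapped columns are non-identical."""
    params = params or AlignParams()
    aln = local_align(query, subject, params)
    value, retained = conservation_from_counts(aln.identical_nt, len(query),
                                               params.retain_threshold)
    return ConservationResult(
        query_id=query_id, subject_id=subject_id,
        identical_nt=aln.identical_nt, query_length=len(query),
        conservation_value=value, retained=retained,
    )


@dataclass
class ORF:
    frame: int       # 0, 1, 2
    start: int       # 0-based offset of the start codon in the transcript
    end: int         # 0-based offset just past the stop codon
    codons: int      # length in codons, start included, stop excluded


def orf_scan(transcript: str, min_codons: int = 10) -> list[ORF]:
    """All sense-strand ORFs longer than ``min_codons`` codons.

    An ORF runs from a start codon (ATG/GTG/TTG) to the next in-frame stop;
    ORFs without a stop in the transcript are not reported; nested starts to
    the same stop each yield an ORF.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = transcript.upper()
    out: list[ORF] = []
    for frame in range(3):
        stops_after: dict[int, int] = {}
        stop_positions = [i for i in range(frame, len(seq) - 2, 3)
                          if seq[i:i + 3] in STOP_CODONS]
        for i in range(frame, len(seq) - 2, 3):
            if seq[i:i + 3] in START_CODONS:
                stop = next((s for s in stop_positions if s > i), None)
                if stop is None:
                    continue
                codons = (stop - i) // 3
                if codons > min_codons:
                    out.append(ORF(frame=frame, start=i, end=stop + 3,
                                   codons=codons))
    out.sort(key=lambda o: (o.start, o.end))
    return out


def is_noncoding(transcript: str, min_codons: int = 10) -> bool:
    """True when no ORF longer than ``min_codons`` codons is present."""
    return not orf_scan(transcript, min_codons)


def gc_content(sequence: str) -> float:
    """(G+C) / (non-N length) x 100; N bases excluded from both sides."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    denom = sum(1 for b in seq if b != "N")
    if denom == 0:
        raise ValueError("sequence is all N")
    gc = sum(1 for b in seq if b in "GC")
    return gc / denom * 100.0
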