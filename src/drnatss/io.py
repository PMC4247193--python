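"""Shared data model and file I/O for the dRNA-seq annotation pipeline.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open.  On disk the standard
dialects are kept: GFF3 and variableStep wiggle are 1-based inclusive.
Replicons are linear; windows are truncated at replicon ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

FORWARD = "+"
REVERSE = "-"

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Feature:
    """A gene/CDS/ncRNA feature, 0-based half-open, strand-aware."""

    locus_tag: str
    replicon: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.locus_tag}: start must be < end")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"{self.locus_tag}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_codon_pos(self) -> int:
        """0-based position of the first base of the annotated start codon."""
        return self.start if self.strand == FORWARD else self.end - 1

    @property
    def stop_codon_pos(self) -> int:
        """0-based position of the last base of the feature (3' boundary)."""
        return self.end - 1 if self.strand == FORWARD else self.start


@dataclass
class GenomeAnnotation:
    """Genome sequence(s) plus strand-aware features and operon membership."""

    sequences: dict[str, str] = field(default_factory=dict)
    features: list[Feature] = field(default_factory=list)
    operons: dict[str, list[str]] = field(default_factory=dict)

    def replicon_length(self, replicon: str) -> int:
        return len(self.sequences[replicon])

    def feature(self, locus_tag: str) -> Feature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    @property
    def feature_index(self) -> dict[str, Feature]:
        return {f.locus_tag: f for f in self.features}

    def validate(self) -> None:
        seen = set()
        idx = set()
        for f in self.features:
            if f.replicon not in self.sequences:
                raise ValueError(f"{f.locus_tag}: unknown replicon {f.replicon}")
            if f.end > self.replicon_length(f.replicon):
                raise ValueError(f"{f.locus_tag}: extends beyond replicon end")
            if f.locus_tag in seen:
                raise ValueError(f"duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)
            if f.kind == "CDS" and f.length % 3 != 0:
                warnings.warn(
                    f"CDS {f.locus_tag} length {f.length} is not a multiple of 3; "
                    "retained (possible pseudogene)",
                    stacklevel=2,
                )
            idx.add(f.locus_tag)
        for op, members in self.operons.items():
            if len(set(members)) != len(members):
                raise ValueError(f"operon {op}: duplicate members")
            for m in members:
                if m not in idx:
                    raise ValueError(f"operon {op}: unknown member {m}")

    def subsequence(self, replicon: str, start: int, end: int, strand: str) -> str:
        """Transcription-oriented subsequence (reverse-complemented on −)."""
        s = self.sequences[replicon][max(start, 0) : end]
        return s if strand == FORWARD else revcomp(s)


def read_genome(path) -> GenomeAnnotation:
    """Read a FASTA genome; sequences normalized to uppercase A/C/G/T/N."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name:
            raise ParseError(f"{path}: record with empty header")
        if name in sequences:
            raise ParseError(f"{path}: duplicate replicon name {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: replicon {name!r} has empty sequence")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ParseError(f"{path}: replicon {name!r} has non-ACGTN characters {bad}")
        sequences[name] = seq
    if not sequences:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeAnnotation(sequences=sequences)


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_annotation(path, genome: GenomeAnnotation) -> GenomeAnnotation:
    """Read gene/CDS/ncRNA rows from GFF3 into a GenomeAnnotation.

    When both a gene and a CDS row carry the same locus_tag the CDS row wins
    (it defines the coding span).  Coordinates are validated against the
    genome; missing locus_tag or out-of-range features raise ParseError.
    """
    by_tag: dict[str, Feature] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            if ftype not in ("gene", "CDS", "ncRNA"):
                continue
            attr = _gff_attributes(attrs)
            tag = attr.get("locus_tag")
            if not tag:
                raise ParseError(f"{path}:{lineno}: feature without locus_tag")
            if seqid not in genome.sequences:
                raise ParseError(f"{path}:{lineno}: unknown replicon {seqid!r}")
            start0, end0 = int(start) - 1, int(end)
            if start0 < 0 or end0 > genome.replicon_length(seqid):
                raise ParseError(f"{path}:{lineno}: {tag} outside replicon bounds")
            feat = Feature(tag, seqid, start0, end0, strand, kind=ftype)
            if tag in by_tag:
                # CDS row refines a gene row; otherwise duplicate definitions clash
                prev = by_tag[tag]
                if ftype == "CDS" and prev.kind == "gene":
                    by_tag[tag] = feat
                elif ftype == "gene" and prev.kind == "CDS":
                    pass
                else:
                    raise ParseError(f"{path}:{lineno}: duplicate feature {tag}")
            else:
                by_tag[tag] = feat
                order.append(tag)
    feats = sorted((by_tag[t] for t in order), key=lambda f: (f.replicon, f.start))
    ann = GenomeAnnotation(sequences=genome.sequences, features=feats,
                           operons=dict(genome.operons))
    ann.validate()
    return ann


def write_annotation(ann: GenomeAnnotation, path) -> None:
    """Write features as GFF3 (gene + CDS row pairs for coding features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(ann.features, key=lambda f: (f.replicon, f.start)):
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            row = [f.replicon, "drnatss", None, str(f.start + 1), str(f.end),
                   ".", f.strand, ".", attrs]
            if f.kind == "CDS":
                row[2] = "gene"
                fh.write("\t".join(row) + "\n")
                row[2] = "CDS"
                fh.write("\t".join(row) + "\n")
            else:
                row[2] = f.kind
                fh.write("\t".join(row) + "\n")


def read_operons(path) -> dict[str, list[str]]:
    """TSV with columns operon_id, locus_tag (ordered)."""
    operons: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("operon_id"):
            raise ParseError(f"{path}: expected header starting with operon_id")
        for line in fh:
            if not line.strip():
                continue
            op, tag = line.rstrip("\n").split("\t")
            operons.setdefault(op, []).append(tag)
    return operons


def write_operons(operons: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\tlocus_tag\n")
        for op in sorted(operons):
            for tag in operons[op]:
                fh.write(f"{op}\t{tag}\n")


@dataclass
class CoverageTrack:
    """Per-strand integer counts of read 5' ends for one library."""

    library_id: str
    condition: str
    treated: bool
    counts_fwd: dict[str, np.ndarray]
    counts_rev: dict[str, np.ndarray]

    @property
    def library_size(self) -> int:
        return int(sum(int(a.sum()) for a in self.counts_fwd.values())
                   + sum(int(a.sum()) for a in self.counts_rev.values()))

    def counts(self, replicon: str, strand: str) -> np.ndarray:
        return (self.counts_fwd if strand == FORWARD else self.counts_rev)[replicon]

    def replicons(self) -> list[str]:
        return sorted(self.counts_fwd)


def _read_wiggle(path, genome: GenomeAnnotation) -> dict[str, np.ndarray]:
    arrays = {name: np.zeros(len(seq), dtype=np.int64)
              for name, seq in genome.sequences.items()}
    current = None
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("variableStep"):
                fields = dict(p.split("=", 1) for p in line.split()[1:])
                current = fields.get("chrom")
                if current not in arrays:
                    raise ParseError(f"{path}:{lineno}: unknown replicon {current!r}")
                continue
            if current is None:
                raise ParseError(f"{path}:{lineno}: data before variableStep header")
            pos_s, val_s = line.split()
            pos, val = int(pos_s), float(val_s)
            if val < 0:
                raise ParseError(f"{path}:{lineno}: negative value")
            if pos < 1 or pos > len(arrays[current]):
                raise ParseError(f"{path}:{lineno}: position {pos} outside replicon")
            if (current, pos) in seen:
                raise ParseError(f"{path}:{lineno}: duplicate position {pos}")
            seen.add((current, pos))
            arrays[current][pos - 1] = int(round(val))
    return arrays


def read_coverage(path_fwd, path_rev, genome: GenomeAnnotation, library_id: str,
                  condition: str, treated: bool) -> CoverageTrack:
    """Read a variableStep wiggle pair (one file per strand) into a dense track."""
    return CoverageTrack(
        library_id=library_id, condition=condition, treated=treated,
        counts_fwd=_read_wiggle(path_fwd, genome),
        counts_rev=_read_wiggle(path_rev, genome),
    )


def write_coverage(track: CoverageTrack, path_fwd, path_rev) -> None:
    for path, arrays in ((path_fwd, track.counts_fwd), (path_rev, track.counts_rev)):
        with open(path, "w") as fh:
            for replicon in sorted(arrays):
                fh.write(f"variableStep chrom={replicon}\n")
                arr = arrays[replicon]
                (idx,) = np.nonzero(arr)
                for i in idx:
                    fh.write(f"{i + 1} {int(arr[i])}\n")


# ---------------------------------------------------------------------------
# TSS master table (one row per class assignment)

TSS_TABLE_COLUMNS = [
    "replicon", "position", "strand", "tss_class", "locus_tag", "utr_length",
    "enrichment_factor", "step_factor", "heights", "detected_in",
]


def _fmt_heights(heights: dict[str, float]) -> str:
    return ",".join(f"{k}={heights[k]:.6g}" for k in sorted(heights))


def _parse_heights(text: str) -> dict[str, float]:
    if not text:
        return {}
    return {k: float(v) for k, v in (p.split("=", 1) for p in text.split(","))}


def write_tss_table(records, path) -> None:
    """Write classified TSS records as TSV, one row per (TSS, class assignment).

    Rows are ordered by (replicon, position, strand, class, locus_tag) for
    stable diffs; positions are written 1-based.
    """
    rows = []
    for rec in records:
        cand = rec.candidate
        for cls, tag in sorted(rec.assignments, key=lambda a: (a[0], a[1] or "")):
            rows.append((
                cand.replicon, cand.position + 1, cand.strand, cls, tag or ".",
                "." if rec.utr_length is None or (cls not in ("pTSS", "sTSS"))
                else str(rec.utr_length),
                f"{cand.enrichment_factor:.6g}", f"{cand.step_factor:.6g}",
                _fmt_heights(cand.heights), ",".join(sorted(cand.detected_in)),
            ))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3], r[4]))
    with open(path, "w") as fh:
        fh.write("\t".join(TSS_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tss_table(path):
    """Re-read a TSS table written by write_tss_table (round-trip identity)."""
    from .classify import TSSRecord
    from .detect import TSSCandidate

    grouped: dict[tuple, TSSRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSS_TABLE_COLUMNS:
            raise ParseError(f"{path}: unexpected header")
        for line in fh:
            if not line.strip():
                continue
            (replicon, pos, strand, cls, tag, utr, enr, step, heights,
             detected) = line.rstrip("\n").split("\t")
            key = (replicon, int(pos) - 1, strand)
            if key not in grouped:
                cand = TSSCandidate(
                    replicon=replicon, position=int(pos) - 1, strand=strand,
                    heights=_parse_heights(heights),
                    enrichment_factor=float(enr), step_factor=float(step),
                    detected_in=frozenset(d for d in detected.split(",") if d),
                )
                grouped[key] = TSSRecord(candidate=cand, assignments=set())
            rec = grouped[key]
            rec.assignments.add((cls, None if tag == "." else tag))
            if utr != ".":
                rec.utr_length = int(utr)
    return [grouped[k] for k in sorted(grouped)]
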