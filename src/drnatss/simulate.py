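"""Synthetic archaeal genomes with planted primary-transcriptome structure.

The generator builds a genome, its gene/operon annotation, and per-condition
TEX-treated / untreated 5'-end coverage with a full ground-truth ledger, so
every pipeline stage can be tested against known answers.  What is planted
mirrors the statistical structure dRNA-seq analysis assumes:

* one primary TSS per transcription unit (TU), with BRE + TATA promoter
  elements at median 33 / 23 bp upstream (shared Gaussian positional jitter);
* a 5'-UTR length mixture (median 16 nt; leaderless ≤8 nt and long 50–300 nt
  classes planted as exact stratified counts);
* a Shine–Dalgarno-like RBS (GGDGRD) upstream of ~half the start codons;
* secondary, internal, antisense (concentrated near gene termini) and orphan
  TSS; mis-annotated GTG starts whose true in-frame ATG lies 3 codons
  downstream with a planted RBS;
* RNA-processing sites whose 5' ends appear only in untreated libraries,
  while primary 5' ends are TEX-enriched (untreated libraries keep an
  attenuated copy);
* a per-TU, per-condition expression program with exact-count silent
  fractions and a two-TU "sulfur switch" (one TU on→off, one off→on).

Coverage is Poisson: peak reads at planted 5' ends (with ±1 nt smear),
dispersed intra-transcript 5' ends proportional to expression, and a uniform
background.  Fixed seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .classify import TSSRecord, assign_primary_secondary, classify_tss
from .config import ClassificationParams
from .detect import TSSCandidate
from .io import FORWARD, REVERSE, CoverageTrack, Feature, GenomeAnnotation, revcomp

REPLICON = "chr"
STOPS = ("TAA", "TAG", "TGA")
STARTS = ("ATG", "GTG", "TTG")
CLASS_HEIGHT = {"pTSS": 1.0, "sTSS": 0.4, "iTSS": 0.5, "aTSS": 0.5, "oTSS": 0.8}


@dataclass
class SimulationParams:
    n_genes: int = 200
    seed: int = 0
    conditions: tuple = ("S_exp", "S_stat", "P_exp", "PS")
    # genome structure
    operon_size_probs: tuple = (0.60, 0.15, 0.15, 0.10)  # TU sizes 1..k
    gene_min_codons: int = 140
    gene_max_codons: int = 280
    intergenic_gap: int = 120
    gc_coding: float = 0.42
    gc_intergenic: float = 0.40
    gc_long_utr: float = 0.48
    # 5'-UTR mixture
    utr_median: int = 16
    leaderless_fraction: float = 0.14
    long_utr_fraction: float = 0.20
    long_utr_median: int = 103
    # translation signals
    rbs_fraction: float = 0.50
    rbs_spacer_range: tuple = (4, 12)
    misannotation_count: int = 10
    # promoter motifs
    tata_consensus: str = "TTTATATA"
    bre_consensus: str = "CGAAAGT"
    tata_offset_median: int = 23
    bre_offset_median: int = 33
    offset_jitter_sd: float = 2.0
    motif_fraction: float = 0.90
    motif_mutation_rate: float = 0.03
    # extra TSS classes
    stss_fraction: float = 0.30           # of TUs carrying one secondary TSS
    itss_per_gene: float = 0.25
    atss_per_gene: float = 0.60
    atss_terminus_fraction: float = 0.58
    terminus_window: int = 150
    otss_per_gene: float = 0.15
    # expression program
    level_mu: float = 0.5                  # lognormal TU expression level
    level_sigma: float = 0.9
    level_min: float = 0.5
    level_max: float = 30.0
    silent_fractions: dict = field(default_factory=lambda: {
        "S_exp": 0.28, "S_stat": 0.87, "P_exp": 0.35, "PS": 0.28})
    switch_log2fc: float = 4.0
    switch_level: float = 10.0
    switch_conditions: tuple = ("P_exp", "PS")
    # coverage model
    depth: float = 40.0                    # expected 5'-end reads per unit level
    untreated_primary_fraction: float = 0.30
    processed_depth_fraction: float = 0.75
    treated_processing_residual: float = 0.0
    processing_sites_per_kb: float = 0.3
    internal_rate_treated: float = 0.005   # 5' ends / nt / unit level
    internal_rate_untreated: float = 0.40
    background_rate: float = 0.02          # 5' ends / nt / strand
    smear_prob: float = 0.10

    def validate(self) -> None:
        for name in ("leaderless_fraction", "long_utr_fraction", "rbs_fraction",
                     "motif_fraction", "atss_terminus_fraction", "stss_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.leaderless_fraction + self.long_utr_fraction > 1.0:
            raise ValueError("UTR class fractions exceed 1")


@dataclass
class PlantedTSS:
    tss_id: str
    replicon: str
    position: int              # 0-based
    strand: str
    intent: str                # class the generator aimed for
    locus_tag: str | None      # associated gene (intent)
    tu_id: str | None
    expected_heights: dict     # condition -> expected treated 5'-end reads
    span: tuple                # (lo, hi) 0-based half-open transcript interval
    classes: tuple = ()        # full geometric truth, incl. p/s finalization


@dataclass
class PlantedMotif:
    kind: str                  # TATA or BRE
    tss_id: str
    start: int                 # 0-based genome interval [start, end)
    end: int
    strand: str
    sequence: str              # transcript-strand sequence as planted
    offset_3p: int             # bp from motif 3' end to the TSS


@dataclass
class PlantedRBS:
    locus_tag: str
    start: int
    end: int
    strand: str
    sequence: str
    spacer: int                # nt between RBS 3' end and the start codon


@dataclass
class PlantedProcessingSite:
    replicon: str
    position: int
    strand: str
    expected_heights: dict     # condition -> expected untreated 5'-end reads


@dataclass
class PlantedMisannotation:
    locus_tag: str
    annotated_start: int       # 0-based first base of the (wrong) GTG
    true_start: int            # 0-based first base of the in-frame ATG
    offset_codons: int
    annotated_utr: int


@dataclass
class GroundTruth:
    conditions: tuple
    genome_length: int
    tss: list = field(default_factory=list)
    motifs: list = field(default_factory=list)
    rbs: list = field(default_factory=list)
    processing_sites: list = field(default_factory=list)
    misannotations: list = field(default_factory=list)
    tu_levels: dict = field(default_factory=dict)   # tu -> {condition: level}
    tu_members: dict = field(default_factory=dict)  # tu -> [locus_tag, ...]
    utr_of_gene: dict = field(default_factory=dict)

    def tss_by_class(self, cls: str) -> list:
        return [t for t in self.tss if any(c == cls for c, _ in t.classes)]

    def expressed_tss(self) -> list:
        """Planted TSS with nonzero expected reads in at least one library."""
        return [t for t in self.tss if any(v > 0 for v in t.expected_heights.values())]


# ---------------------------------------------------------------------------
# sequence helpers

_BASES = np.array(list("ACGT"))


def _random_seq(rng, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(_BASES, size=n, p=p))


def _random_codons(rng, n: int, gc: float, forbid: tuple = STOPS) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    out: list[str] = []
    while len(out) < n:
        batch = rng.choice(_BASES, size=(n - len(out) + 8, 3), p=p)
        for row in batch:
            codon = "".join(row)
            if codon not in forbid:
                out.append(codon)
                if len(out) == n:
                    break
    return out


def _mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = str(rng.choice([x for x in "ACGT" if x != b]))
    return "".join(out)


def _sample_rbs(rng) -> str:
    # GGDGRD, D = A/G/T, R = A/G
    return ("GG" + str(rng.choice(list("AGT"))) + "G"
            + str(rng.choice(list("AG"))) + str(rng.choice(list("AGT"))))


def _utr_mixture_params(p: SimulationParams) -> tuple[float, float]:
    """(mu, sigma) of the mid-length UTR lognormal, located so that the whole
    mixture's median lands on utr_median."""
    sigma = 0.42
    mid_frac = 1.0 - p.leaderless_fraction - p.long_utr_fraction
    if mid_frac <= 0:
        return math.log(max(p.utr_median, 1)), sigma
    q = (0.5 - p.leaderless_fraction) / mid_frac
    q = min(max(q, 0.05), 0.95)
    # aim P(mixture <= utr_median) slightly above 1/2 so the discrete sample
    # median lands on utr_median rather than hovering one above it
    mu = math.log(p.utr_median) - sigma * float(norm.ppf(q))
    return mu, sigma


def _exact_count_flags(rng, n: int, fraction: float) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    k = int(round(fraction * n))
    if k > 0:
        flags[rng.choice(n, size=min(k, n), replace=False)] = True
    return flags


# ---------------------------------------------------------------------------
# genome generation


class _TU:
    """Working state for one transcription unit during layout."""

    def __init__(self, tu_id, strand, gene_codons):
        self.tu_id = tu_id
        self.strand = strand
        self.gene_codons = gene_codons  # body codons per member gene
        self.category = "mid"           # pTSS UTR class: leaderless / mid / long
        self.stss_category = None
        self.utr = 0
        self.utr_s = None               # sTSS's own UTR draw
        self.has_stss = False
        self.has_motif = False
        self.misannotated = False
        self.rbs_flags = [False] * len(gene_codons)
        # filled during block build (local '+' coordinates)
        self.seq: list[str] = []
        self.genes: list[tuple[int, int]] = []      # local [start, end)
        self.tss_local = 0
        self.stss_local: int | None = None
        self.motifs_local: list[tuple[str, int, int, str, int]] = []
        self.rbs_local: list[tuple[int, int, int, str, int]] = []  # gene_i, s, e, seq, spacer
        self.mis_local: tuple[int, int] | None = None  # (annotated, true) start
        self.offset = 0  # genome offset of the block after assembly


def _sample_utr(rng, category: str, p: SimulationParams, mid_mu, mid_sigma) -> int:
    if category == "leaderless":
        return int(rng.integers(0, 9))
    if category == "long":
        L = int(round(float(rng.lognormal(math.log(p.long_utr_median), 0.35))))
        return int(min(max(L, 50), 300))
    L = int(round(float(rng.lognormal(mid_mu, mid_sigma))))
    return int(min(max(L, 9), 49))


def _build_block(rng, tu: _TU, p: SimulationParams) -> None:
    """Assemble one TU's sequence and local (+-oriented) coordinates."""
    # the secondary TSS has its own UTR draw from the same mixture, so the
    # combined p+sTSS UTR statistics reproduce the configured mixture
    upstream_extent = 53
    if tu.has_stss and tu.utr_s is not None and tu.utr_s > tu.utr:
        upstream_extent += tu.utr_s - tu.utr
    tss = upstream_extent
    gene_start = tss + tu.utr

    seq: list[str] = _random_seq(rng, gene_start, p.gc_intergenic)
    # UTR base composition (long UTRs are slightly GC-richer)
    if tu.utr > 0:
        gc = p.gc_long_utr if tu.category == "long" else p.gc_coding
        seq[gene_start - tu.utr:gene_start] = _random_seq(rng, tu.utr, gc)

    genes = []
    cursor = gene_start
    for gi, ncod in enumerate(tu.gene_codons):
        start_codon = "GTG" if (tu.misannotated and gi == 0) else "ATG"
        body: list[str] = []
        if tu.misannotated and gi == 0:
            # codons 1-2 free of starts/stops, codon 3 is the true ATG
            body += _random_codons(rng, 2, p.gc_coding, forbid=STOPS + STARTS)
            body.append("ATG")
            body += _random_codons(rng, ncod - 3, p.gc_coding)
        elif gi == 0 and any(u is not None and u <= 8 for u in (tu.utr, tu.utr_s)):
            # a leaderless p- or sTSS will enter the re-annotation screen:
            # scrub in-frame alternative starts from its whole scan window
            lead = min(u for u in (tu.utr, tu.utr_s) if u is not None and u <= 8)
            n_scrub = max(0, min(ncod, (100 - lead) // 3 + 2))
            body += _random_codons(rng, n_scrub, p.gc_coding, forbid=STOPS + STARTS)
            body += _random_codons(rng, ncod - n_scrub, p.gc_coding)
        else:
            body += _random_codons(rng, ncod, p.gc_coding)
        stop = str(rng.choice(list(STOPS)))
        coding = start_codon + "".join(body) + stop
        seq += list(coding)
        genes.append((cursor, cursor + len(coding)))
        if tu.misannotated and gi == 0:
            tu.mis_local = (cursor, cursor + 9)
        cursor += len(coding)
        if gi < len(tu.gene_codons) - 1:
            gap = int(rng.integers(20, 61))
            seq += _random_seq(rng, gap, p.gc_intergenic)
            cursor += gap
    seq += _random_seq(rng, 40, p.gc_intergenic)

    # ribosome binding sites (4-12 nt spacer upstream of the start codon)
    for gi, flag in enumerate(tu.rbs_flags):
        if not flag or (tu.misannotated and gi == 0):
            continue
        lo_sp, hi_sp = p.rbs_spacer_range
        if gi == 0:
            # the element must fit inside the transcript: shrink the spacer
            # for short UTRs, skip leaderless-ish genes entirely
            hi_sp = min(hi_sp, tu.utr - 6)
            if hi_sp < lo_sp:
                continue
        spacer = int(rng.integers(lo_sp, hi_sp + 1))
        hexamer = _sample_rbs(rng)
        s = genes[gi][0] - spacer - 6
        seq[s:s + 6] = list(hexamer)
        tu.rbs_local.append((gi, s, s + 6, hexamer, spacer))
    if tu.misannotated:
        # RBS for the true ATG, entirely upstream of the annotated GTG
        spacer = int(rng.integers(10, 13))
        hexamer = _sample_rbs(rng)
        true_atg = genes[0][0] + 9
        s = true_atg - spacer - 6
        seq[s:s + 6] = list(hexamer)
        tu.rbs_local.append((0, s, s + 6, hexamer, spacer))

    # promoter: BRE + TATA with one shared positional jitter
    if tu.has_motif:
        j = int(round(rng.normal(0.0, p.offset_jitter_sd)))
        j = max(-5, min(5, j))
        for kind, consensus, median in (("TATA", p.tata_consensus, p.tata_offset_median),
                                        ("BRE", p.bre_consensus, p.bre_offset_median)):
            d = median + j
            w = len(consensus)
            planted = _mutate(rng, consensus, p.motif_mutation_rate)
            s = tss - d - (w - 1)
            seq[s:s + w] = list(planted)
            tu.motifs_local.append((kind, s, s + w, planted, d))

    tu.seq = seq
    tu.genes = genes
    tu.tss_local = tss
    if tu.has_stss and tu.utr_s is not None:
        tu.stss_local = gene_start - tu.utr_s


def _flip_block(tu: _TU) -> None:
    """Reverse-complement a block, turning local + coordinates into − ones."""
    L = len(tu.seq)
    tu.seq = list(revcomp("".join(tu.seq)))
    tu.genes = [(L - e, L - s) for s, e in tu.genes]
    tu.tss_local = L - 1 - tu.tss_local
    if tu.stss_local is not None:
        tu.stss_local = L - 1 - tu.stss_local
    tu.motifs_local = [(k, L - e, L - s, seq, d) for k, s, e, seq, d in tu.motifs_local]
    tu.rbs_local = [(gi, L - e, L - s, seq, sp) for gi, s, e, seq, sp in tu.rbs_local]
    if tu.mis_local is not None:
        s, e = tu.mis_local
        tu.mis_local = (L - e, L - s)


def _downstream(pos: int, strand: str, offset: int) -> int:
    return pos + offset if strand == FORWARD else pos - offset


def generate_genome(params: SimulationParams
                    ) -> tuple[GenomeAnnotation, GroundTruth]:
    """Build the genome, annotation and ground-truth ledger (no coverage)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    mid_mu, mid_sigma = _utr_mixture_params(params)

    # ---- transcription units -------------------------------------------
    sizes = []
    total = 0
    probs = np.asarray(params.operon_size_probs, dtype=float)
    probs = probs / probs.sum()
    while total < params.n_genes:
        k = int(rng.choice(np.arange(1, len(probs) + 1), p=probs))
        k = min(k, params.n_genes - total)
        sizes.append(k)
        total += k
    n_tu = len(sizes)

    tus: list[_TU] = []
    for i, k in enumerate(sizes):
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        codons = [int(rng.integers(params.gene_min_codons,
                                   params.gene_max_codons + 1)) for _ in range(k)]
        tus.append(_TU(f"TU{i + 1:04d}", strand, codons))

    for tu, flag in zip(tus, _exact_count_flags(rng, n_tu, params.stss_fraction)):
        tu.has_stss = bool(flag)
    for tu, flag in zip(tus, _exact_count_flags(rng, n_tu, params.motif_fraction)):
        tu.has_motif = bool(flag)

    # UTR classes planted as exact stratified counts over the *combined*
    # pTSS+sTSS population, which is what the UTR summary is computed on
    n_records = n_tu + sum(tu.has_stss for tu in tus)
    n_lead = int(round(params.leaderless_fraction * n_records))
    n_long = int(round(params.long_utr_fraction * n_records))
    if n_lead + n_long > n_records:
        raise ValueError("UTR class counts exceed the number of p/sTSS records")
    categories = (["leaderless"] * n_lead + ["long"] * n_long
                  + ["mid"] * (n_records - n_lead - n_long))
    rng.shuffle(categories)
    it = iter(categories)
    for tu in tus:
        tu.category = next(it)
    for tu in tus:
        if tu.has_stss:
            tu.stss_category = next(it)

    lead_idx = [i for i, tu in enumerate(tus) if tu.category == "leaderless"]
    if params.misannotation_count > len(lead_idx):
        raise ValueError(
            f"cannot plant {params.misannotation_count} mis-annotations: only "
            f"{len(lead_idx)} leaderless TUs available (raise n_genes or "
            "leaderless_fraction)")
    for i in rng.choice(lead_idx, size=params.misannotation_count, replace=False):
        tus[int(i)].misannotated = True

    gene_flags = _exact_count_flags(rng, params.n_genes, params.rbs_fraction)
    gi = 0
    for tu in tus:
        for k in range(len(tu.gene_codons)):
            tu.rbs_flags[k] = bool(gene_flags[gi])
            gi += 1

    for tu in tus:
        tu.utr = _sample_utr(rng, tu.category, params, mid_mu, mid_sigma)
        if tu.has_stss:
            # the two TSS must sit >=6 nt apart so their peaks never cluster
            for _try in range(100):
                tu.utr_s = _sample_utr(rng, tu.stss_category, params,
                                       mid_mu, mid_sigma)
                if abs(tu.utr_s - tu.utr) >= 6:
                    break
                if _try > 50:
                    tu.utr = _sample_utr(rng, tu.category, params,
                                         mid_mu, mid_sigma)
            else:
                raise ValueError("could not separate pTSS and sTSS UTR draws")
        _build_block(rng, tu, params)
        if tu.strand == REVERSE:
            _flip_block(tu)

    # ---- expression program --------------------------------------------
    levels = np.clip(rng.lognormal(params.level_mu, params.level_sigma, size=n_tu),
                     params.level_min, params.level_max)
    switch_idx = [i for i, tu in enumerate(tus) if len(tu.gene_codons) == 1][:2]
    tu_levels: dict[str, dict[str, float]] = {
        tu.tu_id: {c: float(levels[i]) for c in params.conditions}
        for i, tu in enumerate(tus)}
    pool = [i for i in range(n_tu) if i not in switch_idx]
    for cond, frac in params.silent_fractions.items():
        if cond not in params.conditions:
            continue
        k = min(int(round(frac * n_tu)), len(pool))
        for i in rng.choice(pool, size=k, replace=False):
            tu_levels[tus[int(i)].tu_id][cond] = 0.0
    if len(switch_idx) == 2:
        on, off = params.switch_level, params.switch_level / 2 ** params.switch_log2fc
        a, b = params.switch_conditions
        tu_a, tu_b = tus[switch_idx[0]].tu_id, tus[switch_idx[1]].tu_id
        tu_levels[tu_a][a], tu_levels[tu_a][b] = on, off   # on -> off
        tu_levels[tu_b][a], tu_levels[tu_b][b] = off, on   # off -> on

    # ---- assembly -------------------------------------------------------
    otss_count = int(round(params.otss_per_gene * params.n_genes))
    otss_after = set(int(i) for i in rng.choice(
        n_tu, size=min(otss_count, n_tu), replace=False))
    seq_parts: list[str] = ["".join(_random_seq(rng, 400, params.gc_intergenic))]
    cursor = 400
    otss_positions: list[tuple[int, str]] = []
    for i, tu in enumerate(tus):
        tu.offset = cursor
        seq_parts.append("".join(tu.seq))
        cursor += len(tu.seq)
        gap = params.intergenic_gap + int(rng.integers(0, 61))
        if i in otss_after:
            zone = 900
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            otss_positions.append((cursor + zone // 2, strand))
            seq_parts.append("".join(_random_seq(rng, zone, params.gc_intergenic)))
            cursor += zone
        seq_parts.append("".join(_random_seq(rng, gap, params.gc_intergenic)))
        cursor += gap
    seq_parts.append("".join(_random_seq(rng, 400, params.gc_intergenic)))
    cursor += 400
    genome_seq = "".join(seq_parts)
    L = len(genome_seq)

    # ---- features, truth ------------------------------------------------
    features: list[Feature] = []
    operons: dict[str, list[str]] = {}
    truth = GroundTruth(conditions=tuple(params.conditions), genome_length=L)
    truth.tu_levels = {k: dict(v) for k, v in tu_levels.items()}
    tag_counter = 0
    taken: dict[str, set[int]] = {FORWARD: set(), REVERSE: set()}

    def reserve(pos: int, strand: str) -> bool:
        """Claim a TSS position, enforcing >=5 nt same-strand separation."""
        if any(q in taken[strand] for q in range(pos - 5, pos + 6)):
            return False
        taken[strand].add(pos)
        return True

    for tu in tus:
        members = []  # transcription order: members[0] is promoter-proximal
        for (s, e) in tu.genes:
            tag_counter += 1
            tag = f"SYN_{tag_counter:04d}"
            members.append(tag)
            features.append(Feature(tag, REPLICON, tu.offset + s, tu.offset + e,
                                    tu.strand, kind="CDS"))
        operons[tu.tu_id] = members
        truth.tu_members[tu.tu_id] = members
        first = members[0]
        truth.utr_of_gene[first] = tu.utr
        if tu.utr_s is not None:
            truth.utr_of_gene[f"{first}:s"] = tu.utr_s

        tss_pos = tu.offset + tu.tss_local
        # transcript: from the TSS to the far end of the TU
        if tu.strand == FORWARD:
            span = (tss_pos, tu.offset + max(e for _, e in tu.genes))
        else:
            span = (tu.offset + min(s for s, _ in tu.genes), tss_pos + 1)
        reserve(tss_pos, tu.strand)
        heights = {c: CLASS_HEIGHT["pTSS"] * params.depth * tu_levels[tu.tu_id][c]
                   for c in params.conditions}
        truth.tss.append(PlantedTSS(
            tss_id=f"{tu.tu_id}:p", replicon=REPLICON, position=tss_pos,
            strand=tu.strand, intent="pTSS", locus_tag=first, tu_id=tu.tu_id,
            expected_heights=heights, span=span))
        if tu.stss_local is not None:
            spos = tu.offset + tu.stss_local
            reserve(spos, tu.strand)
            sheights = {c: CLASS_HEIGHT["sTSS"] * params.depth
                        * tu_levels[tu.tu_id][c] for c in params.conditions}
            s_span = ((spos, span[1]) if tu.strand == FORWARD
                      else (span[0], spos + 1))
            truth.tss.append(PlantedTSS(
                tss_id=f"{tu.tu_id}:s", replicon=REPLICON, position=spos,
                strand=tu.strand, intent="sTSS", locus_tag=first, tu_id=tu.tu_id,
                expected_heights=sheights, span=s_span))
        for kind, s, e, mseq, d in tu.motifs_local:
            truth.motifs.append(PlantedMotif(
                kind=kind, tss_id=f"{tu.tu_id}:p", start=tu.offset + s,
                end=tu.offset + e, strand=tu.strand, sequence=mseq, offset_3p=d))
        for gidx, s, e, rseq, spacer in tu.rbs_local:
            truth.rbs.append(PlantedRBS(
                locus_tag=members[gidx], start=tu.offset + s, end=tu.offset + e,
                strand=tu.strand, sequence=rseq, spacer=spacer))
        if tu.mis_local is not None:
            a, b = tu.mis_local
            if tu.strand == FORWARD:
                annotated, true_start = tu.offset + a, tu.offset + a + 9
            else:
                annotated, true_start = tu.offset + b - 1, tu.offset + b - 1 - 9
            truth.misannotations.append(PlantedMisannotation(
                locus_tag=first, annotated_start=annotated, true_start=true_start,
                offset_codons=3, annotated_utr=tu.utr))

    annotation = GenomeAnnotation(sequences={REPLICON: genome_seq},
                                  features=sorted(features,
                                                  key=lambda f: f.start),
                                  operons=operons)
    annotation.validate()

    # orphan TSS in dedicated intergenic zones
    level_pool = np.clip(rng.lognormal(params.level_mu, params.level_sigma,
                                       size=len(otss_positions)),
                         params.level_min, params.level_max)
    for k, (pos, strand) in enumerate(otss_positions):
        reserve(pos, strand)
        h = CLASS_HEIGHT["oTSS"] * params.depth * float(level_pool[k])
        tlen = int(rng.integers(60, 201))
        span = (pos, pos + tlen) if strand == FORWARD else (pos - tlen + 1, pos + 1)
        truth.tss.append(PlantedTSS(
            tss_id=f"o{k + 1:04d}", replicon=REPLICON, position=pos, strand=strand,
            intent="oTSS", locus_tag=None, tu_id=None,
            expected_heights={c: h for c in params.conditions}, span=span))

    # internal TSS (same strand, deep inside genes so the re-annotation screen
    # is untouched), tied to the host TU's expression program
    tu_of_gene = {tag: tu for tu in tus for tag in truth.tu_members[tu.tu_id]}
    all_tags = [f.locus_tag for f in annotation.features]
    index = annotation.feature_index
    n_itss = int(round(params.itss_per_gene * params.n_genes))
    host_tags = rng.choice(all_tags, size=n_itss, replace=False) \
        if n_itss <= len(all_tags) else all_tags
    for k, tag in enumerate(host_tags):
        gene = index[tag]
        tu = tu_of_gene[tag]
        for _try in range(40):
            # away from the start codon (re-annotation screen) and from the
            # 3' end (an iTSS close to a downstream operon member's start
            # would double as that gene's promoter TSS)
            off = int(rng.integers(110, max(gene.length - 250, 111)))
            pos = _downstream(gene.start_codon_pos, gene.strand, off)
            if reserve(pos, gene.strand):
                break
        else:
            continue
        heights = {c: CLASS_HEIGHT["iTSS"] * params.depth
                   * tu_levels[tu.tu_id][c] for c in params.conditions}
        span = ((pos, gene.end) if gene.strand == FORWARD else (gene.start, pos + 1))
        truth.tss.append(PlantedTSS(
            tss_id=f"i{k + 1:04d}", replicon=REPLICON, position=pos,
            strand=gene.strand, intent="iTSS", locus_tag=tag, tu_id=tu.tu_id,
            expected_heights=heights, span=span))

    # antisense TSS, concentrated near gene termini; rejected when the
    # position would double as a sense-strand (upstream or internal) TSS of
    # some gene, so planted aTSS labels stay unambiguous
    def _sense_conflict(pos: int, strand: str) -> bool:
        for g in annotation.features:
            if g.strand != strand:
                continue
            if g.start <= pos < g.end:
                return True
            d = (g.start_codon_pos - pos if strand == FORWARD
                 else pos - g.start_codon_pos)
            if 0 <= d <= 302:
                return True
        return False

    n_atss = int(round(params.atss_per_gene * params.n_genes))
    n_term = int(round(params.atss_terminus_fraction * n_atss))
    a_levels = np.clip(rng.lognormal(params.level_mu, params.level_sigma,
                                     size=n_atss),
                       params.level_min, params.level_max)
    for k in range(n_atss):
        near_terminus = k < n_term
        placed = False
        for _try in range(60):
            gene = index[str(rng.choice(all_tags))]
            astrand = REVERSE if gene.strand == FORWARD else FORWARD
            if near_terminus:
                anchor = (gene.start_codon_pos if rng.random() < 0.5
                          else gene.stop_codon_pos)
                pos = anchor + int(rng.integers(-148, 149))
                if not (gene.start - 98 <= pos < gene.end + 98):
                    continue  # would not be an aTSS of this gene at all
            else:
                lo = min(gene.start_codon_pos, gene.stop_codon_pos) + 161
                hi = max(gene.start_codon_pos, gene.stop_codon_pos) - 161
                if hi <= lo:
                    continue
                pos = int(rng.integers(lo, hi + 1))
            if _sense_conflict(pos, astrand):
                continue
            if reserve(pos, astrand):
                placed = True
                break
        if not placed:
            continue
        h = CLASS_HEIGHT["aTSS"] * params.depth * float(a_levels[k])
        tlen = int(rng.integers(60, 201))
        span = (pos, pos + tlen) if astrand == FORWARD else (pos - tlen + 1, pos + 1)
        truth.tss.append(PlantedTSS(
            tss_id=f"a{k + 1:04d}", replicon=REPLICON, position=pos, strand=astrand,
            intent="aTSS", locus_tag=gene.locus_tag, tu_id=None,
            expected_heights={c: h for c in params.conditions}, span=span))

    # processing sites within transcripts (untreated-library 5' ends)
    for tu in tus:
        pt = next(t for t in truth.tss if t.tss_id == f"{tu.tu_id}:p")
        span_len = pt.span[1] - pt.span[0]
        n_sites = int(rng.poisson(params.processing_sites_per_kb * span_len / 1000))
        for _ in range(n_sites):
            for _try in range(30):
                pos = int(rng.integers(pt.span[0], pt.span[1]))
                if reserve(pos, tu.strand):
                    break
            else:
                continue
            heights = {c: params.processed_depth_fraction * params.depth
                       * tu_levels[tu.tu_id][c] for c in params.conditions}
            truth.processing_sites.append(PlantedProcessingSite(
                replicon=REPLICON, position=pos, strand=tu.strand,
                expected_heights=heights))

    _finalize_truth_classes(annotation, truth, params)
    return annotation, truth


def _finalize_truth_classes(annotation: GenomeAnnotation, truth: GroundTruth,
                            params: SimulationParams) -> None:
    """Geometric class truth for every planted TSS, with the p/s split decided
    on expected summed treated heights (as the pipeline decides it)."""
    cparams = ClassificationParams(terminus_window=params.terminus_window)
    records = []
    for t in truth.tss:
        cand = TSSCandidate(replicon=t.replicon, position=t.position,
                            strand=t.strand,
                            heights=dict(t.expected_heights))
        rec = TSSRecord(candidate=cand,
                        assignments=classify_tss(cand, annotation, cparams))
        records.append(rec)
    assign_primary_secondary(records)
    for t, rec in zip(truth.tss, records):
        t.classes = tuple(sorted((cls, tag) for cls, tag in rec.assignments))


# ---------------------------------------------------------------------------
# coverage simulation


def simulate_coverage(annotation: GenomeAnnotation, truth: GroundTruth,
                      params: SimulationParams, condition: str, treated: bool,
                      seed: int) -> CoverageTrack:
    """Poisson 5'-end counts for one (condition, TEX±) library."""
    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    L = truth.genome_length
    rate = {FORWARD: np.full(L, params.background_rate),
            REVERSE: np.full(L, params.background_rate)}
    internal = (params.internal_rate_treated if treated
                else params.internal_rate_untreated)
    for t in truth.tss:
        h = t.expected_heights[condition]
        if h <= 0:
            continue
        level = h / (CLASS_HEIGHT[t.intent] * params.depth)
        lo, hi = t.span
        # processed/dispersed 5' ends accrue strictly downstream of the
        # primary +1 base (whose untreated signal is the attenuated peak)
        if t.strand == FORWARD:
            lo = min(lo + 1, hi)
        else:
            hi = max(hi - 1, lo)
        rate[t.strand][lo:hi] += internal * level
    counts = {s: rng.poisson(rate[s]).astype(np.int64) for s in (FORWARD, REVERSE)}

    def add_peak(pos: int, strand: str, expected: float) -> None:
        if expected <= 0:
            return
        n = int(rng.poisson(expected))
        if n == 0:
            return
        split = rng.multinomial(n, [params.smear_prob / 2,
                                    1 - params.smear_prob,
                                    params.smear_prob / 2])
        for d, c in zip((-1, 0, 1), split):
            q = pos + d
            if 0 <= q < L:
                counts[strand][q] += int(c)

    for t in sorted(truth.tss, key=lambda t: (t.position, t.strand)):
        scale = 1.0 if treated else params.untreated_primary_fraction
        add_peak(t.position, t.strand, t.expected_heights[condition] * scale)
    for ps in sorted(truth.processing_sites,
                     key=lambda p: (p.position, p.strand)):
        scale = params.treated_processing_residual if treated else 1.0
        add_peak(ps.position, ps.strand, ps.expected_heights[condition] * scale)

    lib = f"{condition}" if treated else f"{condition}_noTEX"
    return CoverageTrack(library_id=lib, condition=condition, treated=treated,
                         counts_fwd={REPLICON: counts[FORWARD]},
                         counts_rev={REPLICON: counts[REVERSE]})


def simulate_all_coverage(annotation: GenomeAnnotation, truth: GroundTruth,
                          params: SimulationParams
                          ) -> dict[tuple[str, bool], CoverageTrack]:
    """One TEX+/TEX− track pair per condition, with per-library seeds derived
    deterministically from the master seed."""
    tracks = {}
    for i, cond in enumerate(truth.conditions):
        for j, treated in enumerate((True, False)):
            seed = (params.seed * 1000 + i * 10 + j) % (2 ** 31)
            tracks[(cond, treated)] = simulate_coverage(
                annotation, truth, params, cond, treated, seed)
    return tracks


# ---------------------------------------------------------------------------
# ground-truth ledger I/O

_RECORD_TYPES = {
    "tss": PlantedTSS,
    "motif": PlantedMotif,
    "rbs": PlantedRBS,
    "processing_site": PlantedProcessingSite,
    "misannotation": PlantedMisannotation,
}


def write_truth(truth: GroundTruth, path) -> None:
    """Round-trippable TSV ledger: record_type + JSON payload per row."""
    with open(path, "w") as fh:
        fh.write("record_type\tpayload\n")
        fh.write("meta\t" + json.dumps(
            {"conditions": list(truth.conditions),
             "genome_length": truth.genome_length}, sort_keys=True) + "\n")
        for name, lst in (("tss", truth.tss), ("motif", truth.motifs),
                          ("rbs", truth.rbs),
                          ("processing_site", truth.processing_sites),
                          ("misannotation", truth.misannotations)):
            for rec in lst:
                fh.write(f"{name}\t" + json.dumps(asdict(rec), sort_keys=True)
                         + "\n")
        for tu, levels in truth.tu_levels.items():
            fh.write("tu_level\t" + json.dumps({"tu": tu, "levels": levels},
                                               sort_keys=True) + "\n")
        for tu, members in truth.tu_members.items():
            fh.write("tu_members\t" + json.dumps({"tu": tu, "members": members},
                                                 sort_keys=True) + "\n")
        for tag, utr in truth.utr_of_gene.items():
            fh.write("utr\t" + json.dumps({"locus_tag": tag, "length": utr},
                                          sort_keys=True) + "\n")


def read_truth(path) -> GroundTruth:
    truth = None
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record_type"):
            raise ValueError(f"{path}: not a truth ledger")
        for line in fh:
            if not line.strip():
                continue
            rtype, payload = line.rstrip("\n").split("\t", 1)
            data = json.loads(payload)
            if rtype == "meta":
                truth = GroundTruth(conditions=tuple(data["conditions"]),
                                    genome_length=data["genome_length"])
            elif rtype in _RECORD_TYPES:
                cls = _RECORD_TYPES[rtype]
                if rtype == "tss":
                    data["span"] = tuple(data["span"])
                    data["classes"] = tuple(tuple(c) for c in data["classes"])
                rec = cls(**data)
                {"tss": truth.tss, "motif": truth.motifs, "rbs": truth.rbs,
                 "processing_site": truth.processing_sites,
                 "misannotation": truth.misannotations}[rtype].append(rec)
            elif rtype == "tu_level":
                truth.tu_levels[data["tu"]] = data["levels"]
            elif rtype == "tu_members":
                truth.tu_members[data["tu"]] = data["members"]
            elif rtype == "utr":
                truth.utr_of_gene[data["locus_tag"]] = data["length"]
            else:
                raise ValueError(f"{path}: unknown record type {rtype!r}")
    if truth is None:
        raise ValueError(f"{path}: empty truth ledger")
    return truth
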