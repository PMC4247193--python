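"""Tunable thresholds for every pipeline stage, with flat key=value serialization.

Each parameter block is a dataclass with documented defaults.  A whole-pipeline
configuration round-trips through a plain text file of ``section.key=value``
lines; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields


@dataclass
class DetectionParams:
    """TSS calling thresholds.

    min_height         minimum normalized 5'-end read height in a treated library
    min_step_factor    minimum fold increase over the position immediately
                       upstream (in transcription direction)
    min_enrichment     minimum TEX-treated / untreated height ratio
    cluster_window     nt window for merging near-duplicate candidates
    pseudocount        reads added to the untreated (and upstream) height
    normalize          reads-per-million normalization of heights
    """

    min_height: float = 5.0
    min_step_factor: float = 2.0
    min_enrichment: float = 2.0
    cluster_window: int = 3
    pseudocount: float = 1.0
    normalize: bool = True


@dataclass
class ClassificationParams:
    """TSS class geometry (bp): p/sTSS within max_upstream of a start codon,
    aTSS within antisense_flank of an opposite-strand gene, terminus_window
    for the antisense 5'/3'-terminus enrichment summary."""

    max_upstream: int = 300
    antisense_flank: int = 100
    terminus_window: int = 150


@dataclass
class UtrParams:
    """5'-UTR class bounds and the start-codon re-annotation screen.

    leaderless_max     UTR length (nt) at or below which an mRNA is leaderless
    long_min/long_max  long-5'-UTR class bounds (nt)
    reassign_window    nt downstream of the TSS scanned for alternative starts;
                       also the max distance of an iTSS from the annotated
                       start for it to enter the screen
    rbs_spacer_min/max spacer (nt) between the RBS 3' end and a candidate start
    """

    leaderless_max: int = 8
    long_min: int = 50
    long_max: int = 300
    reassign_window: int = 100
    rbs_spacer_min: int = 4
    rbs_spacer_max: int = 15
    rbs_pattern: str = "GGDGRD"


@dataclass
class MotifParams:
    """Promoter/RBS motif discovery and scanning.

    Widths are configurable (TATA 8, BRE 7, RBS 6 by default).  EM is
    one-occurrence-per-sequence with ``n_restarts`` seeded restarts;
    ``hit_threshold_frac`` is the fraction of a PWM's maximum log-odds score
    above which a scan position counts as a hit.
    """

    upstream: int = 50
    tata_width: int = 8
    bre_width: int = 7
    rbs_width: int = 6
    n_restarts: int = 10
    max_iter: int = 200
    tol: float = 1e-6
    pseudocount: float = 0.25
    hit_threshold_frac: float = 0.5


@dataclass
class ExpressionParams:
    """Per-gene / per-TU expression aggregation.

    contrast_pseudocount  normalized units added to both sides of a log2 ratio
    detection_threshold   per-gene mean normalized per-kb 5'-end reads below
                          which a TU is binned as "little or no transcription"
    fold_bins             upper fold-over-threshold edges of the expression bins
    """

    contrast_pseudocount: float = 1.0
    detection_threshold: float = 50.0
    fold_bins: tuple = (1.0, 10.0, 100.0, 1000.0)


@dataclass
class PipelineConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    utr: UtrParams = field(default_factory=UtrParams)
    motif: MotifParams = field(default_factory=MotifParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)

    @classmethod
    def default(cls) -> "PipelineConfig":
        """Pipeline defaults for the synthetic study conditions.

        Identical to the dataclass defaults except that detection thresholds
        are applied to raw counts (normalize=False): a fixed height floor in
        reads-per-million units would mean a different raw-read floor for
        every library and genome size, whereas the 5-read floor is what keeps
        stray background coincidences (1-3 reads) from being called at any
        scale.  RPM normalization stays available for reporting.
        """
        cfg = cls()
        cfg.detection.normalize = False
        return cfg

    # -- flat key=value serialization ---------------------------------------
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for section in fields(self):
                block = getattr(self, section.name)
                for f in fields(block):
                    v = getattr(block, f.name)
                    if isinstance(v, tuple):
                        v = ",".join(str(x) for x in v)
                    fh.write(f"{section.name}.{f.name}={v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line or "." not in line.split("=", 1)[0]:
                    raise ValueError(f"{path}:{lineno}: expected section.key=value")
                key, raw = line.split("=", 1)
                section_name, field_name = key.strip().split(".", 1)
                if section_name not in sections:
                    raise ValueError(f"{path}:{lineno}: unknown section {section_name!r}")
                block = sections[section_name]
                ftypes = {f.name: f for f in fields(block)}
                if field_name not in ftypes:
                    raise ValueError(f"{path}:{lineno}: unknown key {key.strip()!r}")
                current = getattr(block, field_name)
                raw = raw.strip()
                if isinstance(current, bool):
                    value = raw.lower() in ("1", "true", "yes", "on")
                elif isinstance(current, int):
                    value = int(raw)
                elif isinstance(current, float):
                    value = float(raw)
                elif isinstance(current, tuple):
                    value = tuple(float(x) for x in raw.split(",") if x)
                else:
                    value = raw
                setattr(block, field_name, value)
        return cfg

    def copy(self) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            detection=dataclasses.replace(self.detection),
            classification=dataclasses.replace(self.classification),
            utr=dataclasses.replace(self.utr),
            motif=dataclasses.replace(self.motif),
            expression=dataclasses.replace(self.expression),
        )
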