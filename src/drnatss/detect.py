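"""TSS calling from paired TEX-treated / untreated 5'-end coverage.

A position is a candidate TSS when, in a treated library, its (normalized)
5'-end height clears an absolute floor, rises sharply over the position
immediately upstream in transcription direction (step factor), and is
enriched over the untreated library at the same position (TEX enrichment
factor).  Candidates within a small window are clustered to absorb ±1 nt
read-end jitter, and calls from different libraries/conditions are merged
as a union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DetectionParams
from .io import FORWARD, REVERSE, CoverageTrack


@dataclass
class TSSCandidate:
    replicon: str
    position: int  # 0-based
    strand: str
    heights: dict[str, float] = field(default_factory=dict)  # per treated library
    enrichment_factor: float = 0.0
    step_factor: float = 0.0
    detected_in: frozenset = frozenset()

    @property
    def total_height(self) -> float:
        return float(sum(self.heights.values()))


def normalize_track(track: CoverageTrack, normalize: bool = True
                    ) -> dict[tuple[str, str], np.ndarray]:
    """Per-position heights: counts x 1e6 / library_size (both strands pooled)
    when ``normalize``; raw counts otherwise."""
    if normalize:
        size = track.library_size
        if size <= 0:
            raise ValueError(f"library {track.library_id}: zero library size")
        factor = 1e6 / size
    else:
        factor = 1.0
    out = {}
    for replicon in track.replicons():
        out[(replicon, FORWARD)] = track.counts_fwd[replicon] * factor
        out[(replicon, REVERSE)] = track.counts_rev[replicon] * factor
    return out


def step_metrics(height_treated: np.ndarray, height_untreated: np.ndarray,
                 position: int, strand: str, params: DetectionParams
                 ) -> tuple[float, float, float]:
    """(height, step_factor, enrichment_factor) at one position.

    The upstream neighbour is position-1 on + and position+1 on −.  At a
    replicon edge no rise over upstream coverage can be demonstrated, so the
    off-array neighbour counts as the position's own height (step factor 1).
    """
    h = float(height_treated[position])
    up = position - 1 if strand == FORWARD else position + 1
    upstream = float(height_treated[up]) if 0 <= up < len(height_treated) else h
    step = h / max(upstream, params.pseudocount)
    enrich = h / (float(height_untreated[position]) + params.pseudocount)
    return h, step, enrich


def call_candidates(treated: CoverageTrack, untreated: CoverageTrack,
                    params: DetectionParams) -> list[TSSCandidate]:
    """All positions passing height, step and enrichment thresholds, both strands."""
    ht = normalize_track(treated, params.normalize)
    hu = normalize_track(untreated, params.normalize)
    if set(ht) != set(hu) or any(ht[k].shape != hu[k].shape for k in ht):
        raise ValueError("treated/untreated tracks have mismatched replicon layout")
    out: list[TSSCandidate] = []
    for (replicon, strand), h in sorted(ht.items()):
        u = hu[(replicon, strand)]
        if strand == FORWARD:
            upstream = np.concatenate((h[:1], h[:-1]))
        else:
            upstream = np.concatenate((h[1:], h[-1:]))
        step = h / np.maximum(upstream, params.pseudocount)
        enrich = h / (u + params.pseudocount)
        mask = ((h >= params.min_height)
                & (step >= params.min_step_factor)
                & (enrich >= params.min_enrichment))
        for pos in np.nonzero(mask)[0]:
            out.append(TSSCandidate(
                replicon=replicon, position=int(pos), strand=strand,
                heights={treated.library_id: float(h[pos])},
                enrichment_factor=float(enrich[pos]),
                step_factor=float(step[pos]),
                detected_in=frozenset({treated.library_id}),
            ))
    out.sort(key=lambda c: (c.replicon, c.strand, c.position))
    return out


def _clusters(positions: list[int], window: int) -> list[list[int]]:
    """Single-linkage 1-D clustering: indices of sorted positions whose
    consecutive gaps are <= window belong to one cluster."""
    groups: list[list[int]] = []
    for i, p in enumerate(positions):
        if groups and p - positions[groups[-1][-1]] <= window:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def _more_upstream(a: int, b: int, strand: str) -> bool:
    return a < b if strand == FORWARD else a > b


def cluster_candidates(candidates: list[TSSCandidate], cluster_window: int
                       ) -> list[TSSCandidate]:
    """Merge same-strand candidates within ``cluster_window`` nt.

    The representative is the member with the maximum height (its own height
    is kept, not a sum); height ties go to the most upstream position in
    transcription direction.
    """
    out: list[TSSCandidate] = []
    bykey: dict[tuple[str, str], list[TSSCandidate]] = {}
    for c in candidates:
        bykey.setdefault((c.replicon, c.strand), []).append(c)
    for (replicon, strand), group in sorted(bykey.items()):
        group.sort(key=lambda c: c.position)
        positions = [c.position for c in group]
        for idxs in _clusters(positions, cluster_window):
            best = group[idxs[0]]
            for i in idxs[1:]:
                c = group[i]
                if (c.total_height > best.total_height
                        or (c.total_height == best.total_height
                            and _more_upstream(c.position, best.position, strand))):
                    best = c
            out.append(best)
    out.sort(key=lambda c: (c.replicon, c.strand, c.position))
    return out


def merge_libraries(per_library: list[list[TSSCandidate]], position_tolerance: int = 1
                    ) -> list[TSSCandidate]:
    """Union of TSS calls across libraries.

    Calls within ``position_tolerance`` nt on the same strand are unified to
    the position with the highest summed (over libraries) height; the merged
    record carries per-library heights, the maximum enrichment/step factors
    seen, and the set of contributing libraries.
    """
    if not per_library:
        raise ValueError("need at least one candidate list")
    pool: list[TSSCandidate] = [c for lst in per_library for c in lst]
    bykey: dict[tuple[str, str], list[TSSCandidate]] = {}
    for c in pool:
        bykey.setdefault((c.replicon, c.strand), []).append(c)
    merged: list[TSSCandidate] = []
    for (replicon, strand), group in sorted(bykey.items()):
        group.sort(key=lambda c: c.position)
        positions = [c.position for c in group]
        for idxs in _clusters(positions, position_tolerance):
            members = [group[i] for i in idxs]
            summed: dict[int, float] = {}
            for m in members:
                summed[m.position] = summed.get(m.position, 0.0) + m.total_height
            rep = max(
                summed,
                key=lambda p: (summed[p],
                               -p if strand == FORWARD else p),
            )
            heights: dict[str, float] = {}
            detected: set[str] = set()
            for m in members:
                detected |= set(m.detected_in)
                for lib, h in m.heights.items():
                    heights[lib] = max(heights.get(lib, 0.0), h)
            merged.append(TSSCandidate(
                replicon=replicon, position=rep, strand=strand, heights=heights,
                enrichment_factor=max(m.enrichment_factor for m in members),
                step_factor=max(m.step_factor for m in members),
                detected_in=frozenset(detected),
            ))
    merged.sort(key=lambda c: (c.replicon, c.strand, c.position))
    return merged


def detect_tss(tracks: dict[tuple[str, bool], CoverageTrack],
               params: DetectionParams) -> list[TSSCandidate]:
    """Full detection over a set of (condition, treated) coverage tracks.

    Candidates are called per condition from its TEX+/TEX− pair, clustered,
    then merged across conditions (union semantics, ±1 nt).
    """
    per_condition: list[list[TSSCandidate]] = []
    conditions = sorted({cond for cond, _ in tracks})
    for cond in conditions:
        treated = tracks[(cond, True)]
        untreated = tracks[(cond, False)]
        cands = call_candidates(treated, untreated, params)
        per_condition.append(cluster_candidates(cands, params.cluster_window))
    merged = merge_libraries(per_condition, position_tolerance=1)
    # the p/s ranking downstream uses "most sequencing reads": record every
    # treated library's height at the final position, not only the libraries
    # in which the TSS passed the calling thresholds
    normalized = {cond: normalize_track(tracks[(cond, True)], params.normalize)
                  for cond in conditions}
    for c in merged:
        for cond in conditions:
            h = float(normalized[cond][(c.replicon, c.strand)][c.position])
            lib = tracks[(cond, True)].library_id
            c.heights[lib] = max(c.heights.get(lib, 0.0), h)
    return merged
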