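"""Promoter/RBS motif discovery and scanning.

Discovery is a one-occurrence-per-sequence (OOPS) expectation–maximization
over fixed-width position weight matrices: every input window is assumed to
contain exactly one motif site at an unknown offset; the E-step computes the
posterior over offsets under the current PWM against a 0-order background,
the M-step re-estimates the PWM from posterior-weighted counts with
pseudocounts.  The best of several seeded restarts (by log-likelihood) is
kept, so results are deterministic given a seed.  Scanning is plain additive
log-odds (bits) on the sense strand; degenerate IUPAC patterns (e.g. the
ribosome-binding consensus GGDGRD) are matched exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64,
                           count=len(seq))
    except KeyError as e:
        raise ValueError(f"non-ACGT base {e} in sequence") from None


@dataclass
class MotifModel:
    pwm: np.ndarray        # (width, 4) column-stochastic over ACGT
    background: np.ndarray  # (4,)
    width: int
    log_likelihood: float

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.pwm.argmax(axis=1))

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) log2(pwm / background)."""
        return np.log2(self.pwm) - np.log2(self.background)[None, :]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def to_file(self, path) -> None:
        """One row per motif position, four columns A C G T."""
        with open(path, "w") as fh:
            fh.write("# pos\tA\tC\tG\tT\n")
            for i, row in enumerate(self.pwm, 1):
                fh.write(f"{i}\t" + "\t".join(f"{p:.6f}" for p in row) + "\n")


@dataclass
class MotifHit:
    anchor_id: str
    offset: int           # 0-based start of the hit within the scanned window
    matched: str
    score: float          # log-odds, bits

    def three_prime_distance(self, window_length: int, width: int) -> int:
        """Distance (bp) from the motif's 3'-most base to the window's last
        base (the TSS anchor in −upstream..TSS windows)."""
        return (window_length - 1) - (self.offset + width - 1)


def extract_windows(records, annotation, upstream: int = 50, classes=None
                    ) -> tuple[list[str], list[str]]:
    """Strand-aware (upstream+1)-nt windows ending on each TSS base.

    Windows that would be truncated by a replicon edge are excluded.
    Returns (sequences, anchor ids 'replicon:pos1:strand').
    """
    seqs: list[str] = []
    anchors: list[str] = []
    for rec in records:
        if classes is not None and not (rec.classes() & set(classes)):
            continue
        c = rec.candidate
        L = annotation.replicon_length(c.replicon)
        if c.strand == "+":
            lo, hi = c.position - upstream, c.position + 1
        else:
            lo, hi = c.position, c.position + upstream + 1
        if lo < 0 or hi > L:
            continue
        seqs.append(annotation.subsequence(c.replicon, lo, hi, c.strand))
        anchors.append(f"{c.replicon}:{c.position + 1}:{c.strand}")
    return seqs, anchors


def _background_from(seq_arrays: list[np.ndarray]) -> np.ndarray:
    counts = np.zeros(4)
    for a in seq_arrays:
        counts += np.bincount(a, minlength=4)
    return counts / counts.sum()


def _site_matrix(arr: np.ndarray, width: int) -> np.ndarray:
    """(n_sites, width) array of all w-mers of one sequence."""
    n = len(arr) - width + 1
    return np.lib.stride_tricks.sliding_window_view(arr, width)[:n]


def find_motif_em(sequences: list[str], width: int, n_restarts: int = 10,
                  seed: int = 0, max_iter: int = 200, tol: float = 1e-6,
                  pseudocount: float = 0.25
                  ) -> tuple[MotifModel, list[int]]:
    """OOPS EM motif discovery; returns the best model over restarts and the
    maximum-posterior site offset per sequence.

    The log-likelihood is guaranteed non-decreasing across EM iterations;
    two runs with the same seed are identical.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    for i, s in enumerate(sequences):
        if len(s) < width:
            raise ValueError(f"sequence {i} shorter than motif width {width}")
    arrays = [encode(s) for s in sequences]
    background = _background_from(arrays)
    log_bg = np.log(background)
    sites = [_site_matrix(a, width) for a in arrays]
    lengths = {m.shape[0] for m in sites}
    pad = max(lengths)
    # stack into (n_seq, pad, width); short sequences padded with masked rows
    S = np.zeros((len(sites), pad, width), dtype=np.int64)
    valid = np.zeros((len(sites), pad), dtype=bool)
    for i, m in enumerate(sites):
        S[i, :m.shape[0]] = m
        valid[i, :m.shape[0]] = True
    widx = np.arange(width)
    # constant part of the LL: background over every base of every sequence,
    # plus the uniform site prior
    const = (sum(float(log_bg[a].sum()) for a in arrays)
             + sum(-np.log(m.shape[0]) for m in sites))

    def _scores(log_ratio: np.ndarray) -> np.ndarray:
        s = log_ratio[widx[None, None, :], S].sum(axis=2)  # (n, pad)
        return np.where(valid, s, -np.inf)

    rng = np.random.default_rng(seed)

    def _em(pwm: np.ndarray) -> tuple[float, np.ndarray]:
        prev_ll = -np.inf
        for _it in range(max_iter):
            log_ratio = np.log(pwm) - log_bg[None, :]  # (w,4)
            scores = _scores(log_ratio)
            ll = const + float(logsumexp(scores, axis=1).sum())
            z = np.exp(scores - scores.max(axis=1, keepdims=True))
            z /= z.sum(axis=1, keepdims=True)
            counts = np.full((width, 4), pseudocount)
            zflat = z.ravel()
            for k in range(width):
                counts[k] += np.bincount(S[:, :, k].ravel(), weights=zflat,
                                         minlength=4)
            pwm = counts / counts.sum(axis=1, keepdims=True)
            if ll - prev_ll < tol and _it > 0:
                return ll, pwm
            prev_ll = ll
        return prev_ll, pwm

    def _best_sites(pwm: np.ndarray) -> np.ndarray:
        return _scores(np.log(pwm) - log_bg[None, :]).argmax(axis=1)

    best: tuple[float, np.ndarray] | None = None
    flat = [(si, off) for si, m in enumerate(sites) for off in range(m.shape[0])]
    for _ in range(n_restarts):
        si, off = flat[rng.integers(len(flat))]
        seed_site = sites[si][off]
        pwm0 = np.full((width, 4), 0.15)
        pwm0[widx, seed_site] = 0.55
        ll, pwm = _em(pwm0)
        if best is None or ll > best[0]:
            best = (ll, pwm)
    # phase polish: EM converges to column-shifted optima; refit from the best
    # sites shifted by ±1..2 and keep the highest-likelihood model
    base_sites = _best_sites(best[1])
    limits = np.array([m.shape[0] - 1 for m in sites])
    for delta in (-2, -1, 1, 2):
        shifted = np.clip(base_sites + delta, 0, limits)
        counts = np.full((width, 4), pseudocount)
        for i, off in enumerate(shifted):
            counts[widx, sites[i][off]] += 1.0
        ll, pwm = _em(counts / counts.sum(axis=1, keepdims=True))
        if ll > best[0]:
            best = (ll, pwm)
    ll, pwm = best
    site_hats = [int(i) for i in _best_sites(pwm)]
    model = MotifModel(pwm=pwm, background=background, width=width,
                       log_likelihood=float(ll))
    return model, site_hats


def mask_sites(sequences: list[str], site_offsets: list[int], width: int,
               seed: int = 0) -> list[str]:
    """Replace each best site with background-sampled bases (for discovering
    a second motif in the same windows)."""
    rng = np.random.default_rng(seed)
    out = []
    for s, off in zip(sequences, site_offsets):
        repl = "".join(rng.choice(list(ALPHABET), size=width))
        out.append(s[:off] + repl + s[off + width:])
    return out


def scan_pwm(sequence: str, model: MotifModel, threshold_bits: float,
             anchor_id: str = "") -> list[MotifHit]:
    """Additive log-odds scan on the sense strand; hits score >= threshold."""
    if len(sequence) < model.width:
        return []
    arr = encode(sequence)
    lo = model.log_odds
    sites = _site_matrix(arr, model.width)
    scores = lo[np.arange(model.width)[None, :], sites].sum(axis=1)
    hits = []
    for off in np.nonzero(scores >= threshold_bits)[0]:
        hits.append(MotifHit(anchor_id=anchor_id, offset=int(off),
                             matched=sequence[off:off + model.width],
                             score=float(scores[off])))
    return hits


def match_iupac(sequence: str, pattern: str) -> list[int]:
    """All offsets at which the IUPAC ``pattern`` matches exactly."""
    sets = []
    for code in pattern:
        if code.upper() not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r}")
        sets.append(set(IUPAC[code.upper()]))
    w = len(pattern)
    out = []
    for off in range(len(sequence) - w + 1):
        if all(sequence[off + k] in sets[k] for k in range(w)):
            out.append(off)
    return out


@dataclass
class OffsetSummary:
    n_anchors: int
    n_with_hit: int
    fraction_with_hit: float
    median_offset: float  # bp from motif 3' end to the TSS; nan if no hits
    histogram: dict[int, int]


def best_hits(windows: list[str], anchors: list[str], model: MotifModel,
              threshold_bits: float) -> list[MotifHit | None]:
    """Best-scoring hit per window (None when no position clears threshold)."""
    out = []
    for seq, anchor in zip(windows, anchors):
        hits = scan_pwm(seq, model, threshold_bits, anchor_id=anchor)
        out.append(max(hits, key=lambda h: h.score) if hits else None)
    return out


def offset_distribution(hits: list[MotifHit | None], window_length: int,
                        width: int) -> OffsetSummary:
    """Median/ histogram of motif→TSS distances over anchors with a hit.

    Distances are measured from the motif's 3'-most base to the TSS (the last
    base of each window); anchors without hits count toward the fraction but
    not the median.
    """
    dists = [h.three_prime_distance(window_length, width) for h in hits
             if h is not None]
    hist: dict[int, int] = {}
    for d in dists:
        hist[d] = hist.get(d, 0) + 1
    n = len(hits)
    return OffsetSummary(
        n_anchors=n,
        n_with_hit=len(dists),
        fraction_with_hit=len(dists) / n if n else float("nan"),
        median_offset=float(np.median(dists)) if dists else float("nan"),
        histogram=dict(sorted(hist.items())),
    )
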