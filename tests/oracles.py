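"""Independent brute-force reference implementations used only by tests.

These are deliberately written as plain, slow, nested-loop code so they form
a second route to the same answers as the package's vectorized/indexed
implementations.
"""

from __future__ import annotations


def naive_classify(pos, strand, genes, max_upstream=300, antisense_flank=100):
    """Direct transcription of the positional class rules.

    genes: list of (locus_tag, start, end, strand) with 0-based half-open
    coordinates; the start codon's first base is at ``start`` on + and
    ``end - 1`` on −.  Returns a set of (class, locus_tag) with the
    upstream-sense class left provisional as 'upstream'.
    """
    out = set()
    for tag, gstart, gend, gstrand in genes:
        sc = gstart if gstrand == "+" else gend - 1
        if gstrand == strand:
            dist = sc - pos if strand == "+" else pos - sc
            if 0 <= dist <= max_upstream:
                out.add(("upstream", tag))
            elif gstart <= pos < gend:
                out.add(("iTSS", tag))
        else:
            if gstart - antisense_flank <= pos < gend + antisense_flank:
                out.add(("aTSS", tag))
    if not out:
        out.add(("oTSS", None))
    return out


def naive_primary_secondary(tss_list, genes, max_upstream=300,
                            antisense_flank=100):
    """Full classification of (pos, strand, height) tuples, finalizing the
    per-gene p/s split by maximum height with upstream tie-break."""
    assigned = [naive_classify(p, s, genes, max_upstream, antisense_flank)
                for p, s, _h in tss_list]
    for tag, gstart, gend, gstrand in genes:
        group = [i for i, a in enumerate(assigned) if ("upstream", tag) in a]
        if not group:
            continue
        def rank(i):
            pos, strand, h = tss_list[i]
            return (h, -pos if strand == "+" else pos)
        best = max(group, key=rank)
        for i in group:
            assigned[i].discard(("upstream", tag))
            assigned[i].add(("pTSS" if i == best else "sTSS", tag))
    return assigned


def naive_cluster(positions, window):
    """Single-linkage clustering of sorted 1-D positions: partition only."""
    parts = []
    for p in sorted(positions):
        placed = False
        for part in parts:
            if any(abs(p - q) <= window for q in part):
                part.append(p)
                placed = True
        if not placed:
            parts.append([p])
    # merge transitively (a later point can bridge two parts)
    changed = True
    while changed:
        changed = False
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                if any(abs(a - b) <= window for a in parts[i] for b in parts[j]):
                    parts[i] += parts[j]
                    del parts[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(sorted(p)) for p in parts)


def naive_scan_hits(seq, log_odds, threshold):
    """Per-offset PWM scoring by explicit loops; returns offsets >= threshold."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    width = len(log_odds)
    hits = []
    for off in range(len(seq) - width + 1):
        score = 0.0
        for k in range(width):
            score += log_odds[k][base_index[seq[off + k]]]
        if score >= threshold:
            hits.append(off)
    return hits


def naive_size_factors(matrix_rows):
    """Median-of-ratios (standardized to geometric mean 1) on a dict
    gene -> list of counts (per library)."""
    import math
    n_lib = len(next(iter(matrix_rows.values())))
    usable = {g: v for g, v in matrix_rows.items() if all(x > 0 for x in v)}
    factors = []
    for j in range(n_lib):
        ratios = []
        for g, v in usable.items():
            geo = math.exp(sum(math.log(x) for x in v) / n_lib)
            ratios.append(v[j] / geo)
        ratios.sort()
        m = len(ratios)
        med = (ratios[m // 2] if m % 2 == 1
               else 0.5 * (ratios[m // 2 - 1] + ratios[m // 2]))
        factors.append(med)
    g = math.exp(sum(math.log(f) for f in factors) / n_lib)
    return [f / g for f in factors]


def naive_orfs(seq, min_codons):
    starts = ("ATG", "GTG", "TTG")
    stops = ("TAA", "TAG", "TGA")
    found = []
    for i in range(len(seq) - 2):
        if seq[i:i + 3] in starts:
            j = i + 3
            while j + 3 <= len(seq):
                if seq[j:j + 3] in stops:
                    if (j - i) // 3 > min_codons:
                        found.append((i % 3, i, j + 3, (j - i) // 3))
                    break
                j += 3
    return sorted(found)
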