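"""Independent brute-force / exact-arithmetic oracles used by the tests.

These deliberately avoid the implementation paths they check: the count
test is re-derived with exact rational arithmetic, tag matching with a
naive sliding-window Hamming scan, and clustering with an O(n^2)
union-find over pairwise chains.
"""

from __future__ import annotations

from fractions import Fraction

from supersage.models import AnchorRecord, TranscriptModel

TAG_LENGTH = 26
ANCHOR = "CATG"


def ac_pvalue_exact(x: int, total_a: int, y: int, total_b: int) -> Fraction:
    """Two-sided Audic-Claverie p-value by direct summation of the exact
    conditional distribution, in rational arithmetic (no rounding at all)."""
    r = Fraction(total_b, total_a)
    # p(k | x) built iteratively: p(0) = 1/(1+r)^(x+1),
    # p(k+1) = p(k) * r * (x+k+1) / ((k+1) * (1+r))
    pmf = Fraction(1, 1) / (1 + r) ** (x + 1)
    lower = Fraction(0)
    for k in range(y + 1):
        lower += pmf
        pmf = pmf * r * (x + k + 1) / ((k + 1) * (1 + r))
    # upper tail including y: 1 - P(K <= y-1) = 1 - (lower - p(y)) needs p(y);
    # recompute the cumulative up to y-1 instead
    pmf = Fraction(1, 1) / (1 + r) ** (x + 1)
    below = Fraction(0)
    for k in range(y):
        below += pmf
        pmf = pmf * r * (x + k + 1) / ((k + 1) * (1 + r))
    upper = 1 - below
    return min(Fraction(1), 2 * min(lower, upper))


def ac_pvalue_exact_table(max_total: int, total_a: int, total_b: int) -> dict:
    """Exact p-values for every (x, y) with x + y <= max_total."""
    r = Fraction(total_b, total_a)
    out = {}
    for x in range(max_total + 1):
        pmf = Fraction(1, 1) / (1 + r) ** (x + 1)
        cumulative = [Fraction(0)]
        for k in range(max_total - x + 1):
            cumulative.append(cumulative[-1] + pmf)
            pmf = pmf * r * (x + k + 1) / ((k + 1) * (1 + r))
        for y in range(max_total - x + 1):
            lower = cumulative[y + 1]
            upper = 1 - cumulative[y]
            out[(x, y)] = min(Fraction(1), 2 * min(lower, upper))
    return out


def hamming(a: str, b: str) -> int:
    return sum(1 for ca, cb in zip(a, b) if ca != cb)


def brute_force_matches(
    tag: str, transcripts: list[TranscriptModel]
) -> set[tuple[str, int, int]]:
    """All (transcript_id, offset, mismatches) under the anchored rules, by
    naive scanning of every window of every transcript."""
    hits = set()
    for t in transcripts:
        seq = t.sequence.upper()
        for offset in range(len(seq) - TAG_LENGTH + 1):
            window = seq[offset : offset + TAG_LENGTH]
            if not window.startswith(ANCHOR):
                continue
            if window[:4] != tag[:4]:
                continue
            mm = hamming(window[4:], tag[4:])
            if mm <= 1:
                hits.add((t.transcript_id, offset, mm))
    return hits


def brute_force_candidates(seq: str) -> list[tuple[str, int, int]]:
    """Candidate tags by naive scanning (checked against the implementation)."""
    seq = seq.upper()
    positions = [
        p
        for p in range(len(seq) - 3)
        if seq[p : p + 4] == ANCHOR and p + TAG_LENGTH <= len(seq)
    ]
    n = len(positions)
    return [(seq[p : p + TAG_LENGTH], p, n - i) for i, p in enumerate(positions)]


def brute_force_clusters(
    anchors: list[AnchorRecord], max_gap: int, min_size: int
) -> set[frozenset]:
    """Cluster membership by O(n^2) union-find: two anchors are connected
    when every consecutive gap on the sorted path between them is small."""
    parent = list(range(len(anchors)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].chromosome, anchors[i].start, anchors[i].locus_id))
    for a_pos in range(len(order)):
        for b_pos in range(a_pos + 1, len(order)):
            i, j = order[a_pos], order[b_pos]
            if anchors[i].chromosome != anchors[j].chromosome:
                continue
            chain_ok = True
            for k_pos in range(a_pos, b_pos):
                u, v = order[k_pos], order[k_pos + 1]
                if anchors[u].chromosome != anchors[v].chromosome:
                    chain_ok = False
                    break
                gap = max(0, anchors[v].start - anchors[u].end - 1)
                if gap > max_gap:
                    chain_ok = False
                    break
            if chain_ok:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i, anchor in enumerate(anchors):
        groups.setdefault(find(i), set()).add(anchor.locus_id)
    return {frozenset(g) for g in groups.values() if len(g) >= min_size}
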