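"""Independent brute-force reference implementations used only by tests.

These deliberately take the most literal, slowest path (expanded multisets,
transitive closures, direct tail summation) so they share no code with the
library implementations they check.
"""

from __future__ import annotations

import math


def classify_shape_oracle(ctss: dict[int, int]) -> str:
    """Literal transcription of the four shape criteria on an expanded
    tag-position multiset."""
    xs = sorted(p for p, c in ctss.items() for _ in range(c))
    n = len(xs)

    def pct(q: float) -> int:
        rank = max(1, math.ceil(q / 100.0 * n))
        return xs[rank - 1]

    if (pct(75) - pct(25)) < 4 or (pct(85) - pct(15)) < 6:
        return "SP"
    counts = sorted(ctss.values(), reverse=True)
    peak1 = counts[0]
    peak2 = counts[1] if len(counts) > 1 else 0
    if peak1 > 2 * peak2 and peak1 > 0.2 * n:
        return "DP"
    peaks = sorted(p for p, c in ctss.items() if c > 0.15 * n)
    if len(peaks) >= 2 and all(b - a > 5 for a, b in zip(peaks, peaks[1:])):
        return "MP"
    return "BP"


def cluster_oracle(tags: list[tuple[int, str]], tag_length: int = 27
                   ) -> list[set[int]]:
    """Transitive closure of pairwise tag-body overlaps (same strand).

    ``tags`` is a list of (pos, strand); returns sets of tag indices.
    """

    def body(pos: int, strand: str) -> tuple[int, int]:
        return (pos, pos + tag_length - 1) if strand == "+" else (pos - tag_length + 1, pos)

    n = len(tags)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if tags[i][1] != tags[j][1]:
                continue
            (s1, e1), (s2, e2) = body(*tags[i]), body(*tags[j])
            if s1 <= e2 and s2 <= e1:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


def poisson_tail_oracle(n: int, lam: float, terms: int = 500) -> float:
    """P(X >= n) by direct summation of the Poisson pmf."""
    term = math.exp(-lam)            # P(X = 0)
    for k in range(1, n):
        term *= lam / k
    total = 0.0
    for k in range(n, n + terms):
        term *= lam / k
        total += term
    return total


def binom_two_sided_oracle(k: int, n: int, p: float) -> float:
    """Two-sided binomial p-value by the minimum-likelihood rule: sum of
    P(X = j) over all j whose probability does not exceed P(X = k)."""
    def pmf(j):
        return math.comb(n, j) * p ** j * (1 - p) ** (n - j)

    pk = pmf(k)
    return min(1.0, sum(pmf(j) for j in range(n + 1) if pmf(j) <= pk * (1 + 1e-9)))


def hypergeom_tail_oracle(a: int, query: int, members: int, universe: int) -> float:
    """P(overlap >= a) for a query of given size drawn from the universe."""
    total = 0.0
    for x in range(a, min(query, members) + 1):
        total += (math.comb(members, x) * math.comb(universe - members, query - x)
                  / math.comb(universe, query))
    return total


def count_aug_oracle(sequences: list[str]) -> int:
    """Regex-free triple-loop occurrence count of 'ATG'."""
    total = 0
    for seq in sequences:
        for i in range(len(seq)):
            if seq[i:i + 3] == "ATG":
                total += 1
    return total
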