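"""Independent brute-force oracles used by several test modules.

These deliberately use plain Python dicts/loops (no numpy vectorization) so
they share no code path with the implementations they check.
"""

from __future__ import annotations

from itertools import combinations


def brute_force_shared_count(read_hits: dict[str, list[str]]) -> dict[str, float]:
    """Naive two-step attribution: unique reads first, then each shared
    read split across its candidates by the ratio of unique counts."""
    unique: dict[str, float] = {}
    for rid, genes in read_hits.items():
        if len(genes) == 1:
            unique[genes[0]] = unique.get(genes[0], 0.0) + 1.0
    counts = dict(unique)
    for rid, genes in read_hits.items():
        if len(genes) <= 1:
            continue
        weights = [unique.get(g, 0.0) for g in genes]
        total = sum(weights)
        if total == 0:
            weights = [1.0] * len(genes)
            total = float(len(genes))
        for g, w in zip(genes, weights):
            counts[g] = counts.get(g, 0.0) + w / total
    return counts


def enumerate_richness(reads_genes: list[str], depth: int) -> tuple[float, float]:
    """Exact expected richness (and its variance) over all equiprobable
    depth-subsets of uniquely-mapped reads."""
    vals = []
    for combo in combinations(range(len(reads_genes)), depth):
        vals.append(len({reads_genes[i] for i in combo}))
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / len(vals)
    return mean, var


def enumerate_downsize(reads_genes: list[str], depth: int) -> dict[str, float]:
    """Exact expected per-gene count over all equiprobable depth-subsets."""
    acc: dict[str, float] = {}
    combos = list(combinations(range(len(reads_genes)), depth))
    for combo in combos:
        for i in combo:
            g = reads_genes[i]
            acc[g] = acc.get(g, 0.0) + 1.0
    return {g: v / len(combos) for g, v in acc.items()}
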