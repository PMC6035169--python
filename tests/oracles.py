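"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by naive enumeration, staying
independent of the library code paths they check.
"""
from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Set, Tuple

from Bio.Data.CodonTable import standard_dna_table

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOPS = set(standard_dna_table.stop_codons)
BASES = "ACGT"


def ng86_site_count(codon: str) -> float:
    """Synonymous sites of a codon by enumerating all nine changes."""
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOPS and CODON_TO_AA[alt] == aa:
                syn += 1
    return syn / 3.0


def ng86_pair_diffs(c1: str, c2: str) -> Tuple[float, float]:
    """(Sd, Nd) of a codon pair by enumerating every mutational path."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: List[Tuple[int, int]] = []
    fallback: List[Tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                hit_stop = True
            if (cur not in STOPS and nxt not in STOPS
                    and CODON_TO_AA[cur] == CODON_TO_AA[nxt]):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if hit_stop else valid).append((sd, nd))
    use = valid or fallback
    k = len(use)
    return sum(s for s, _ in use) / k, sum(n for _, n in use) / k


def minimum_gene_cover(
    intervals: Dict[str, Tuple[int, int]],
    genes: Sequence[Tuple[int, int, str]],
) -> Tuple[Set[str], int]:
    """Exhaustive minimum set of intervals containing all coverable genes.

    Returns (coverable gene ids, minimum number of intervals needed).
    """
    ids = sorted(intervals)

    def contained(bac: str, gene: Tuple[int, int, str]) -> bool:
        s, e = intervals[bac]
        return s <= gene[0] and gene[1] <= e

    coverable = {g[2] for g in genes if any(contained(b, g) for b in ids)}
    for r in range(len(ids) + 1):
        for subset in itertools.combinations(ids, r):
            covered = {
                g[2] for g in genes if any(contained(b, g) for b in subset)
            }
            if coverable <= covered:
                return coverable, r
    return coverable, len(ids)
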