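"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a statistic from first principles in the most
literal way available (pairwise enumeration, explicit scalar loops,
recursive pathway enumeration, exhaustive combinatorics) so that the
vectorised implementations in the package are checked against code that
shares none of their structure.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Data import CodonTable

_CODE = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
_STOPS = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)


# --------------------------------------------------------------------- #
# nucleotide diversity
# --------------------------------------------------------------------- #
def brute_force_pi(haplotypes: np.ndarray, span_bp: int) -> float:
    """Mean pairwise Hamming distance over all haplotype pairs, per bp."""
    n = haplotypes.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(haplotypes[i] != haplotypes[j]))
            pairs += 1
    return total / pairs / span_bp


# --------------------------------------------------------------------- #
# Weir & Cockerham 1984 variance components, scalar re-derivation
# --------------------------------------------------------------------- #
def wc_site_abc(genotypes_a: list[int], genotypes_b: list[int]):
    """Per-site (a, b, c) from diploid genotype lists (0/1/2 alt copies)."""
    pops = [genotypes_a, genotypes_b]
    r = 2
    n = [len(g) for g in pops]
    p = [sum(g) / (2 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]

    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


# --------------------------------------------------------------------- #
# NG86 + JC69, recursive pathway enumeration
# --------------------------------------------------------------------- #
def _syn_sites_of_codon(codon: str) -> float:
    aa = _CODE[codon]
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b != codon[pos]:
                mutant = codon[:pos] + b + codon[pos + 1 :]
                if _CODE.get(mutant) == aa:
                    syn += 1 / 3
    return syn


def _paths(cur: str, target: str, avoid_stops: bool):
    """All substitution orderings cur -> target as (sd, nd) tuples."""
    diffs = [i for i in range(3) if cur[i] != target[i]]
    if not diffs:
        yield (0.0, 0.0)
        return
    for i in diffs:
        nxt = cur[:i] + target[i] + cur[i + 1 :]
        if avoid_stops and nxt in _STOPS:
            continue
        step_syn = 1.0 if _CODE.get(cur) == _CODE.get(nxt) and nxt not in _STOPS else 0.0
        for sd, nd in _paths(nxt, target, avoid_stops):
            yield (sd + step_syn, nd + (1.0 - step_syn))


def ng86_oracle(seq_a: str, seq_b: str):
    """(dN, dS) by literal NG86 + JC69, averaging over substitution paths."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        S += (_syn_sites_of_codon(ca) + _syn_sites_of_codon(cb)) / 2
        paths = list(_paths(ca, cb, avoid_stops=True))
        if not paths:
            paths = list(_paths(ca, cb, avoid_stops=False))
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
    N = len(seq_a) - S

    def jc(p):
        if p == 0:
            return 0.0
        if p >= 0.75:
            return math.nan
        return -0.75 * math.log(1 - 4 * p / 3)

    return jc(Nd / N), jc(Sd / S)


# --------------------------------------------------------------------- #
# hypergeometric tail by exhaustive enumeration
# --------------------------------------------------------------------- #
def hypergeom_tail_enumerated(universe: int, n_family: int, n_cluster: int, overlap: int) -> float:
    """P(X >= overlap) by enumerating every size-n_cluster draw."""
    items = list(range(universe))
    family = set(items[:n_family])
    hits = 0
    total = 0
    for draw in itertools.combinations(items, n_cluster):
        total += 1
        if len(family & set(draw)) >= overlap:
            hits += 1
    return hits / total
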