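"""Ortholog pairing and molecular-evolution rates.

Reciprocal-best-hit (RBH) ortholog pairing from a BLAST-like similarity
table, the Nei–Gojobori (1986) counting estimator of dN and dS with the
Jukes–Cantor (1969) multiple-hit correction, synonymous-rate divergence
times ``T = dS / (2λ) × 10⁻⁶`` Mya, and homoeolog-ratio classification
of orthogroups across the A/B/D subgenomes (1:1:1 triads vs others).

The NG86 estimator averages synonymous/non-synonymous site counts over
the two sequences and resolves multi-hit codons by averaging over all
shortest substitution pathways, skipping pathways that pass through a
stop codon.  Pairs with ``dS ≥ 0.3`` are flagged as excluded from
divergence summaries (saturation guard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "rbh_pairs",
    "ng86_dnds",
    "NGResult",
    "divergence_time",
    "OrthogroupRatio",
    "classify_orthogroup",
    "pair_report",
    "DS_EXCLUSION",
    "DEFAULT_LAMBDA",
]

#: pairs at or above this dS are flagged excluded (saturation guard)
DS_EXCLUSION = 0.3
#: synonymous substitutions per site per year
DEFAULT_LAMBDA = 6.5e-9

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid, or None for a stop codon."""
    return _AA.get(codon)


# --------------------------------------------------------------------- #
# reciprocal best hits
# --------------------------------------------------------------------- #
def rbh_pairs(
    similarity_table: pd.DataFrame, evalue_ceiling: float = 1e-5
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit pairs from a (query, subject, score, evalue) table.

    Hits above the e-value ceiling and self hits are dropped; each
    query's single best hit is the highest score, ties broken by lower
    e-value then lexicographic subject id.  A pair is kept iff each gene
    is the other's best hit.  Pairs are returned sorted, each gene
    appearing in at most one pair.
    """
    df = similarity_table.rename(columns=str.lower)
    need = {"query", "subject", "score", "evalue"}
    if not need <= set(df.columns):
        raise ValueError(f"similarity table needs columns {sorted(need)}")
    df = df[(df["evalue"] <= evalue_ceiling) & (df["query"] != df["subject"])]
    if df.empty:
        return []
    best: dict[str, str] = {}
    df = df.sort_values(
        ["query", "score", "evalue", "subject"], ascending=[True, False, True, True]
    )
    for q, grp in df.groupby("query", sort=False):
        best[q] = grp.iloc[0]["subject"]
    pairs = set()
    for a, b in best.items():
        if best.get(b) == a:
            pairs.add(tuple(sorted((a, b))))
    return sorted(pairs)


# --------------------------------------------------------------------- #
# NG86 dN/dS
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class NGResult:
    dN: float
    dS: float
    omega: float  # NaN when dS == 0 (undefined, not infinity)
    S: float  # synonymous sites (averaged over the two sequences)
    N: float
    Sd: float  # synonymous differences (pathway-averaged)
    Nd: float
    saturated: bool  # JC correction undefined (p >= 3/4) for dN or dS


def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous/non-synonymous site counts of one codon.

    At each position the synonymous fraction is the share of the three
    possible point mutations that preserve the amino acid; mutations to
    stop codons count as non-synonymous.
    """
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon} in sequence")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if _translate(mut) == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/non-synonymous differences of a codon pair."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = ca
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                valid = False
                break
            if _translate(cur) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            results.append((sd, nd))
    if not results:  # every path crosses a stop codon: fall back to all paths
        for order in permutations(diff):
            cur = ca
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                ta, tb = _translate(cur), _translate(nxt)
                if ta is not None and ta == tb:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


def _jc69(p: float) -> float:
    """Jukes–Cantor multiple-hit correction; NaN when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_dnds(cds_a: str, cds_b: str) -> NGResult:
    """Nei–Gojobori (1986) dN and dS for a pre-aligned, gap-free CDS pair.

    Both sequences must be equal-length multiples of 3 over A/C/G/T with
    no internal stop codons.  ``omega`` is NaN when ``dS = 0``.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3 != 0:
        raise ValueError("length is not a multiple of 3")
    if set(a) - set(_BASES) or set(b) - set(_BASES):
        raise ValueError("sequences must contain only A/C/G/T")

    S_a = S_b = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        sa, _ = _codon_sites(ca)
        sb, _ = _codon_sites(cb)
        S_a += sa
        S_b += sb
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    S = (S_a + S_b) / 2.0
    N = len(a) - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc69(pS)
    dN = _jc69(pN)
    saturated = math.isnan(dS) or math.isnan(dN)
    omega = dN / dS if (not saturated and dS > 0) else math.nan
    return NGResult(dN=dN, dS=dS, omega=omega, S=S, N=N, Sd=Sd, Nd=Nd,
                    saturated=saturated)


def divergence_time(dS: float, lambda_rate: float = DEFAULT_LAMBDA) -> float:
    """Divergence time in Mya: ``T = dS / (2λ) × 10⁻⁶``.

    With the default λ = 6.5e-9 synonymous substitutions per site per
    year, dS of 0.01–0.02 corresponds to 0.77–1.54 Mya.
    """
    if dS < 0:
        raise ValueError("dS cannot be negative")
    if lambda_rate <= 0:
        raise ValueError("lambda_rate must be positive")
    return dS / (2.0 * lambda_rate) * 1e-6


# --------------------------------------------------------------------- #
# homoeolog ratios
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class OrthogroupRatio:
    group_id: str
    counts: tuple[int, int, int]  # members on A, B, D
    label: str

    @property
    def is_triad(self) -> bool:
        return self.counts == (1, 1, 1)

    @property
    def is_singleton(self) -> bool:
        return sorted(self.counts) == [0, 0, 1]


def classify_orthogroup(
    group_id: str,
    members: list[str],
    subgenome_of: dict[str, str] | None = None,
) -> OrthogroupRatio:
    """Label an orthogroup by its A:B:D member counts (e.g. "1:1:1").

    Subgenomes are resolved through ``subgenome_of`` when given,
    otherwise from the last subgenome letter (A/B/D) appearing in the
    gene id; an unresolvable gene raises.
    """
    counts = {"A": 0, "B": 0, "D": 0}
    for gid in members:
        sub = None
        if subgenome_of is not None:
            sub = subgenome_of.get(gid)
        else:
            hits = [ch for ch in gid if ch in "ABD"]
            sub = hits[-1] if hits else None
        if sub not in counts:
            raise ValueError(f"cannot resolve subgenome of gene {gid!r}")
        counts[sub] += 1
    c = (counts["A"], counts["B"], counts["D"])
    return OrthogroupRatio(group_id=group_id, counts=c, label=f"{c[0]}:{c[1]}:{c[2]}")


def pair_report(
    pairs: list[tuple[str, str]],
    cds: dict[str, str],
    lambda_rate: float = DEFAULT_LAMBDA,
) -> pd.DataFrame:
    """dN/dS/T table for RBH pairs with the dS < 0.3 retention flag."""
    rows = []
    for a, b in pairs:
        res = ng86_dnds(cds[a], cds[b])
        excluded = res.saturated or (res.dS >= DS_EXCLUSION)
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "dN": res.dN,
                "dS": res.dS,
                "omega": res.omega,
                "T_mya": (
                    divergence_time(res.dS, lambda_rate)
                    if not math.isnan(res.dS)
                    else math.nan
                ),
                "excluded": excluded,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "dN", "dS", "omega", "T_mya", "excluded"]
    )
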