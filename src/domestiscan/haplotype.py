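"""Per-gene diplotype catalogues and major-haplotype tracking.

For each gene the SNPs in the gene body plus flanking (promoter /
downstream) sequence are concatenated, per sample, into a diplotype
string with two nucleotide letters per site in genomic order — e.g.
``"CCAACCAA"`` is four sites, each contributing the sample's two phased
allele letters.  Sample-level counting matches published per-subgroup
haplotype percentages (e.g. 24/29 = 82.76%).

A *major haplotype* is the (necessarily unique) diplotype carried by
strictly more than half of a subpopulation.  Tracking which lineage
steps replace one major haplotype with another across an ordered
domestication series (wild emmer → domesticated emmer → durum →
landrace → cultivar) is the module's main product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .annotations import GeneModel
from .panel import PhasedPanel

__all__ = [
    "HaplotypeCatalog",
    "build_gene_haplotypes",
    "haplotype_frequencies",
    "major_haplotypes",
    "track_major_shifts",
    "catalog_table",
]


def _display_percent(freq: float) -> float:
    """Percentage rounded half-up to 2 decimals, for display only."""
    return float(Decimal(repr(freq * 100)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class HaplotypeCatalog:
    """Diplotype strings of one gene over all panel samples."""

    gene_id: str
    chrom: str
    site_pos: np.ndarray  # 0-based positions of the sites used, ascending
    diplotypes: pd.Series  # sample_id -> string
    subpops: pd.Series  # sample_id -> subpopulation

    @property
    def n_sites(self) -> int:
        return int(self.site_pos.size)


def build_gene_haplotypes(
    panel: PhasedPanel,
    gene: GeneModel,
    flank_bp: int = 2000,
    include_introns: bool = True,
) -> HaplotypeCatalog | None:
    """Concatenate phased allele letters over a gene's SNPs, per sample.

    Sites within ``[gene.start - flank_bp, gene.end + flank_bp)`` are
    used, in ascending genomic order regardless of input order; with
    ``include_introns=False`` genic sites are restricted to exonic
    (CDS/UTR) positions, keeping the flanks.  Returns ``None`` when no
    SNP falls in the span (such genes are excluded from cataloguing).
    """
    lo, hi = max(0, gene.start - flank_bp), gene.end + flank_bp
    mask = panel.site_mask(gene.chrom, lo, hi)
    if not include_introns:
        pos = panel.pos
        exonic = np.zeros_like(mask)
        for s, e in gene.exons:
            exonic |= (panel.chrom == gene.chrom) & (pos >= s) & (pos < e)
        flank = mask & ((pos < gene.start) | (pos >= gene.end))
        mask = flank | (mask & exonic)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    idx = idx[np.argsort(panel.pos[idx], kind="stable")]

    ref = panel.ref[idx]
    alt = panel.alt[idx]
    letters = np.stack([ref, alt], axis=0)  # [allele 0/1, site]
    strings = []
    for i in range(panel.n_samples):
        h1 = panel.haplotypes[2 * i, idx]
        h2 = panel.haplotypes[2 * i + 1, idx]
        strings.append(
            "".join(letters[h1[j], j] + letters[h2[j], j] for j in range(idx.size))
        )
    samples = pd.Index(panel.samples, name="sample_id")
    return HaplotypeCatalog(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        site_pos=panel.pos[idx],
        diplotypes=pd.Series(strings, index=samples),
        subpops=pd.Series(list(panel.subpops), index=samples),
    )


def haplotype_frequencies(catalog: HaplotypeCatalog) -> pd.DataFrame:
    """Per-subpopulation diplotype counts and frequencies.

    ``frequency`` is samples carrying the diplotype over subpopulation
    size at full precision; ``percent`` is the half-up 2-decimal display
    value.  Frequencies within a subpopulation sum to 1.
    """
    rows = []
    for sp, group in catalog.diplotypes.groupby(catalog.subpops, sort=False):
        n = len(group)
        if n == 0:
            raise ValueError(f"empty subpopulation {sp}")
        counts = group.value_counts()
        for hap, c in counts.items():
            freq = c / n
            rows.append(
                {
                    "gene_id": catalog.gene_id,
                    "subpopulation": sp,
                    "haplotype": hap,
                    "count": int(c),
                    "n": n,
                    "frequency": freq,
                    "percent": _display_percent(freq),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["subpopulation", "frequency", "haplotype"], ascending=[True, False, True]
    ).reset_index(drop=True)


def major_haplotypes(
    frequency_table: pd.DataFrame, threshold: float = 0.5
) -> dict[str, str | None]:
    """Per-subpopulation major haplotype: frequency strictly > threshold.

    With the default 0.5 the major haplotype is unique whenever it
    exists; ``None`` marks subpopulations without one.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    out: dict[str, str | None] = {}
    for sp, grp in frequency_table.groupby("subpopulation", sort=False):
        above = grp[grp["frequency"] > threshold]
        out[sp] = None if above.empty else str(above.iloc[0]["haplotype"])
    return out


def track_major_shifts(
    freq_tables: dict[str, pd.DataFrame],
    ordered_lineages: list[str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Major-haplotype replacement events along an ordered lineage series.

    ``freq_tables`` maps gene id to its frequency table.  For every gene
    and each consecutive lineage pair where the major haplotype differs
    (including none↔some transitions) one event row is emitted:
    ``gene_id, from_lineage, to_lineage, from_major, to_major``.  The
    summary counts are available via :func:`shift_summary`.
    """
    events = []
    for gene_id, table in freq_tables.items():
        present = set(table["subpopulation"])
        unknown = [l for l in ordered_lineages if l not in present]
        if unknown:
            raise KeyError(f"{gene_id}: unknown lineage(s) {unknown}")
        majors = major_haplotypes(table, threshold)
        for a, b in zip(ordered_lineages, ordered_lineages[1:]):
            if majors.get(a) != majors.get(b):
                events.append(
                    {
                        "gene_id": gene_id,
                        "from_lineage": a,
                        "to_lineage": b,
                        "from_major": majors.get(a),
                        "to_major": majors.get(b),
                    }
                )
    return pd.DataFrame(
        events, columns=["gene_id", "from_lineage", "to_lineage", "from_major", "to_major"]
    )


def shift_summary(
    freq_tables: dict[str, pd.DataFrame],
    ordered_lineages: list[str],
    threshold: float = 0.5,
) -> dict[str, int]:
    """Counts of genes with any major haplotype / with differing majors.

    A gene with no major haplotype in any lineage contributes to
    ``n_genes`` only; differing-major counting compares the major (or
    its absence) across the ordered lineages.
    """
    n_with_major = 0
    n_differing = 0
    for table in freq_tables.values():
        majors = major_haplotypes(table, threshold)
        vals = [majors.get(l) for l in ordered_lineages]
        defined = [v for v in vals if v is not None]
        if defined:
            n_with_major += 1
            if len(set(vals)) > 1 and len(set(defined)) > 1:
                n_differing += 1
    return {
        "n_genes": len(freq_tables),
        "n_with_major": n_with_major,
        "n_differing_major": n_differing,
    }


def catalog_table(
    freq_tables: dict[str, pd.DataFrame], threshold: float = 0.5
) -> pd.DataFrame:
    """Flat export table: gene, subpopulation, haplotype, count, frequency, is_major."""
    frames = []
    for gene_id, table in freq_tables.items():
        majors = major_haplotypes(table, threshold)
        t = table.copy()
        t["is_major"] = [
            majors[sp] == hap
            for sp, hap in zip(t["subpopulation"], t["haplotype"])
        ]
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene_id", "subpopulation", "haplotype", "count", "n",
                "frequency", "percent", "is_major",
            ]
        )
    return pd.concat(frames, ignore_index=True)
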