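"""Genome annotations and genotype input.

Reads GFF3 gene models (via :mod:`gffutils`) and phased VCF genotypes
(via :mod:`cyvcf2`), classifies SNPs into genic / promoter / downstream /
intergenic regions, and summarises gene-structure contrasts between TF
and non-TF genes.

All internal coordinates are 0-based half-open; GFF3 and VCF I/O convert
to the formats' native 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

from .panel import PhasedPanel, read_panel_tsv

__all__ = [
    "GeneModel",
    "QTLInterval",
    "read_annotations",
    "write_gff3",
    "read_qtl_tsv",
    "write_qtl_tsv",
    "read_family_tsv",
    "read_genotypes",
    "assign_site_regions",
    "snp_region_counts",
    "gene_structure_summary",
]

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A located, stranded gene with exon/UTR structure (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    family: str | None = None
    subgenome: str = "synthetic"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene body")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cdna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter_interval(self, promoter_bp: int) -> Interval:
        """Half-open promoter interval immediately upstream of the TSS."""
        if self.strand == "+":
            return (max(0, self.start - promoter_bp), self.start)
        return (self.end, self.end + promoter_bp)

    def downstream_interval(self, downstream_bp: int) -> Interval:
        if self.strand == "+":
            return (self.end, self.end + downstream_bp)
        return (max(0, self.start - downstream_bp), self.start)


@dataclass(frozen=True)
class QTLInterval:
    """Trait-labelled genomic interval (0-based half-open)."""

    trait: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"QTL {self.trait}@{self.chrom}: start > end")


class AnnotationError(ValueError):
    """GFF3 content violates the gene/exon hierarchy assumptions."""


# --------------------------------------------------------------------- #
# GFF3 I/O
# --------------------------------------------------------------------- #
def write_gff3(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            a1, b1 = g.start + 1, g.end  # 1-based inclusive
            fh.write(
                f"{g.chrom}\tdomestiscan\tgene\t{a1}\t{b1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};subgenome={g.subgenome}\n"
            )
            tid = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tdomestiscan\tmRNA\t{a1}\t{b1}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for kind, ivals in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in ivals:
                    fh.write(
                        f"{g.chrom}\tdomestiscan\t{kind}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tParent={tid}\n"
                    )


def read_annotations(gff_path: str, family_tsv: str | None = None) -> list[GeneModel]:
    """Parse a GFF3 into gene models, keeping one transcript per gene.

    When a gene carries several mRNA children only the first variant —
    the lowest-sorting transcript ID — is retained.  An exon outside its
    gene body raises :class:`AnnotationError` naming the feature.
    """
    try:
        db = gffutils.create_db(
            gff_path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    fam = read_family_tsv(family_tsv) if family_tsv else {}
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        start, end = g.start - 1, g.end
        transcripts = sorted(db.children(g, featuretype="mRNA"), key=lambda t: t.id)
        exons: list[Interval] = []
        cds: list[Interval] = []
        utr5: list[Interval] = []
        utr3: list[Interval] = []
        if transcripts:
            t = transcripts[0]
            for child in db.children(t):
                iv = (child.start - 1, child.end)
                if iv[0] < start or iv[1] > end:
                    raise AnnotationError(
                        f"{child.featuretype} {iv} outside gene body of {g.id} "
                        f"(line: {str(child)})"
                    )
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(iv)
        sub = g.attributes.get("subgenome", [None])[0]
        if sub is None:
            sub = g.seqid[-1] if g.seqid and g.seqid[-1] in "ABD" else "synthetic"
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=start,
                end=end,
                strand=g.strand,
                exons=sorted(exons),
                cds=sorted(cds),
                utr5=sorted(utr5),
                utr3=sorted(utr3),
                family=fam.get(g.id),
                subgenome=sub,
            )
        )
    return genes


def write_qtl_tsv(qtls: list[QTLInterval], path: str) -> None:
    pd.DataFrame(
        {
            "chrom": [q.chrom for q in qtls],
            "start": [q.start for q in qtls],
            "end": [q.end for q in qtls],
            "trait": [q.trait for q in qtls],
        }
    ).to_csv(path, sep="\t", index=False)


def read_qtl_tsv(path: str) -> list[QTLInterval]:
    df = pd.read_csv(path, sep="\t")
    return [
        QTLInterval(trait=r.trait, chrom=str(r.chrom), start=int(r.start), end=int(r.end))
        for r in df.itertuples()
    ]


def read_family_tsv(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["gene_id"], df["family"]))


# --------------------------------------------------------------------- #
# VCF input
# --------------------------------------------------------------------- #
def read_genotypes(vcf_path: str, panel_tsv: str) -> PhasedPanel:
    """Read phased biallelic SNPs for the samples listed in the panel file.

    Multi-allelic and non-SNP records are skipped (their count is
    reported via the returned panel's ``skipped_records`` attribute).
    Any unphased ("/") genotype raises, since imputation/phasing is out
    of scope here.
    """
    panel_df = read_panel_tsv(panel_tsv)
    wanted = list(panel_df["sample_id"])
    vcf = VCF(vcf_path)
    missing = [s for s in wanted if s not in vcf.samples]
    if missing:
        raise ValueError(f"panel samples absent from VCF: {missing}")
    vcf = VCF(vcf_path, samples=wanted)
    order = [vcf.samples.index(s) for s in wanted]

    chrom, pos, ref, alt, cols = [], [], [], [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        col = np.empty(2 * len(wanted), dtype=np.int8)
        for k, idx in enumerate(order):
            a, b, phased = v.genotypes[idx][0], v.genotypes[idx][1], v.genotypes[idx][2]
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {wanted[k]} at "
                    f"{v.CHROM}:{v.POS}; phased input is required"
                )
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {v.CHROM}:{v.POS}")
            col[2 * k], col[2 * k + 1] = a, b
        chrom.append(v.CHROM)
        pos.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        cols.append(col)

    lengths = {}
    for c in vcf.seqnames:
        try:
            lengths[c] = vcf.seqlens[vcf.seqnames.index(c)]
        except Exception:
            pass
    panel = PhasedPanel(
        samples=wanted,
        subpops=list(panel_df["subpopulation"]),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        haplotypes=(
            np.stack(cols, axis=1) if cols else np.zeros((2 * len(wanted), 0), np.int8)
        ),
        chrom_lengths=lengths or None,
    )
    panel.skipped_records = skipped  # type: ignore[attr-defined]
    return panel


# --------------------------------------------------------------------- #
# site region labels
# --------------------------------------------------------------------- #
_CLASS_RANK = {"genic": 0, "promoter": 1, "downstream": 2}


def _in_any(p: int, intervals: list[Interval]) -> bool:
    return any(s <= p < e for s, e in intervals)


def assign_site_regions(
    panel: PhasedPanel,
    genes: list[GeneModel],
    promoter_bp: int = 2000,
    downstream_bp: int = 2000,
) -> pd.DataFrame:
    """Label every site genic / promoter / downstream / intergenic.

    Promoter and downstream windows are strand-aware (upstream of the
    TSS, past the gene end).  Genic labels take precedence over a
    neighbouring gene's promoter, promoter over downstream; ties between
    genes offering the same class are broken by distance to the gene
    start, then lexicographic gene id.  Genic sites carry a sub-label
    (CDS > UTR > intron) where the gene model has those features.

    Returns a DataFrame with columns ``site_index, chrom, pos, label,
    sublabel, gene_id``.
    """
    if promoter_bp <= 0:
        raise ValueError("promoter_bp must be positive")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    labels, sublabels, owners = [], [], []
    for j in range(panel.n_sites):
        c, p = panel.chrom[j], int(panel.pos[j])
        best = None  # (class_rank, dist_to_gene_start, gene_id, sublabel)
        for g in by_chrom.get(c, []):
            cand = None
            if g.start <= p < g.end:
                if _in_any(p, g.cds):
                    sub = "CDS"
                elif _in_any(p, g.utr5) or _in_any(p, g.utr3):
                    sub = "UTR"
                elif g.exons:
                    sub = "intron"  # in gene body but not exonic
                else:
                    sub = None
                if _in_any(p, g.exons) and sub == "intron":
                    sub = "exon"  # exon without CDS/UTR annotation
                cand = (0, abs(p - g.start), g.gene_id, sub)
            else:
                ps, pe = g.promoter_interval(promoter_bp)
                ds, de = g.downstream_interval(downstream_bp)
                if ps <= p < pe:
                    cand = (1, abs(p - g.start), g.gene_id, None)
                elif ds <= p < de:
                    cand = (2, abs(p - g.start), g.gene_id, None)
            if cand is not None and (best is None or cand < best):
                best = cand
        if best is None:
            labels.append("intergenic")
            sublabels.append(None)
            owners.append(None)
        else:
            labels.append({0: "genic", 1: "promoter", 2: "downstream"}[best[0]])
            sublabels.append(best[3])
            owners.append(best[2])
    return pd.DataFrame(
        {
            "site_index": np.arange(panel.n_sites),
            "chrom": panel.chrom,
            "pos": panel.pos,
            "label": labels,
            "sublabel": sublabels,
            "gene_id": owners,
        }
    )


def snp_region_counts(
    labels: pd.DataFrame, panel: PhasedPanel, by_subpopulation: bool = True
) -> pd.DataFrame:
    """Count segregating sites per region class (and subpopulation).

    A site counts for a subpopulation only if it is polymorphic within
    it (0 < alternate-allele count < haplotype count).
    """
    groups = panel.subpop_names() if by_subpopulation else [None]
    rows = []
    classes = ["genic", "promoter", "downstream", "intergenic"]
    lab = labels["label"].to_numpy()
    for sp in groups:
        ac = panel.alt_counts(sp)
        n = len(panel.hap_rows(sp))
        seg = (ac > 0) & (ac < n)
        row = {"subpopulation": sp if sp is not None else "ALL"}
        for cl in classes:
            row[cl] = int(np.sum(seg & (lab == cl)))
        row["segregating_total"] = int(seg.sum())
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# gene structure contrasts
# --------------------------------------------------------------------- #
def gene_structure_summary(genes: list[GeneModel], tf_ids: set[str]) -> pd.DataFrame:
    """Median/mean gene-structure metrics for TF vs non-TF genes.

    Metrics: exon count, transcript (gene-body) length, cDNA (exonic)
    length and 5'/3' UTR lengths, with a two-sided Wilcoxon rank-sum
    p-value per contrast.
    """
    tf = [g for g in genes if g.gene_id in tf_ids]
    non = [g for g in genes if g.gene_id not in tf_ids]
    if not tf or not non:
        raise ValueError("both TF and non-TF classes must be non-empty")

    def metrics(gs: list[GeneModel]) -> dict[str, np.ndarray]:
        return {
            "exon_count": np.array([len(g.exons) for g in gs], dtype=float),
            "transcript_length": np.array([g.length for g in gs], dtype=float),
            "cdna_length": np.array([g.cdna_length for g in gs], dtype=float),
            "utr5_length": np.array(
                [sum(e - s for s, e in g.utr5) for g in gs], dtype=float
            ),
            "utr3_length": np.array(
                [sum(e - s for s, e in g.utr3) for g in gs], dtype=float
            ),
        }

    mt, mn = metrics(tf), metrics(non)
    rows = []
    for key in mt:
        stat = stats.ranksums(mt[key], mn[key])
        rows.append(
            {
                "metric": key,
                "tf_median": float(np.median(mt[key])),
                "tf_mean": float(np.mean(mt[key])),
                "non_tf_median": float(np.median(mn[key])),
                "non_tf_mean": float(np.mean(mn[key])),
                "pvalue": float(stat.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
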