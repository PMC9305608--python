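"""Synthetic domestication-series fixture generator.

Generates a complete analysis fixture — phased VCF, GFF3 gene models, a
sample/subpopulation panel, QTL intervals, TF-family labels and an FPKM
expression matrix — with the statistical structure the downstream scan
assumes: a wild source population, bottlenecked domesticated derivatives
with reduced nucleotide diversity and elevated Fst, implanted selective
sweeps, and tissue-structured expression.

The generator is deliberately non-genealogical: ancestral variation is
drawn from the neutral site-frequency spectrum (derived-allele count ``i``
with probability proportional to ``1/i``), derived populations are produced
by founder sampling followed by Wright–Fisher resampling, and sweeps are
implanted by copying a donor haplotype over a fraction of the population
within a region.  This reproduces the diversity/differentiation signature
that window statistics consume without simulating recombination or
hitch-hiking.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import GeneModel, QTLInterval, write_gff3, write_qtl_tsv
from .panel import PhasedPanel, write_panel_tsv

__all__ = [
    "SubpopSpec",
    "SweepSpec",
    "SimulationConfig",
    "nine_subpop_config",
    "sweep_demo_config",
    "simulate_ancestral_panel",
    "derive_bottlenecked_population",
    "implant_sweep",
    "simulate_panel",
    "synthesize_annotations",
    "synthesize_expression",
    "export_fixture",
    "simulate_fixture",
    "TRAIT_CODES",
    "TF_FAMILIES",
]

#: the 14 agronomic trait codes used for QTL labels
TRAIT_CODES = [
    "GY", "GC", "KNS", "KW", "KL", "SNS", "SR",
    "SP", "LSD", "LR", "YR", "HT", "HD", "NWI",
]

#: default TF family label set for synthetic gene tables
TF_FAMILIES = [
    "bHLH", "AP2/ERF-ERF", "C2H2", "NAC", "B3", "MYB", "bZIP",
    "WRKY", "GARP-G2-like", "MADS-MIKC", "HB-BELL", "Tify",
]

_BASES = np.array(list("ACGT"), dtype=object)


@dataclass(frozen=True)
class SubpopSpec:
    """One subpopulation of the series.

    ``parent is None`` marks a root population drawn from the ancestral
    pool; otherwise the subpopulation descends from ``parent`` through
    ``n_founders`` founder haplotypes and ``n_drift_generations`` of
    Wright–Fisher resampling.
    """

    name: str
    n_samples: int
    parent: str | None = None
    n_founders: int = 0
    n_drift_generations: int = 0


@dataclass(frozen=True)
class SweepSpec:
    """A region swept in ``target`` to ``final_frequency`` (half-open bp)."""

    chrom: str
    start: int
    end: int
    target: str
    final_frequency: float


@dataclass
class SimulationConfig:
    genome_length: int = 1_000_000
    n_chromosomes: int = 5
    n_sites: int = 3_000
    subpop_spec: list[SubpopSpec] = field(default_factory=list)
    sweep_spec: list[SweepSpec] = field(default_factory=list)
    n_genes: int = 60
    n_qtls: int = 8
    n_libraries: int = 16
    tf_fraction: float = 0.5
    qtl_gene_fraction: float = 0.4
    specificity_mix: tuple[float, float, float] = (0.25, 0.25, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for sp in self.subpop_spec:
            if sp.n_samples < 1:
                raise ValueError(f"subpopulation {sp.name} has no samples")
        names = {sp.name for sp in self.subpop_spec}
        by_name = {sp.name: sp for sp in self.subpop_spec}
        for sp in self.subpop_spec:
            if sp.parent is not None:
                if sp.parent not in names:
                    raise ValueError(f"{sp.name}: unknown parent {sp.parent}")
                if sp.n_founders > 2 * by_name[sp.parent].n_samples:
                    raise ValueError(
                        f"{sp.name}: n_founders exceeds parent haplotype count"
                    )
        for sw in self.sweep_spec:
            if not (0 <= sw.start < sw.end <= self.genome_length):
                raise ValueError(f"sweep {sw} outside chromosome bounds")

    def chromosome_names(self) -> list[str]:
        """Synthetic names like 1A, 1B, 1D, 2A, ... (suffix = subgenome)."""
        return [f"{i // 3 + 1}{'ABD'[i % 3]}" for i in range(self.n_chromosomes)]


def nine_subpop_config(seed: int = 0, scale: float = 1.0, **overrides) -> SimulationConfig:
    """Default nine-subpopulation domestication series.

    Mirrors a wheat-like panel: wild einkorn (31), domesticated einkorn
    (31), urartu (29), wild emmer (28), domesticated emmer (29), durum
    (13), landrace (45), cultivar (25) and Ae. tauschii (30), with the
    domesticated lineages derived from their wild relatives through
    founder bottlenecks.  ``scale`` multiplies sample sizes for quick
    test runs.
    """

    def n(x: int) -> int:
        return max(2, int(round(x * scale)))

    subpops = [
        SubpopSpec("wild_einkorn", n(31)),
        SubpopSpec("domesticated_einkorn", n(31), "wild_einkorn", max(2, n(16)), 8),
        SubpopSpec("urartu", n(29)),
        SubpopSpec("wild_emmer", n(28)),
        SubpopSpec("domesticated_emmer", n(29), "wild_emmer", max(2, n(16)), 8),
        SubpopSpec("durum", n(13), "domesticated_emmer", max(2, n(10)), 8),
        SubpopSpec("landrace", n(45), "domesticated_emmer", max(2, n(20)), 8),
        SubpopSpec("cultivar", n(25), "landrace", max(2, n(16)), 8),
        SubpopSpec("ae_tauschii", n(30)),
    ]
    cfg = dict(
        genome_length=1_000_000,
        n_chromosomes=6,
        n_sites=3_600,
        subpop_spec=subpops,
        sweep_spec=[SweepSpec("1B", 400_000, 450_000, "domesticated_emmer", 0.95)],
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def anchor_sweep_on_gene(
    config: SimulationConfig,
    window_bp: int = 50_000,
    target: str = "domesticated_emmer",
    final_frequency: float = 0.95,
) -> SimulationConfig:
    """Re-position the configured sweep onto a gene-containing window.

    Annotations are derived deterministically from the config seed, so
    the sweep can be implanted over a known gene — preferring one inside
    a QTL — giving downstream gene-level stages a guaranteed positive
    control.  The sweep interval is the ``window_bp`` grid window
    holding the gene's start.
    """
    genes, qtls, _ = synthesize_annotations(config)
    in_qtl = [
        g for g in genes
        if any(q.chrom == g.chrom and g.start < q.end and q.start < g.end for q in qtls)
    ]
    pool = in_qtl or genes
    if not pool:
        raise ValueError("no genes to anchor the sweep on")
    g = pool[0]
    start = (g.start // window_bp) * window_bp
    config.sweep_spec = [
        SweepSpec(g.chrom, start, start + window_bp, target, final_frequency)
    ]
    return config


def sweep_demo_config(seed: int = 0) -> SimulationConfig:
    """Two-population sweep-recovery fixture.

    A wild population of 20 samples, a domesticated derivative of 20
    samples (12 founder haplotypes, 8 generations of drift) and one
    implanted 50-kb sweep at final frequency 0.95 on five 1-Mb
    chromosomes (600 SNPs each).
    """
    return SimulationConfig(
        genome_length=1_000_000,
        n_chromosomes=5,
        n_sites=3_000,
        subpop_spec=[
            SubpopSpec("wild", 20),
            SubpopSpec("dom", 20, "wild", 12, 8),
        ],
        sweep_spec=[SweepSpec("2A", 500_000, 550_000, "dom", 0.95)],
        n_genes=60,
        n_qtls=8,
        n_libraries=16,
        seed=seed,
    )


# --------------------------------------------------------------------- #
# panel simulation
# --------------------------------------------------------------------- #
def _site_table(config: SimulationConfig, rng: np.random.Generator):
    """Sorted site coordinates and ref/alt letters for every chromosome."""
    chroms = config.chromosome_names()
    per = [config.n_sites // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_sites % config.n_chromosomes):
        per[i] += 1
    chrom_col, pos_col = [], []
    for name, k in zip(chroms, per):
        if k > config.genome_length:
            raise ValueError("more sites than base pairs on a chromosome")
        pos = np.sort(rng.choice(config.genome_length, size=k, replace=False))
        chrom_col.append(np.full(k, name, dtype=object))
        pos_col.append(pos)
    chrom = np.concatenate(chrom_col) if chrom_col else np.array([], dtype=object)
    pos = np.concatenate(pos_col) if pos_col else np.array([], dtype=np.int64)
    r = rng.integers(0, 4, size=pos.size)
    a = (r + rng.integers(1, 4, size=pos.size)) % 4
    return chrom, pos, _BASES[r], _BASES[a]


def simulate_ancestral_panel(config: SimulationConfig) -> PhasedPanel:
    """Draw the ancestral (root-population) panel from a neutral SFS.

    All root subpopulations (``parent is None``) are sampled jointly from
    one panmictic ancestral pool: for each segregating site the
    derived-allele count ``i`` among the ``2N`` root haplotypes is drawn
    with probability proportional to ``1/i`` and assigned to a uniformly
    random haplotype subset.  Deterministic given ``config.seed``.
    """
    roots = [sp for sp in config.subpop_spec if sp.parent is None]
    if not roots:
        raise ValueError("configuration has no root subpopulation")
    n_samples = sum(sp.n_samples for sp in roots)
    if n_samples == 0:
        raise ValueError("zero samples configured")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F5]))

    chrom, pos, ref, alt = _site_table(config, rng)
    two_n = 2 * n_samples
    H = np.zeros((two_n, pos.size), dtype=np.int8)
    if pos.size:
        i = np.arange(1, two_n)
        probs = (1.0 / i) / np.sum(1.0 / i)
        counts = rng.choice(i, size=pos.size, p=probs)
        for j, c in enumerate(counts):
            H[rng.choice(two_n, size=c, replace=False), j] = 1

    samples, subpops = [], []
    for sp in roots:
        samples.extend(f"{sp.name}_{k:03d}" for k in range(sp.n_samples))
        subpops.extend([sp.name] * sp.n_samples)
    lengths = {c: config.genome_length for c in config.chromosome_names()}
    return PhasedPanel(samples, subpops, chrom, pos, ref, alt, H, lengths)


def derive_bottlenecked_population(
    parent: PhasedPanel,
    n_founders: int,
    n_generations: int,
    n_out: int,
    seed,
    name: str = "derived",
) -> PhasedPanel:
    """Found a derived population from a parent panel.

    ``n_founders`` haplotypes are sampled from the parent without
    replacement; each of ``n_generations`` then redraws ``2 * n_out``
    haplotypes with replacement (Wright–Fisher).  With all parent
    haplotypes as founders and zero generations the output is a
    permutation of the parent's haplotypes.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    if n_founders > parent.n_haplotypes:
        raise ValueError("n_founders exceeds parent haplotype count")
    rng = np.random.default_rng(seed)
    pool = parent.haplotypes[rng.choice(parent.n_haplotypes, n_founders, replace=False)]
    for _ in range(n_generations):
        pool = pool[rng.integers(0, pool.shape[0], size=2 * n_out)]
    if pool.shape[0] == 2 * n_out:
        pool = pool[rng.permutation(2 * n_out)]
    else:
        pool = pool[rng.integers(0, pool.shape[0], size=2 * n_out)]
    return PhasedPanel(
        samples=[f"{name}_{k:03d}" for k in range(n_out)],
        subpops=[name] * n_out,
        chrom=parent.chrom,
        pos=parent.pos,
        ref=parent.ref,
        alt=parent.alt,
        haplotypes=pool.copy(),
        chrom_lengths=dict(parent.chrom_lengths) if parent.chrom_lengths else None,
    )


def implant_sweep(
    panel: PhasedPanel,
    region: tuple[str, int, int],
    donor_haplotype_index: int,
    final_frequency: float,
    seed,
    subpop: str | None = None,
) -> PhasedPanel:
    """Copy a donor haplotype over a fraction of haplotypes within a region.

    Within half-open ``region = (chrom, start, end)`` a fraction
    ``final_frequency`` of the target haplotypes (rounded to the nearest
    count) is overwritten with the donor's allele string; all sites
    outside the region are untouched.  ``subpop=None`` targets every
    haplotype in the panel.
    """
    chrom, start, end = region
    if start >= end:
        raise ValueError("empty sweep region")
    if not (0 < final_frequency <= 1):
        raise ValueError("final_frequency must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = panel.hap_rows(subpop)
    if donor_haplotype_index not in set(rows.tolist()):
        raise ValueError("donor haplotype is not in the target population")
    mask = panel.site_mask(chrom, start, end)
    H = panel.haplotypes.copy()
    n_replace = int(round(final_frequency * rows.size))
    chosen = rng.choice(rows, size=n_replace, replace=False)
    H[np.ix_(chosen, np.flatnonzero(mask))] = panel.haplotypes[
        donor_haplotype_index, mask
    ]
    out = PhasedPanel(
        samples=list(panel.samples),
        subpops=list(panel.subpops),
        chrom=panel.chrom,
        pos=panel.pos,
        ref=panel.ref,
        alt=panel.alt,
        haplotypes=H,
        chrom_lengths=dict(panel.chrom_lengths) if panel.chrom_lengths else None,
    )
    return out


def simulate_panel(config: SimulationConfig) -> PhasedPanel:
    """Full panel: ancestral roots, bottlenecked derivatives, implanted sweeps."""
    root_panel = simulate_ancestral_panel(config)
    panels = {sp: root_panel.take_samples(root_panel.sample_indices(sp))
              for sp in root_panel.subpop_names()}

    pending = [sp for sp in config.subpop_spec if sp.parent is not None]
    guard = 0
    while pending:
        progressed = False
        for sp in list(pending):
            if sp.parent in panels:
                child_seed = np.random.SeedSequence(
                    [config.seed, 0xB07, zlib.crc32(sp.name.encode()) % (2**31)]
                )
                panels[sp.name] = derive_bottlenecked_population(
                    panels[sp.parent],
                    sp.n_founders,
                    sp.n_drift_generations,
                    sp.n_samples,
                    child_seed,
                    name=sp.name,
                )
                pending.remove(sp)
                progressed = True
        guard += 1
        if not progressed or guard > len(config.subpop_spec) + 1:
            raise ValueError("cyclic or unresolvable subpopulation parentage")

    ordered = [panels[sp.name] for sp in config.subpop_spec]
    panel = PhasedPanel.concat_samples(ordered)

    for k, sw in enumerate(config.sweep_spec):
        rows = panel.hap_rows(sw.target)
        panel = implant_sweep(
            panel,
            (sw.chrom, sw.start, sw.end),
            donor_haplotype_index=int(rows[0]),
            final_frequency=sw.final_frequency,
            seed=np.random.SeedSequence([config.seed, 0x5E9, k]),
            subpop=sw.target,
        )
    return panel


# --------------------------------------------------------------------- #
# annotations
# --------------------------------------------------------------------- #
def synthesize_annotations(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[QTLInterval], pd.DataFrame]:
    """Non-overlapping gene models, trait-labelled QTLs and a family table.

    Genes get 1–12 exons, strand-aware UTRs on the terminal exons and a
    TF family label for a ``tf_fraction`` share of genes (the rest carry
    family ``"non-TF"``).  Each QTL interval is anchored on a gene so
    that about ``qtl_gene_fraction`` of genes fall inside a QTL, and is
    labelled with one of the 14 agronomic trait codes.
    """
    if config.genome_length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA110]))
    chroms = config.chromosome_names()

    per = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per[i] += 1

    genes: list[GeneModel] = []
    gi = 0
    for chrom, k in zip(chroms, per):
        if k == 0:
            continue
        max_len = config.genome_length // max(1, k) - 200
        if max_len <= 400:
            raise ValueError("genome too small for requested gene count")
        slot = config.genome_length // k
        for j in range(k):
            glen = int(rng.integers(400, min(8000, max_len)))
            lo = j * slot
            start = int(rng.integers(lo, lo + slot - glen))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, min(12, max(1, glen // 150)) + 1))
            exons = _random_exons(rng, start, end, n_exons)
            utr5, utr3, cds = _split_utrs(rng, exons, strand)
            subgenome = chrom[-1] if chrom[-1] in "ABD" else "synthetic"
            genes.append(
                GeneModel(
                    gene_id=f"SYNG{gi:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    cds=cds,
                    utr5=utr5,
                    utr3=utr3,
                    family=None,
                    subgenome=subgenome,
                )
            )
            gi += 1

    # family labels
    is_tf = rng.random(len(genes)) < config.tf_fraction
    fam_idx = rng.integers(0, len(TF_FAMILIES), size=len(genes))
    for g, tf, fi in zip(genes, is_tf, fam_idx):
        g.family = TF_FAMILIES[fi] if tf else "non-TF"
    family = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "family": [g.family for g in genes]}
    )

    # QTLs anchored on genes
    qtls: list[QTLInterval] = []
    if config.n_qtls > 0 and genes:
        n_cover = int(round(config.qtl_gene_fraction * len(genes)))
        covered = rng.choice(len(genes), size=min(n_cover, len(genes)), replace=False)
        anchors = (
            covered if covered.size else rng.integers(0, len(genes), size=config.n_qtls)
        )
        for q in range(config.n_qtls):
            g = genes[int(anchors[q % max(1, anchors.size)])]
            flank_l = int(rng.integers(10_000, 100_000))
            flank_r = int(rng.integers(10_000, 100_000))
            start = max(0, g.start - flank_l)
            end = min(config.genome_length, g.end + flank_r)
            trait = TRAIT_CODES[int(rng.integers(0, len(TRAIT_CODES)))]
            qtls.append(QTLInterval(trait=trait, chrom=g.chrom, start=start, end=end))
    return genes, qtls, family


def _random_exons(rng, start, end, n_exons):
    glen = end - start
    if n_exons == 1:
        return [(start, end)]
    # 2*n-2 distinct interior breakpoints -> alternating exon/intron runs
    cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [glen]])
    return [
        (start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
        for i in range(n_exons)
    ]


def _split_utrs(rng, exons, strand):
    """Carve UTRs off the terminal exons; the rest of the exonic span is CDS."""
    first, last = exons[0], exons[-1]
    u_head = int(rng.integers(0, max(1, min(300, (first[1] - first[0]) // 2))))
    u_tail = int(rng.integers(0, max(1, min(300, (last[1] - last[0]) // 2))))
    head = [(first[0], first[0] + u_head)] if u_head else []
    tail = [(last[1] - u_tail, last[1])] if u_tail else []
    utr5, utr3 = (head, tail) if strand == "+" else (tail, head)
    cds = []
    for s, e in exons:
        cs, ce = s, e
        if head and s == first[0]:
            cs = max(cs, head[0][1])
        if tail and e == last[1]:
            ce = min(ce, tail[0][0])
        if cs < ce:
            cds.append((cs, ce))
    return utr5, utr3, cds


# --------------------------------------------------------------------- #
# expression
# --------------------------------------------------------------------- #
def synthesize_expression(
    genes: list[GeneModel] | list[str],
    n_libraries: int,
    specificity_mix: tuple[float, float, float] = (0.25, 0.25, 0.5),
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x library FPKM matrix with known specificity classes.

    Three classes in proportions ``specificity_mix`` (uniform,
    single-library, graded): *uniform* genes have the same positive FPKM
    in every library (downstream τ = 0); *single-library* genes are
    positive in exactly one library (τ = 1 under the log2(x+1)
    transform); *graded* genes follow a library-peaked mean profile with
    log-normal noise.  Returns ``(matrix, truth)`` where ``truth`` has
    columns ``gene_id, class, peak_library``.
    """
    if n_libraries < 2:
        raise ValueError("need at least two libraries")
    if abs(sum(specificity_mix) - 1.0) > 1e-9:
        raise ValueError("specificity proportions must sum to 1")
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    counts = [int(round(p * n)) for p in specificity_mix]
    counts[2] = n - counts[0] - counts[1]
    classes = (
        ["uniform"] * counts[0] + ["single"] * counts[1] + ["graded"] * counts[2]
    )
    rng.shuffle(classes)

    libs = [f"lib{j:02d}" for j in range(n_libraries)]
    X = np.zeros((n, n_libraries))
    peaks = np.full(n, -1)
    for i, cls in enumerate(classes):
        if cls == "uniform":
            X[i, :] = rng.lognormal(2.0, 0.5)
        elif cls == "single":
            j = int(rng.integers(0, n_libraries))
            X[i, j] = rng.lognormal(3.0, 0.5)
            peaks[i] = j
        else:
            j = int(rng.integers(0, n_libraries))
            dist = np.abs(np.arange(n_libraries) - j)
            mean = 20.0 * np.exp(-dist / 2.0) + 0.05
            X[i, :] = mean * rng.lognormal(0.0, 0.3, size=n_libraries)
            peaks[i] = j
    matrix = pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"), columns=libs)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "class": classes, "peak_library": peaks}
    ).set_index("gene_id")
    return matrix, truth


# --------------------------------------------------------------------- #
# export
# --------------------------------------------------------------------- #
def write_vcf(panel: PhasedPanel, path: str) -> None:
    """Write the panel as an uncompressed VCF v4.2 with phased GT calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=domestiscan-simulate\n")
        if panel.chrom_lengths:
            for c, ln in panel.chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in panel.chromosomes():
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        H = panel.haplotypes
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j] + 1}\t.\t{panel.ref[j]}\t"
                f"{panel.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def export_fixture(
    panel: PhasedPanel,
    genes: list[GeneModel],
    qtls: list[QTLInterval],
    expression: pd.DataFrame,
    directory: str,
) -> dict[str, str]:
    """Write the whole fixture file set; returns a name -> path map."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "variants.vcf"),
        "gff": os.path.join(directory, "genes.gff3"),
        "panel": os.path.join(directory, "panel.tsv"),
        "qtl": os.path.join(directory, "qtls.tsv"),
        "family": os.path.join(directory, "families.tsv"),
        "fpkm": os.path.join(directory, "fpkm.tsv"),
    }
    write_vcf(panel, paths["vcf"])
    write_gff3(genes, paths["gff"])
    write_panel_tsv(panel, paths["panel"])
    write_qtl_tsv(qtls, paths["qtl"])
    pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "family": [g.family for g in genes]}
    ).to_csv(paths["family"], sep="\t", index=False)
    expression.to_csv(paths["fpkm"], sep="\t")
    return paths


def simulate_fixture(config: SimulationConfig, directory: str | None = None):
    """One-call driver: panel + annotations + expression (+ optional export)."""
    panel = simulate_panel(config)
    genes, qtls, family = synthesize_annotations(config)
    matrix, truth = synthesize_expression(
        genes,
        config.n_libraries,
        config.specificity_mix,
        seed=np.random.SeedSequence([config.seed, 0xE49]),
    )
    paths = export_fixture(panel, genes, qtls, matrix, directory) if directory else None
    return {
        "panel": panel,
        "genes": genes,
        "qtls": qtls,
        "family": family,
        "expression": matrix,
        "expression_truth": truth,
        "paths": paths,
    }
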