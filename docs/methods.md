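# Methods

This note records the models behind each stage, the parameter defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions the implementation commits to.

## Population statistics

**Per-site π.** For a biallelic site with `ref` and `alt` allele copies
among `n = ref + alt` haplotypes, π_site = `ref·alt / C(n,2)` — the mean
pairwise difference, algebraically equal to `(n/(n−1))·2p(1−p)`. Sites with
`n < 2` are undefined and skipped.

**Windowed π.** Σ site-π over the window divided by the *full window span*
in bp, the VCFtools `--window-pi` convention: monomorphic and uncovered
positions contribute zero. Windows are half-open `[start, end)` on a fixed
grid; the default step equals the window (non-overlapping), a smaller step
gives sliding windows. The trailing window of a chromosome may be shorter
and is scaled by its actual span. Default window: 50 kb, the standard grain
for domestication scans.

**Fst.** Weir & Cockerham (1984) variance components per site from diploid
genotypes — `a` (among populations), `b` (among individuals within
populations), `c` (within individuals, i.e. heterozygosity) — and the
windowed *weighted* estimator Σa/Σ(a+b+c) over usable sites (sites with
zero total variance are skipped). The heterozygosity term is retained
because samples are diploid; negative estimates are reported as computed,
not clamped, and ranking uses raw values. The weighted (ratio-of-sums)
variant was chosen over the mean-of-ratios variant because it is the
default headline number of the common tooling and is better behaved in
windows with low-information sites.

**π ratio.** Numerator/denominator of two aligned window tables
(wild/derived for domestication, derived/improved for improvement).
Windows with fewer than `min_sites = 2` segregating sites in either
population, or a zero denominator, are flagged `insufficient` and excluded
from quantile ranking — a guard against unstable ratios, not a data-quality
judgement.

## Sweep calling

Thresholds are type-7 (linear interpolation) quantiles of the finite,
unflagged values; the selection rule is `value ≥ threshold`, so ties at the
threshold are included. The default rule is the *intersection* of the two
top-5% sets (π ratio AND Fst) — the stricter reading and the common
practice for sweep candidacy — with `rule="union"` available. `q = 1.0`
returns no regions by policy: under a ≥-threshold rule the maxima would
always survive, which contradicts the intent of "top 0%". Adjacent selected
windows on the grid are merged; regions report supporting window counts and
the maxima of both statistics. Gene/region and gene/QTL overlap is any
shared base pair on half-open intervals.

## Haplotype catalogue

Diplotype strings concatenate, per sample and in genomic order, the two
phased allele letters at every SNP in the gene body plus `flank_bp = 2000`
on each side (matching the promoter/downstream defaults below). Sample-
level (two letters per site) rather than haploid counting was adopted
because published per-subgroup percentages of the kind this stage
reproduces (e.g. 24/29 = 82.76%) are consistent with per-sample counting.
Intronic SNPs are included by default (`include_introns=False` restricts
genic sites to exonic positions; the flanks are always kept). Genes with no
SNP in the span are excluded from the catalogue but remain in gene totals.

The major haplotype is the diplotype with within-subpopulation frequency
*strictly* greater than 0.5 (threshold configurable in (0,1]); the >50%
rule makes it unique whenever it exists. Display percentages are rounded
half-up to 2 decimals; all comparisons use full precision. Replacement
events are consecutive lineage pairs in a user-supplied order whose majors
differ, including none↔some transitions; the differing-majors summary count
requires two *defined* distinct majors.

## Region labels

Internal coordinates are 0-based half-open everywhere; VCF and GFF3 I/O
convert at the boundary. The promoter is `promoter_bp = 2000` upstream of
the strand-aware TSS and the downstream window `downstream_bp = 2000` past
the strand-aware gene end — 2 kb being the common plant-genomics convention
where no definition is given. When a site falls in several classes, genic
beats promoter beats downstream (a base inside one gene is not another
gene's promoter); ties within a class are broken by distance to the gene
start, then lexicographic gene id, making labels deterministic. Genic
sub-labels follow CDS > UTR > intron. Segregating-site counts are
per-subpopulation: a site monomorphic within a subpopulation does not count
for it.

Only the first transcript variant per gene (lowest-sorting transcript ID)
is read from GFF3; unphased VCF genotypes are an error (phasing and
imputation are out of scope), and multi-allelic or non-SNP records are
skipped with a count.

## Molecular evolution

dN/dS uses the Nei–Gojobori (1986) counting method: per-codon synonymous
site fractions (mutations to stop codons count as non-synonymous), site
totals averaged over the two sequences, observed differences resolved by
averaging over all shortest substitution pathways with stop-crossing
pathways excluded (if every pathway crosses a stop, all are used), and the
Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)` applied to pN and pS.
`p ≥ 3/4` is flagged saturated rather than extrapolated, and dN/dS is
undefined (NaN), not infinite, when dS = 0. A counting estimator was chosen
over a maximum-likelihood codon model because it is self-contained and
exactly testable against enumeration, and in the low-divergence regime the
pipeline retains (dS < 0.3) the two agree closely. Divergence time is
`T = dS/(2λ)·10⁻⁶` Mya with λ = 6.5×10⁻⁹ synonymous substitutions per site
per year; dS of 0.01–0.02 maps to 0.77–1.54 Mya. RBH pairing keeps a pair
iff each gene is the other's single best hit at e ≤ 1e-5, with score ties
broken by lower e-value then subject id. Orthogroups are labelled by their
A:B:D member counts ("1:1:1" = triad).

## Expression

τ is computed on `x̂ = log2(FPKM+1)`; the log transform tames FPKM's
dynamic range and gives the two anchor behaviours exactly: τ = 0 for a
uniform profile and τ = 1 for a single-positive-library profile. The result
is clamped to [0,1] against floating noise and undefined for an all-zero
gene. A gene is "expressed" with FPKM > 0 in ≥ `min_libraries` libraries
(default 1, configurable — the stricter "more than one" reading is a flag
away). Clustering is Ward/Euclidean agglomeration on per-gene z-scored log
profiles, cut at k = 7 by default; the method is deterministic, so the
`seed` parameter is accepted and ignored. Enrichment is the one-sided
hypergeometric tail P(X ≥ overlap) over the expressed universe with BH
adjustment across all (family, cluster) pairs at FDR 0.05. Co-expression
partners are ranked by Pearson correlation of log profiles — an
intentionally simple neighbour ranking, not a network-module analysis.

## Synthetic generator

The generator produces the structure the statistics consume, not a
genealogical simulation:

- **Ancestral pool** — every root subpopulation is drawn jointly from one
  panmictic pool; each site's derived-allele count `i` among the 2N root
  haplotypes has probability ∝ 1/i (the neutral SFS) and is assigned to a
  uniform random haplotype subset. There is no linkage, recombination or
  coalescent tree; root subpopulations are therefore undifferentiated
  (Fst ≈ 0 among them), which is exactly the null the scan needs.
- **Bottleneck** — a derived population samples `n_founders` haplotypes
  without replacement, then resamples 2N haplotypes with replacement for
  `n_drift_generations` (Wright–Fisher). Diploids are two independent
  haplotypes; no inbreeding or mating structure.
- **Sweeps** — within the region, a `final_frequency` fraction of target
  haplotypes (rounded to a count) is overwritten with one donor haplotype;
  sites outside are untouched. This reproduces the diversity loss and
  differentiation of a hard sweep without hitchhiking dynamics.
- **Annotations** — non-overlapping gene bodies with 1–12 exons, strand-
  aware terminal UTRs, TF-family labels for a configurable fraction of
  genes, and QTL intervals anchored on genes so a configurable gene
  fraction is QTL-covered, each labelled with one of the 14 trait codes.
- **Expression** — three gene classes (uniform / single-library / graded
  log-normal around a peaked mean) with recorded ground truth, giving known
  τ anchors at 0 and 1.

Default study conditions: the nine-subpopulation series mirrors a wheat
panel (wild einkorn 31, domesticated einkorn 31, urartu 29, wild emmer 28,
domesticated emmer 29, durum 13, landrace 45, cultivar 25, Ae. tauschii 30);
the two-population sweep-recovery fixture uses 20 + 20 samples on five 1-Mb
chromosomes with one 50-kb sweep at final frequency 0.95. Constants the
series does not pin down were fixed once, at values a population geneticist
would call unremarkable, and not revisited: 600 SNPs per Mb (enough for
~30 informative sites per 50-kb window), 12 founder haplotypes of 40 with
8 drift generations for the demo bottleneck (a strong but not degenerate
founder event; founder counts 10–20 across the nine-subpop series), and a
0.25/0.25/0.5 uniform/single/graded expression mix. `anchor_sweep_on_gene`
optionally re-positions the configured sweep onto a window holding a
(preferably QTL-covered) gene so the integrated report has a known positive
control. All randomness flows from one integer seed through named
`SeedSequence` streams; identical configurations give byte-identical
exported fixtures.

What passing on this generator does *not* show: behaviour under linkage and
recombination, soft sweeps, missing or unphased data, multi-allelic sites,
ascertainment bias, or realistic population divergence among the wild
progenitors. The oracle tests establish the estimators are computed
correctly; the fixture tests establish the pipeline detects the signature
it targets under its own assumptions.

## Problem sizes

The test suite and drivers run everything at desk scale by design: 3,000 –
3,600 segregating sites per fixture, 40–261 samples, 100–120 windows per
scan, 40-seed replication for the stochastic claims (bottleneck ordering,
sweep recovery, Fst null). These sizes keep every replicated experiment in
the low seconds while leaving each window ~30 segregating sites, the
resolution the 50-kb statistics assume.

## Known limitations

- The scan assumes phased, complete, biallelic input; no imputation.
- Sweep totals (Mb of selective region) depend on the AND/OR rule choice
  and the step size and are therefore reported but not treated as stable
  quantities of interest.
- The co-expression stage is a correlation ranking, not a weighted network;
  intramodular-connectivity semantics are out of scope.
- NG86 assumes equal base frequencies and no transition/transversion bias;
  with the dS < 0.3 filter this bias is small, but absolute dS for deeply
  diverged pairs should not be interpreted.
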