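"""GFF3/VCF input, region labelling and gene-structure contrasts."""

import numpy as np
import pytest

from domestiscan import simulate as sim
from domestiscan.annotations import (
    AnnotationError,
    GeneModel,
    assign_site_regions,
    gene_structure_summary,
    read_annotations,
    read_genotypes,
    snp_region_counts,
)

from conftest import build_diplotype_panel, random_panel

GFF_TWO_TRANSCRIPTS = """##gff-version 3
1A\tsrc\tgene\t101\t500\t.\t+\t.\tID=G1
1A\tsrc\tmRNA\t101\t500\t.\t+\t.\tID=G1.2;Parent=G1
1A\tsrc\texon\t101\t500\t.\t+\t.\tParent=G1.2
1A\tsrc\tmRNA\t101\t500\t.\t+\t.\tID=G1.1;Parent=G1
1A\tsrc\texon\t101\t200\t.\t+\t.\tParent=G1.1
1A\tsrc\texon\t301\t500\t.\t+\t.\tParent=G1.1
"""


class TestReadAnnotations:
    def test_first_transcript_variant_retained(self, tmp_path):
        path = tmp_path / "two.gff3"
        path.write_text(GFF_TWO_TRANSCRIPTS)
        genes = read_annotations(str(path))
        assert len(genes) == 1
        # G1.1 sorts before G1.2, so the two-exon variant wins
        assert genes[0].exons == [(100, 200), (300, 500)]

    def test_empty_gff_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n")
        assert read_annotations(str(path)) == []

    def test_exon_outside_gene_body_raises(self, tmp_path):
        bad = GFF_TWO_TRANSCRIPTS.replace(
            "1A\tsrc\texon\t301\t500", "1A\tsrc\texon\t301\t900"
        )
        path = tmp_path / "bad.gff3"
        path.write_text(bad)
        with pytest.raises(AnnotationError):
            read_annotations(str(path))

    def test_gff_round_trip_preserves_coordinates(self, tmp_path):
        cfg = sim.SimulationConfig(
            genome_length=200_000, n_chromosomes=2, n_sites=10,
            subpop_spec=[sim.SubpopSpec("w", 3)], n_genes=20, seed=5,
        )
        genes, _, _ = sim.synthesize_annotations(cfg)
        from domestiscan.annotations import write_gff3

        write_gff3(genes, str(tmp_path / "x.gff3"))
        back = read_annotations(str(tmp_path / "x.gff3"))
        orig = {(g.gene_id, g.start, g.end, tuple(g.exons)) for g in genes}
        seen = {(g.gene_id, g.start, g.end, tuple(g.exons)) for g in back}
        assert orig == seen


class TestReadGenotypes:
    def _write_vcf(self, path, records, samples=("s1", "s2")):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=1A,length=10000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        path.write_text(header + "".join(records))

    def _write_panel(self, path, samples=("s1", "s2")):
        path.write_text(
            "sample_id\tsubpopulation\n" + "".join(f"{s}\tpop\n" for s in samples)
        )

    def test_multiallelic_records_are_skipped(self, tmp_path):
        records = [f"1A\t{100 + i}\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t0|0\n" for i in range(9)]
        records.insert(4, "1A\t99\t.\tA\tT,G\t.\tPASS\t.\tGT\t0|1\t0|2\n")
        self._write_vcf(tmp_path / "v.vcf", records)
        self._write_panel(tmp_path / "p.tsv")
        panel = read_genotypes(str(tmp_path / "v.vcf"), str(tmp_path / "p.tsv"))
        assert panel.n_sites == 9
        assert panel.skipped_records == 1

    def test_unphased_call_rejected(self, tmp_path):
        self._write_vcf(
            tmp_path / "v.vcf", ["1A\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0|0\n"]
        )
        self._write_panel(tmp_path / "p.tsv")
        with pytest.raises(ValueError, match="unphased"):
            read_genotypes(str(tmp_path / "v.vcf"), str(tmp_path / "p.tsv"))

    def test_missing_panel_sample_listed(self, tmp_path):
        self._write_vcf(
            tmp_path / "v.vcf", ["1A\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t0|0\n"]
        )
        self._write_panel(tmp_path / "p.tsv", samples=("s1", "s2", "ghost"))
        with pytest.raises(ValueError, match="ghost"):
            read_genotypes(str(tmp_path / "v.vcf"), str(tmp_path / "p.tsv"))

    def test_round_trip_with_export(self, tmp_path):
        cfg = sim.SimulationConfig(
            genome_length=50_000, n_chromosomes=2, n_sites=60,
            subpop_spec=[sim.SubpopSpec("w", 4), sim.SubpopSpec("d", 3, "w", 4, 1)],
            n_genes=4, seed=8,
        )
        fx = sim.simulate_fixture(cfg, tmp_path)
        back = read_genotypes(fx["paths"]["vcf"], fx["paths"]["panel"])
        assert fx["panel"].equals(back)


def _gene(gene_id, start, end, strand="+", chrom="1A", **kw):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
        exons=kw.pop("exons", [(start, end)]), **kw,
    )


class TestAssignSiteRegions:
    def _panel_at(self, positions):
        n = len(positions)
        return build_diplotype_panel(
            chrom="1A",
            positions=positions,
            ref=["A"] * n,
            alt=["G"] * n,
            subpop_strings={"pop": ["AG" * n, "AA" * n]},
            chrom_length=100_000,
        )

    def test_cds_utr_intron_sublabels(self):
        gene = _gene(
            "G1", 1000, 2000,
            exons=[(1000, 1300), (1700, 2000)],
            cds=[(1100, 1300), (1700, 1900)],
            utr5=[(1000, 1100)],
            utr3=[(1900, 2000)],
        )
        panel = self._panel_at([1050, 1150, 1500, 1950])
        labels = assign_site_regions(panel, [gene]).set_index("pos")
        assert labels.loc[1150, "sublabel"] == "CDS"
        assert labels.loc[1050, "sublabel"] == "UTR"
        assert labels.loc[1500, "sublabel"] == "intron"
        assert labels.loc[1950, "sublabel"] == "UTR"
        assert (labels["label"] == "genic").all()

    def test_promoter_upstream_of_plus_strand_tss(self):
        gene = _gene("G1", 5000, 6000, strand="+")
        panel = self._panel_at([4500])  # 500 bp upstream
        labels = assign_site_regions(panel, [gene], promoter_bp=2000)
        assert labels["label"].iloc[0] == "promoter"

    def test_promoter_is_strand_aware_for_minus_genes(self):
        """500 bp past the 3'-coordinate end of a minus gene is promoter."""
        gene = _gene("G1", 5000, 6000, strand="-")
        panel = self._panel_at([6500])
        labels = assign_site_regions(panel, [gene], promoter_bp=2000)
        assert labels["label"].iloc[0] == "promoter"
        down = assign_site_regions(self._panel_at([4500]), [gene])
        assert down["label"].iloc[0] == "downstream"

    def test_genic_beats_neighbouring_promoter(self):
        a = _gene("A", 1000, 2000)
        b = _gene("B", 2500, 3500)  # promoter of B covers A's tail region
        panel = self._panel_at([1900])
        labels = assign_site_regions(panel, [a, b], promoter_bp=2000)
        assert labels["label"].iloc[0] == "genic"
        assert labels["gene_id"].iloc[0] == "A"

    def test_intergenic_default_and_determinism(self):
        gene = _gene("G1", 1000, 2000)
        panel = self._panel_at([50_000])
        l1 = assign_site_regions(panel, [gene])
        l2 = assign_site_regions(panel, [gene])
        assert l1["label"].iloc[0] == "intergenic"
        assert l1.equals(l2)


class TestSnpRegionCounts:
    def test_counts_match_known_placement(self):
        gene = _gene("G1", 1000, 2000)
        panel = build_diplotype_panel(
            chrom="1A",
            positions=[500, 1500, 2500, 9000],
            ref=["A"] * 4,
            alt=["G"] * 4,
            subpop_strings={
                # site at 9000 is monomorphic in pop2 (AA only there)
                "pop1": ["AGAGAGAG", "AAAAAAAA"],
                "pop2": ["AGAGAGAA", "AAAAAAAA"],
            },
            chrom_length=100_000,
        )
        labels = assign_site_regions(panel, [gene], promoter_bp=2000, downstream_bp=2000)
        counts = snp_region_counts(labels, panel).set_index("subpopulation")
        assert counts.loc["pop1", "genic"] == 1
        assert counts.loc["pop1", "promoter"] == 1
        assert counts.loc["pop1", "downstream"] == 1
        assert counts.loc["pop1", "intergenic"] == 1
        assert counts.loc["pop2", "intergenic"] == 0  # monomorphic there
        # conservation: class totals equal the segregating count
        cls = ["genic", "promoter", "downstream", "intergenic"]
        assert (counts[cls].sum(axis=1) == counts["segregating_total"]).all()


class TestGeneStructureSummary:
    def test_single_exon_gene_cdna_equals_length(self):
        g = _gene("T1", 0, 300)
        h = _gene("N1", 0, 500)
        out = gene_structure_summary([g, h], {"T1"})
        assert out.loc["cdna_length", "tf_median"] == 300

    def test_identical_classes_have_equal_medians(self):
        genes = [_gene(f"T{i}", i * 1000, i * 1000 + 300) for i in range(3)]
        genes += [_gene(f"N{i}", (i + 10) * 1000, (i + 10) * 1000 + 300) for i in range(3)]
        out = gene_structure_summary(genes, {"T0", "T1", "T2"})
        assert (out["tf_median"] == out["non_tf_median"]).all()

    def test_shorter_tf_class_detected(self):
        tf = [_gene(f"T{i}", i * 10_000, i * 10_000 + 500) for i in range(10)]
        non = [_gene(f"N{i}", (i + 20) * 10_000, (i + 20) * 10_000 + 4000) for i in range(10)]
        out = gene_structure_summary(tf + non, {g.gene_id for g in tf})
        assert (
            out.loc["transcript_length", "tf_median"]
            < out.loc["transcript_length", "non_tf_median"]
        )
        assert out.loc["transcript_length", "pvalue"] < 0.01

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            gene_structure_summary([_gene("T1", 0, 100)], {"T1"})
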