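"""Diplotype catalogues, major haplotypes and replacement tracking."""

import numpy as np
import pandas as pd
import pytest

from domestiscan import simulate as sim
from domestiscan.annotations import GeneModel, read_annotations, read_genotypes
from domestiscan.haplotype import (
    build_gene_haplotypes,
    catalog_table,
    haplotype_frequencies,
    major_haplotypes,
    shift_summary,
    track_major_shifts,
)

from conftest import build_diplotype_panel


class TestBuildGeneHaplotypes:
    def test_homozygous_reference_string(self):
        panel = build_diplotype_panel(
            chrom="1A", positions=[10, 20, 30, 40],
            ref=["C", "C", "C", "C"], alt=["T", "T", "T", "T"],
            subpop_strings={"pop": ["CCCCCCCC"]},
        )
        gene = GeneModel(gene_id="G", chrom="1A", start=5, end=50, strand="+",
                        exons=[(5, 50)])
        cat = build_gene_haplotypes(panel, gene, flank_bp=0)
        assert cat.diplotypes.iloc[0] == "CCCCCCCC"

    def test_four_distinct_diplotype_classes(self, nac_gene_panel):
        panel, gene = nac_gene_panel
        cat = build_gene_haplotypes(panel, gene)
        urartu = cat.diplotypes[cat.subpops == "urartu"]
        assert set(urartu) == {"CCAACCAA", "TTGGCCAA", "TTGGTTAA", "TCGATCAA"}

    def test_gene_without_snps_is_excluded(self, nac_gene_panel):
        panel, _ = nac_gene_panel
        far = GeneModel(gene_id="far", chrom="1A", start=9000, end=9100, strand="+",
                        exons=[(9000, 9100)])
        assert build_gene_haplotypes(panel, far, flank_bp=10) is None

    def test_flank_pulls_in_promoter_snps(self, nac_gene_panel):
        panel, _ = nac_gene_panel
        downstream_gene = GeneModel(
            gene_id="nearby", chrom="1A", start=1350, end=1400, strand="+",
            exons=[(1350, 1400)],
        )
        with_flank = build_gene_haplotypes(panel, downstream_gene, flank_bp=2000)
        without = build_gene_haplotypes(panel, downstream_gene, flank_bp=0)
        assert with_flank.n_sites == 4
        assert without is None


class TestHaplotypeFrequencies:
    def test_published_urartu_percentages(self, nac_gene_panel):
        panel, gene = nac_gene_panel
        freqs = haplotype_frequencies(build_gene_haplotypes(panel, gene))
        urartu = freqs[freqs["subpopulation"] == "urartu"]
        assert list(urartu["percent"]) == [82.76, 10.34, 3.45, 3.45]
        assert urartu.iloc[0]["haplotype"] == "CCAACCAA"

    def test_published_wild_emmer_top_frequency(self, nac_gene_panel):
        panel, gene = nac_gene_panel
        freqs = haplotype_frequencies(build_gene_haplotypes(panel, gene))
        emmer = freqs[freqs["subpopulation"] == "wild_emmer"]
        assert emmer.iloc[0]["percent"] == 96.43
        assert emmer.iloc[0]["haplotype"] == "TTGGTTAA"

    def test_three_class_wild_emmer_distribution(self, bzip_gene_panel):
        panel, gene = bzip_gene_panel
        freqs = haplotype_frequencies(build_gene_haplotypes(panel, gene))
        emmer = freqs[freqs["subpopulation"] == "wild_emmer"]
        assert list(emmer["percent"]) == [75.0, 21.43, 3.57]

    def test_single_sample_subpopulation_is_100(self):
        panel = build_diplotype_panel(
            chrom="1A", positions=[10], ref=["A"], alt=["C"],
            subpop_strings={"solo": ["AC"]},
        )
        gene = GeneModel(gene_id="G", chrom="1A", start=0, end=20, strand="+",
                        exons=[(0, 20)])
        freqs = haplotype_frequencies(build_gene_haplotypes(panel, gene))
        assert freqs.iloc[0]["percent"] == 100.0

    def test_frequencies_sum_to_one_per_subpopulation(self, nac_gene_panel):
        panel, gene = nac_gene_panel
        freqs = haplotype_frequencies(build_gene_haplotypes(panel, gene))
        sums = freqs.groupby("subpopulation")["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_sample_order_permutation_invariance(self, nac_gene_panel):
        panel, gene = nac_gene_panel
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_samples)
        shuffled = panel.take_samples(perm)
        a = haplotype_frequencies(build_gene_haplotypes(panel, gene))
        b = haplotype_frequencies(build_gene_haplotypes(shuffled, gene))
        key = ["subpopulation", "haplotype"]
        assert a.set_index(key)["frequency"].sort_index().equals(
            b.set_index(key)["frequency"].sort_index()
        )


class TestMajorHaplotypes:
    def _table(self, freqs):
        return pd.DataFrame(
            {
                "subpopulation": ["p"] * len(freqs),
                "haplotype": list("ABCDEFG")[: len(freqs)],
                "frequency": freqs,
            }
        )

    def test_fifty_fifty_has_no_major(self):
        assert major_haplotypes(self._table([0.5, 0.5]))["p"] is None

    def test_just_above_half_is_major(self):
        assert major_haplotypes(self._table([0.51, 0.49]))["p"] == "A"

    def test_published_major_in_urartu(self, nac_gene_panel):
        panel, gene = nac_gene_panel
        freqs = haplotype_frequencies(build_gene_haplotypes(panel, gene))
        assert major_haplotypes(freqs)["urartu"] == "CCAACCAA"

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            major_haplotypes(self._table([1.0]), threshold=0.0)


LINEAGES = ["wild_emmer", "domesticated_emmer", "durum", "landrace", "cultivar"]


class TestTrackMajorShifts:
    def test_single_replacement_at_domestication_step(self, bzip_gene_panel):
        panel, gene = bzip_gene_panel
        freqs = haplotype_frequencies(build_gene_haplotypes(panel, gene))
        events = track_major_shifts({gene.gene_id: freqs}, LINEAGES)
        assert len(events) == 1
        e = events.iloc[0]
        assert (e["from_lineage"], e["to_lineage"]) == ("wild_emmer", "domesticated_emmer")
        assert (e["from_major"], e["to_major"]) == ("CCGG", "CCAA")

    def test_constant_major_gives_no_events(self):
        table = pd.DataFrame(
            {
                "subpopulation": LINEAGES,
                "haplotype": ["AA"] * 5,
                "frequency": [1.0] * 5,
            }
        )
        assert track_major_shifts({"g": table}, LINEAGES).empty

    def test_unknown_lineage_raises(self, bzip_gene_panel):
        panel, gene = bzip_gene_panel
        freqs = haplotype_frequencies(build_gene_haplotypes(panel, gene))
        with pytest.raises(KeyError):
            track_major_shifts({gene.gene_id: freqs}, LINEAGES + ["spelt"])

    def test_gene_without_major_counts_in_totals_only(self):
        no_major = pd.DataFrame(
            {
                "subpopulation": np.repeat(LINEAGES, 2),
                "haplotype": ["AA", "CC"] * 5,
                "frequency": [0.5, 0.5] * 5,
            }
        )
        summary = shift_summary({"g": no_major}, LINEAGES)
        assert summary == {"n_genes": 1, "n_with_major": 0, "n_differing_major": 0}


def test_rebuild_from_exported_fixture_is_bit_exact(tmp_path):
    """Export -> re-read -> rebuild reproduces the catalogue exactly."""
    cfg = sim.SimulationConfig(
        genome_length=60_000, n_chromosomes=1, n_sites=150,
        subpop_spec=[sim.SubpopSpec("w", 6), sim.SubpopSpec("d", 5, "w", 6, 2)],
        n_genes=6, seed=13,
    )
    fx = sim.simulate_fixture(cfg, tmp_path)
    panel2 = read_genotypes(fx["paths"]["vcf"], fx["paths"]["panel"])
    genes2 = read_annotations(fx["paths"]["gff"], fx["paths"]["family"])
    for g_orig, g_back in zip(fx["genes"], genes2):
        a = build_gene_haplotypes(fx["panel"], g_orig)
        b = build_gene_haplotypes(panel2, g_back)
        if a is None:
            assert b is None
            continue
        assert a.diplotypes.equals(b.diplotypes)
        assert haplotype_frequencies(a).equals(haplotype_frequencies(b))


def test_catalog_table_flags_majors(nac_gene_panel):
    panel, gene = nac_gene_panel
    freqs = haplotype_frequencies(build_gene_haplotypes(panel, gene))
    flat = catalog_table({gene.gene_id: freqs})
    majors = flat[flat["is_major"]]
    assert set(majors["subpopulation"]) == {"urartu", "wild_emmer"}
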