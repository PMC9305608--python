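"""Simulator: SFS shape, bottleneck behaviour, sweep implanting, export."""

import numpy as np
import pytest
from scipy import stats as sps

from domestiscan import simulate as sim
from domestiscan.panel import PhasedPanel
from domestiscan.popgen import scan_windows, windowed_pi


def small_config(seed=0, **kw):
    base = dict(
        genome_length=100_000,
        n_chromosomes=1,
        n_sites=200,
        subpop_spec=[sim.SubpopSpec("wild", 15)],
        n_genes=5,
        n_qtls=2,
        n_libraries=6,
        seed=seed,
    )
    base.update(kw)
    return sim.SimulationConfig(**base)


class TestAncestralPanel:
    def test_zero_sites_gives_empty_site_list(self):
        panel = sim.simulate_ancestral_panel(small_config(n_sites=0))
        assert panel.n_sites == 0
        assert panel.n_samples == 15

    def test_same_seed_is_bit_identical(self):
        a = sim.simulate_ancestral_panel(small_config(seed=42))
        b = sim.simulate_ancestral_panel(small_config(seed=42))
        assert a.equals(b)

    def test_zero_samples_is_configuration_error(self):
        with pytest.raises(ValueError):
            small_config(subpop_spec=[sim.SubpopSpec("wild", 0)])

    def test_sfs_follows_neutral_expectation(self):
        """Derived-allele counts fit the 1/i neutral SFS (chi-square GOF)."""
        two_n = 60
        i = np.arange(1, two_n)
        expected_prob = (1 / i) / np.sum(1 / i)
        for seed in range(20):
            cfg = small_config(
                seed=seed, n_sites=10_000, genome_length=1_000_000,
                subpop_spec=[sim.SubpopSpec("wild", two_n // 2)],
            )
            panel = sim.simulate_ancestral_panel(cfg)
            counts = panel.alt_counts()
            observed = np.bincount(counts, minlength=two_n)[1:two_n]
            chi = sps.chisquare(observed, expected_prob * 10_000)
            assert chi.pvalue > 0.001


class TestBottleneck:
    def test_all_founders_no_drift_is_permutation(self):
        parent = sim.simulate_ancestral_panel(small_config(seed=1))
        child = sim.derive_bottlenecked_population(
            parent, n_founders=parent.n_haplotypes, n_generations=0,
            n_out=parent.n_samples, seed=5,
        )
        key = lambda H: sorted(map(tuple, H))
        assert key(child.haplotypes) == key(parent.haplotypes)

    def test_single_founder_forces_monomorphism(self):
        parent = sim.simulate_ancestral_panel(small_config(seed=2))
        child = sim.derive_bottlenecked_population(parent, 1, 3, 10, seed=0)
        assert (child.haplotypes == child.haplotypes[0]).all()
        pi = windowed_pi(child, None, window_bp=100_000)
        assert (pi["pi"] == 0).all()

    def test_zero_founders_rejected(self):
        parent = sim.simulate_ancestral_panel(small_config())
        with pytest.raises(ValueError):
            sim.derive_bottlenecked_population(parent, 0, 1, 5, seed=0)

    def test_two_founders_reduce_diversity(self):
        """pi(child) <= pi(parent) in >= 95% of 40 seeded replicates."""
        ok = 0
        for seed in range(40):
            cfg = small_config(seed=seed, n_sites=300)
            parent = sim.simulate_ancestral_panel(cfg)
            child = sim.derive_bottlenecked_population(parent, 2, 2, 15, seed=seed)
            pp = windowed_pi(parent, None, window_bp=100_000)["pi"].iloc[0]
            cp = windowed_pi(child, None, window_bp=100_000)["pi"].iloc[0]
            ok += cp <= pp
        assert ok >= 38

    def test_bottleneck_reduces_mean_windowed_pi(self):
        """Diversity ordering holds across the default two-pop fixture."""
        ok = 0
        for seed in range(40):
            panel = sim.simulate_panel(sim.sweep_demo_config(seed))
            pw = windowed_pi(panel, "wild", 50_000)["pi"].mean()
            pd_ = windowed_pi(panel, "dom", 50_000)["pi"].mean()
            ok += pd_ < pw
        assert ok >= 38


class TestSweepImplant:
    def _panel(self, seed=0):
        return sim.simulate_ancestral_panel(small_config(seed=seed))

    def test_fixation_makes_region_monomorphic(self):
        panel = self._panel()
        swept = sim.implant_sweep(panel, ("1A", 0, 100_000), 0, 1.0, seed=1)
        assert (swept.haplotypes == swept.haplotypes[0]).all()

    def test_sites_outside_region_untouched(self):
        panel = self._panel(3)
        region = ("1A", 40_000, 60_000)
        swept = sim.implant_sweep(panel, region, 0, 0.8, seed=2)
        outside = ~panel.site_mask(*region)
        assert np.array_equal(
            swept.haplotypes[:, outside], panel.haplotypes[:, outside]
        )

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            sim.implant_sweep(self._panel(), ("1A", 500, 500), 0, 0.5, seed=0)

    def test_swept_window_ratio_ranks_above_median(self):
        """A 0.9-frequency 50-kb sweep lifts that window's pi ratio."""
        cfg = sim.sweep_demo_config(7)
        cfg.sweep_spec = [sim.SweepSpec("2A", 500_000, 550_000, "dom", 0.9)]
        panel = sim.simulate_panel(cfg)
        table = scan_windows(panel, "wild", "dom", 50_000)
        swept = table[(table["chrom"] == "2A") & (table["start"] == 500_000)]
        med = table.loc[~table["insufficient"], "pi_ratio"].median()
        assert swept["pi_ratio"].iloc[0] > med

    def test_sweep_windows_exceed_background_fst(self):
        """Implanted windows carry mean Fst above genome background."""
        ok = 0
        for seed in range(40):
            cfg = sim.sweep_demo_config(seed)
            panel = sim.simulate_panel(cfg)
            table = scan_windows(panel, "wild", "dom", 50_000)
            sw = cfg.sweep_spec[0]
            in_sweep = (
                (table["chrom"] == sw.chrom)
                & (table["start"] < sw.end)
                & (sw.start < table["end"])
            )
            ok += np.nanmean(table.loc[in_sweep, "fst"]) > np.nanmean(
                table.loc[~in_sweep, "fst"]
            )
        assert ok >= 36


class TestAnnotationsSynthesis:
    def test_forced_overlap_places_gene_in_qtl(self):
        cfg = small_config(n_genes=1, n_qtls=1, qtl_gene_fraction=1.0)
        genes, qtls, _ = sim.synthesize_annotations(cfg)
        g, q = genes[0], qtls[0]
        assert q.chrom == g.chrom and q.start <= g.start and g.end <= q.end

    def test_gene_bodies_never_overlap(self):
        cfg = small_config(
            n_genes=200, n_chromosomes=5, genome_length=1_000_000, n_sites=10
        )
        genes, _, _ = sim.synthesize_annotations(cfg)
        assert len(genes) == 200
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        overlaps = 0
        for ivals in by_chrom.values():
            ivals.sort()
            overlaps += sum(b[0] < a[1] for a, b in zip(ivals, ivals[1:]))
        assert overlaps == 0

    def test_exon_counts_within_bounds(self):
        genes, _, _ = sim.synthesize_annotations(small_config(n_genes=50))
        assert all(1 <= len(g.exons) <= 12 for g in genes)

    def test_qtl_traits_come_from_the_14_codes(self):
        _, qtls, _ = sim.synthesize_annotations(small_config(n_qtls=10))
        assert {q.trait for q in qtls} <= set(sim.TRAIT_CODES)

    def test_genome_too_small_raises(self):
        with pytest.raises(ValueError):
            sim.synthesize_annotations(small_config(genome_length=5_000, n_genes=50))


class TestExpressionSynthesis:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            sim.synthesize_expression(["g1"], 4, specificity_mix=(0.5, 0.5, 0.5))

    def test_class_structure(self):
        matrix, truth = sim.synthesize_expression(
            [f"g{i}" for i in range(30)], 8, specificity_mix=(0.3, 0.3, 0.4), seed=1
        )
        uni = truth[truth["class"] == "uniform"].index
        single = truth[truth["class"] == "single"].index
        assert (matrix.loc[uni].nunique(axis=1) == 1).all()
        assert ((matrix.loc[single] > 0).sum(axis=1) == 1).all()

    def test_seed_determinism(self):
        a, _ = sim.synthesize_expression(["g1", "g2"], 5, seed=9)
        b, _ = sim.synthesize_expression(["g1", "g2"], 5, seed=9)
        assert a.equals(b)


class TestExportFixture:
    def test_fixture_is_byte_deterministic(self, tmp_path):
        cfg = small_config(seed=11, subpop_spec=[sim.SubpopSpec("wild", 5)])
        p1 = sim.simulate_fixture(cfg, tmp_path / "a")["paths"]
        p2 = sim.simulate_fixture(cfg, tmp_path / "b")["paths"]
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_vcf_calls_are_phased_and_conserved(self, tmp_path):
        cfg = small_config(seed=4)
        fx = sim.simulate_fixture(cfg, tmp_path)
        body = [
            l for l in open(fx["paths"]["vcf"]) if not l.startswith("#")
        ]
        assert len(body) == fx["panel"].n_sites
        for line in body:
            for call in line.rstrip("\n").split("\t")[9:]:
                assert "|" in call and "/" not in call
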