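#!/usr/bin/env python
"""Fold every evidence layer into the ranked candidate-gene report.

Re-runs the sweep scan, haplotype catalogue, QTL co-location and tau
stages of the seed-17 fixture and intersects them: the headline tier is
the set of genes simultaneously inside a called sweep region, inside a
trait QTL, carrying a major haplotype and expressed.
"""

import os

from domestiscan import simulate as sim
from domestiscan.expression import cluster_profiles, tau_table
from domestiscan.haplotype import (
    build_gene_haplotypes,
    haplotype_frequencies,
    major_haplotypes,
)
from domestiscan.integrate import colocate_qtl, prioritize_candidates
from domestiscan.popgen import scan_windows
from domestiscan.sweep import call_sweeps, genes_in_regions

SEED = 17
OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    os.makedirs(OUT, exist_ok=True)
    cfg = sim.anchor_sweep_on_gene(sim.nine_subpop_config(SEED))
    fx = sim.simulate_fixture(cfg)
    panel, genes, qtls = fx["panel"], fx["genes"], fx["qtls"]

    dom_scan = scan_windows(panel, "wild_emmer", "domesticated_emmer", 50_000)
    imp_scan = scan_windows(panel, "domesticated_emmer", "durum", 50_000)
    dom_regions = call_sweeps(dom_scan, process="domestication")
    imp_regions = call_sweeps(imp_scan, process="improvement")
    dom_genes = set(genes_in_regions(genes, dom_regions)["gene_id"])
    imp_genes = set(genes_in_regions(genes, imp_regions)["gene_id"])

    qtl_map, trait_counts = colocate_qtl(genes, qtls)

    major, shifted = set(), set()
    for g in genes:
        cat = build_gene_haplotypes(panel, g, flank_bp=2000)
        if cat is None:
            continue
        majors = major_haplotypes(haplotype_frequencies(cat))
        defined = {m for m in majors.values() if m is not None}
        if defined:
            major.add(g.gene_id)
        if len(defined) > 1:
            shifted.add(g.gene_id)

    taus = tau_table(fx["expression"])
    expressed = fx["expression"].loc[taus.index[taus["expressed"]]]
    if len(expressed) >= 7:
        taus.loc[expressed.index, "cluster"] = cluster_profiles(expressed, k=7)

    report = prioritize_candidates(
        genes, dom_genes, imp_genes, qtl_map, major, shifted, taus
    )
    report.to_csv(os.path.join(OUT, "07_candidates.tsv"), sep="\t", index=False)

    headline = report[report["headline"]]
    print(f"sweep genes: {len(dom_genes)} domestication, {len(imp_genes)} improvement, "
          f"{len(dom_genes & imp_genes)} shared")
    print(f"QTL co-located genes: {len(qtl_map)}; per-trait counts:")
    print(trait_counts.to_string(index=False))
    print(f"genes with a major haplotype: {len(major)}; with a shift: {len(shifted)}")
    print(f"\nheadline tier (sweep & QTL & major haplotype & expressed): "
          f"{len(headline)} genes")
    if not headline.empty:
        cols = ["gene_id", "family", "traits", "tau", "evidence_count"]
        print(headline[cols].to_string(index=False))


if __name__ == "__main__":
    main()
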