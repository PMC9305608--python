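"""QTL co-location and multi-evidence candidate prioritization.

The report stage: genes are co-located with trait-labelled QTL
intervals by any base-pair overlap, then every evidence layer — sweep
membership (domestication / improvement), QTL co-location, major
haplotypes, major-haplotype shifts, expression — is folded into one
ranked candidate table.  The *headline tier* is the strict intersection
of four evidence classes (sweep ∩ QTL ∩ major haplotype ∩ expressed);
no scoring beyond evidence counting is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotations import GeneModel, QTLInterval

__all__ = ["colocate_qtl", "prioritize_candidates"]


def colocate_qtl(
    genes: list[GeneModel], qtls: list[QTLInterval]
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Assign trait labels to genes overlapping QTL intervals.

    Any base-pair overlap (half-open) counts; a gene may carry several
    traits.  QTLs on chromosomes absent from the gene set are skipped
    with a warning.  Returns ``(gene -> sorted trait list, per-trait
    gene-count table)``.
    """
    gene_chroms = {g.chrom for g in genes}
    assignments: dict[str, set[str]] = {}
    for q in qtls:
        if q.chrom not in gene_chroms:
            warnings.warn(f"QTL {q.trait}@{q.chrom} on unknown chromosome; skipped")
            continue
        for g in genes:
            if g.chrom == q.chrom and g.start < q.end and q.start < g.end:
                assignments.setdefault(g.gene_id, set()).add(q.trait)
    gene_traits = {g: sorted(ts) for g, ts in assignments.items()}
    counts: dict[str, int] = {}
    for ts in gene_traits.values():
        for t in ts:
            counts[t] = counts.get(t, 0) + 1
    count_df = (
        pd.DataFrame(
            sorted(counts.items()), columns=["trait", "n_genes"]
        )
        if counts
        else pd.DataFrame(columns=["trait", "n_genes"])
    )
    return gene_traits, count_df


_EVIDENCE_FLAGS = [
    "in_sweep_domestication",
    "in_sweep_improvement",
    "in_qtl",
    "has_major_haplotype",
    "major_shift_observed",
    "expressed",
]


def prioritize_candidates(
    genes: list[GeneModel],
    sweep_genes_domestication: set[str],
    sweep_genes_improvement: set[str],
    qtl_map: dict[str, list[str]],
    major_haplotype_genes: set[str],
    shift_genes: set[str],
    tau_results: pd.DataFrame,
) -> pd.DataFrame:
    """Fold all evidence layers into one ranked candidate report.

    ``tau_results`` is indexed by gene id with ``expressed`` and ``tau``
    columns (``cluster`` optional).  Evidence ids referring to genes
    outside ``genes`` raise, listing the offenders.  The report carries
    one row per gene, boolean evidence flags, the evidence count and a
    ``headline`` flag for genes with all four core evidence classes
    (sweep ∩ QTL ∩ major haplotype ∩ expressed); it is sorted by
    evidence count descending, then gene id.
    """
    known = {g.gene_id for g in genes}
    offenders = sorted(
        (
            (sweep_genes_domestication | sweep_genes_improvement)
            | set(qtl_map)
            | major_haplotype_genes
            | shift_genes
            | set(tau_results.index)
        )
        - known
    )
    if offenders:
        raise ValueError(f"evidence refers to unknown gene ids: {offenders}")

    rows = []
    for g in genes:
        gid = g.gene_id
        in_dom = gid in sweep_genes_domestication
        in_imp = gid in sweep_genes_improvement
        traits = qtl_map.get(gid, [])
        has_tau = gid in tau_results.index
        expressed = bool(tau_results.loc[gid, "expressed"]) if has_tau else False
        tau = float(tau_results.loc[gid, "tau"]) if has_tau else np.nan
        cluster = (
            tau_results.loc[gid, "cluster"]
            if has_tau and "cluster" in tau_results.columns
            else None
        )
        flags = {
            "in_sweep_domestication": in_dom,
            "in_sweep_improvement": in_imp,
            "in_qtl": bool(traits),
            "has_major_haplotype": gid in major_haplotype_genes,
            "major_shift_observed": gid in shift_genes,
            "expressed": expressed,
        }
        rows.append(
            {
                "gene_id": gid,
                "family": g.family,
                **flags,
                "traits": ",".join(traits),
                "tau": tau,
                "cluster": cluster,
                "evidence_count": sum(flags.values()),
                "headline": (
                    (in_dom or in_imp)
                    and bool(traits)
                    and gid in major_haplotype_genes
                    and expressed
                ),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["evidence_count", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
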