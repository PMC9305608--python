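"""Candidate selective-region calling from window statistics.

A window is a sweep candidate when it falls in the top quantile of the
π ratio and (by default; ``rule="union"`` for either) of Fst — the
top-5% rule used in domestication scans.  Adjacent selected windows on
the grid are merged into one region.  The threshold is the linear-
interpolation (type-7) quantile, with the selection rule ``value ≥
threshold`` (ties included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import GeneModel

__all__ = ["quantile_threshold", "call_sweeps", "genes_in_regions", "regions_to_bed"]


def quantile_threshold(values, q: float) -> float:
    """Type-7 (linear interpolation) quantile of the finite values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to rank")
    return float(np.quantile(v, q))


def call_sweeps(
    window_stats: pd.DataFrame,
    q: float = 0.95,
    rule: str = "intersection",
    contrast: str | None = None,
    process: str | None = None,
) -> pd.DataFrame:
    """Call candidate selective regions from a scan-window table.

    ``window_stats`` must carry ``chrom, start, end, pi_ratio, fst`` and
    optionally ``insufficient`` (flagged windows are never selected nor
    ranked).  ``q = 0.95`` keeps the top 5% of each statistic; with
    ``rule="intersection"`` a window must pass both thresholds, with
    ``"union"`` either.  ``q = 1.0`` selects nothing by policy (the
    ≥-threshold rule would otherwise keep the maxima).

    Returns one row per merged region: ``chrom, start, end, n_windows,
    max_pi_ratio, max_fst`` plus optional ``contrast`` / ``process``
    labels.
    """
    if rule not in ("intersection", "union"):
        raise ValueError("rule must be 'intersection' or 'union'")
    df = window_stats.reset_index(drop=True)
    ok = np.isfinite(df["pi_ratio"].to_numpy()) & np.isfinite(df["fst"].to_numpy())
    if "insufficient" in df.columns:
        ok &= ~df["insufficient"].to_numpy().astype(bool)

    cols = [
        "chrom", "start", "end", "n_windows", "max_pi_ratio", "max_fst",
        "contrast", "process",
    ]
    if q >= 1.0 or not ok.any():
        return pd.DataFrame(columns=cols)
    thr_ratio = quantile_threshold(df.loc[ok, "pi_ratio"], q)
    thr_fst = quantile_threshold(df.loc[ok, "fst"], q)
    top_ratio = ok & (df["pi_ratio"].to_numpy() >= thr_ratio)
    top_fst = ok & (df["fst"].to_numpy() >= thr_fst)
    sel = (top_ratio & top_fst) if rule == "intersection" else (top_ratio | top_fst)

    picked = df[sel].sort_values(["chrom", "start"]).reset_index(drop=True)
    regions = []
    for _, w in picked.iterrows():
        if (
            regions
            and regions[-1]["chrom"] == w["chrom"]
            and w["start"] <= regions[-1]["end"]  # adjacent or overlapping on grid
        ):
            r = regions[-1]
            r["end"] = max(r["end"], int(w["end"]))
            r["n_windows"] += 1
            r["max_pi_ratio"] = max(r["max_pi_ratio"], float(w["pi_ratio"]))
            r["max_fst"] = max(r["max_fst"], float(w["fst"]))
        else:
            regions.append(
                {
                    "chrom": w["chrom"],
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "n_windows": 1,
                    "max_pi_ratio": float(w["pi_ratio"]),
                    "max_fst": float(w["fst"]),
                    "contrast": contrast,
                    "process": process,
                }
            )
    return pd.DataFrame(regions, columns=cols)


def genes_in_regions(genes: list[GeneModel], regions: pd.DataFrame) -> pd.DataFrame:
    """Map genes into regions by any base-pair overlap (half-open).

    A gene may map to several regions; one output row per (gene,
    region) pair, with the region's row index in ``region_index``.
    """
    rows = []
    for i, r in regions.reset_index(drop=True).iterrows():
        for g in genes:
            if g.chrom == r["chrom"] and g.start < r["end"] and r["start"] < g.end:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "region_index": i,
                        "chrom": g.chrom,
                        "region_start": int(r["start"]),
                        "region_end": int(r["end"]),
                        "process": r.get("process"),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "region_index", "chrom", "region_start", "region_end", "process"],
    )


def regions_to_bed(regions: pd.DataFrame, path: str) -> None:
    """Export regions as BED (0-based half-open, matching internal coords)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            name = r.get("process") or r.get("contrast") or "sweep"
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{name}\n")
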