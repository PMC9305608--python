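"""Nucleotide diversity and Fst, per site and in genomic windows.

Window statistics follow the VCFtools conventions the field uses for
domestication scans: per-window π is the sum of per-site pairwise
diversity divided by the full window span in bp (monomorphic or absent
sites contribute zero), and windowed Fst is Weir & Cockerham's (1984)
weighted estimator Σa / Σ(a+b+c) over the usable sites of the window,
computed from diploid genotypes including the heterozygosity (c)
component.

Windows are half-open ``[start, end)`` on a fixed grid (default step =
window, i.e. non-overlapping); the trailing window of a chromosome may
be shorter.  All functions return tidy :class:`pandas.DataFrame` window
tables that the sweep caller consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import PhasedPanel

__all__ = [
    "site_pi",
    "windowed_pi",
    "wc_site_components",
    "weir_cockerham_fst",
    "pi_ratio_windows",
    "scan_windows",
]


def site_pi(ref_count, alt_count):
    """Per-site nucleotide diversity: mean pairwise difference.

    ``π_site = ref·alt / C(n, 2)`` with ``n = ref + alt`` non-missing
    haplotypes.  Accepts scalars or arrays; sites with ``n < 2`` yield
    NaN (undefined).
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    n = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n >= 2, ref * alt / (n * (n - 1) / 2.0), np.nan)
    if np.isscalar(ref_count) and np.isscalar(alt_count):
        return float(out)
    return out


def _chrom_length(panel: PhasedPanel, chrom: str) -> int:
    if panel.chrom_lengths and chrom in panel.chrom_lengths:
        return int(panel.chrom_lengths[chrom])
    p = panel.pos[panel.chrom == chrom]
    return int(p.max()) + 1 if p.size else 0


def _window_grid(length: int, window_bp: int, step_bp: int):
    starts = np.arange(0, max(length, 1), step_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, length)
    keep = starts < length
    return starts[keep], ends[keep]


def windowed_pi(
    panel: PhasedPanel,
    subpopulation: str | None,
    window_bp: int,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Windowed per-bp nucleotide diversity for one subpopulation.

    Returns columns ``chrom, start, end, n_sites, pi`` where ``n_sites``
    counts segregating sites in the window and ``pi`` is Σ site-π over
    the full window span (per-bp, VCFtools ``--window-pi`` convention).
    """
    if window_bp <= 0 or (step_bp is not None and step_bp <= 0):
        raise ValueError("window_bp and step_bp must be positive")
    step_bp = step_bp or window_bp
    ac = panel.alt_counts(subpopulation)
    n = len(panel.hap_rows(subpopulation))
    if n < 2:
        raise ValueError("need at least two haplotypes for pi")
    pi_site = site_pi(np.full_like(ac, n) - ac, ac)
    seg = (ac > 0) & (ac < n)

    frames = []
    for chrom in panel.chromosomes():
        m = panel.chrom == chrom
        pos = panel.pos[m]
        pvals = pi_site[m]
        svals = seg[m]
        starts, ends = _window_grid(_chrom_length(panel, chrom), window_bp, step_bp)
        n_sites = np.empty(starts.size, dtype=np.int64)
        pis = np.empty(starts.size)
        for i, (s, e) in enumerate(zip(starts, ends)):
            in_w = (pos >= s) & (pos < e)
            n_sites[i] = int(np.sum(svals & in_w))
            pis[i] = float(np.sum(pvals[in_w])) / float(e - s)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends,
                 "n_sites": n_sites, "pi": pis}
            )
        )
    return pd.concat(frames, ignore_index=True)


def wc_site_components(panel: PhasedPanel, pop_a: str, pop_b: str):
    """Weir & Cockerham (1984) per-site variance components (a, b, c).

    Computed from diploid genotypes of the two subpopulations: ``a`` is
    the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals (heterozygosity).  Returns
    ``(a, b, c)`` arrays over all panel sites.
    """
    comps = []
    r = 2
    ns, ps, hs = [], [], []
    for sp in (pop_a, pop_b):
        idx = panel.sample_indices(sp)
        if idx.size < 1:
            raise ValueError(f"empty subpopulation {sp}")
        h1 = panel.haplotypes[2 * idx]
        h2 = panel.haplotypes[2 * idx + 1]
        geno = h1.astype(np.int16) + h2
        ns.append(float(idx.size))
        ps.append(geno.sum(axis=0) / (2.0 * idx.size))
        hs.append(np.mean(geno == 1, axis=0))
    n1, n2 = ns
    if n1 + n2 < 1 or min(n1, n2) < 1:
        raise ValueError("both subpopulations must be non-empty")
    p1, p2 = ps
    h1_, h2_ = hs
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1_ + n2 * h2_) / (r * nbar)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    return a, b, c


def weir_cockerham_fst(
    panel: PhasedPanel,
    pop_a: str,
    pop_b: str,
    window_bp: int,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Windowed weighted Fst = Σa / Σ(a+b+c) between two subpopulations.

    Sites whose total variance ``a+b+c`` is zero are skipped; windows
    with no usable site get ``fst = NaN``.  Negative estimates are
    reported as computed (not clamped).  Returns columns ``chrom, start,
    end, n_sites, fst``.
    """
    if len(panel.hap_rows(pop_a)) < 2 or len(panel.hap_rows(pop_b)) < 2:
        raise ValueError("both subpopulations need at least 2 haploid genomes")
    step_bp = step_bp or window_bp
    a, b, c = wc_site_components(panel, pop_a, pop_b)
    total = a + b + c
    usable = total != 0

    frames = []
    for chrom in panel.chromosomes():
        m = panel.chrom == chrom
        pos = panel.pos[m]
        av, tv, uv = a[m], total[m], usable[m]
        starts, ends = _window_grid(_chrom_length(panel, chrom), window_bp, step_bp)
        n_sites = np.empty(starts.size, dtype=np.int64)
        fst = np.empty(starts.size)
        for i, (s, e) in enumerate(zip(starts, ends)):
            in_w = (pos >= s) & (pos < e) & uv
            n_sites[i] = int(in_w.sum())
            fst[i] = (
                float(av[in_w].sum()) / float(tv[in_w].sum()) if n_sites[i] else np.nan
            )
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends,
                 "n_sites": n_sites, "fst": fst}
            )
        )
    return pd.concat(frames, ignore_index=True)


def pi_ratio_windows(
    wild_stats: pd.DataFrame, derived_stats: pd.DataFrame, min_sites: int = 2
) -> pd.DataFrame:
    """π ratio (numerator/denominator) on an aligned window grid.

    Windows with fewer than ``min_sites`` segregating sites in either
    population, or a zero denominator, are flagged ``insufficient`` and
    excluded from downstream quantile ranking.
    """
    for col in ("chrom", "start", "end"):
        if not np.array_equal(
            wild_stats[col].to_numpy(), derived_stats[col].to_numpy()
        ):
            raise ValueError("window grids are misaligned")
    out = wild_stats[["chrom", "start", "end"]].copy()
    out["n_sites_num"] = wild_stats["n_sites"].to_numpy()
    out["n_sites_den"] = derived_stats["n_sites"].to_numpy()
    num = wild_stats["pi"].to_numpy()
    den = derived_stats["pi"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pi_num"] = num
        out["pi_den"] = den
        out["pi_ratio"] = np.where(den > 0, num / den, np.nan)
    out["insufficient"] = (
        (out["n_sites_num"] < min_sites)
        | (out["n_sites_den"] < min_sites)
        | (den <= 0)
    )
    return out


def scan_windows(
    panel: PhasedPanel,
    wild: str,
    derived: str,
    window_bp: int = 50_000,
    step_bp: int | None = None,
    min_sites: int = 2,
) -> pd.DataFrame:
    """Full sweep-scan window table for one wild/derived contrast.

    Combines windowed π for both populations, the π ratio
    (wild/derived) and the weighted Fst into one table with columns
    ``chrom, start, end, n_sites_num, n_sites_den, pi_num, pi_den,
    pi_ratio, fst, insufficient``.
    """
    pw = windowed_pi(panel, wild, window_bp, step_bp)
    pdv = windowed_pi(panel, derived, window_bp, step_bp)
    out = pi_ratio_windows(pw, pdv, min_sites=min_sites)
    fst = weir_cockerham_fst(panel, wild, derived, window_bp, step_bp)
    out["fst"] = fst["fst"].to_numpy()
    out["insufficient"] |= ~np.isfinite(out["fst"])
    return out
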