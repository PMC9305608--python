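"""Phased multi-sample genotype panel.

The :class:`PhasedPanel` is the in-memory substrate for every population
statistic in this package: per-site nucleotide diversity, windowed
Weir–Cockerham Fst, and gene-level diplotype strings.  It holds ordered
biallelic SNPs and a dense 0/1 haplotype matrix with two rows per diploid
sample (rows ``2*i`` and ``2*i + 1`` are the two phased haplotypes of
sample ``i``).

Coordinates are stored 0-based; VCF I/O converts to and from the 1-based
convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhasedPanel", "read_panel_tsv", "write_panel_tsv"]


@dataclass
class PhasedPanel:
    """Ordered biallelic SNPs over phased diploid samples.

    Parameters
    ----------
    samples
        Sample identifiers, one per diploid individual.
    subpops
        Subpopulation label of each sample, aligned with ``samples``.
    chrom, pos, ref, alt
        Per-site chromosome name, 0-based position, reference and
        alternate allele (single nucleotides).
    haplotypes
        ``(2 * n_samples, n_sites)`` int8 matrix; 0 codes the reference
        allele and 1 the alternate.  No missing data.
    chrom_lengths
        Optional chromosome sizes in bp, used for window grids and VCF
        contig headers.
    """

    samples: list[str]
    subpops: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.subpops):
            raise ValueError("samples and subpops must be aligned")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.pos)):
            raise ValueError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        # positions strictly increasing within each chromosome
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if p.size and np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------ #
    # basic shape
    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_samples

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def subpop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subpops:
            seen.setdefault(s, None)
        return list(seen)

    # ------------------------------------------------------------------ #
    # indexing helpers
    # ------------------------------------------------------------------ #
    def sample_indices(self, subpop: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.subpops, dtype=object) == subpop)
        if idx.size == 0:
            raise KeyError(f"unknown subpopulation: {subpop!r}")
        return idx

    def hap_rows(self, subpop: str | None = None) -> np.ndarray:
        """Row indices into ``haplotypes`` for one subpopulation (or all)."""
        if subpop is None:
            return np.arange(self.n_haplotypes)
        s = self.sample_indices(subpop)
        return np.stack([2 * s, 2 * s + 1], axis=1).ravel()

    def subpop_haplotypes(self, subpop: str) -> np.ndarray:
        return self.haplotypes[self.hap_rows(subpop)]

    def site_mask(self, chrom: str, start: int | None = None, end: int | None = None) -> np.ndarray:
        """Boolean mask of sites on ``chrom`` within half-open [start, end)."""
        m = self.chrom == chrom
        if start is not None:
            m &= self.pos >= start
        if end is not None:
            m &= self.pos < end
        return m

    def alt_counts(self, subpop: str | None = None) -> np.ndarray:
        """Per-site alternate-allele counts over a subpopulation's haplotypes."""
        H = self.haplotypes if subpop is None else self.subpop_haplotypes(subpop)
        return H.sum(axis=0, dtype=np.int64)

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    def take_sites(self, mask: np.ndarray) -> "PhasedPanel":
        return PhasedPanel(
            samples=list(self.samples),
            subpops=list(self.subpops),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            haplotypes=self.haplotypes[:, mask],
            chrom_lengths=dict(self.chrom_lengths) if self.chrom_lengths else None,
        )

    def take_samples(self, indices: np.ndarray | list[int]) -> "PhasedPanel":
        indices = np.asarray(indices, dtype=np.int64)
        rows = np.stack([2 * indices, 2 * indices + 1], axis=1).ravel()
        return PhasedPanel(
            samples=[self.samples[i] for i in indices],
            subpops=[self.subpops[i] for i in indices],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            haplotypes=self.haplotypes[rows],
            chrom_lengths=dict(self.chrom_lengths) if self.chrom_lengths else None,
        )

    @staticmethod
    def concat_samples(panels: list["PhasedPanel"]) -> "PhasedPanel":
        """Stack panels that share an identical site list, sample-wise."""
        first = panels[0]
        for p in panels[1:]:
            if not (
                np.array_equal(p.chrom, first.chrom)
                and np.array_equal(p.pos, first.pos)
                and np.array_equal(p.ref, first.ref)
                and np.array_equal(p.alt, first.alt)
            ):
                raise ValueError("panels do not share a site list")
        return PhasedPanel(
            samples=[s for p in panels for s in p.samples],
            subpops=[s for p in panels for s in p.subpops],
            chrom=first.chrom,
            pos=first.pos,
            ref=first.ref,
            alt=first.alt,
            haplotypes=np.concatenate([p.haplotypes for p in panels], axis=0),
            chrom_lengths=dict(first.chrom_lengths) if first.chrom_lengths else None,
        )

    def equals(self, other: "PhasedPanel") -> bool:
        return (
            self.samples == other.samples
            and self.subpops == other.subpops
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.haplotypes, other.haplotypes)
        )


def write_panel_tsv(panel: PhasedPanel, path: str) -> None:
    """Write the sample -> subpopulation table (columns: sample_id, subpopulation)."""
    pd.DataFrame({"sample_id": panel.samples, "subpopulation": panel.subpops}).to_csv(
        path, sep="\t", index=False
    )


def read_panel_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "subpopulation"} - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} lacks columns: {sorted(missing)}")
    return df
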