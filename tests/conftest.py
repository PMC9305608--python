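"""Shared fixtures: hand-built diplotype panels and small random panels."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from domestiscan.annotations import GeneModel
from domestiscan.panel import PhasedPanel

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_diplotype_panel(chrom, positions, ref, alt, subpop_strings, chrom_length=None):
    """Panel from per-sample diplotype strings (2 letters per site).

    ``subpop_strings`` maps subpopulation -> list of strings like
    "CCAACCAA" (4 sites).  Letters must match the site's ref or alt.
    """
    positions = np.asarray(positions, dtype=np.int64)
    n_sites = positions.size
    samples, subpops, rows = [], [], []
    for sp, strings in subpop_strings.items():
        for k, s in enumerate(strings):
            assert len(s) == 2 * n_sites, f"{s}: expected {2 * n_sites} letters"
            h1 = np.empty(n_sites, dtype=np.int8)
            h2 = np.empty(n_sites, dtype=np.int8)
            for j in range(n_sites):
                for hap, letter in ((h1, s[2 * j]), (h2, s[2 * j + 1])):
                    if letter == ref[j]:
                        hap[j] = 0
                    elif letter == alt[j]:
                        hap[j] = 1
                    else:
                        raise ValueError(f"letter {letter} not in ({ref[j]},{alt[j]})")
            samples.append(f"{sp}_{k:03d}")
            subpops.append(sp)
            rows.extend([h1, h2])
    return PhasedPanel(
        samples=samples,
        subpops=subpops,
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=positions,
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        haplotypes=np.stack(rows, axis=0),
        chrom_lengths={chrom: chrom_length} if chrom_length else None,
    )


def random_panel(seed, n_samples=10, n_sites=100, chrom="1A", length=10_000, subpops=None):
    """Small random biallelic panel for oracle comparisons."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(length, size=n_sites, replace=False))
    H = (rng.random((2 * n_samples, n_sites)) < rng.uniform(0.05, 0.6, n_sites)).astype(
        np.int8
    )
    bases = np.array(list("ACGT"), dtype=object)
    r = rng.integers(0, 4, n_sites)
    a = (r + rng.integers(1, 4, n_sites)) % 4
    if subpops is None:
        subpops = ["pop1"] * n_samples
    return PhasedPanel(
        samples=[f"s{i:03d}" for i in range(n_samples)],
        subpops=list(subpops),
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=pos,
        ref=bases[r],
        alt=bases[a],
        haplotypes=H,
        chrom_lengths={chrom: length},
    )


# --------------------------------------------------------------------- #
# published worked-example reconstructions (synthetic stand-ins)
# --------------------------------------------------------------------- #
@pytest.fixture(scope="session")
def nac_gene_panel():
    """Synthetic reconstruction of the four-haplotype NAC-gene catalogue.

    urartu (n=29): 24 CCAACCAA, 3 TTGGCCAA, 1 TTGGTTAA, 1 TCGATCAA;
    wild emmer (n=28): 27 TTGGTTAA, 1 CCAACCAA.
    """
    strings = {
        "urartu": ["CCAACCAA"] * 24 + ["TTGGCCAA"] * 3 + ["TTGGTTAA"] + ["TCGATCAA"],
        "wild_emmer": ["TTGGTTAA"] * 27 + ["CCAACCAA"],
    }
    panel = build_diplotype_panel(
        chrom="1A",
        positions=[1000, 1100, 1200, 1300],
        ref=["C", "A", "C", "A"],
        alt=["T", "G", "T", "G"],
        subpop_strings=strings,
        chrom_length=10_000,
    )
    gene = GeneModel(
        gene_id="NACdemo", chrom="1A", start=900, end=1400, strand="+",
        exons=[(900, 1400)], family="NAC",
    )
    return panel, gene


@pytest.fixture(scope="session")
def bzip_gene_panel():
    """Synthetic reconstruction of the bZIP-gene major-haplotype shift.

    wild emmer (28): 21 CCGG, 6 CCAA, 1 CCAG; domesticated emmer (29):
    26 CCAA, 3 CCGG; durum (13): 12 CCAA, 1 CCGG; landrace (45): 44
    CCAA, 1 CCGG; cultivar (25): 25 CCAA.  The major haplotype CCGG is
    replaced by CCAA at the wild -> domesticated emmer step.
    """
    strings = {
        "wild_emmer": ["CCGG"] * 21 + ["CCAA"] * 6 + ["CCAG"],
        "domesticated_emmer": ["CCAA"] * 26 + ["CCGG"] * 3,
        "durum": ["CCAA"] * 12 + ["CCGG"],
        "landrace": ["CCAA"] * 44 + ["CCGG"],
        "cultivar": ["CCAA"] * 25,
    }
    panel = build_diplotype_panel(
        chrom="3B",
        positions=[5000, 5100],
        ref=["C", "G"],
        alt=["T", "A"],
        subpop_strings=strings,
        chrom_length=10_000,
    )
    gene = GeneModel(
        gene_id="bZIPdemo", chrom="3B", start=4900, end=5200, strand="+",
        exons=[(4900, 5200)], family="bZIP",
    )
    return panel, gene
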