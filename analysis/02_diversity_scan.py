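#!/usr/bin/env python
"""Windowed pi / pi-ratio / Fst scan over the domestication contrasts.

Re-derives the seed-17 fixture and scans the wild->domesticated
(domestication) and domesticated->improved (improvement) contrasts in
50-kb windows, writing one window table per contrast to results/.
"""

import os

from domestiscan import simulate as sim
from domestiscan.popgen import scan_windows

SEED = 17
OUT = os.path.join(os.path.dirname(__file__), "..", "results")

CONTRASTS = [
    ("wild_einkorn", "domesticated_einkorn", "domestication"),
    ("wild_emmer", "domesticated_emmer", "domestication"),
    ("domesticated_emmer", "durum", "improvement"),
    ("landrace", "cultivar", "improvement"),
]


def main():
    os.makedirs(OUT, exist_ok=True)
    panel = sim.simulate_panel(sim.anchor_sweep_on_gene(sim.nine_subpop_config(SEED)))
    for wild, derived, process in CONTRASTS:
        table = scan_windows(panel, wild, derived, window_bp=50_000)
        name = f"02_windows_{wild}_vs_{derived}.tsv"
        table.to_csv(os.path.join(OUT, name), sep="\t", index=False)
        usable = table[~table["insufficient"]]
        print(
            f"{wild} vs {derived} ({process}): {len(table)} windows, "
            f"{len(usable)} usable; median pi ratio "
            f"{usable['pi_ratio'].median():.2f}, mean Fst {usable['fst'].mean():.3f}"
        )


if __name__ == "__main__":
    main()
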