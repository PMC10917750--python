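"""Simulate the synthetic AGO2 iCLIP study.

Writes a 20-gene toy transcriptome with one designated sponge transcript
(gene01/tx01: 2 control + 34 treated crosslink sites, 10-fold treated
enrichment, planted miRNA seed matches in exon 3 and the 3'UTR) and a
truncation-tag table for 3 replicates x 2 conditions, into
results/simulated/.

Run from the repository root: python analysis/01_simulate_iclip.py [seed]
"""

import sys
from pathlib import Path

from spongeclip.cli import _simulate

OUT = Path("results/simulated")


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    paths = _simulate(OUT, seed)
    n_tags = sum(1 for _ in open(paths["tags"]))
    print(f"simulated transcriptome and tags (seed {seed}) -> {OUT}/")
    print(f"  {n_tags} truncation tags across 3 replicates x 2 conditions")
    print("  ground truth (planted sites and seed matches): "
          f"{OUT / 'ground_truth.tsv'}")


if __name__ == "__main__":
    main()
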