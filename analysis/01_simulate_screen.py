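#!/usr/bin/env python
"""Generate the synthetic screen dataset used by the downstream analyses.

Writes a dataset directory under scratch/screen_data: codon "orthologs" for
six genes evolved on the 27-primate tree (one under foreground selection on
the human branch, plus one read-through and one recent-duplicate decoy),
archaic and great-ape genotype tables, and a modern-human variant injected at
one codon of the selected gene with the derived allele at 25% — the
reference-allele-artifact situation the verification stage must catch.
"""

import argparse
import json
from pathlib import Path

from primsel.pipeline import generate_screen_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "screen_data")
    args = ap.parse_args()

    # the demo uses a deliberately strong selective episode (omega2 = 10 on
    # ~20% of sites, 600 codons) so a single-replicate walkthrough is
    # informative; calibration at the standard effect sizes lives in
    # analysis/04_calibration.py and the test suite
    data = generate_screen_dataset(
        args.out,
        n_genes=6,
        n_selected=1,
        n_codons=600,
        omega2=10.0,
        p0_selected=0.5,
        p1_selected=0.3,
        seed=args.seed,
        n_read_through=1,
        n_human_dup=1,
        minor_allele_codon=50,
    )
    truth = json.loads((data / "truth.json").read_text())
    selected = [g for g, t in truth.items() if t["selected"]]
    print(f"dataset written to {data}")
    print(f"genes: {len(truth)} (+2 flagged decoys); under selection: {selected}")
    print(f"selected-gene class-2 sites: {truth[selected[0]]['class2_sites']}")


if __name__ == "__main__":
    main()
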