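#!/usr/bin/env python
"""Generate the synthetic study cohort and write its truth tables.

Writes the pooled per-feature truth table for all 60 genomes and one example
genome as FASTA + GFF3, so the planted structure can be inspected directly.
"""

from pathlib import Path

import pandas as pd

import linchrom as lc
from cohort import study_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    cohort = study_cohort()
    chrom, feats, truth = cohort[0]
    lc.write_genome(chrom, feats, truth, OUT / "example_genome")

    pooled = pd.concat([t for _, _, t in cohort], ignore_index=True)
    pooled.to_csv(OUT / "cohort_truth.tsv", sep="\t", index=False, na_rep=".")

    planted_tirs = pooled[pooled.kind == "tir"]
    print(f"wrote {len(cohort)} genomes' truth to results/cohort_truth.tsv")
    print(f"planted TIRs: median {planted_tirs.length.median():.0f} bp, "
          f"range {planted_tirs.length.min()}-{planted_tirs.length.max()} bp")
    print("example genome in results/example_genome.{fasta,gff3,truth.tsv}")


if __name__ == "__main__":
    main()
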