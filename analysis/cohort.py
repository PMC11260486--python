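"""The deterministic synthetic study cohort shared by the analysis scripts.

Sixty 2 Mb linear chromosomes: centre-jittered dnaA on a random strand, 20
central core genes (2 with a distal duplicate copy), one distal protocluster
from each of PKS / NRPS / terpene / RiPP, and a planted terminal inverted
repeat whose length spans 1-30 kb log-uniformly across the cohort.
"""

from dataclasses import replace

import numpy as np
import pandas as pd

import linchrom as lc

SEED = 20_240_101
N_GENOMES = 60

CONFIG = lc.SynthConfig(
    L=2_000_000, n_core=20, n_dup=2, n_bgc=4,
    bgc_categories=["PKS", "NRPS", "terpene", "RiPP"],
)


def study_cohort():
    """Returns a list of (chromosome, features, truth-table) triples."""
    rng = np.random.default_rng(SEED)
    tir_lengths = np.round(10 ** rng.uniform(3.0, 4.5, size=N_GENOMES)).astype(int)
    child = np.random.SeedSequence(SEED).generate_state(N_GENOMES)
    out = []
    for i, (tir_len, s) in enumerate(zip(tir_lengths, child)):
        chrom, feats, truth = lc.generate_chromosome(
            replace(CONFIG, tir_len=int(tir_len), seed=int(s))
        )
        chrom = lc.LinearChromosome(f"genome_{i:04d}", chrom.seq, "linear")
        feats = [replace(f, replicon_id=chrom.id) for f in feats]
        truth = truth.assign(genome_id=chrom.id)
        out.append((chrom, feats, truth))
    return out


def oriented_centered(cohort):
    """Orient every genome by dnaA and return pooled centred features + flip flags."""
    centered, flips = [], []
    for chrom, feats, _ in cohort:
        oriented, ofeats, flipped = lc.orient_by_dnaA(chrom, feats)
        centered.extend(lc.center_features(ofeats, oriented.length))
        flips.append({"genome_id": chrom.id, "flipped": flipped})
    return centered, pd.DataFrame(flips)
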