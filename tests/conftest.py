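"""Shared fixtures: small synthetic genomes and an antiSMASH-style GenBank file."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

import linchrom as lc


def make_antismash_genbank(path, protoclusters, length=60_000, record_id="contig1"):
    """Write a minimal antiSMASH-dialect GenBank file.

    ``protoclusters`` is a list of (start, end, product, category) tuples
    (0-based half-open); overlapping protoclusters are wrapped in one region
    feature, mirroring how hybrid regions appear in real output.
    """
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    record = SeqRecord(Seq(seq), id=record_id, annotations={"molecule_type": "DNA"})
    if protoclusters:
        rstart = min(p[0] for p in protoclusters)
        rend = max(p[1] for p in protoclusters)
        record.features.append(
            SeqFeature(
                SimpleLocation(rstart, rend), type="region",
                qualifiers={"region_number": ["1"], "product": [p[2] for p in protoclusters]},
            )
        )
    for i, (start, end, product, category) in enumerate(protoclusters, start=1):
        record.features.append(
            SeqFeature(
                SimpleLocation(start, end), type="protocluster",
                qualifiers={
                    "protocluster_number": [str(i)], "product": [product],
                    "category": [category], "tool": ["antismash"],
                },
            )
        )
    SeqIO.write([record], str(path), "genbank")
    return path


@pytest.fixture
def hybrid_genbank(tmp_path):
    """One region holding overlapping T1PKS and NRPS protoclusters (a hybrid)."""
    return make_antismash_genbank(
        tmp_path / "hybrid.gbk",
        [(5_000, 30_000, "T1PKS", "PKS"), (20_000, 45_000, "NRPS", "NRPS")],
    )


@pytest.fixture
def disjoint_genbank(tmp_path):
    return make_antismash_genbank(
        tmp_path / "disjoint.gbk",
        [(1_000, 9_000, "terpene", "terpene"),
         (15_000, 24_000, "lassopeptide", "RiPP"),
         (30_000, 55_000, "T3PKS", "PKS")],
    )


@pytest.fixture(scope="session")
def tir_chromosome():
    """A 200 kb chromosome with an exact planted 10 kb TIR."""
    cfg = lc.SynthConfig(L=200_000, tir_len=10_000, n_core=0, seed=42)
    chrom, _, truth = lc.generate_chromosome(cfg)
    return chrom, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Ten oriented genomes with core genes, duplicates and protoclusters."""
    cfg = lc.SynthConfig(L=1_000_000, n_core=20, n_dup=3, n_bgc=3, bgc_categories=["PKS", "NRPS", "other"])
    return lc.generate_cohort(10, cfg, seed=77)


@pytest.fixture(scope="session")
def species_set():
    """Three planted species clusters of four genomes each, 0.5% divergence."""
    return lc.generate_species_set(3, 4, within_rate=0.005, L=50_000, seed=11)
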