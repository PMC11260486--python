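"""Reading and writing of genome and annotation files.

Formats handled: FASTA (assemblies), GFF3 (gene features), GenBank in the
antiSMASH output dialect (protocluster features), and BUSCO-style full-table
TSV (single-copy ortholog hits).  All coordinates are converted to 0-based
half-open intervals at the parsing boundary; GFF3 and GenBank are 1-based
inclusive on disk, and the writers convert back, so write(parse(x)) == x for
well-formed input.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

Topology = Literal["linear", "circular"]
FeatureType = Literal["gene", "core_gene", "protocluster", "domain_hit"]

#: the six protocluster categories used for placement statistics
PROTOCLUSTER_CATEGORIES = ("NRPS", "PKS", "terpene", "RiPP", "oligosaccharide", "other")

# antiSMASH product -> category fallback, used when a protocluster feature
# carries no explicit ``category`` qualifier (older antiSMASH versions).
_PRODUCT_TO_CATEGORY = {
    "T1PKS": "PKS", "T2PKS": "PKS", "T3PKS": "PKS", "transAT-PKS": "PKS",
    "transAT-PKS-like": "PKS", "PKS-like": "PKS", "hglE-KS": "PKS",
    "arylpolyene": "PKS",
    "NRPS": "NRPS", "NRPS-like": "NRPS", "NRP-metallophore": "NRPS",
    "thioamide-NRP": "NRPS", "NAPAA": "NRPS",
    "terpene": "terpene",
    "RiPP-like": "RiPP", "lanthipeptide-class-i": "RiPP",
    "lanthipeptide-class-ii": "RiPP", "lanthipeptide-class-iii": "RiPP",
    "lanthipeptide-class-iv": "RiPP", "lanthipeptide-class-v": "RiPP",
    "lassopeptide": "RiPP", "thiopeptide": "RiPP", "linaridin": "RiPP",
    "LAP": "RiPP", "ranthipeptide": "RiPP", "cyanobactin": "RiPP",
    "oligosaccharide": "oligosaccharide", "saccharide": "oligosaccharide",
    "amglyccycl": "oligosaccharide",
}

# antiSMASH v7 category qualifier values -> our labels
_CATEGORY_ALIASES = {
    "pks": "PKS", "nrps": "NRPS", "terpene": "terpene", "ripp": "RiPP",
    "saccharide": "oligosaccharide", "oligosaccharide": "oligosaccharide",
    "other": "other",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LinearChromosome:
    """A named nucleotide sequence with a declared replicon topology."""

    id: str
    seq: str
    topology: Topology = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("chromosome id must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "LinearChromosome":
        return LinearChromosome(self.id, reverse_complement(self.seq), self.topology)


@dataclass
class FeatureRecord:
    """A located, stranded, typed annotation on a replicon.

    Coordinates are 0-based half-open.  ``category`` is set only for
    protoclusters (one of :data:`PROTOCLUSTER_CATEGORIES`).
    """

    replicon_id: str
    feature_type: FeatureType
    model_id: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"
    category: str = ""
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.model_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if (self.feature_type == "protocluster") != bool(self.category):
            raise ValueError("category must be set iff feature_type is protocluster")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class AssemblyRecord:
    """A genome assembly: one or more contigs plus an NCBI-style assembly level."""

    genome_id: str
    contigs: list[LinearChromosome]
    level: str  # "complete" / "chromosome" / "contig" / "scaffold"

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("assembly must have at least one contig")
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("contig ids must be unique within an assembly")


def parse_fasta(path: str | Path, topology: Topology = "linear") -> list[LinearChromosome]:
    """Read a FASTA file into :class:`LinearChromosome` records.

    Sequences are uppercased; characters outside A/C/G/T/N are replaced by N
    with a logged warning.  Empty files and duplicate ids are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[LinearChromosome] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = re.sub("[^ACGTN]", "N", seq)
        n_bad = sum(a != b for a, b in zip(seq, cleaned))
        if n_bad:
            logger.warning("%s: %d non-ACGTN characters replaced by N", rec.id, n_bad)
        out.append(LinearChromosome(rec.id, cleaned, topology))
    return out


def write_fasta(chromosomes: Iterable[LinearChromosome], path: str | Path, width: int = 80) -> None:
    """Write chromosomes as uppercase FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for chrom in chromosomes:
            fh.write(f">{chrom.id}\n")
            for i in range(0, chrom.length, width):
                fh.write(chrom.seq[i : i + width] + "\n")


def _parse_gff3_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            key, value = part.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def _parse_gff3(path: str | Path) -> list[FeatureRecord]:
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _source, ftype, start1, end1, _score, strand, _phase, attr_text = cols
            start1, end1 = int(start1), int(end1)
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start {start1} > end {end1}")
            attrs = _parse_gff3_attributes(attr_text)
            model_id = attrs.get("ID") or attrs.get("Name") or f"{ftype}_{lineno}"
            if ftype == "protocluster":
                feature_type: FeatureType = "protocluster"
                category = attrs.get("category", "other")
            elif ftype == "core_gene" or attrs.get("busco_model"):
                feature_type, category = "core_gene", ""
            else:
                feature_type, category = "gene", ""
            qualifiers = {k: v for k, v in attrs.items() if k not in ("ID", "Name", "category")}
            features.append(
                FeatureRecord(
                    replicon_id=seqid, feature_type=feature_type, model_id=model_id,
                    start=start1 - 1, end=end1, strand="-" if strand == "-" else "+",
                    category=category, qualifiers=qualifiers,
                )
            )
    return features


#: column layout of a BUSCO full table (header lines start with '#')
_BUSCO_COLUMNS = ["busco_id", "status", "sequence", "start", "end", "strand", "score", "length"]


def _parse_busco_tsv(path: str | Path) -> list[FeatureRecord]:
    table = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_BUSCO_COLUMNS,
        dtype={"busco_id": str, "status": str}, na_values=["."],
    )
    features: list[FeatureRecord] = []
    for row in table.itertuples(index=False):
        if row.status == "Missing":
            continue
        start1, end1 = int(row.start), int(row.end)
        if start1 > end1:
            raise ValueError(f"BUSCO row {row.busco_id}: start {start1} > end {end1}")
        qualifiers = {"status": row.status}
        if row.status == "Fragmented":
            # kept but flagged: some lineage datasets systematically fragment
            # one model (e.g. the cold-shock protein), dropping it would bias
            # per-model placement statistics
            qualifiers["fragmented"] = "true"
        features.append(
            FeatureRecord(
                replicon_id=str(row.sequence), feature_type="core_gene",
                model_id=str(row.busco_id), start=start1 - 1, end=end1,
                strand="-" if row.strand == "-" else "+", qualifiers=qualifiers,
            )
        )
    return features


def parse_feature_table(path: str | Path, format: str) -> list[FeatureRecord]:
    """Parse GFF3 (``format='gff3'``) or BUSCO full-table TSV (``'busco_tsv'``).

    1-based inclusive coordinates become 0-based half-open.  BUSCO rows with
    status ``Missing`` are skipped; all ``Duplicated`` rows are retained;
    ``Fragmented`` rows are retained and flagged in ``qualifiers``.
    """
    if format == "gff3":
        return _parse_gff3(path)
    if format == "busco_tsv":
        return _parse_busco_tsv(path)
    raise ValueError(f"unknown feature table format {format!r}")


def write_gff3(features: Iterable[FeatureRecord], path: str | Path, source: str = "linchrom") -> None:
    """Write features as GFF3 (coordinates converted back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.model_id}"]
            if f.category:
                attrs.append(f"category={f.category}")
            for key, value in f.qualifiers.items():
                attrs.append(f"{key}={value}")
            fh.write(
                "\t".join(
                    [
                        f.replicon_id, source, f.feature_type,
                        str(f.start + 1), str(f.end), ".", f.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def parse_antismash_protoclusters(path: str | Path) -> list[FeatureRecord]:
    """Extract protocluster features from an antiSMASH-dialect GenBank file.

    One record per *protocluster* feature, never per region: a hybrid region
    containing, say, a T1PKS and an NRPS protocluster yields two records, so
    hybrid cluster types are represented in all their individual
    protoclusters.  Region features are only used to annotate hybrid
    membership in ``qualifiers``.
    """
    features: list[FeatureRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        regions = [
            (int(f.location.start), int(f.location.end), f.qualifiers.get("region_number", ["?"])[0])
            for f in rec.features
            if f.type == "region"
        ]
        n_proto = 1
        for feat in rec.features:
            if feat.type != "protocluster":
                continue
            if "product" not in feat.qualifiers:
                raise ValueError(
                    f"protocluster feature at {feat.location} in {rec.id} lacks a product qualifier"
                )
            product = feat.qualifiers["product"][0]
            if "category" in feat.qualifiers:
                raw = feat.qualifiers["category"][0]
                category = _CATEGORY_ALIASES.get(raw.lower(), "other")
            else:
                category = _PRODUCT_TO_CATEGORY.get(product, "other")
            start, end = int(feat.location.start), int(feat.location.end)
            qualifiers = {"product": product}
            for rstart, rend, rnum in regions:
                if start < rend and rstart < end:
                    qualifiers["region"] = str(rnum)
                    break
            features.append(
                FeatureRecord(
                    replicon_id=rec.id, feature_type="protocluster",
                    model_id=f"protocluster_{rec.id}_{n_proto}",
                    start=start, end=end, category=category, qualifiers=qualifiers,
                )
            )
            n_proto += 1
    return features


def assembly_quality_class(assembly: AssemblyRecord) -> str:
    """HQ/MQ/LQ assembly classing.

    Complete or chromosome-level assemblies are high quality (HQ); contig or
    scaffold level assemblies with at most 100 contigs are medium quality
    (MQ); everything else is low quality (LQ).
    """
    if assembly.level in ("complete", "chromosome"):
        return "HQ"
    if len(assembly.contigs) <= 100:
        return "MQ"
    return "LQ"


def gc_content(chromosome: LinearChromosome) -> float:
    """GC fraction over unambiguous bases; N is excluded from the denominator."""
    seq = chromosome.seq
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError(f"{chromosome.id}: no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
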