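"""Chromosome orientation and centre-relative coordinates.

Linear actinomycete chromosomes have no intrinsic left/right: assemblers emit
either strand.  For cross-genome positional statistics every chromosome is
first oriented so the replication-initiator gene *dnaA* lies on the forward
strand, and every feature is then described by the signed distance of its
midpoint from the mathematical chromosome centre L/2.  Positions are also
expressed as ``arm_pos`` = offset / (L/2) in [-1, 1], which makes chromosomes
of different lengths commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from .io import FeatureRecord, LinearChromosome


@dataclass
class CenteredFeature:
    """A feature with centre-relative coordinates on a dnaA-oriented chromosome."""

    feature: FeatureRecord
    midpoint: float
    offset: float  # midpoint - L/2, negative upstream of the centre
    arm_pos: float  # offset / (L/2), in [-1, 1]
    copy_rank: Literal["primary", "secondary", "unassigned"] = "unassigned"


def _flip_feature(feature: FeatureRecord, L: int) -> FeatureRecord:
    return replace(
        feature,
        start=L - feature.end,
        end=L - feature.start,
        strand="+" if feature.strand == "-" else "-",
    )


def orient_by_dnaA(
    chromosome: LinearChromosome, features: Sequence[FeatureRecord]
) -> tuple[LinearChromosome, list[FeatureRecord], bool]:
    """Orient a chromosome so its dnaA gene is on the forward strand.

    If dnaA lies on the minus strand the sequence is reverse-complemented and
    every feature is mapped to (L-end, L-start) with its strand inverted.
    Applying the operation twice restores the input (involution).

    Raises if no dnaA annotation exists or if multiple dnaA copies disagree
    on strand (no orientation rule is defined for that case).
    """
    dnaa = [f for f in features if f.model_id == "dnaA"]
    if not dnaa:
        raise ValueError(f"{chromosome.id}: no dnaA feature, cannot orient")
    strands = {f.strand for f in dnaa}
    if len(strands) > 1:
        raise ValueError(f"{chromosome.id}: dnaA copies on opposite strands")
    if strands == {"+"}:
        return chromosome, list(features), False
    L = chromosome.length
    flipped = [_flip_feature(f, L) for f in features]
    return chromosome.reverse_complement(), flipped, True


def center_offset(feature: FeatureRecord, L: int) -> CenteredFeature:
    """Centre-relative coordinates of a feature midpoint on a length-L chromosome."""
    if L <= 0:
        raise ValueError("chromosome length must be positive")
    midpoint = (feature.start + feature.end) / 2.0
    offset = midpoint - L / 2.0
    return CenteredFeature(feature=feature, midpoint=midpoint, offset=offset, arm_pos=offset / (L / 2.0))


def center_features(features: Iterable[FeatureRecord], L: int) -> list[CenteredFeature]:
    return [center_offset(f, L) for f in features]


def assign_primary_copies(centered: Sequence[CenteredFeature]) -> list[CenteredFeature]:
    """Mark, per model, the most central copy as primary and the rest secondary.

    Exactly one primary per model: the copy with minimal ``|offset|``; ties
    are broken by the smaller start coordinate.  This forces every secondary
    copy to be at least as distal as its primary.  Grouping is per replicon,
    so pooled multi-genome inputs are ranked within each genome.
    """
    by_model: dict[tuple[str, str], list[CenteredFeature]] = {}
    for cf in centered:
        by_model.setdefault((cf.feature.replicon_id, cf.feature.model_id), []).append(cf)
    out: list[CenteredFeature] = []
    for copies in by_model.values():
        primary = min(copies, key=lambda cf: (abs(cf.offset), cf.feature.start))
        for cf in copies:
            out.append(replace(cf, copy_rank="primary" if cf is primary else "secondary"))
    return out


def dnaA_center_offset(centered: Sequence[CenteredFeature]) -> float:
    """Signed centre offset of the dnaA midpoint (most central copy if several)."""
    dnaa = [cf for cf in centered if cf.feature.model_id == "dnaA"]
    if not dnaa:
        raise ValueError("no dnaA among centered features")
    return min(dnaa, key=lambda cf: abs(cf.offset)).offset
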