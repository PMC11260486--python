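"""Plasmid classification of extrachromosomal replicons.

An extrachromosomal element is called a plasmid if it carries at least one
domain from a curated list of plasmid-specific PFAM domains; elements with no
listed domain stay 'extrachromosomal'.  The rule is presence-only: no e-value
threshold is applied to the domain hits, and the method's accuracy has not
been experimentally confirmed.  The domain list is an input — the repository
ships only a small synthetic placeholder for fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import file_sha256

#: bundled synthetic placeholder list (see data/plasmid_domains_synthetic.txt)
SYNTHETIC_DOMAIN_LIST = "plasmid_domains_synthetic.txt"


@dataclass(frozen=True)
class DomainList:
    """A set of plasmid-marker domain accessions with file provenance."""

    accessions: frozenset[str]
    source: str
    sha256: str

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("domain list is empty")


def load_domain_list(path: str | Path) -> DomainList:
    """Read one accession per line (blank lines and '#' comments ignored)."""
    lines = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if len(lines) != len(set(lines)):
        raise ValueError(f"duplicate accessions in {path}")
    return DomainList(accessions=frozenset(lines), source=str(path), sha256=file_sha256(path))


def load_synthetic_domain_list() -> DomainList:
    """The bundled synthetic placeholder marker list (fixtures and examples)."""
    with resources.as_file(resources.files("linchrom.data") / SYNTHETIC_DOMAIN_LIST) as p:
        return load_domain_list(p)


def classify_replicon(
    hit_accessions: Iterable[str],
    domains: DomainList,
    *,
    is_chromosome: bool = False,
) -> str:
    """'plasmid' if any hit accession is in the marker list, else 'extrachromosomal'.

    The caller must flag primary chromosomes; classifying one is an error.
    """
    if is_chromosome:
        raise ValueError("replicon is flagged as a chromosome; classification applies to extrachromosomal elements")
    return "plasmid" if set(hit_accessions) & domains.accessions else "extrachromosomal"


def classify_hit_table(hits: pd.DataFrame, domains: DomainList, replicon_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Classify every replicon in a (replicon_id, domain_accession, ...) hit table.

    ``replicon_ids`` may supply replicons with zero hits so they appear in the
    output as 'extrachromosomal'.
    """
    ids = set(hits["replicon_id"]) | set(replicon_ids if replicon_ids is not None else [])
    grouped = hits.groupby("replicon_id")["domain_accession"].apply(set).to_dict()
    rows = [
        {"replicon_id": rid, "classification": classify_replicon(grouped.get(rid, set()), domains)}
        for rid in sorted(ids)
    ]
    return pd.DataFrame(rows)


def classification_summary(classifications: Iterable[str]) -> dict:
    """Plasmid fraction and per-class counts."""
    values = list(classifications)
    if not values:
        raise ValueError("no classifications")
    counts = pd.Series(values).value_counts().to_dict()
    return {
        "n": len(values),
        "counts": counts,
        "plasmid_fraction": counts.get("plasmid", 0) / len(values),
    }
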