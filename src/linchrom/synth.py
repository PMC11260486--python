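"""Synthetic linear chromosomes, annotations and genome sets with known truth.

The generator emulates the coordinate structure the downstream analyses
assume, at test scale rather than real genome scale:

* i.i.d. random sequence at a target GC (default 0.72, the middle of the
  65-74% range typical for actinomycetes); no repeat structure beyond the
  planted TIR, because the analyses only need coordinate structure and k-mer
  divergence;
* an optional terminal inverted repeat: the last ``tir_len`` bases are the
  reverse complement of the first ``tir_len``.  The three bases immediately
  inside each repeat copy are resampled to break the repeat there, so the
  planted length is exactly the maximal TIR of the sequence (otherwise a
  chance boundary match would silently lengthen the true repeat);
* a dnaA gene jittered around the chromosome centre on a uniformly random
  strand (real cohorts flip roughly half the assemblies);
* core genes placed by per-model Gaussian positional models on the arm
  coordinate (defaults spread over the central half of the chromosome, the
  region where near-universal single-copy genes concentrate), with optional
  distal duplicate copies;
* BGC protoclusters placed by per-category models, distal mirrored Gaussians
  by default except for the deliberately unstructured 'other' category;
* species sets: per-cluster base genomes diverged by independent per-site
  substitution, so the Mash distance-substitution rate relation stays
  monotone.

Every generated feature is recorded in a machine-readable truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import FeatureRecord, LinearChromosome, write_fasta, write_gff3

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G on 2-bit codes


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a feature without overlap."""


#: default per-category protocluster positional models:
#: category -> (|mean arm_pos|, sigma, mirrored across the two arms)
DEFAULT_BGC_MODEL: dict[str, tuple[float, float, bool]] = {
    "PKS": (0.80, 0.07, True),
    "NRPS": (0.80, 0.07, True),
    "terpene": (0.80, 0.07, True),
    "RiPP": (0.80, 0.07, True),
    "oligosaccharide": (0.80, 0.07, True),
    "other": (0.0, 0.35, False),
}

#: positional model for planted duplicate core-gene copies (distal arms)
DUPLICATE_MODEL: tuple[float, float] = (0.80, 0.07)


@dataclass
class SynthConfig:
    """Parameters of one synthetic chromosome.

    ``core_model`` holds one (mu, sigma) pair per core gene in arm-fraction
    units (mu in [-1, 1]); if omitted, ``n_core`` models are spread evenly
    over [-0.5, 0.5] with sigma 0.08.  ``bgc_categories`` lists the category
    of each of the ``n_bgc`` protoclusters (defaults to cycling through the
    six categories); ``bgc_model`` maps categories to (|mu|, sigma, mirrored).
    """

    L: int = 200_000
    gc: float = 0.72
    tir_len: int = 0
    n_core: int = 20
    core_model: list[tuple[float, float]] | None = None
    n_dup: int = 0
    n_bgc: int = 0
    bgc_categories: list[str] | None = None
    bgc_model: dict[str, tuple[float, float, bool]] = field(
        default_factory=lambda: dict(DEFAULT_BGC_MODEL)
    )
    gene_len: tuple[int, int] = (1_000, 3_000)
    bgc_len: tuple[int, int] = (20_000, 100_000)
    dnaa_sigma: float = 0.05
    seed: int = 0
    max_tries: int = 5_000

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if not 0 <= self.tir_len <= self.L // 2:
            raise ValueError("tir_len must be in [0, L/2]")

    def resolved_core_model(self) -> list[tuple[float, float]]:
        if self.core_model is not None:
            return list(self.core_model)
        if self.n_core == 0:
            return []
        mus = np.linspace(-0.5, 0.5, self.n_core)
        return [(float(mu), 0.08) for mu in mus]

    def resolved_bgc_categories(self) -> list[str]:
        if self.bgc_categories is not None:
            return list(self.bgc_categories)
        cats = list(self.bgc_model)
        return [cats[i % len(cats)] for i in range(self.n_bgc)]


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _random_codes(rng: np.random.Generator, L: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=L, p=p).astype(np.uint8)


def _mutate_codes(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size).astype(np.uint8)) % 4
    return out


def _plant_tir(rng: np.random.Generator, codes: np.ndarray, tir_len: int) -> None:
    """Overwrite the sequence end with the reverse complement of its start.

    Also breaks the repeat at the three positions just inside each boundary,
    guaranteeing the maximal TIR equals ``tir_len`` exactly.
    """
    L, t = codes.size, tir_len
    if t == 0:
        return
    codes[L - t :] = _COMP_CODE[codes[:t]][::-1]
    for off in range(3):
        left, right = t + off, L - 1 - t - off
        if left >= right:  # no interior left to break (palindrome-like)
            break
        forbidden = _COMP_CODE[codes[right]]
        if codes[left] == forbidden:
            options = np.setdiff1d(np.arange(4, dtype=np.uint8), [forbidden])
            codes[left] = rng.choice(options)


def _place_interval(
    rng: np.random.Generator,
    L: int,
    placed: list[tuple[int, int]],
    mid_sampler,
    len_range: tuple[int, int],
    max_tries: int,
) -> tuple[int, int]:
    """Rejection-sample a non-overlapping interval with midpoint from ``mid_sampler``."""
    for _ in range(max_tries):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        mid = float(mid_sampler())
        start = int(round(mid - length / 2))
        end = start + length
        if start < 0 or end > L:
            continue
        if any(start < e and s < end for s, e in placed):
            continue
        placed.append((start, end))
        return start, end
    raise PlacementError(f"could not place a feature of {len_range} bp after {max_tries} tries")


def generate_chromosome(
    config: SynthConfig,
) -> tuple[LinearChromosome, list[FeatureRecord], pd.DataFrame]:
    """One synthetic linear chromosome with features and a truth table.

    The same seed always yields byte-identical output.  Features (dnaA, core
    genes, duplicates, protoclusters) are mutually non-overlapping by
    rejection sampling; a :class:`PlacementError` is raised if a feature
    cannot be placed within ``config.max_tries`` attempts.
    """
    rng = np.random.default_rng(config.seed)
    L, arm = config.L, config.L / 2.0
    codes = _random_codes(rng, L, config.gc)
    _plant_tir(rng, codes, config.tir_len)

    chrom_id = f"synth_{config.seed}"
    placed: list[tuple[int, int]] = []
    features: list[FeatureRecord] = []
    truth_rows: list[dict] = []

    def record(kind: str, label: str, start: int, end: int, strand: str, category: str = "") -> None:
        ftype = {"dnaA": "gene", "core": "core_gene", "duplicate": "core_gene", "protocluster": "protocluster"}[kind]
        features.append(
            FeatureRecord(
                replicon_id=chrom_id, feature_type=ftype, model_id=label,
                start=start, end=end, strand=strand, category=category,
            )
        )
        mid = (start + end) / 2.0
        truth_rows.append(
            {
                "feature_id": f"{kind}_{len(truth_rows)}", "kind": kind, "label": label,
                "start": start, "end": end, "length": end - start, "strand": strand,
                "midpoint": mid, "offset": mid - arm, "arm_pos": (mid - arm) / arm,
            }
        )

    # dnaA: jittered around the centre, random strand
    start, end = _place_interval(
        rng, L, placed,
        lambda: arm + rng.normal(0.0, config.dnaa_sigma) * arm,
        config.gene_len, config.max_tries,
    )
    record("dnaA", "dnaA", start, end, "+" if rng.random() < 0.5 else "-")

    core_model = config.resolved_core_model()
    for i, (mu, sigma) in enumerate(core_model):
        start, end = _place_interval(
            rng, L, placed,
            lambda: arm + np.clip(rng.normal(mu, sigma), -0.98, 0.98) * arm,
            config.gene_len, config.max_tries,
        )
        record("core", f"core_{i:04d}", start, end, "+" if rng.random() < 0.5 else "-")

    if config.n_dup:
        if config.n_dup > len(core_model):
            raise ValueError("n_dup exceeds number of core models")
        dup_mu, dup_sigma = DUPLICATE_MODEL
        for i in sorted(rng.choice(len(core_model), size=config.n_dup, replace=False)):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            start, end = _place_interval(
                rng, L, placed,
                lambda: arm + np.clip(sign * rng.normal(dup_mu, dup_sigma), -0.98, 0.98) * arm,
                config.gene_len, config.max_tries,
            )
            record("duplicate", f"core_{i:04d}", start, end, "+" if rng.random() < 0.5 else "-")

    for i, category in enumerate(config.resolved_bgc_categories()):
        mu_abs, sigma, mirrored = config.bgc_model[category]
        def bgc_mid() -> float:
            sign = (1.0 if rng.random() < 0.5 else -1.0) if mirrored else 1.0
            return arm + np.clip(rng.normal(sign * mu_abs if mirrored else mu_abs, sigma), -0.99, 0.99) * arm
        start, end = _place_interval(rng, L, placed, bgc_mid, config.bgc_len, config.max_tries)
        record("protocluster", f"bgc_{i:04d}", start, end, "+", category=category)

    truth_rows.append(
        {
            "feature_id": "tir", "kind": "tir", "label": "tir",
            "start": 0, "end": config.tir_len, "length": config.tir_len, "strand": "+",
            "midpoint": np.nan, "offset": np.nan, "arm_pos": np.nan,
        }
    )
    chrom = LinearChromosome(chrom_id, _codes_to_str(codes), "linear")
    return chrom, features, pd.DataFrame(truth_rows)


def generate_cohort(
    n_genomes: int, config: SynthConfig, seed: int = 0
) -> list[tuple[LinearChromosome, list[FeatureRecord], pd.DataFrame]]:
    """A cohort of chromosomes sharing one config, with per-genome child seeds."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_genomes)
    out = []
    for i, child in enumerate(child_seeds):
        genome = generate_chromosome(replace(config, seed=int(child)))
        chrom, features, truth = genome
        chrom = LinearChromosome(f"genome_{i:04d}", chrom.seq, "linear")
        features = [replace(f, replicon_id=chrom.id) for f in features]
        truth = truth.assign(genome_id=chrom.id)
        out.append((chrom, features, truth))
    return out


def generate_species_set(
    n_clusters: int,
    genomes_per_cluster: int,
    within_rate: float,
    between_mode: str = "independent",
    L: int = 50_000,
    gc: float = 0.72,
    seed: int = 0,
    between_rate: float | None = None,
) -> tuple[list[LinearChromosome], pd.DataFrame]:
    """Genome clusters with controlled within/between sequence divergence.

    Per cluster one base genome is drawn; members are independent per-site
    substitution copies of it at ``within_rate``.  ``between_mode`` is either
    ``'independent'`` (cluster bases unrelated) or ``'diverged'`` (cluster
    bases derived from one ancestor at ``between_rate``, which must exceed
    ``within_rate`` or the clusters are inseparable by construction).
    """
    if not 0 <= within_rate < 0.2:
        raise ValueError("within_rate must be in [0, 0.2)")
    rng = np.random.default_rng(seed)
    genomes: list[LinearChromosome] = []
    rows: list[dict] = []
    if between_mode == "diverged":
        if between_rate is None or within_rate >= between_rate:
            raise ValueError("diverged mode needs between_rate > within_rate")
        ancestor = _random_codes(rng, L, gc)
    elif between_mode != "independent":
        raise ValueError(f"unknown between_mode {between_mode!r}")
    for c in range(n_clusters):
        if between_mode == "independent":
            base = _random_codes(rng, L, gc)
        else:
            base = _mutate_codes(rng, ancestor, between_rate)
        for g in range(genomes_per_cluster):
            member = _mutate_codes(rng, base, within_rate)
            gid = f"c{c}_g{g}"
            genomes.append(LinearChromosome(gid, _codes_to_str(member), "linear"))
            rows.append({"genome_id": gid, "cluster": c})
    return genomes, pd.DataFrame(rows)


def generate_replicon_panel(
    n_plasmid: int,
    n_other: int,
    marker_domains: list[str],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Domain-hit tables for a panel of extrachromosomal replicons.

    ``n_plasmid`` replicons carry 1-3 marker-domain hits (plus possible decoy
    hits); ``n_other`` replicons carry only decoy hits or none.  Returns
    (hits, truth): hits has columns replicon_id / domain_accession / evalue.
    """
    if not marker_domains:
        raise ValueError("marker_domains must be non-empty")
    rng = np.random.default_rng(seed)
    decoys = [f"DECOY{i:04d}" for i in range(50)]
    hit_rows: list[dict] = []
    truth_rows: list[dict] = []

    def add_hits(rid: str, accessions: list[str]) -> None:
        for acc in accessions:
            hit_rows.append(
                {"replicon_id": rid, "domain_accession": acc, "evalue": float(10.0 ** -rng.uniform(5, 50))}
            )

    for i in range(n_plasmid):
        rid = f"plasmid_{i:03d}"
        n_marker = int(rng.integers(1, min(3, len(marker_domains)) + 1))
        marked = list(rng.choice(marker_domains, size=n_marker, replace=False))
        extra = list(rng.choice(decoys, size=rng.integers(0, 3), replace=False))
        add_hits(rid, marked + extra)
        truth_rows.append({"replicon_id": rid, "is_plasmid": True})
    for i in range(n_other):
        rid = f"extra_{i:03d}"
        add_hits(rid, list(rng.choice(decoys, size=rng.integers(0, 3), replace=False)))
        truth_rows.append({"replicon_id": rid, "is_plasmid": False})
    return pd.DataFrame(hit_rows, columns=["replicon_id", "domain_accession", "evalue"]), pd.DataFrame(truth_rows)


def write_genome(chrom: LinearChromosome, features, truth: pd.DataFrame, prefix) -> None:
    """Write one synthetic genome as FASTA + GFF3 + truth TSV."""
    write_fasta([chrom], f"{prefix}.fasta")
    write_gff3(features, f"{prefix}.gff3")
    truth.to_csv(f"{prefix}.truth.tsv", sep="\t", index=False, na_rep=".")
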