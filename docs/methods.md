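# Methods

This note documents the models, conventions and numerical choices behind
`linchrom`, and what the synthetic-data experiments do and do not show.

## Coordinate conventions

All coordinates are 0-based half-open in memory; GFF3, GenBank and BUSCO
tables are 1-based inclusive on disk and are converted exactly once at the
parsing/writing boundary, so `write(parse(x)) == x` for well-formed input.
Every positional statistic uses the **midpoint** `(start + end)/2` of a
feature (real-valued, no rounding), so long and short features contribute
identically. The chromosome centre is the mathematical midpoint `L/2`;
`offset = midpoint − L/2` (negative upstream of the centre in dnaA
orientation) and `arm_pos = offset/(L/2) ∈ [−1, 1]`. Pooling across genomes
uses `arm_pos` because chromosome lengths differ; raw bp offsets remain
available per genome. When a genome carries several same-strand dnaA copies,
the most central one anchors the dnaA-offset statistic (consistent with the
primary-copy rule); copies on opposite strands are an error, as no
orientation rule exists for that case.

## TIR detection

A terminal inverted repeat is modelled as a local alignment between `S` and
`revcomp(S)` whose query start falls in the first `W` bp of the chromosome
and whose subject end falls in the last `W` bp. `W = 99` bp of slack absorbs
end-polishing artifacts in real assemblies.

Implementation: exact seeds of length `seed_k = 15` between the first `W`
positions of `S` and of `revcomp(S)` (one anchor per diagonal, smallest start
wins), greedy exact backward extension toward the ends, then forward
extension by a three-state (Gotoh) banded affine-gap DP with band half-width
200 and X-drop 50. Scores: match +1, mismatch −2, gap open 2, gap extend 1;
only the gap costs are externally pinned (they are the blastn settings used
for this kind of search), the reward/penalty pair is the conventional partner
of those costs and all are configurable. The banded extension is linear in
repeat length, which matters because real TIRs reach megabases; near-identical
repeat copies stay deep inside the band. Among qualifying alignments, the
longest query span wins; ties break by higher score, then smaller left start.
Reported `tir_len` is the query-side span, capped at `L/2` (a perfect
palindrome has chromosome fraction `2·tir_len/L = 1`). Detection requires at
least `min_report = 20` bp, well below the <100 bp repeats that occur in real
data.

**Boundary refinement.** A maximum-score endpoint can overshoot the true
repeat boundary when, in the unrelated sequence beyond it, an indel is
followed by a chance match run (probability of order 1% per chromosome at
these scores). The two candidate repeat copies are therefore re-aligned
(edit-distance path via edlib) and the tail is trimmed unless the columns
after the last indel contain at least `seed_k` matches; trailing mismatch and
indel columns are removed likewise. Substitution-only alignments are never
trimmed, so the refinement cannot bias lengths for point-mutation-diverged
repeats; repeats whose genuine tail contains an indel closely followed by the
boundary may be reported marginally short. Identity is the fraction of
matching columns of this re-alignment, a lower bound on the affine-path
identity.

Cohort summaries report detected count/fraction and, over detected TIRs,
median/quartiles (linear interpolation) and SD (denominator `n − 1`, missing
for a single observation) for both length and chromosome fraction.

## Placement densities

Densities are Gaussian KDEs with bandwidth `h = 0.5 · n^(−1/5) · σ`
(`σ` the sample SD, `n^(−1/5)` the Scott factor, 0.5 a deliberate
under-smoothing that preserves the multi-modal structure of per-model
placements). The grid is 512 points spanning the data range padded by `3h`.
Each curve integrates to one, so heights are not comparable between groups
with different `n`; positions are. Near chromosome ends the estimate leaks
mass outside `[−1, 1]` and tends toward zero even where data are dense; this
edge artifact is documented, not boundary-corrected. Degenerate inputs
(fewer than two observations, zero variance) raise errors rather than
producing misleading curves; categories with a single observation are counted
but not plotted.

Duplicate core-gene copies are ranked per `(replicon, model)` group: the copy
with minimal `|offset|` is primary (ties: smaller start coordinate, a
deterministic rule chosen because no external convention exists). This
*forces* secondaries to be at least as distal as their primary — the distal
placement of secondary copies is partly a consequence of the rule, and the
analysis scripts say so.

BGC-count regression is ordinary least squares of per-genome protocluster
count on genome length, per group, with Pearson r; groups with fewer than two
genomes or zero length variance are skipped with a warning.

## MinHash species delineation

Sketches use canonical k-mers (lexicographic minimum of k-mer and reverse
complement; `k = 21` must be odd so none is its own reverse complement),
2-bit-encoded (collision-free at `k ≤ 31`) and passed through a splitmix64
finalizer seeded by `hash_seed = 42`; the `s = 1000` smallest distinct values
form the sketch. k-mers containing N are skipped. The Jaccard estimate uses
the bottom-`s` of the *merged* hash set (the unbiased single-sketch-size
estimator), and `D = −ln(2j/(1+j))/k`, capped at 1 when `j = 0`. At
`s = 1000` the estimate of `D` is within 0.01 of the exact full-k-mer-set
Jaccard distance for the genome sizes used in the tests; the test suite
checks this against a brute-force oracle.

The similarity network is unweighted with an edge iff `D ≤ 0.05`; isolates
are retained. Community detection is standard two-phase Louvain
(networkx implementation) at resolution 1.0 with an exposed seed — community
structure can in principle vary between seeds, so the seed is part of the
recorded output. Modularity
`Q = (1/2m) Σᵢⱼ [Aᵢⱼ − kᵢkⱼ/2m] δ(cᵢ,cⱼ)` is reported with the partition;
an edgeless graph is assigned all-singleton communities with `Q = 0` by
convention. Tests verify the two-triangle optimum `Q = 1/2` against an
exhaustive search over all 203 partitions of six nodes, independent of the
library.

## Plasmid classification

Presence-only rule: a replicon flagged extrachromosomal by the caller is a
plasmid iff any of its domain hits is in the marker list; no e-value
threshold. The marker list is a runtime input with recorded checksum — the
bundled `plasmid_domains_synthetic.txt` is a synthetic placeholder vocabulary
for fixtures, not a curated biological list. The rule is monotone (adding
hits can only promote) and its accuracy on real replicons is not established
here.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *coordinate and divergence structure* the
analyses consume, at desk scale:

* i.i.d. sequence at target GC 0.72 (actinomycete genomes run 65–74% GC);
  no repeats, operons, coding structure or compositional skew beyond the TIR;
* planted TIRs by overwriting the final `t` bases with the reverse complement
  of the first `t`; the three bases just inside each boundary are resampled
  to mismatch their partner, so the planted length is the *maximal* TIR —
  without this, a chance boundary match lengthens the true repeat and exact
  recovery would be ill-defined;
* dnaA jittered `N(0, 0.05)` (arm units) around the centre on a uniformly
  random strand, so roughly half of all cohort genomes get flipped;
* core genes: one gene per model, `arm_pos ~ N(μₘ, σₘ)`, defaults spread over
  `[−0.5, 0.5]` with σ = 0.08 (the central-compartment scale); optional
  duplicate copies at mirrored `±0.8 ± 0.07`;
* protoclusters: per-category mirrored Gaussians, `|μ| = 0.8, σ = 0.07` for
  PKS/NRPS/terpene/RiPP/oligosaccharide and a broad central `N(0, 0.35)` for
  'other'; lengths 20–100 kb, genes 1–3 kb; all features mutually
  non-overlapping by rejection sampling (bounded tries, then an error);
* species sets: per-cluster base genomes (independent, or diverged from a
  common ancestor at a higher rate), members by substitution-only per-site
  mutation — no indels or rearrangements, keeping the Mash-distance ↔ rate
  relation monotone by construction.

Consequently, passing tests demonstrate correctness of the *algorithms* under
their stated models — exact TIR recovery, orientation involution, density
normalisation, sketch accuracy, cluster recovery — not performance on real
assemblies, where repeats, polishing artifacts, horizontal transfer and
taxonomic imbalance all intrude. Truth tables accompany every generated
object so any downstream measurement can be checked against what was planted.

## Problem sizes and determinism

Test and analysis cohorts use 2 Mb chromosomes (60–100 genomes), 200 kb
chromosomes for TIR sweeps (planted 100 bp – 50 kb) and 50–100 kb genomes for
sketching experiments — sizes chosen so the full pipeline remains a
minutes-scale desk computation while every statistic has enough observations
to be stable. All randomness flows from explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence`); equal seeds give byte-identical
genomes, sketches and community assignments. `scripts/acceptance.py` threads
its single `--seed` through every stage and writes each measured quantity
with the problem size it was computed at.

## Known limitations

* TIR detection assumes both repeat copies survive in the assembly; collapsed
  or clipped TIRs (a known assembler failure mode) are invisible to it, and
  whether undetected repeats reflect biology or assembly is not decidable
  from within this method.
* The banded extension misses grossly rearranged or indel-rich repeats whose
  alignment leaves the ±200 diagonal band.
* KDE mass fractions near the chromosome ends are biased downward by the edge
  artifact described above.
* Louvain is a heuristic: the returned partition is a local modularity
  optimum; only the six-node fixture is verified globally optimal.
* The plasmid rule inherits whatever biases the supplied marker list has.
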