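# Methods

This note documents the models, operational definitions, defaults and
numerical choices behind `syntevo`, and what the built-in simulator does
and does not emulate.

## Genome-rearrangement simulator

An ancestral genome of `n_genes` genes, partitioned over `n_scaffolds`
scaffolds, evolves independently along every branch of a dated tree.
On a branch of duration *t* MY the number of events of each type is
Poisson with mean rate × *t*:

| event | default rate | effect |
|---|---|---|
| inversion | 0.1 / MY | reverses a contiguous gene segment, flips strands |
| translocation | 0.02 / MY | moves a segment to a uniformly chosen position, possibly on another scaffold |
| gene loss | 0.001 / gene / MY | deletes a uniformly chosen gene |
| gene gain | 0.5 / MY | inserts a novel gene (fresh id, no homology) at a uniform position |

Segment lengths for inversions and translocations are truncated
geometric with mean 5 genes (small rearrangements dominate genome
evolution; configurable). Events are applied in random order within a
branch. Emitted coordinates are cosmetic — 1,000 bp genes with 100 bp
spacers, 1-based inclusive — because only order and strand matter
downstream.

**Defaults as study conditions.** The default genome is 2,000 genes on
200 scaffolds (10 genes per scaffold). This mirrors the fragmentation
of short-read draft assemblies, where most gene-bearing scaffolds carry
only a handful of genes; it also matters scientifically: on very long
scaffolds, small inversions are absorbed by the block rules (a ≤ 5-gene
inversion is just a counted inversion inside a block; a larger one
splits a chain into pieces that usually re-qualify as blocks), so an
unrealistically contiguous ancestor makes the detector nearly blind to
rearrangement. Per-MY event rates were chosen so that a 10-MY species
pair retains *p*ₛ near 1 while a 60-MY study shows measurable decay —
the weak-signal regime in which rate estimation is actually hard.

**Random streams and monotone coupling.** Randomness is split into
named substreams: per-branch streams are keyed by a hash of the clade
below the branch (so results on one branch do not shift when unrelated
configuration changes), event *counts* are drawn by inverting the
Poisson CDF on a branch-level uniform, and every individual event draws
its parameters from its own stream keyed by (branch, event type, event
index). Consequently, for a fixed seed, raising one event rate only
*adds* events of that type while all other events stay identical. This
monotone coupling is what makes dose–response experiments (estimated
loss rate versus true inversion rate) well behaved at modest replicate
counts; it is verified by the calibration tests.

**Truth.** Simulated genes keep their ids, so the `TruthSet` maps each
ancestral gene to its surviving descendant (or absence) per species;
this is the oracle for orthology recovery tests.

**Hit tables.** Every surviving orthologue pair receives a hit in both
directions with a bit score drawn in [200, 400]; with probability
`noise` per gene a spurious hit to a random partner gene is added with
a score in [50, 150]. Because spurious scores sit strictly below the
true-hit margin, RBH precision is 1 by construction and only recall is
at stake — the generator probes threshold and tie-breaking logic, not
homology-search errors. E-values are a fixed monotone transform of the
score (10^(−score/10)), preserving the anti-monotonicity BLAST output
guarantees. Novel (gained) genes have no true homologue and can only
appear in spurious hits.

**Family counts** evolve by a gain/loss step process: per branch each
family gains Poisson(λ_g·*t*) and loses Poisson(λ·*t*) members, floored
at zero. A shift `(clade, m)` multiplies the *gain* intensity by *m* on
branches inside the clade. A symmetric intensity change would leave the
mean unchanged, so directional expansion (the signal the node-dynamics
test looks for) is modelled as gain-biased; contraction can be
simulated with *m* < 1.

**Traits** follow Brownian motion from 0 at the root with independent
Normal(0, σ²·*t*) branch increments, plus an additive offset per leaf
group.

## Orthology

Best hit per query = maximal bit score, ties broken by smaller e-value,
then lexicographically smallest subject id (the tie order is a
determinism requirement, not biology). Hits with e-value ≥ 10⁻⁵ are
ignored. A pair is linked iff each gene is the other's best hit;
RBH links are one-to-one by construction. When one gene pair has
several HSP rows, the max-bit-score row is used. Multi-species groups
are connected components of the link graph; components with two genes
from one species are discarded (logged), and by default only components
spanning every species are kept (`require_all=False` keeps partial
groups). An optional alignment-length filter exists but is off by
default: length cutoffs belong to family clustering, not RBH.

## Synteny

Gene order is the rank of the start coordinate within each scaffold.
Anchors (one-to-one orthologue pairs placed in both gene orders) are
grouped by scaffold pair and chained greedily in increasing order of
the A-genome index; an anchor joins the open chain iff the number of
intervening genes since the previous anchor is ≤ `max_gap` **in both
genomes** (|Δidx| − 1 ≤ 4 by default; the B-side gap is unsigned).
Chains close when the next anchor cannot join; each anchor belongs to
at most one chain. A chain is a block iff it has ≥ `min_genes` (5)
anchors and ≤ `max_inversions` (5) inversions, where the inversion
count is the number of maximal strictly descending runs of length ≥ 2
in the chain's B-index sequence — a parameter-free count that is
invariant to anchor density and gives 0 for a perfectly collinear chain
and 1 for a single internally reversed segment.

Design choices where the rules admit readings: the gap rule is enforced
symmetrically in both genomes (the stricter, deterministic reading);
*p*ₛ counts anchors, not base pairs; chains failing the inversion cap
are discarded whole. Greedy chaining is equivalent, on the sorted
anchor sequence, to splitting at adjacent-pair violations; the test
suite checks it against an exhaustive enumeration of maximal legal
chains on hundreds of random instances.

*p*ₛ = anchors in blocks / total anchors; zero anchors is an error
(undefined), no blocks gives 0. The loss rate is 1 − *p*ₛ^(1/*T*) with
*T* the age of the pair's MRCA in the dated tree (a `double_time` flag
switches to the 2*T* total path length); *p*ₛ = 0 returns rate 1 with a
warning.

## Branch fitting

Branch losses *b* minimise Σᵢ<ⱼ *w*ᵢⱼ(*d*ᵢⱼ − pathᵢⱼ(*b*))² on the
path-incidence system of the fixed topology, with *w*ᵢⱼ = *d*ᵢⱼ^(−P)
(unit weight where *d* = 0). P defaults to 2, the classic
Fitch–Margoliash weighting; 0 gives ordinary least squares. The
non-negativity constraint is solved by Lawson–Hanson active-set NNLS on
the weighted system — not by truncating an unconstrained fit, which
does not minimise the constrained objective. Leaf-path lengths never
separate the two root-adjacent branches, so their sum is fitted as one
parameter and reported split proportionally to the branches' time
durations, flagged `root_pair` in the output; exactness claims are
therefore stated for non-root branches, the root-pair sum, and the
reconstructed distance matrix. Branch rate = fitted loss / (parent age
− child age); zero-duration branches get a missing rate and a warning.
Fewer than three leaves is degenerate.

## Family dynamics

Expansion at an internal node: min over in-clade terminal counts >
max over out-clade counts; contraction is the mirror; ties count as
neither (strictness avoids counting drift-free families), and a family
can never be both. The root has no out-clade and is rejected. The
permutation null shuffles each family's counts across species
independently — preserving every family's size spectrum while breaking
the phylogenetic association; a `columns` mode permuting whole species
columns is available since the choice of permutation unit is a genuine
design fork. Envelopes are empirical 5th/95th percentiles with linear
order-statistic interpolation (reproducible, no distributional
assumption); with the default within-family null and 200+ permutations
the observed count exceeds the 95th percentile for about 5% of
exchangeable datasets (verified by a 1,000-dataset calibration test).

## Statistics

* **Mann–Whitney.** U = Σ[xᵢ < yⱼ] + ½Σ[xᵢ = yⱼ], reported folded as
  min(U, n₁n₂ − U). Exact p by full enumeration of label assignments
  when n₁ + n₂ ≤ 16 and the data are tie-free; two-sided = doubled
  lower tail of the folded statistic, capped at 1 (this is one of
  several defensible two-sided conventions; it matches the enumeration
  oracle by construction). Otherwise a tie-corrected normal
  approximation with continuity correction.
* **Kruskal–Wallis.** Midranks, H = 12/(N(N+1)) Σ Rⱼ²/nⱼ − 3(N+1),
  divided by the tie-correction factor; p from χ²(k−1). All-identical
  data: H = 0, p = 1 by convention.
* **Steel–Dwass.** Each pair compared on its own pooled midranks; the
  standardized rank sum is referred to the studentized range with k
  groups and ∞ df (p = Pr(Q ≥ |z|√2)). This is the large-sample
  approximation; no exact small-sample tables are used, so p-values for
  groups of fewer than ~8 observations are approximate.
* **Binomial equal-counts test.** Two-sided minimum-likelihood p at
  success probability ½, computed in exact integer arithmetic
  (Σ C(n,m) over outcomes no more probable than the observed one,
  divided by 2ⁿ).
* **Phylogenetic ANOVA.** Observed statistic is the classical one-way
  F. The null is simulation-based: Brownian motion on the tree at rate
  σ̂² = (x − â1)ᵀC⁻¹(x − â1)/(n − 1), with â the GLS phylogenetic mean
  and C the shared-path-length covariance; F is recomputed for each of
  `n_sim` simulations with the same group labels and
  p = (1 + #{F_sim ≥ F_obs})/(n_sim + 1). Groups need ≥ 2 leaves; a
  zero-variance trait is degenerate.
* **Protein properties.** Net charge uses the EMBOSS pK set (N-term
  8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1);
  charge is strictly decreasing in pH, so the pI is found by bisection
  on [0, 14] to |charge| < 10⁻⁶. Average residue weight is the mean
  average monomer mass minus water over the sequence. Non-standard
  residues raise an error unless explicitly skipped.

## Problem sizes in tests and the acceptance script

The calibration experiments run at sizes chosen to make their
statistical claims meaningful while staying desk-scale: 500 random
instances for the block-detection oracle; 2,000-gene two-species
genomes at four inversion-rate levels × 20 coupled replicates for rate
recovery; 1,000 exchangeable datasets × 200 permutations for the
family-dynamics calibration; 500 replicates × 200 simulations for the
phylogenetic-ANOVA type-I error; 100 random 4–10-leaf trees for
branch-fit exactness. The acceptance script uses a six-species,
2,000-gene, 60-MY study with 1,000 families and 500 permutations.

## What the simulator does not emulate

No nucleotide sequences, alignment or annotation error; no gene
duplication, paralogy or whole-genome duplication (hit-table "paralogs"
are score-bounded noise, so orthology precision is 1 by construction
and real paralog confusion is untested); no assembly chimerism or
missing genes beyond simulated loss; family counts evolve independently
across families; traits follow homoskedastic Brownian motion. Passing
tests therefore demonstrate correctness and calibration of the
*methods* under their stated assumptions, not robustness to the messier
failure modes of real genomic data.

## Known limitations

Greedy chaining does not revisit closed chains, so a single aberrant
anchor can split an otherwise valid block into two (both usually still
qualify); the exhaustive-oracle tests bound this behaviour on small
instances. The Steel–Dwass approximation is anticonservative for very
small groups. The root-adjacent branch split is a reporting convention,
not an estimate. The exponential-decay rate treats *p*ₛ as a point
estimate and propagates no uncertainty.
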