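# Methods

This note documents the models implemented in `copanet`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
does and does not emulate.

## Data model and filtering

The pipeline's entry point is a table of post events (pseudonymous
`user_id`, `community`, UTC `created_utc`, unique `post_id`, optional
`text`) plus a community→disorder mapping (each community maps to exactly
one ICD-10 level-4 code; each code to exactly one F0–F9 category).  Filters
are applied in a fixed order: first the half-open study window
`[start, end)` in UTC (default calendar year 2022), then user-level
exclusion of accounts with **more than** 365 retained posts (exactly 365 is
kept: the cutoff is a rate of more than one post per day) and of accounts on
a user-supplied bot list (exact, case-sensitive id match).  The activity
threshold is evaluated after the window restriction, so it acts as a
within-year rate, and removal always drops all of a user's posts.  Filtering
is idempotent.

Aggregation to the binary user–disorder bipartite graph unions a disorder's
communities: an edge (u, d) exists iff u has at least one retained post in
at least one community mapped to d.  Post counts never enter the graph; the
null model operates on this binary layer.

A lightweight validation utility reports the fraction of texted posts whose
self-referential pronoun count (`I`, `me`, `myself`) strictly exceeds the
other-referential count (default other-lexicon: second- and third-person
pronouns; ties do not count as self-dominant; matching is case-insensitive
on word boundaries).  This is the only text processing in the package.

## Association inference

**Metric.** The overlap coefficient |A∩B|/min(|A|,|B|) normalizes shared
membership by the smaller community, so a niche community largely embedded
in a bigger one scores high.  It is undefined for empty sets; disorders with
zero retained users are dropped before pair enumeration and the pair count
is recomputed.

**Null model.** The null ensemble is the set of simple bipartite graphs
with the observed user- and disorder-degree sequences.  Sampling uses
double edge swaps: draw two distinct edges (u1,d1), (u2,d2) and propose
(u1,d2), (u2,d1), rejecting proposals that would duplicate an edge (or
touch fewer than four distinct endpoints).  The default swap budget is
10×|E| **proposal attempts** per replicate.  Counting attempts rather than
acceptances is deliberate: the attempt-counted ("lazy") chain has a
symmetric proposal and therefore a uniform stationary distribution over the
ensemble, whereas a chain that runs until a fixed number of *successful*
swaps over-weights graphs with many legal swaps.  On a 6-user × 3-disorder
instance small enough to enumerate (80 degree-matched graphs), that bias
reaches ~3 Monte-Carlo standard errors at 10,000 replicates — detectable at
exactly the resolution we test at — while the attempt-counted chain matches
enumeration within sampling error.  `count="successful"` is still available
(with a 100×|E| attempt cap) for sensitivity analyses.  Every replicate
restarts from the observed graph with a per-replicate seed derived as
`seed XOR replicate_index` (masked to 31 bits), making results reproducible
and order-independent.

**Testing.** Each pair's observed overlap is reduced to
z = (obs − μ)/σ against the replicate mean μ and sample (n−1) SD σ, with a
two-sided p from the standard normal.  The p-value uses the normal
approximation rather than the empirical replicate rank on purpose: an
empirical p over R replicates is floored at 1/R, which can never clear a
Bonferroni threshold like 0.001/1176 ≈ 8.5×10⁻⁷ at any feasible R.  The
Bonferroni rule is interpreted as per-test level α/n_pairs with family-wise
α = 0.001 (the stricter reading; both α and the rule are configurable).
Sign follows the direction of z.  A degenerate null (σ = 0, which happens
exactly when the degree sequences admit a single realization) classifies as
"none" when obs = μ; an obs ≠ μ there indicates an inconsistency and is
surfaced as a warning with p recorded as 0.

**Networks.** Significant pairs split into a positive and a negative layer
sharing the node set.  Weights are obs − μ, kept signed; magnitudes are
used wherever a distance or a degree sum needs them.  Node-level summaries
(degree, weighted degree = Σ|w|, intra- vs inter-category split) are
reported for the positive layer; node-level aggregation of the negative
layer is deliberately not offered, because the overlap coefficient loses
sensitivity at low coposting rates in small communities and node sums over
negative edges inherit that bias — negative results should be read edge by
edge.

## Criteria layer

Disorders are sets of diagnostic criteria; two disorders are linked iff
they share at least one criterion (no significance filtering — shared
criteria are definitional), weighted by the same overlap-coefficient code
path used for coposting.  Criterion identity is exact string match after
lower-casing and whitespace collapsing.  A minimum-weight cutoff exists but
defaults to "any nonzero overlap".  The layer is restricted to the disorders
present in the coposting network before any comparison.

## Hierarchy

Similarity converts to distance as d(x,y) = max(e) − e(x,y); node pairs
without an edge get similarity 0, i.e. maximal distance, and isolated nodes
therefore sit at maximal distance from everything and surface as singletons
("unclustered") at any informative cut.  Clustering runs on the positive
layer only (magnitudes); negative edges never enter the hierarchy.

UPGMA is implemented in-package so tie-breaking is deterministic: among
minimal-average-distance cluster pairs, the pair whose smallest member codes
sort first lexicographically merges first.  (It is cross-checked against
SciPy's average linkage on tie-free inputs.)  Average linkage on a
non-metric dissimilarity can produce height inversions; they are permitted,
logged, and handled by defining the cut at height τ as the union of all
merges with height ≤ τ, which is well defined regardless of merge order.
Admissible cuts are the n−1 distinct merge heights plus the all-singletons
partition.

Weighted modularity follows the standard strength-preserving form
Q_w = (1/2W) Σ_ij [w_ij − s_i s_j/2W] 1{c_i=c_j} over ordered pairs
including i = j, which makes the single-cluster partition score exactly 0.
The null for ΔQ_w rewires the unipartite network by double edge swaps in
which each relocated edge carries its weight, preserving the degree
sequence and the weight multiset; Q_w(G′, π) is evaluated with π held
fixed.  One ensemble of 1,000 rewired graphs (default) is drawn once and
reused across all cuts: the argmax over cuts then compares candidates on
identical null samples, keeping their noise correlated, at 1/n_cuts of the
cost; a per-cut ensemble mode exists.  Exact ΔQ_w ties break toward fewer
clusters.  Note that a complete graph is rigid under simple-graph edge
swaps, so its null ensemble equals the observed graph and ΔQ_w ≡ 0; a
warning is emitted.

ARI uses the permutation-model chance correction and NMI the
arithmetic-mean entropy normalization (scikit-learn implementations,
cross-checked against exhaustive pair counting).  Edge-set similarity is
reported as Jaccard |E1∩E2|/|E1∪E2| plus the shared fraction relative to
each layer, since "x% of links shared" is otherwise ambiguous about its
base set.

## Synthetic data

The generator is membership-first: a user's disorder set is drawn before
any posts, because inference operates on the binary bipartite layer.  Each
user draws a primary disorder from the baseline participation vector
(default uniform), then joins each other disorder d independently with
probability `secondary_rate × baseline[d] × factor(primary, d)`; the factor
is a planted boost (> 1), suppression (in [0,1)), within-block boost
(default 8), or 1.  Isolated disorders get factor 0 in both directions.
With nothing planted the membership law is exchangeable across disorders up
to the baseline vector, which is what makes the false-positive tests
meaningful.  `secondary_rate` defaults to 0.18, putting the share of
multi-community users near the ~18% observed in large coposting corpora
under the null configuration; planted structure raises it.

Posts per user follow a discrete power law P(k) ∝ k^−2.5 on {1..1000}
(heavy-tailed activity; the exponent, floor and cap are configurable —
activity data of this kind is reported only through means, so the shape is
a modeling choice, not an estimate).  A configurable `bot_fraction` of
users instead emits a uniform 366–730 posts, so they are exactly the
accounts the >365/year filter removes.  Every membership is realized by at
least one post; remaining posts spread multinomially over the user's
communities.  Timestamps are uniform over 2022 in UTC.  Optional template
texts with a configurable self-dominant share exercise the pronoun
validator.

`block_similarity_network` generates weighted similarity networks directly
(within-block edges ~0.5, sparse between-block edges ~0.05, log-normal
noise): between-block sparsity keeps the topology non-rigid so the
modularity null can actually randomize it.  In the demo configuration used
by `scripts/acceptance.py`, consecutive blocks are additionally bridged by
one planted pair at the same strength as block membership; weaker bridges
are invisible to the configuration-model test because planted blocks
inflate their members' degrees and hence the null expectation of every
cross-block overlap.  The bridges connect the inferred layer into a single
giant component while average linkage still separates the blocks.

What the generator does *not* emulate: post text semantics, comment
threads, temporal dynamics within the year, community-size heterogeneity
beyond the baseline vector, and user churn.  Passing tests demonstrate the
statistical machinery (calibration, power, recovery) under a known model,
not the sociology of any real platform.

## Problem sizes and determinism

Test and demo sizes were chosen as the smallest instances where the tested
property is statistically unambiguous: calibration and power use 20 seeded
runs of 500–2,000 users × 10 disorders with 2,000-replicate nulls;
enumeration checks use a 6×3 instance (80-graph ensemble); cluster recovery
uses 12-node, 3-block similarity networks with 200-graph nulls; the
acceptance script runs 4,000 users × 15 disorders with 2,000/500-replicate
nulls.  All randomness flows from a single integer seed: generators use
`numpy.random.default_rng(seed)`, null replicates use derived seeds
`seed XOR r`, and reports are byte-identical across reruns of the same
configuration.

## Known limitations

- The normal approximation for p-values is an approximation to the true
  null law of the overlap coefficient; at extreme tails the calibration is
  untested (the Bonferroni margin in our checks is ≥4σ).
- The overlap coefficient's insensitivity at low coposting rates biases
  negative associations for small communities (see above); only edge-level
  negative results are supported.
- Degree-preserving rewiring cannot randomize rigid (e.g. complete)
  graphs; ΔQ_w is then identically 0 and the cut choice falls back to the
  fewer-clusters tie rule.
- UPGMA inversions are handled but not removed; branch lengths in exported
  Newick trees are clamped at 0 for inverted merges.
- The pronoun validator is a token counter, not an NLP model.
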