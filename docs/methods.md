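# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, the numerical decisions that affect results, and
what validation on synthetic data does and does not establish.

## Marker-gene phylogeny

**Filtering.** Marker sequences are kept when their length falls in an
inclusive window (default 1,300–1,550 bp, the usual near-full-length 16S
range), and exact duplicate sequences are removed keeping the first
occurrence. Redundancy removal by exact duplication is the strictest
reading of "non-redundant"; clustering near-identical sequences of unequal
length would be the laxer alternative and is deliberately not done, so the
reported kept/dropped counts are unambiguous.

**TN93 distances.** For an aligned pair, sites with a gap or ambiguity in
either sequence are excluded (pairwise deletion — complete deletion would
discard most columns on ragged public data). From the remaining sites we
take P1 (proportion differing A↔G), P2 (C↔T), Q (transversions) and base
frequencies averaged over both sequences, and evaluate the closed-form
TN93 estimator with its two transition terms and transversion term. When
any logarithm argument is ≤ 0 the estimator has no real solution — the
pair is beyond saturation — and the distance is the explicit `NaN`
sentinel, serialized as `NA`, never a silently clamped number. In the
equal-frequency, P1 = P2 limit the estimator reduces exactly to Kimura's
two-parameter distance, and with a 1:2 transition:transversion split to
Jukes–Cantor; both limits are enforced in tests at 1e-12.

**Saturation diagnostic.** For every pair we record s = P1 + P2 and
v = Q. A pair counts as saturated when v ≥ s (excluding identical pairs,
where s = v = 0 carries no evidence either way); the alignment verdict is
`saturated` when at least half the pairs are. This operationalizes the
standard visual transitions-vs-distance plot as a reproducible rule; a
formal information-entropy index test is out of scope.

**Tree building.** Neighbor joining (Saitou–Nei Q-criterion) on the TN93
(or composition-vector) distance matrix. Ties in Q are broken by the
lexicographically smallest label pair, making output independent of input
order; negative branch lengths, which NJ can produce on non-additive
input, are clamped to zero with a warning. On additive matrices NJ is
exact, and the suite checks recovery of random trees to 1e-9. NJ is used
rather than a maximum-likelihood search: it preserves the distance model
while keeping the stage deterministic and dependency-free; ML tree search
is explicitly out of scope. Outgroup rooting places the root at the
midpoint of the outgroup's subtending edge.

## ANI

Query genomes are fragmented into consecutive, non-overlapping 1,020 bp
windows per contig; a trailing fragment is kept only when it is at least
half a window (the count of fragments enters the denominator of nothing,
but accepted-fragment identities are averaged, so the rule is stated).
Each fragment is aligned by exact 11-mer seeding on both strands followed
by a local alignment (match +1, mismatch −1, gap open −5, gap extend −2)
of the fragment against the seeded subject window; identity is matches
over alignment columns. A fragment is accepted when its best hit reaches
≥ 30% identity across ≥ 70% of the fragment length — the conventional
ANIb acceptance rule — and ANI is the mean identity over accepted
fragments, undefined when none is accepted. The coverage criterion is what
rejects chance seed hits between unrelated genomes: random local hits are
short, so they fail the 70% rule regardless of their identity.

ANI is direction-dependent (fragmenting A against B is not fragmenting B
against A); both directions are always computed and surfaced, and the CLI
prints their mean for the species call. Species delineation uses the
conventional threshold: same species iff ANI ≥ 95% (boundary inclusive).

At the scale this package targets (≤ a few hundred kb per synthetic
genome) the seeded local aligner is insensitive, at the ±0.5% level the
tests assert, to the heuristics that distinguish production aligners.

## Ortholog clustering

Genes annotated with mobile-genetic-element keywords (transposase,
integrase, insertion sequence, IS family, phage, prophage, recombinase;
case-insensitive substring match) are excluded before clustering, since
lineage-specific MGE expansions distort accessory-genome counts.

Remaining proteins from all genomes are pooled, sorted by length
descending (ties by gene id), and clustered greedily: each protein joins
the first (oldest) centroid it matches at ≥ 50% identity and ≥ 50%
coverage of the shorter sequence, else founds a new family with itself as
centroid. The global length sort makes the outcome invariant to the order
genomes are supplied in. Identity comes from a global alignment with
affine gaps under BLOSUM62 (gap open −11, extend −1) and is defined as
matches over alignment columns excluding terminal gaps; this denominator
convention is stated because identity definitions differ between tools and
the 50% cutoff sits exactly where they diverge. The coverage requirement
stands in for an E-value cutoff, which a score-only aligner does not
produce.

A prefilter skips alignment against centroids sharing fewer than two
distinct 4-mers with the query: a pair at the 50% cutoff shares ~9 such
4-mers in expectation, unrelated proteins ~0.1, so the filter prunes
nearly all futile alignments while leaving the decision to the alignment.
Paralogs co-cluster, so matrix cells may exceed 1; presence/absence is
obtained by thresholding at ≥ 1. No manual post-correction of clusters is
implemented — there is no reproducible rule for one.

The partition classifies families by presence pattern: core (all genomes),
accessory (≥ 2 but not all), unique (exactly one). With a single genome
"all" and "one" coincide and families are reported as unique
(strain-specific), the reading that stays meaningful as genomes are added.

## Pan-genome models

Rarefaction draws random genome orders (default 100 permutations, seeded)
and records, for each prefix length n, the number of families present in
≥ 1 prefix genome (pan) and in all prefix genomes (core); the medians
across permutations form the curves. Medians, not means, are used.

The pan curve is fitted with Heaps' law Ps(n) = κnᵞ by linear least
squares on log-log scale — deterministic, and exact on noiseless power-law
data (κ = exp(intercept), γ = slope). The core curve is fitted with
Fc(n) = κ_c·e^(−dn) + Ω by bounded nonlinear least squares; the
two-parameter form fixes Ω = 0. Initialization is documented and data
driven: Ω₀ = min(y) (offset form), d₀ from the log-slope between first and
last points, κ_c0 from the first point; three starts (d₀ scaled by 1, 1/4,
4) guard against local minima and the best residual wins; convergence is
1e-10 on the relative residual change, capped at 1,000 function
evaluations. Openness: 0 < γ < 1 ⇒ open, γ < 0 ⇒ closed, the boundaries
γ = 0 and γ ≥ 1 are reported as indeterminate rather than silently
assigned.

Note a published pair of fitted curves of this shape can be mutually
inconsistent when the printed exponential omits its offset term (a
two-parameter curve cannot plateau at a positive core size); both forms
are therefore available and nothing attempts to reconstruct an unprinted
offset.

## Gene turnover (Wagner parsimony)

Gene-family counts at the leaves are integer characters under linear
(Wagner) cost with equal gain and loss weight. The bottom-up pass computes
each node's optimal interval: for two children the classic Farris rule
(intersection if non-empty, else the gap between the intervals); for m
children the interval between the m-th and (m+1)-th order statistics of
the 2m child-interval endpoints, which is the exact minimizer set of the
convex piecewise-linear subtree cost and reduces to Farris for m = 2. The
top-down pass assigns each node the value in its interval closest to its
parent's assignment — optimal because the subtree cost has integer slopes
≥ 1 outside its minimizer interval. The root takes its interval's
*minimum*: the most parsimonious ancestor with the fewest families, i.e.
events are counted from the minimum number of family members at internal
nodes. Total absolute change along branches equals the parsimony minimum
(verified against exhaustive enumeration on 500 random instances).

Costs default to 1:1 (plain Wagner); asymmetric gain/loss costs are
available and route through an exact dynamic program over the bounded
ancestral state range — minimality is then in weighted cost while the
reported events remain unweighted counts.

Per-branch gains are Σ_f max(0, child_f − parent_f) and losses the
mirror image; dividing by branch length gives per-branch rates — the
free-rates view in which every branch has its own turnover rate.
Zero-length branches get the undefined sentinel, with a warning if events
sit on them. Likelihood-based birth–death rate models are deliberately not
implemented; the deliverable is the parsimony event count and its
per-length normalization. Parsimony systematically undercounts when event
density is high (multiple events per family per branch collapse), which
the test suite asserts as an inequality rather than pretending it away.

## Composition-vector phylogeny

Per genome, all length-K windows (K = 6 by default, configurable ≥ 3 —
the background needs K−1 and K−2 marginals) are counted over each protein
separately, never bridging two proteins. The (K−2)-order Markov background
f0(a1..aK) = f(a1..a_{K−1})·f(a2..aK)/f(a2..a_{K−1}) is subtracted and
normalized: a(t) = (f − f0)/f0, with a(t) = 0 where f0 = 0. Components
are kept for every tuple with positive expectation, including observed-0
tuples (a = −1), which carry real signal in the cosine. The pairwise
distance is (1 − C)/2 with C the cosine over the tuple union — 0 for
identical composition, 1 for anti-parallel — and the distance matrix feeds
the same NJ/rooting path as the marker pipeline, for whole proteomes or
core-ortholog subsets alike. Protein mode only; nucleotide CV trees are
out of scope.

## Synthetic data: what it emulates and what it does not

The generator produces a clade under one consistent ground truth:

- **Tree**: pure-birth (Yule) with unit birth rate, rescaled to a chosen
  root-to-tip height (default 1.0, the unit in which all rates are
  expressed), or any fixed Newick. Leaves are labelled deterministically.
- **Gene content**: per branch of length L, each family survives with
  probability e^(−loss·L) and Poisson(gain·L) new families arrive. Gains
  found brand-new families (infinite-alleles); a lost family is never
  regained. This is exactly the regime in which an open pan-genome arises
  and in which Wagner-parsimony ground truth is well defined. Defaults
  (200 root families, gain 30, loss 0.1 per unit branch) produce
  clades whose core/accessory/unique proportions resemble a small
  congeneric genome set while staying desk-sized.
- **Marker**: gapless alignment evolved site-i.i.d. under the TN93 rate
  matrix (16S-like base composition, strong transition bias), with branch
  lengths scaled by a marker clock (default 0.1 substitutions per site per
  unit tree distance — conserved markers diverge far more slowly than
  gene content). One marker per genome; intragenomic marker heterogeneity
  is not modelled.
- **Proteomes**: one protein per family member, evolved from a random
  family ancestor by i.i.d. site substitution (no indels), so within-family
  identity is an analytic function of tree distance (≈ e^(−decay·t)). A
  configurable fraction of genes receives MGE-like product annotations.
- **Genomes**: a single ancestral chromosome diverging by per-site
  substitution, giving a clean ANI structure.

Everything is driven by one seed; identical configurations give
byte-identical outputs.

Not emulated: indels, rearrangement and gene order, horizontal transfer of
*existing* families (re-gain), codon structure, intragenomic 16S copies,
plasmids, sequencing artefacts. Consequently, passing tests demonstrate
algorithmic correctness under the stated model — clustering recovery, for
instance, is shown in an identity regime (within-family high, between-family
random) that real proteomes only approximate, and parsimony recovery is
shown at the low event densities where parsimony is a consistent
estimator. They do not certify performance on real data with domain
shuffling, partial genes or assembly noise.

## Problem sizes used in validation

Test and demonstration runs use desk-scale inputs chosen to exercise every
code path with comfortable statistical margins: clades of 5–10 genomes
(28 where node-count arithmetic is the point), 10–50 kb markers for
convergence checks, 100 kb genomes for ANI, hundreds of families for
clustering and rarefaction, 500 random instances for the parsimony
optimality check and 100 random additive matrices for NJ. The fitted-model
recovery checks regenerate the published 28-point pan/core series exactly
and invert them with the package's own fitting routines.

## Known limitations

- The ANI aligner is a seeded local aligner, not a tuned production
  search; at real-genome scale (multi-Mb) it would need seed-and-extend
  banding and masking to stay fast and to handle repeats.
- Greedy centroid clustering depends on the length-sort order by design;
  it is deterministic but, like all greedy clustering, not invariant to
  the identity threshold in borderline regimes.
- The saturation verdict is a majority rule over pairs, a deliberately
  simple operationalization; strongly rate-heterogeneous alignments
  deserve a model-based test.
- Wagner parsimony with equal costs cannot distinguish a gain from a pair
  of losses on adjacent branches when both cost the same; asymmetric cost
  ratios shift that balance but no likelihood alternative is provided.
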