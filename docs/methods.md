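# Methods

## Problem and pipeline

`dsnfuse` integrates heterogeneous per-drug annotation into a single
weighted drug network and mines that network for repositioning signal.
The pipeline is: per-property similarity networks → non-linear fusion →
spectral clustering with data-driven cluster count → evaluation against
therapeutic labels → edge attribution, enrichment and candidate
extraction. Every stage consumes and produces plain-text formats
(dense TSV matrices with drug-ID headers, sparse pair tables, FASTA) so
runs are diff-able and reproducible.

## Similarity measures

*Feature-set views.* Side-effect and chemical similarity are Tanimoto
coefficients over finite token sets. Two empty sets score 0, not 1:
absence of evidence must not assert maximal similarity. Side-effect
terms are filtered before network construction: a term occurring for at
most one drug corpus-wide is removed, as is any drug–term pair whose
attached report frequency is below 0.1 % (`min_frequency = 0.001`). The
frequency rule fires only where frequency data exist; the count rule
applies always. Drugs left with empty profiles stay in the network
(flagged in the log) rather than being dropped silently.

*Chemical tokens.* Atom-pair descriptors (typed heavy-atom pair +
topological distance) are computed from SMILES via RDKit's atom-pair
fingerprint, namespaced `ap:`. Because many users arrive with
precomputed fingerprints, the chemical view equally accepts token-pair
tables, and RDKit is an optional dependency.

*Target view.* Drug–drug similarity is the mean over all cross-target
pairs of the normalized Smith–Waterman score
SW(p, q)/√(SW(p,p)·SW(q,q)). The geometric-mean denominator makes
self-similarity exactly 1, which the unit-scale matrix contract
requires; an alternative normalization would not be monotone-equivalent,
so the choice is fixed rather than configurable by default. Alignment
uses Biopython's `PairwiseAligner` in local mode. The scoring scheme is
BLOSUM62 with gap open 10 and extend 0.5 (the common EMBOSS-water
protein defaults; a gap of length L costs open + (L−1)·extend), fully
configurable through `AlignmentScoring`. Self-alignment scores are
cached per protein when building a whole network.

## Fusion

SNF is implemented as the standard cross-diffusion recurrence: the full
kernel P places half its row mass on the diagonal and distributes half
over neighbours proportionally to similarity; the sparse kernel S
row-normalizes each drug's K nearest neighbours (self excluded, ties
broken stably by drug order). Each round updates
P_v ← S_v · mean(P_u≠v) · S_vᵀ, re-symmetrizes, and re-normalizes to the
full-kernel form (without the re-normalization the iterates drift off
the kernel scale); the output is the mean of the final kernels.
Defaults K = 20, T = 20.

The similarity networks are fed to SNF directly as affinities — they
are already bounded, comparable similarities. The kernel bandwidth η
(default 0.5) therefore matters only on the optional path that builds
affinities from raw feature distances (`affinity_kernel`, a scaled
exponential with locally adaptive bandwidth); it is accepted and echoed
everywhere for interface stability. Inputs with n ≤ K are rejected
rather than silently clamped.

Baselines: elementwise maximum; weighted average over the 0.1-step
simplex grid (66 weight vectors for three views); probability
disjunction 1 − Π(1 − S_v), which requires unit-scale inputs and always
dominates the maximum. All integrators are deterministic and
permutation-equivariant (property-tested).

## Clustering and cluster count

Spectral clustering uses the symmetric normalized Laplacian, the bottom
k eigenvectors, row normalization, and k-means with `n_init = 10` under
a fixed seed — deterministic given (matrix, k, seed). A graph with more
connected components than k is rejected with advice to raise k.

Validity indices operate on d = 1 − s of the unit-scale matrix (fused
affinities are first rescaled by their maximum off-diagonal entry, a
monotone transform). The triangle inequality is not guaranteed and not
needed. The scan selects k by mean silhouette width, ties broken by the
Dunn index, then by smaller k; the full per-k profile is always
returned so users can override. This combination rule is this package's
own declared choice — silhouette is bounded and robust to cluster-size
imbalance, Dunn sharpens the decision between near-ties.

Degenerate-input conventions: silhouette contributions are 0 for
singleton-cluster members and for points with a_i = b_i = 0 (co-located
points split across clusters — exactly what noiseless planted blocks
produce); the Dunn index returns +inf for zero-diameter, positively
separated partitions and errors only when every cluster is a singleton;
k values whose subgraph structure makes spectral clustering infeasible
are recorded as NaN in the validity profile and skipped.

## Evaluation statistics

NMI uses base-2 logs and the geometric-mean normalization
MI/√(H(X)H(Y)); if either entropy is 0 the quotient is undefined and 0
is returned. The ATC label vector reduces a multi-code drug to its
alphabetically first first-level code by default (`random-seeded`
selectable) — the reduction is a declared convention, not a claim about
the right answer. AOR (shared first-level ATC code) and SOR (identical
superclass) exclude pairs with missing annotation, with logged counts,
rather than scoring them as non-overlap; this avoids penalizing sparse
annotation. Rogers–Tanimoto doubles the weight of pair-level
disagreements: (n11+n00)/(n11+n00+2(n10+n01)). The AOR curve slides a
bin (default 3000 pairs, step 100 — both configurable down to toy
scale) along the similarity-ranked pair list.

## Interpretation

*Edge attribution.* The three per-view scores of an edge are sorted and
the contributor cut is placed at the first relative gap of ≥ 10 %
(S_i ≥ 1.1·S_j). "10 % higher" is read relatively because the three
views live on different natural scales; an absolute mode is available.
The generalization to v views walks the sorted scores to the first
qualifying gap. By default attribution summarizes the top 5 % of fused
edges (the same restriction the repositioning graph uses); an all-edge
mode exists. Summaries report, per scope (all, within-cluster,
between-cluster, per cluster), the fraction of edges per contributor
subset; the fractions partition each scope.

*Enrichment.* For each (cluster, term): ES = (k/n)/(m/N) and the
hypergeometric upper tail P(X ≥ k). The vocabulary is pluggable (ATC
first levels, superclass, or any drug→terms mapping such as ADMET
flags); multi-label drugs count once per distinct term.
Benjamini–Hochberg q values are computed across all tests and always
reported; the significance flag defaults to raw p < α (α = 0.05) with q
selectable.

*Repositioning.* Route one ranks all pairs by fused similarity and
flags top pairs whose first-level ATC sets are disjoint. Route two
flags cluster members whose own codes miss every significantly enriched
code of their cluster, proposing the enriched codes as the novel
property; drugs with no ATC annotation are never flagged. The ATC
repositioning graph assigns each drug in the top 5 % of pairs to all its
first-level codes and weights each between-code edge by the mean
similarity of spanning pairs. Property deviation for a numeric drug
property is D = (C − A)/A with a Welch (unequal-variance) two-sample
t-test; Welch is chosen because cluster and reference variances have no
reason to match.

## Synthetic universes

The generator plants a partition of n drugs into k clusters and renders
it in three views with independent signal-to-noise. Token views draw
disjoint per-cluster signatures (plus one background signature) from a
fixed vocabulary; per-drug noise at rate r drops each signature token
with probability r and adds Binomial(|signature|, r) random vocabulary
tokens. The target view gives each cluster an anchor protein (random
120-mer over the 20-letter alphabet) and each drug a copy point-mutated
at the stated rate, so normalized SW similarity is near 1 within
clusters and near background between — without any real biology.
Clusters where a view is marked uninformative draw from the shared
background signature/anchor, making them indistinguishable *in that
view only*. ATC codes follow the cluster's dominant first-level code;
label noise flips a drug's code to a uniformly random other code and
records the flip, creating exact ground truth for the unexpected-drug
route. Superclass labels follow the cluster without noise.

Default condition sizes: 120 drugs, 6 clusters, vocabulary 400 with
signature 25 per token view, 120-residue proteins. The canned
complementary benchmark fixes moderate noise (token noise 0.2, mutation
rate 0.1) and the informative sets {1,2,3}/{3,4,5}/{5,6,1}, so each
view alone merges half the clusters while their union covers all six —
the regime where non-linear fusion should, and measurably does,
dominate any single view.

What the synthetic data does *not* emulate: real marginal distributions
of side-effect frequencies, correlated chemical scaffolds, hub target
proteins shared across unrelated drugs, or incomplete/biased
annotation. Passing benchmarks therefore demonstrate the machinery's
correctness and the fusion principle under controlled complementarity,
not expected performance on DrugBank/SIDER-scale data.

## Problem sizes used in checks

The automated end-to-end checks run the complementary benchmark
(n = 120) over 20 seeds for the integrator comparison, 10 seeds per
planted k ∈ {2, 3, 5} (n = 60) for cluster-count recovery, and single
seeds for the repositioning and reproducibility checks — sizes chosen
so a full verification pass completes in minutes on one CPU while
keeping every cluster ≥ 15 drugs.

## Known limitations

- SNF output is an affinity, not a probability; only its monotone
  rescaling is comparable across runs.
- The silhouette/Dunn selection rule is one defensible choice among
  several; very unbalanced planted structures may prefer connectivity,
  which is reported but not used for selection.
- Smith–Waterman is exact dynamic programming via Biopython; for
  thousands of drugs with large target sets a vectorized aligner would
  be the first optimization target.
- The attribution margin rule is scale-free but threshold-sensitive
  near ties; margins other than 0.10 change subset sizes smoothly, not
  qualitatively.
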