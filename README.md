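# dsnfuse

Drug repositioning by non-linear integration of drug similarity networks.

Most approved drugs are annotated along several weakly overlapping axes —
the side effects they cause in the clinic, their chemical structure, and
the proteins they bind. Each axis defines a *drug similarity network*
(DSN): drugs as nodes, pairwise similarity as weighted edges. Any single
network sees only part of the pharmacological picture; `dsnfuse` fuses
them non-linearly into one integrated network (iDSN), clusters it,
explains which data type drives each edge, and extracts repositioning
candidates — drug pairs that are highly similar yet carry discordant
therapeutic labels, and cluster members whose own labels miss what their
cluster is enriched for.

The package is aimed at computational pharmacologists who already have
(or can export) per-drug annotations as plain-text tables, and at
methods researchers who want a fully synthetic, seeded benchmark for
multi-view network integration.

## The model

**Per-property similarity.** For side effects and chemical structure,
drugs are feature sets and similarity is the Tanimoto coefficient

    S(d, d') = |F(d) ∩ F(d')| / (|F(d)| + |F(d')| − |F(d) ∩ F(d')|)

with F(d) the filtered side-effect term set E(d) or the atom-pair
descriptor set C(d). For targets, with P^d the target protein set of
drug d and SW(·,·) the Smith–Waterman local-alignment score,

    S(d, d') = (1 / |P^d||P^d'|) Σ_i Σ_j SW(p_i, q_j) / √(SW(p_i,p_i) SW(q_j,q_j)).

**Fusion.** Similarity network fusion (SNF): each view's diffusion
kernel is iteratively updated through its K-nearest-neighbour kernel
with the average kernel of the other views (K = 20, T = 20 iterations by
default), so complementary signal propagates across views. Linear
baselines — elementwise maximum, weighted average over a 0.1-step weight
grid, and probability disjunction 1 − Π_v (1 − S_v) — are provided for
comparison.

**Clustering and validation.** Normalized-cut spectral clustering with
seeded k-means; the cluster count is scanned and selected by mean
silhouette width with the Dunn index as tie-break (connectivity is
reported too). Partitions are scored by NMI against ATC first-level
codes, ATC/superclass overlap rates of within-cluster pairs, and the
Rogers–Tanimoto index between partitions.

**Interpretation.** Each fused edge is attributed to the data types
whose single-view scores dominate (a ≥ 10 % relative margin rule);
clusters are annotated by hypergeometric enrichment of any drug→label
vocabulary, ES = (k/n)/(m/N) with upper-tail P values and BH q values;
repositioning candidates come from top-ranked discordant pairs and from
"unexpected" cluster members.

## Worked example

Everything runs end to end on a synthetic drug universe — no database
downloads:

```
dsnfuse simulate --preset blocks --n-drugs 40 --n-clusters 4 --seed 3 --outdir data/
dsnfuse build-dsn --kind side_effect --input data/side_effects.tsv --out side.tsv
dsnfuse build-dsn --kind chem        --input data/atom_pairs.tsv   --out chem.tsv
dsnfuse build-dsn --kind target      --input data/targets.tsv --fasta data/proteins.fasta --out target.tsv
dsnfuse fuse --method snf --views side.tsv --views chem.tsv --views target.tsv --out idsn.tsv
dsnfuse cluster --matrix idsn.tsv --k-range 2:6 --seed 1 --out clusters.tsv --report validity.tsv
dsnfuse evaluate --matrix idsn.tsv --clusters clusters.tsv --registry data/drugs.tsv \
    --reference-clusters data/planted_clusters.tsv --out metrics.tsv
```

`metrics.tsv` from this exact run:

```
nmi_atc	within_cluster_aor	within_cluster_sor	rogers_tanimoto	dunn	silhouette	connectivity
1.0	1.0	1.0	1.0	7.924856484967695	0.9543911646449394	4.000000000000002
```

Read: the clustering of the fused network matches the planted partition
exactly (Rogers–Tanimoto 1.0), every within-cluster drug pair shares an
ATC first-level code (AOR 1.0) and a superclass (SOR 1.0), NMI against
the ATC labels is 1.0, and the validity indices confirm compact,
well-separated clusters (silhouette 0.95, Dunn 7.9). The same library
calls are available in Python (`dsnfuse.snf_fuse`,
`dsnfuse.spectral_cluster`, ...).

The Python-level benchmark is one call:

```python
from dsnfuse.benchmark import integrator_comparison
print(integrator_comparison(seed=0))
# (rounded) {'view_side_effect': 0.698, 'view_atom_pair': 0.704,
#  'view_target': 0.714, 'snf': 1.0, 'max': 0.822,
#  'disjunction': 0.811, 'wavg_best': 1.0}
```

On this benchmark each view can separate only part of the planted
cluster structure, so every single view tops out near NMI 0.7 while SNF
pools the complementary signal and recovers the partition exactly.

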