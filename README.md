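# meadownet

Downstream analysis of multi-domain soil microbiome surveys under herbivore
disturbance: from rarefied OTU count tables of bacteria, fungi and archaea to
co-occurrence networks, cross-domain (inter-kingdom) interaction summaries,
an ecosystem-multifunctionality index, and permutation-based inference —
plus a synthetic community generator with planted ground truth so every
stage of the pipeline can be validated without any sequencing data.

The package targets the kind of blocked field experiment used to study
grassland degradation on alpine meadows: control meadow plots (C), plots
disturbed by burrowing herbivores such as plateau pika (P), and plots under
combined pika-plus-livestock disturbance (PL), with quadrats along the
surface succession grassland (G) → new mound (N) → old mound (O) → bare
land (B), plus inside-mound (I) samples.

## What it computes

**Diversity.** Per-sample alpha diversity — observed OTUs, Chao1
(S_obs + F1²/2F2, bias-corrected branch when F2 = 0), Shannon entropy
−Σ pᵢ ln pᵢ and Gini-Simpson 1 − Σ pᵢ² — and Bray-Curtis dissimilarity
d(u,v) = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ), with community similarity 1 − d.

**Co-occurrence networks.** On rarefied tables restricted to dominant OTUs
(mean relative abundance > 0.01 %), Spearman rank correlation ρ for every
OTU pair; an edge wherever |ρ| > 0.7 and P < 0.05 (Benjamini-Hochberg
optional). Cross-domain networks drop every within-domain edge, leaving
only bacteria–fungi, bacteria–archaea and fungi–archaea associations.
Topology per network: nodes, edges, average degree 2E/N, density
2E/N(N−1), Newman modularity of a seeded Louvain partition, diameter and
average path length over connected pairs, mean local clustering
coefficient, and the positive/negative edge-sign proportions. Cross-domain
edges are additionally tallied per domain pair with their sign proportions.

**Ecosystem multifunctionality (EMF).** Per sample, the mean of the
Z-scores ((x − mean)/SD, jointly over all samples) of seven
support/regulation variables: total vegetation coverage, dry weight, wet
weight, NH₄-N, NO₃-N, SOC and TN. The grand mean is exactly 0, so group
means read directly as standard deviations above or below the survey-wide
typical function level.

**Inference.** Per-OTU enrichment ratios vs the control meadow (one-way
ANOVA on relative abundance; "enriched" requires significance *and* a
higher focal mean), Mann-Whitney U, PERMANOVA (pseudo-F on a distance
matrix with add-one permutation p, exhaustive enumeration for tiny designs),
the Mantel test, multiple regression on distance matrices (MRM), and
least-squares regression with R².

**Synthetic communities.** `meadownet.synthetic` generates the full 110
sample blocked design, count tables from a latent Gaussian model (softmax →
multinomial at negative-binomial depth) with planted correlation blocks,
planted group enrichments and monotone environmental gradients, and exposes
the planted truth for scoring edge and enrichment recovery.

## Worked example

```python
from meadownet import (DesignConfig, CommunityConfig, CorrelationBlock,
                       GradientConfig, generate_design, generate_counts,
                       generate_env, rarefy, filter_dominant, subset_by_group,
                       spearman_all_pairs, build_network, topology_summary,
                       alpha_diversity, function_matrix, emf_scores, group_emf)

design = generate_design(DesignConfig(seed=0))          # 110 samples
cfg = CommunityConfig(n_otus=120, seed=1)
ids = cfg.otu_ids()
cfg.correlation_blocks = [CorrelationBlock(otus=tuple(ids[60:65]), rho=0.9)]
counts = rarefy(generate_counts(design, cfg, "bacteria"), depth=6000, seed=2)

print(alpha_diversity(counts).head(3).round(3))
#            observed    chao1  shannon  simpson
# sample_id
# C1.s1.G         120  120.167    4.160    0.973
# C1.s2.G         117  117.000    4.219    0.979
# C1.s3.G         120  122.667    4.163    0.977

sub = filter_dominant(subset_by_group(counts, design, disturbance="P"))
net = build_network(spearman_all_pairs(sub), r_threshold=0.7,
                    p_threshold=0.05, domains="bacteria")
t = topology_summary(net, community_seed=3)
print(t.n_nodes, t.n_edges, t.positive_proportion)
# 5 10 1.0
```

The thresholded network recovers exactly the planted 5-OTU block — all
C(5,2) = 10 positive edges, no false edges among the 7 140 candidate pairs.
The EMF of the same design shows the planted surface gradient:

```python
env = generate_env(design, GradientConfig(), seed=4)
emf = emf_scores(function_matrix(env))
print(group_emf(emf, design, by="surface").round(3))
#   surface   mean     sd   n
# 0       B -1.002  0.220  20
# 1       G  0.970  0.220  30
# 2       I -0.184  0.204  20
# 3       N  0.209  0.201  20
# 4       O -0.479  0.190  20
```

i.e. multifunctionality declines monotonically along G → N → O → B, about
two pooled standard deviations from grassland to bare land.

A full run (rarefaction → diversity → networks → EMF → statistics, with a
provenance report of output hashes):

```sh
meadownet run --outdir out --seed 7           # synthetic data
meadownet run --config my.yaml --outdir out   # your own tables
```

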