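# tcrfocus

Analysis toolkit for paired T-cell receptor (TCR) repertoires, built for the
question of how the bone-marrow T-cell compartment changes across autologous
stem cell transplantation (ASCT): is the post-transplant repertoire narrower
and more focused than at diagnosis, and do the clones that dominate it
pre-exist at baseline?

It is aimed at immunologists and bioinformaticians with bulk TCR-seq
clonotype tables (AIRR Rearrangement TSV or Decombinator-style frequency
CSV) from paired samples — baseline (BL) and a post-treatment timepoint —
who need depth-controlled diversity comparisons, clonal-expansion calls,
CDR3 sequence-similarity clustering and clonotype persistence tracking, plus
a fully controlled synthetic-data generator for validating the whole
pipeline.

## What it computes

**Depth matching.** Diversity statistics are depth-dependent, so the deeper
member of each pair is iteratively subsampled (default 100 iterations) to
the shallower member's read count. Draws are without replacement at the
read level — a multivariate hypergeometric draw over the clone count vector
— and statistics are summarized as median with min/max across iterations.

**Rényi diversity spectrum.** For clone frequencies *p·*, the Rényi entropy
of order *q* is

    H_q = (1/(1−q)) · ln Σᵢ pᵢ^q        (nats)

with H₀ = ln S (log-richness), H₁ = −Σ pᵢ ln pᵢ (Shannon),
H₂ = −ln Σ pᵢ² (log inverse-Simpson) and H∞ = −ln max pᵢ (dominance).
H_q is non-increasing in *q*; one sample's curve lying entirely below
another's means lower diversity under every weighting of the clone-size
distribution. Default subsample depths follow the α/β chain convention of
3,000 / 9,000 reads.

**Clonal expansion.** A clonotype is *expanded* when its frequency strictly
exceeds 1/1,000. The package reports expanded counts, the expanded
proportion of unique clonotypes, and threshold–count curves across a
frequency grid.

**CDR3 similarity networks.** The top 50 expanded CDR3 amino-acid sequences
per sample are compared with a triplet (3-mer) spectrum kernel,
cosine-normalized to [0, 1]; pairs at similarity ≥ 0.80 are connected and
clusters are connected components of ≥ 2 sequences. The threshold is
calibrated so motif-free control sequences show minimal clustering
(`calibrate_control`).

**Persistence.** For each patient, the fraction of post-treatment expanded
clonotypes already present at baseline (at any baseline frequency), keyed
either by nucleotide clonotype (V gene, J gene, CDR3 nt) or by CDR3
amino-acid sequence.

**Synthetic paired cohorts.** `simulate_paired` generates baseline/post
pairs with Zipf clone sizes, a post-transplant richness bottleneck,
preferential persistence and boosting of expanded clones, novel
low-frequency clones, and optional planted CDR3 motif families — with a
ground-truth record for parameter-recovery testing.

## Worked example

Simulate a two-patient paired cohort and run the full analysis:

```
tcrfocus simulate --patients 2 --outdir demo --seed 11 \
    --clones 1000 --reads-bl 12000 --reads-post 6000
tcrfocus run demo/manifest.tsv --outdir demo/report --iterations 20 --depth 2000
```

`demo/report/richness.tsv` (excerpt):

```
sample_id    timepoint  total_reads  richness  matched_depth  matched_richness_median
SIM-01_BL    BL         12000        1000      6000           744.5
SIM-01_post  postASCT    6000         651      6000           651
```

The baseline sample had 1,000 clonotypes at 12,000 reads; at the matched
depth of 6,000 reads it still shows a median of 744.5 clonotypes across 20
subsample iterations, versus 651 post-transplant — a richness drop. The
expansion table shows the mirror-image focusing (proportion of clonotypes
above 1/1,000 rises from 0.074 at BL to 0.098 post):

```
sample_id    threshold  n_expanded  richness  proportion_expanded
SIM-01_BL    0.001      74          1000      0.074
SIM-01_post  0.001      64           651      0.098
```

and the Rényi table confirms reduced diversity even at order ∞
(BL median 1.348 nats vs post 1.243 — the dominant post clone is larger).
Persistence of the expansions:

```
tcrfocus overlap demo/SIM-01_post.tsv demo/SIM-01_BL.tsv --patient SIM-01
patient_id  chain  key_mode  n_expanded_post  n_shared  shared_fraction
SIM-01      alpha  nt        64               64        1
```

All 64 post-transplant expanded clonotypes were present at baseline — as
expected here, since the generator's default persistence probability for
expanded clones is 0.9 and boosted survivors dominate the expanded set.

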