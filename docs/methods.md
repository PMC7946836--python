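# Methods

## Scope and data model

The package analyses bulk TCR-seq clonotype tables from paired samples of
the same patient and chain (baseline vs post-transplant). A clonotype is a
CDR3 amino-acid string with optional nucleotide junction and V/J gene
labels plus a read count; all statistics are functions of the clone
frequency vector `p_i = count_i / total_reads`. Upstream processing (raw
read handling, V(D)J annotation, UMI collapsing, error correction) is
assumed done by the tool that produced the table; duplicate rows sharing a
clonotype key are therefore merged by summing counts at read time.
Nonproductive CDR3s (containing `*`) are retained at I/O time so that
reading and writing is lossless; they are excluded only by stages that need
amino-acid sequence (kernel similarity, top-expanded selection).

Clonotype identity has two key modes. `nt` keys on
`(v_call, j_call, cdr3_nt)` and is clonotype-faithful; `aa` keys on the
CDR3 amino-acid string alone and merges convergent rearrangements, so any
overlap fraction computed in `aa` mode is an upper bound on the `nt`-mode
value. The default is `nt` whenever nucleotide junctions are available.
Sample metadata is never inferred from file content — it comes from
explicit arguments or the cohort manifest — because heuristic parsing of
filenames is a classic source of silent sample swaps.

## Depth matching

Richness and entropy estimates grow with sequencing depth, so paired
comparisons are made after the deeper member of each pair is subsampled to
the shallower member's read count. Subsampling draws reads **without
replacement** — a multivariate hypergeometric draw over the clone count
vector — because the target is the composition of the observed read
multiset at lower depth, not a bootstrap of the frequency estimate.
(Sampling with replacement would inflate count variance; it is documented
here as the alternative and deliberately not implemented.) Each of the
`n_iterations` (default 100) iterations uses a seed derived
deterministically from `(master seed, iteration index, sample_id)`, making
cohort runs reproducible and independent of pair processing order.
Per-iterate statistics are summarized as median with min/max extremes
(mean also reported); the median is the headline summary because it is
robust to the skewed iterate distributions that heavy-tailed repertoires
produce.

## Rényi spectrum

`H_q = ln(Σ p_i^q)/(1−q)` in nats, with the three limits computed by their
own closed forms: `H_0 = ln S`, `H_1 = −Σ p_i ln p_i`,
`H_∞ = −ln max p_i`. The q=1 case is never approximated by letting q
approach 1 numerically. The general case is evaluated as
`logsumexp(q·ln p)/(1−q)` for numerical stability at large q. The default
order grid is {0, 0.25, 0.5, 1, 2, 4, 8, 16, 32, 64, ∞}, a geometric ladder
spanning the rare-clone-sensitive and dominance-sensitive ends of the
spectrum; it is configurable. Default profile depths are 3,000 reads for
the α-chain and 9,000 for the β-chain, capped at a pair's matched depth.

## Expansion

A clone is expanded iff `count/total_reads > threshold` (strict), default
threshold 1/1,000. The expanded proportion divides by unique clonotypes
(richness); `expanded_read_fraction` gives the read-weighted companion
number. Expansion is computed on full-sample frequencies by default: under
pure subsampling the expected frequency of each clone is unchanged, so the
call is depth-invariant in expectation, while the realized count of
*detected* expanded clones does vary with depth — `threshold_curve` with a
`SubsampleSpec` provides the per-iterate, depth-matched version for strict
cross-sample comparability. Both modes exist because either convention is
defensible; results tables always state which was used.

## Triplet kernel and clustering

Similarity between CDR3s is the cosine-normalized spectrum kernel on
contiguous amino-acid 3-mers: `K(s,t) = Σ_u c_s(u)c_t(u)`,
`sim = K(s,t)/√(K(s,s)K(t,t))`. This is the plain unweighted spectrum
kernel; gap-weighted or multi-length substring variants exist in the string
kernel literature but the unweighted triplet form already satisfies every
constraint this analysis needs (triplet sharing, symmetric similarity in
[0,1], and minimal control clustering at the 0.80 threshold — verified
empirically by `calibrate_control`, which yields a median clustered-node
fraction of 0 over motif-free random CDR3 sets). The edge rule is
inclusive (`sim ≥ threshold`). A cluster is a connected component with ≥ 2
nodes; singletons are not clusters, since counting them would make
"minimal clustering of controls" unmeasurable. Clustering operates on the
top 50 expanded CDR3 amino-acid sequences per sample, ranked by descending
frequency with lexicographic tie-break, after pooling counts of clones
sharing an amino-acid CDR3.

## Paired persistence

`shared_expanded_fraction` counts post-treatment expanded clonotypes whose
key occurs in the baseline repertoire at **any** frequency — presence, not
expansion, at baseline is the question. The full baseline is used (no
subsampling): membership testing does not need depth control the way
diversity does, and subsampling the baseline could only delete evidence of
presence. When no post clone is expanded the fraction is NaN, reported as
such rather than 0, since the quantity is undefined.

## Synthetic paired repertoires

The generator replaces inaccessible patient data and defines the regime in
which the pipeline is validated.

*Baseline.* `n_clones_bl` clonotypes with sampling weights
`w_r ∝ r^(−s)` (Zipf, default exponent s = 1.3; log-normal behind a flag),
sampled at `total_reads_bl` reads as `1 + multinomial(total − n, w)` — the
+1 floor conditions on every clone being observed, so realized richness
equals `n_clones_bl` exactly and is declared in the ground-truth record.
CDR3s are uniform-random over the 20-letter alphabet at lengths 8–20,
unique within a cohort, with nucleotide junctions produced by random
reverse translation (standard codon table) and random V/J labels; the
deliberate absence of positional amino-acid bias means any clustering
signal is fully controlled by the motif-family parameters.

*Transplant.* Each baseline clone survives with probability
`persistence_rho` (default 0.9) if it was expanded at baseline,
`bottleneck` (default 0.4) otherwise. Dominant marrow clones are
overwhelmingly recaptured after autologous transplantation — the graft is
the patient's own mobilized compartment — which motivates the high default
for expanded clones. Survivors are re-ranked in baseline order and
reassigned weights from the same Zipf law over the compacted ranks,
modelling refilling of the emptied niche by homeostatic proliferation;
keeping the raw conditional baseline weights instead would make
post-transplant dominance *fall* whenever the single largest clone happens
to die, an artefact of the heavy tail rather than a property of the
biology being emulated. Surviving baseline-expanded clones additionally
have their weights multiplied by `expansion_boost` (default 5), modelling
antigen-driven re-expansion; boosting all survivors equally would cancel in
normalization. `n_novel_post` novel clonotypes (default 1,000, i.e. 20% of
baseline richness — the CLI scales this with `--clones`) enter at the
trailing ranks, i.e. at low frequency, standing in for new naïve-derived
specificities without asserting their biology. Post counts use the same
+1-floor multinomial at `total_reads_post` (default 20,000 vs 50,000 at
baseline, reflecting the consistently shallower post-treatment libraries).

*Motif families.* A family is a full-length template CDR3 (drawn at the top
of the length range, 20 residues) plus single-substitution variants at
positions outside an intact core window of `family_core_length` (default
6) residues. Members therefore share the core and nearly all triplets:
template–variant similarity stays ≥ 0.8 for 20-mers, so each family forms
a star component through its template at the default threshold. A lone
6-mer embedded in otherwise random long sequences would sit far below the
0.80 cosine threshold (≈ 4 shared triplets of ~18), so near-duplicate
families are the construction under which "clones sharing an implanted
core cluster together" is actually detectable by a triplet kernel.
Families are assigned round-robin to the top-ranked clones so the planted
signal lands among the expanded set that clustering operates on.

The ground-truth record (surviving/novel/expanded key sets, realized
persistent-expanded fraction, family membership, count floor) is emitted
with every pair and is consistent with the emitted repertoires by
construction, enabling exact parameter-recovery tests.

What the generator does **not** emulate: V/J gene usage bias, CDR3 length
and composition bias, sequencing error (tables are assumed
error-corrected upstream), convergent recombination, and any dependence of
survival on clone identity beyond the expanded/unexpanded dichotomy.
Passing tests therefore demonstrate correctness of the statistical
machinery under a controlled heavy-tailed regime, not fidelity of any
biological parameter estimate on real data.

## Cohort pipeline

`run_cohort` resolves one BL + one post sample per (patient, chain) from
the manifest, then runs depth matching, richness summaries, Rényi profiles,
threshold curves (on matched iterates, over a log-spaced frequency grid
restricted to thresholds above 1/matched-depth), expansion calls, top-50
clustering, and persistence, writing one TSV per stage plus a JSON
metadata echo (package version, full configuration, seed) and SVG figures.
Numeric output uses a fixed `%.10g` float format and deterministic SVG
settings, so identical inputs and seed reproduce every file byte for byte.

Across patients, baseline vs post richness is compared with a two-sided
paired t-test on full-sample richness. The p-value is reported unadjusted
and labelled as such; Bonferroni and Holm adjustments are available
explicitly (`adjust_pvalues`) for users testing multiple chains or metrics,
because silently building one adjustment convention into the table would
hide the analyst's multiplicity decision. Zero-variance paired differences
raise a degenerate-input error instead of emitting an undefined statistic.

## Numerical and edge-case choices

- Frequencies are validated to sum to 1 within 1e-9; zero or negative
  frequencies are rejected rather than silently dropped.
- Rényi monotonicity holds to ~1e-9 in floating point; tests allow that
  slack.
- Self-similarity of the kernel is exactly 1.0 in IEEE arithmetic (integer
  kernel values; `sqrt` of a perfect square is exact).
- `subsample` at full depth returns counts identical to the input
  (hypergeometric support collapses to a point).
- Empty repertoires: richness 0 is legal; expansion and depth matching on
  empty repertoires raise, since their statistics are undefined.
- Problem sizes in the validation suite (cohorts of 2–5 patients, 10–100
  subsample iterations, repertoires of 10³–10⁴ clones) were chosen as the
  smallest at which the targeted properties are statistically unambiguous.

## Known limitations

- The `aa` key mode conflates convergent rearrangements; nt-mode requires
  nucleotide junctions, which the Decombinator dialect as consumed here
  does not carry.
- The Decombinator reader fixes one field layout (five classifier fields,
  abundance, CDR3-aa); other layouts need a new dialect, which the
  `--dialect` flag namespaces.
- The spectrum kernel treats amino acids as symbols; no physicochemical
  similarity between different residues is modelled.
- Iterative subsampling controls depth but not library-preparation or
  amplification biases between samples.
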