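# Methods

This note documents the statistical models implemented in `bxdnet`, the
assumptions behind them, the synthetic-data generator used to validate the
pipeline, and the numerical and design choices that were genuinely open.

## S-score differential-response statistic

The S-score compares one strain's two arrays (reference = saline,
alternative = ethanol) directly at the probe level. Each probe contributes

    z_j = (I_Bj − I_Aj) / ε_j ,   ε_j = sqrt(γ² (I_Aj² + I_Bj²) + 2 σ²_add)

and a probe-set's score is `Σ_j z_j / √N`. The error model combines a
multiplicative component (coefficient γ, default 0.1 — roughly a 10 %
coefficient of variation per probe) with an additive background floor
(σ²_add, default 1.0, in squared intensity units), the standard two-chip
error structure for oligonucleotide arrays. The published S-score software
derived its scale constants from vendor-specific chip statistics; this
implementation instead preserves the property every downstream statistic
relies on — **scores are N(0, 1) when no expression change exists** — by an
explicit studentization step: the score vector of each comparison is
centered and scaled by its trimmed mean and trimmed standard deviation
(2 % per tail by default). The trimmed SD of Gaussian data underestimates
σ, so it is divided by the truncated-normal consistency factor
`sqrt(1 − 2 z_f φ(z_f) / (1 − 2f))`; without this correction the null SD
would land near 1.12 rather than 1. Trimming makes the calibration robust
to a small fraction (≲ 2 f) of genuinely changed probe-sets; when the
responsive fraction is larger the null is mildly over-dispersed and the
calls become conservative, never anti-conservative. Replicated chip pairs
combine as `Σ_pairs S / √(n_pairs)`, which keeps the null variance at 1.

## Responsome calling

Probe-sets absent in ≥ 95 % of samples are excluded first (boundary
inclusive); when detection calls are unavailable a proxy is used (present =
log2 expression ≥ 6.0). Per probe-set, two-sided normal p-values of the
per-strain S-scores are aggregated with Fisher's combined probability test,
`X = −2 Σ ln p_i` on 2k degrees of freedom, which rewards consistent
moderate responses across the family as well as large responses in a few
strains. Significance is assessed against a permutation null: probe-set
labels are shuffled independently within each strain column — preserving
every strain's marginal score distribution while destroying cross-strain
alignment — and the p→Fisher pipeline recomputed (1,000 permutations by
default; add-one convention, so p ≥ 1/(n+1), ties counted as ≥). Empirical
p-values are converted to q-values with Storey's procedure; π₀ is the
median of `#{p > λ}/(m(1−λ))` over λ ∈ {0.05, …, 0.95} (the median is used
in place of the original spline smoother; for fewer than 100 p-values π₀
falls back to 1, i.e. Benjamini–Hochberg). Responsive means q ≤ 0.05.

## Paraclique networks and hubs

Co-expression graphs are unweighted: vertices are probe-sets, an edge is
present iff `|Pearson r| ≥ 0.7` across strains (inclusive; at n = 27 this
corresponds to a two-sided correlation p ≈ 4.8e-5). Modules are
paracliques: an exact maximum clique core plus, in a single pass, every
remaining vertex adjacent to at least `⌈g·|core|⌉` core vertices (glom
factor g = 0.7, boundary inclusive). Extraction iterates — extract, remove
members, repeat — until the maximum clique falls below `min_core` (5);
paracliques smaller than `min_size` (10) are discarded; results are
vertex-disjoint. The glom pass is evaluated against the core clique only,
the closest literal reading of glomming "onto the clique"; iterating to
closure is not done. Maximum clique is exact branch-and-bound with a
greedy-coloring bound; among maximum cliques, a refinement pass returns the
lexicographically smallest vertex set, making extraction fully
deterministic.

Hubs are ranked by degree within the induced `|0.7|` subgraph and
betweenness centrality within the induced `|0.9|` subgraph — at the looser
threshold the two measures are nearly redundant (Spearman ρ typically
> 0.9), while the stringent threshold isolates nodes bridging dense
subnetworks. Both are reported raw and scaled to [0, 1] (by n−1 and
(n−1)(n−2)/2). Enrichment of a paraclique for responsive probe-sets uses
the one-tailed hypergeometric test against the detection-filtered universe,
Bonferroni-corrected over the number of paracliques (enriched at adjusted
p ≤ 0.05).

## eQTL scans, tiers, intervals, hotspots

Each trait is regressed on the additive genotype code (B=0, D=1) at every
marker; `LOD = −(n/2) log₁₀(1 − R²)`. With complete RI genotypes this
coincides with Haley–Knott regression at the markers, so no pseudomarker
grid is used. `1 − R²` is floored at 1e-12 so a perfect fit stays finite;
monomorphic markers get LOD 0. Genome-wide p-values come from per-trait
strain-label permutations of the maximum LOD (1,000 by default, add-one
convention); significant means p ≤ 0.01 and suggestive p ≤ 0.63 (the
conventional one-false-positive-per-scan level). A peak is cis when it lies
on the trait's chromosome strictly within 5 Mb of the gene; unannotated
traits are classed trans. Support intervals span the outermost markers
within 1.5 LOD of the peak, extended one marker beyond on each side and
clipped at chromosome ends.

Hotspots: suggestive trans eQTL are counted in half-open 10 Mb bins
anchored at 0 per chromosome. The null reassigns every eQTL to a uniformly
random marker (so marker density shapes the null) and records the most
populous bin; over 10,000 permutations, a bin is a significant trans-band
when its observed count strictly exceeds the 95th percentile of that
max-count distribution. The consensus interval of a band is the contiguous
run of markers contained in ≥ 80 % of member support intervals that also
contains the modal member peak (the modal-peak requirement resolves the
ambiguity when two disjoint runs qualify); it can be empty.

## Candidate ranking

Genes inside a consensus interval score points across four categories
(defaults chosen so each category can contribute comparably, all
configurable): non-synonymous SNPs 3 (else any coding SNP 1); significant
cis eQTL 3 (suggestive 1), taking the better of the basal and S-score
datasets; responsiveness (q ≤ 0.05) 2; membership in the trans-band's own
network 2, plus up to 2 each for scaled connectivity and scaled centrality
in the gene's resident network. Because probes are designed against the B6
reference, a SNP under a probe can fake a cis eQTL with B6 as the
increaser allele; such cis evidence carries a −2 penalty, applied at most
once and only when a probe SNP exists, a cis eQTL exists and B6 is the
increaser. Categories are summed (not lexicographically prioritized); ties
break by scaled connectivity, then gene symbol.

## PC-traits and phenotype correlation

A trans-band's members-by-strains expression block is row-centered and
row-scaled; PC1 scores (which have mean 0 by construction) form the
synthetic trait, signed so the majority of loadings are positive. Observed
Pearson correlations against each phenotype are tested by permuting the
PC-trait's sample order (1,000 times, add-one), two-sided on |r| since both
signs are of interest; significance is p < 0.01. Phenotypes are matched
pairwise-complete with a minimum of 5 shared strains. PC-traits are built
from the basal (saline) expression of band members, which carries both the
heritable and the module-activity variation that planted phenotypes track.

## Synthetic-data generator

The generator emulates the study conditions at desk scale: 27 strains, 5
chromosomes × 20 markers at 10 Mb spacing, 2,000 probe-sets with 11 probes
each. Genotypes are independent two-state Markov chains per chromosome
(recombination probability 0.25 per 10 Mb interval by default; no
RI map expansion is modeled, since the pipeline consumes genotypes, not
crossing designs). Summarized log2 expression is

    x = baseline + a_cis·g + a_trans·g_master + Σ_k load_k·F_k + noise

with the ethanol arm adding planted response terms
`shift + b·g_marker`. Gene-by-strain noise (SD 0.3) is **shared** between a
strain's two arms — it represents strain-level biological variation, which
cancels from the within-strain treatment comparison — while a smaller
arm-specific component (SD 0.05) represents animal pooling and technical
variation and is what actually contaminates S-scores. Probe-level
intensities are `2^x · affinity_j · exp(N(0, 0.1))` with per-probe
log-normal affinities (σ = 0.5) fixed across arrays, mimicking probe
effects without modelling summarization internals.

Default planted structure: three 40-gene modules with loading 1 and latent
factor SD 0.6 (twice the shared noise SD, putting within-module population
correlation at 0.8); 50 cis eQTL of 2.0 log2 units; one master locus
(middle of chromosome 2, i.e. 100 Mb) whose 30 targets — members of module
M1 — receive a basal trans effect of 1.0 and a genotype-dependent ethanol
response of 0.4 log2 units, making the trans-band visible in both the basal
and the differential-response eQTL data and turning M1 into an S-score
co-expression network; 200 independent responders with ±0.2 log2 shifts
(≈ |S| = 3 under the default error model); and a regulator gene located at
the master marker, member of M1, with a cis eQTL and a genotype-driven
response — the configuration candidate ranking should place first.
Phenotypes are linear in a module's total planted activity (latent factor
plus its average genetic drive) with noise SD 0.5; at least one phenotype
is always pure noise as a negative control. Latent factors are derived
deterministically from the truth record's seed so the expression and
phenotype generators see identical realizations.

What the generator does **not** emulate: batch effects, array-level
artifacts, detection-call failures (all simulated genes are expressed),
probe-target SNPs (SNP evidence enters ranking only through optional
tables), hierarchical pooling variance (folded into the noise SDs), and
linkage disequilibrium structure beyond the first-order Markov chain.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the stated model, not robustness to real-array pathology.

## Numerical choices and problem sizes

- Permutation p-values everywhere use the add-one convention and count ties
  as exceedances; they are never exactly 0.
- LOD ties resolve to the lowest genomic coordinate; maximum-clique ties to
  the lexicographically smallest vertex set; zero-variance expression rows
  are dropped from graphs and PC-traits with warnings.
- The hotspot percentile comparison is strict (">"), reading "exceeded"
  literally.
- One global seed expands into per-stage seeds through a fixed
  `SeedSequence` spawn order (data, responsome, eqtl-saline, eqtl-sscore,
  hotspots, phenocorr); identical seed + config gives byte-identical
  outputs.
- The test suite and the acceptance script run everything at reduced but
  statistically adequate sizes — 150–500 permutations for calibration
  suites, 2,000 for hotspot nulls, 10 seeded replicates for recovery rates,
  250–800 probe-sets for planted-structure datasets — sizes chosen so tail
  quantiles remain meaningful for the thresholds being exercised (e.g.
  300 permutations resolve p ≤ 0.01). A full default run (2,000 probe-sets,
  1,000/10,000 permutations) completes in well under a minute on one core.

## Known limitations

- The S-score implementation is contract-level: it preserves the N(0,1)
  null and the sign convention, not the numeric output of the historical
  software, whose internal scale constants are tied to vendor chip
  statistics.
- With a large responsive fraction (≳ 20 % of probe-sets) the studentized
  null becomes conservative (see above).
- The permutation axis for the responsome null (within-strain shuffling of
  probe-set labels) is one of several defensible readings of "permuting the
  S-score matrix"; it was chosen because it preserves per-strain marginals.
- Hotspot detection treats bins independently; overlapping regulatory
  signals across adjacent bins are reported as separate bands.
- Candidate ranking sums category points; a lexicographic prioritization
  across categories would order sparse-evidence genes differently.
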