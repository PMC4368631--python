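# Methods

## Scope and model

`promdiff` quantifies how promoter-proximal histone-modification
occupancy differs between two small groups of ChIP-seq samples —
the motivating design is monocyte chromatin from 2 sepsis patients vs
4 healthy controls, profiled for two active marks (H3K4me3, H3K9ac) and
one repressive mark (H3K27me3). The analysis chain is:

1. aligned reads (BED6 or SAM text) → strand-aware deduplication →
   fragment extension → per-base coverage → reads-per-million scaling →
   1000 bp moving-average smoothing → cross-sample quantile
   normalization → TSS meta-profiles in 50 bp bins;
2. ±1 kb promoter windows around every annotated TSS → genes × samples
   raw count matrices per mark;
3. per-mark differential occupancy with a negative-binomial conditional
   exact test; selection of genes changed in ≥ 1 mark;
4. complete-linkage hierarchical clustering of the selected genes on
   their per-mark log2 fold-change vectors, cut into k flat clusters,
   each labeled silenced / active / poised_up / poised_down / mixed;
5. hypergeometric gene-set over-representation per cluster and
   Mann–Whitney comparison of a gene group's fold changes against the
   genome background.

## Coordinate conventions

All coordinates are 0-based, half-open; interval length is `end − start`.
A minus-strand gene's TSS is `end − 1` (the 5′-most transcribed base).
Browser-style printed ranges are imported as `start=first, end=second`,
so a printed pair such as 102,282,711–102,874,166 spans exactly
591,455 bp. Promoter windows are strand-aware mirrors: `[t−u, t+d)` on
plus, `[t−d+1, t+u+1)` on minus (u = upstream, d = downstream, both
1000 bp by default), which makes all counting exactly invariant under
genome reflection.

## Count model and differential test

Raw promoter counts `k_ij` are modeled NB with mean `s_j q_i(group)` and
variance `μ + α_i μ²`.

* **Size factors** are median-of-ratios: `s_j = median_i k_ij / g_i`
  over genes with all-positive counts, `g_i` the per-gene geometric
  mean. Factors are reported unscaled (their geometric mean is a
  diagnostic, not forced to 1).
* **Dispersion** is method-of-moments on size-factor-normalized counts:
  `α_i = max(10⁻⁸, (v_i − q_i ξ)/q_i²)` with `ξ = mean_j 1/s_j`. `v_i`
  is the *within-group* residual variance pooled across the two groups
  (n − 2 denominator), so a genuine patient–control shift is not
  mistaken for overdispersion; with only 2 + 4 samples this estimate is
  noisy, so by default it is shrunk conservatively to
  `max(gene-wise, trend)` where the trend is a log–log linear fit of α
  on the mean. The floor 10⁻⁸ makes constant genes Poisson-like rather
  than degenerate.
* **Test**: with group-summed counts `K_A, K_B` and group-summed size
  factors `S_A, S_B`, the p-value conditions on `K_S = K_A + K_B`:

      p = Σ_{a+b=K_S : P(a)P(b) ≤ P(K_A)P(K_B)} P(a)P(b)
          / Σ_{a+b=K_S} P(a)P(b)

  where `P` are NB masses with means `q̂ S_A`, `q̂ S_B`
  (`q̂ = K_S/(S_A+S_B)`) and the gene's dispersion. Evaluation is in
  log space (stable to `K_S ≈ 10⁶`); a relative slack of 10⁻¹⁰ in the
  log-probability comparison keeps exactly tied splits (e.g. mirror
  splits under symmetric designs) on the inclusive side. Dispersion 0
  degrades to the Poisson case, where the test coincides with the
  probability-ordered two-sided binomial conditional test.
* **Fold change** is `log2((mean normalized patient + 1)/(mean
  normalized control + 1))`; the pseudocount of 1 normalized count
  keeps all-zero genes at exactly 0 and bounds extreme ratios.
* **Selection**: a gene is significant if `|log2FC| ≥ 1` and
  `p ≤ 0.05` for at least one mark. No multiple-testing correction is
  applied to this per-gene selection by default (the thresholds are raw,
  configurable, and BH adjustment is available in the set-statistics
  layer). The source analyses state the fold-change-2 / p ≤ 0.05 rule in
  one place and p < 0.01 in another; 0.05 is the default and the cutoff
  is a config knob.

## Coverage processing

Duplicate reads are collapsed to one per (chromosome, 5′ position,
strand) before any coverage or counting step (a PCR-duplicate guard;
disable with `deduplicate: false`). Reads are extended to 200 bp
fragments anchored at their 5′ end — the sonication size range in the
emulated protocol is 150–600 bp and no extension length is stated, so
the conventional midpoint 200 is the default and configurable — but a
fragment is never shorter than the read itself. Smoothing uses a
centered moving average whose window is widened to odd (1000 → 1001);
at chromosome ends the window truncates rather than padding, so no
signal is invented outside the chromosome.

Quantile normalization is the classic rank-based procedure applied
genome-wide to the concatenated per-base values, independently within
each mark (samples of a mark are forced onto the mark's average
distribution; a flag can pool marks instead). Ties within a sample
receive the mean of the reference values their rank span covers. Note a
consequence of that tie rule: when samples have *different* tie
structures (e.g. different numbers of zero bases), their sorted value
vectors agree only up to tie-block averaging and a second application
is no longer an exact no-op; for tie-free signal both the
identical-distribution property and idempotence are exact, and the
package's tests verify them in that regime. `ties="stable"` is provided
for callers who need the exact fixed-point behavior at the cost of
splitting tied inputs.

Meta-profiles orient every ±flank window 5′→3′ (minus-strand windows
reversed), average per-base signal within 50 bp bins and then across
TSSs; TSSs closer than the flank to a chromosome end are skipped with a
warning.

## Clustering and phenotype labels

Clustering operates on the genes × marks log2FC matrix (the z-scaled
count matrix is computed only for heatmap export, averaged within
groups). The agglomeration is complete linkage on Euclidean distances,
written out explicitly so that ties break deterministically (the
lowest-index pair merges first); merge heights are exactly those of a
naive O(n³) reference and match SciPy's `linkage(..., "complete")` on
tie-free data. k is a required parameter: the motivating study reported
25 clusters for 743 genes but no cut rule, so no default could be
defended; the tests and analysis scripts use small k on planted
structure. Cluster phenotypes compare per-mark mean log2FCs against a
magnitude threshold t = 0.5 log2 units (configurable): silenced = both
active marks ≤ −t and the repressive mark ≥ +t; active = the mirror;
poised_up/down = all marks concordant; otherwise mixed.

## Set statistics

Over-representation uses the upper-tail hypergeometric probability
`P(X ≥ overlap)` with the universe defined as all genes with a
quantified promoter (only those could have been selected), sets
intersected with the universe first, and optional BH adjustment across
sets. The group-vs-background comparison is the two-sample Mann–Whitney
U (the design is unpaired): exact enumeration when `n₁n₂ ≤ 400` with no
ties, otherwise the normal approximation with mid-rank tie correction
and continuity correction; a paired t-test is provided separately for
paired designs.

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes, not sequence-level realism. Genes are placed evenly with
jitter on a toy genome (defaults: 4 chromosomes × 2 Mb, 2000 genes),
strand-alternating, promoter windows disjoint, TSSs ≥ 2 kb from ends.
Baseline promoter intensities are lognormal across genes (σ = 1, a
typical promoter-strength spread) and normalized so promoter reads are
70% of the library; the rest is uniform background. Archetype genes
("silenced": −2/−2/+2 log2 on H3K4me3/H3K9ac/H3K27me3; "active": the
mirror; 5% of genes each) shift patient means only. Per-sample counts
are NB (dispersion 0.05, a clean-replicate ChIP-seq value; 0 = Poisson)
with true depth multipliers cycling {0.5, 1, 2} so size-factor recovery
is testable. Promoter fragment midpoints are triangular over TSS ± 1 kb,
which yields the peaked TSS meta-profile real marks show; input
libraries are pure background. One RNG stream per (sample, mark) is
spawned from the master seed (`SeedSequence(seed, spawn_key=(2,
mark_index, sample_index))`), so adding samples never changes existing
data; regeneration under a fixed seed is byte-identical.

What the generator does not emulate: mappability and alignment
artifacts, copy-number and GC biases, input-dependent enrichment biases
(the emulated protocol describes none), multi-TSS transcripts, and
promoter-density effects of real annotations. On dense toy genomes a
substantial share of uniform background falls inside promoter windows,
which dilutes apparent fold changes (visible in the read-level analysis
as implanted |log2FC| = 2 attenuating toward ~1–1.5); recovery tests
therefore validate the machinery under the stated conditions, not
effect-size fidelity on real genomes.

## Problem sizes and numerical choices

The shipped analyses and tests run at desk scale by design: read-level
runs use ~200 genes on 2 × 300 kb chromosomes with 20k-read libraries;
count-level statistical checks use the full 2000-gene design (5000
genes for null calibration). Tolerances: dispersion floor 10⁻⁸;
exact-test tie slack 10⁻¹⁰ in log space; quantile-normalization
idempotence verified at 10⁻¹⁰–10⁻¹². Degenerate inputs are defined, not
special-cased: zero totals give p = 1, all-zero genes get zero log2FC
and floor dispersion, constant rows z-scale to zeros, sd-zero guards
avoid division warnings.

## Known limitations

* The exact test assumes a single shared dispersion per gene across
  groups and is conservative with n = 2 vs 4 (shrinkage takes a
  maximum); power claims transfer to real data only qualitatively.
* Overlapping promoter windows in real annotations are each counted
  independently, so a read can contribute to several genes.
* k for the cluster cut is user-chosen; no stability or model-selection
  criterion is provided.
* Quantile normalization is genome-wide per-base; for large genomes a
  binned mode would be needed (promoter counting does not depend on it).
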