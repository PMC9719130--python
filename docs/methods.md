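# Methods

This note documents the models, conventions and design choices behind
`cfmeth`: what each stage computes, which knobs matter, what the synthetic
data generator emulates, and where the genuinely open decisions were made.

## Coordinate and counting conventions

All intervals are 0-based half-open (BED). The window universe (methylation
blocks: runs of adjacent CpGs with concordant methylation) is sorted by
(chrom, start), non-overlapping, with unique window IDs — violations raise at
construction.

Fragments are assigned to the window containing their midpoint,
`(start + end) // 2`, via binary search over the sorted universe. Over a
non-overlapping universe this guarantees at most one count per fragment and is
deterministic; the upstream fragment counter the workflow emulates does not
document its overlap policy, so the midpoint rule is this package's choice.
Counting conserves mass: assigned + unassigned + unknown-chromosome equals the
input fragment count, and the tallies are reported.

`library_size` is the number of window-assigned fragments over the *full*
universe, frozen at count time. RPKM denominators therefore do not change when
the matrix is later subset to DMR windows, which keeps 5-mC scores stable
under re-subsetting. RPKM uses window length in bp (`end − start`), not CpG
count.

## Background combination and masking

The hematopoietic background per window is the weighted sum
β̄_w = Σ_c w_c β_{c,w} over cell types, with weights normalized to sum to 1.
Weights are an input (in real use, predicted cell-type contributions to
healthy cfDNA); the simulator emits its own ground-truth weights. A window
with any missing cell-type β is "not evaluable" and never kept.

The keep rule is β̄_w ≤ τ with default τ = 0.15. The boundary β̄ = τ is
*kept*; the source workflow describes the exclusion as "> τ" in one place and
the kept set as "< τ" in another, so the boundary is a convention and is
documented as such. Kept sets are nested in τ.

The threshold scan splits the healthy cohort into two disjoint halves at
random under a seed (an odd sample is dropped), computes case-cfDNA and
case-tissue log2 fold-changes against the two halves with an ε = 0.5 RPKM
pseudocount (symmetric, avoids division by zero), and selects the τ
maximizing Spearman correlation over kept windows (ties → smallest τ; a τ
keeping < 10 windows is ineligible).

## Differential methylation

* **Low-count filter.** A window must have a nonzero count in at least
  ⌈0.2 · n_samples⌉ samples. The "low read counts … < 20% of the total number
  of samples" rule is ambiguous; presence-in-≥20%-of-samples is the only
  depth-scale-free reading, with the boundary kept.
* **TMM.** Reference sample = the one whose upper-quartile count fraction is
  closest to the cohort mean. Per sample, M and A statistics over windows
  nonzero in both; rank-based double trimming (30% on M, 5% on A, both tails,
  the conventional defaults); factor = 2^(precision-weighted mean of retained
  M) with inverse asymptotic binomial variances as weights; factors rescaled
  to geometric mean 1. A sample sharing no nonzero window with the reference
  gets factor 1 with a warning.
* **log-CPM.** `log2((c + p_s) / (eff_s + 2 p_s) · 1e6)` with effective
  library `eff_s = N_s · factor_s` and per-sample prior `p_s = prior · eff_s ·
  1e-6` — the prior is specified on the CPM scale (default 0.5 CPM). Tying
  the prior to depth makes the transform exactly invariant to jointly scaling
  one sample's counts and library size, which a constant prior cannot be.
* **Moderated t.** Per window, the two-group OLS difference (log2FC) and
  residual variance s² on d = n₁+n₂−2 df. The prior (d₀, s0²) is fitted by
  the method of moments on log s² (digamma/trigamma matching; trigamma
  inverted by Newton iteration). Posterior variance
  s̃² = (d₀s0² + d s²)/(d₀+d); t = log2FC / (s̃ √(1/n₁+1/n₂)) on d₀+d df
  (normal when d₀ = ∞; d₀ = 0 reproduces the ordinary pooled t exactly).
  The design here is two-group without observational weights, so weighted
  least squares reduces to OLS; voom-style precision weights are a possible
  extension, not implemented.
* **Calling.** Hyper: adj p < α and log2FC > 1; hypo symmetric. Defaults
  α = 0.1, |log2FC| > 1. BH adjustment via statsmodels.

Tissue DMRs (tumor vs normal tissue) use the same machinery *without* the
background mask.

## Overlap validation

The null resamples window IDs uniformly without replacement from the tested
universe (background-depleted, low-count-filtered) — windows are the testing
unit, so ID resampling rather than coordinate shuffling is the appropriate
null, and it is exactly hypergeometric, which the tests exploit.
p = #(null ≥ observed)/n_perm with no +1 correction, matching the published
formula; display floors at 1/n_perm ("< 1e-04" at 10,000 draws). Sampling is
chunked Gumbel-top-k, seeded and deterministic.

## 5-mC score and detection

The baseline downsamples each healthy sample to `target_depth // n` fragments
(binomial thinning in the counts route — the count-level equivalent of uniform
fragment subsampling), pools, and computes RPKM once. The pipeline default for
`target_depth` is n × the shallowest healthy library, so every sample can
reach the common depth; the genome-scale analog (tens of millions of pairs)
is configurable.

Score = median |RPKM_sample − RPKM_baseline| over the scoring DMR set;
midpoint median for even counts. The default scoring set is the
tissue-validated hyper-DMRs, with a switch to the full cfDNA hyper set.

Detection thresholds are the healthy-cohort maximum. The 5-mC rule is strict
">" and the t-MAD rule "≥" — the two conventions are encoded per marker
because the source descriptions differ, and both are configurable. VAF-like
markers use a fixed floor (default 0.01%) with "≥". Missing marker values are
not-evaluable, never negative, and drop out of denominators at both sample
and patient level (a patient is positive iff any sample is).

## Monitoring

The therapy-line nadir is the running minimum over *strictly earlier*
timepoints, making the ≥25%-above-nadir call prospective (a whole-line nadir
would peek into the future; causality is asserted by prefix-replay in tests).
A nadir of exactly 0 makes the ratio undefined; any later positive value then
triggers the call with infinite percent rise — a rise from undetectable is
maximal evidence. For the paired test, a pair is (first timepoint of the
line, first radiologic-PD timepoint) in lines ending in switch or death;
two-sided Wilcoxon signed-rank (exact for small n; a warning below 6 pairs).
Lead time = calendar days from call to radiologic PD; calls after PD are
missed and excluded from medians.

## t-MAD

Counts in fixed 1-Mb bins are scaled to proportions; the reference is the
per-bin median proportion of a healthy panel; log2R = log2((p+ε)/(ref+ε)),
ε = 1e-9. Bins with zero reference or in the top 1% of panel
coefficient-of-variation are blacklisted; after removing the 2% most extreme
|log2R| bins, the score is median |log2R| — deviation from 0 (neutrality),
not from the sample median, so a mostly-altered genome scores high. This
panel-normalization scheme deliberately avoids HMM segmentation and
GC/mappability correction: the quantitative readout is the instability score
itself, and platform-specific bin biases cancel when each platform is
normalized against its own panel. The blacklist/trim parameters are this
package's operationalization of "trimmed"; both are configurable. At least
100 usable bins are required.

## The synthetic data generator

`SimulationConfig` defaults define the emulated study: 20,000 windows
(lengths 200–1,000 bp, CpG counts geometric with mean 4, a 2% sex-chromosome
fraction to exercise filters), 7 hematopoietic/solid cell types with fixed
cfDNA weights, 20 cases vs 13 healthy controls, 15 tumor and 10 normal
tissues, depth 5×10⁵ fragments/sample, negative-binomial dispersion 0.2.

* **Methylation structure.** 35% of windows are lowly methylated across cell
  types (combined β ≤ 0.15 by construction), 10% methylated in a single
  random cell type, the rest clearly methylated. 200 tumor hyper-DMRs
  (Δβ = 0.6, capped at 1) are planted only in filter-passing low-background
  windows, so with cases at tumor fraction f ~ U(0.2, 0.4) the count-space
  effect at DMRs is ≈ 2 on the log2 scale.
* **Confounders.** 300 windows with combined β in (0.2, 0.5] carry a
  case-specific non-tumor methylation shift (Δ = 0.35), modeling
  disease-associated blood-cell methylation changes. This is the package's
  modeling choice for *why* background depletion helps: such windows produce
  real case-control count differences that are not tumor-derived, and the
  β ≤ 0.15 mask removes them. Passing the mask-benefit tests shows the
  pipeline removes this class of confounding; it does not certify the
  mechanism of confounding in real plasma.
* **MeDIP enrichment.** Expected pulldown propensity
  λ_w = L_w (a + m_w · n_cpg,w) with nonspecific capture a = 0.05 — the
  simplest monotone model of immunoprecipitation of methylated fragments, a
  modeling choice rather than a measured enrichment curve. Counts are NB with
  mean depth·λ_w/Σλ (Poisson as dispersion → 0).
* **Trajectories.** f(t) = f₀ e^(−r_resp t) until resistance onset, then
  exponential regrowth; f₀ ~ U(0.10, 0.30), response 0.02–0.05/day, onset
  60–200 d, regrowth 0.015–0.035/day, sampling every 30 d for up to 720 d.
  Radiologic PD is labeled at the first sampling with f ≥ 0.35 after onset —
  a latent-fraction stand-in for imaging criteria, which guarantees molecular
  regrowth precedes the PD label by construction.
* **CNA.** Whole-chromosome gains (p = 0.3) and losses (p = 0.2) over eight
  40-Mb chromosomes in 1-Mb bins; sample tumor fractions U(0.05, 0.5); the
  MeDIP-like platform carries a fixed lognormal per-bin bias (σ = 0.3) shared
  with its healthy panel.

What the generator does **not** emulate: real fragment-length and GC biases,
fine-scale methylation haplotypes, cfDNA fragmentomics, sampling-time
irregularity, multiple therapy lines per patient, germline CNVs, and the
scale of a real universe (7.3 M blocks, tens of millions of read pairs).
Tests passing on this generator demonstrate internal correctness and the
qualitative phenomena (mask benefit, score–tumor-fraction monotonicity,
early molecular calls, cross-platform t-MAD concordance), not clinical
performance on patient data.

## Problem sizes

Default experiment sizes were chosen so each property is measured with
comfortable statistical margin at desk scale: 20 seeds for DMR
recovery/mask-benefit and score monotonicity; 1,000 replicates at 499
permutations for null calibration (configuration 3000/900/300 chosen so the
discrete hypergeometric null admits rejection rates near 0.05); 50 patients
for the monitoring property; 30 paired samples at a common depth of 150,000
fragments for cross-platform concordance.

## Known limitations

* The moderated test is the trend-free (unweighted) variant; very low counts
  at small libraries are handled by the CPM prior rather than precision
  weights.
* The baseline's binomial thinning approximates without-replacement
  downsampling; exact at full depth, negligibly different otherwise.
* t-MAD bins carry no GC/mappability correction (hook off by default); on
  real data a correction layer would precede panel normalization.
* The permutation null does not length-match resampled windows; on a
  shared-universe design the unit is the window ID, but coordinate-level
  nulls would need a different scheme.
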