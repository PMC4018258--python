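# Methods

`icdmr` identifies *consistently differentially methylated regions* (DMRs)
in tiling-array methylation data without predefined comparison groups.
This note documents the model, the estimation choices, the simulation
design and the known limitations.

## Data model

The input is a probe × sample matrix of M-values — log₂ ratios of
methylation-enriched over input DNA — with probes ordered by genomic
position. On this scale the unmethylated state sits near M = 0 (no
enrichment) and methylated DNA at positive M; across samples a probe that
is differentially methylated shows a *bimodal* distribution. β-values
(fraction methylated, in (0,1)) are accepted on input through the logit₂
link M = log₂(β/(1−β)), whose inverse is β = 2^M/(1+2^M). Missing values
are rejected rather than imputed: nothing downstream has a missing-data
mechanism.

## Per-probe mixture model

For probe *d* with sample values m_d = (m_{d,1},…,m_{d,n}), we fit a
two-component univariate normal mixture with a common variance:

    L_d = ∏_j [ (1−π) φ(m_{d,j}; μ_u, σ²) + π φ(m_{d,j}; μ_m, σ²) ]

where π is the prior weight of the methylated component and the
higher-mean component is labelled "methylated" (μ_m ≥ μ_u). Posterior
methylation probabilities p_{d,j} follow from Bayes' rule; on the log-odds
scale p = expit( log(π/(1−π)) + (μ_m−μ_u)(m − (μ_m+μ_u)/2)/σ² ).

**Estimation.** EM from a single deterministic start: split the sorted
sample at the median, use the half-means as component means, π = 0.5 and
the pooled within-half variance for σ². Convergence is declared when the
relative change of the observed-data log-likelihood falls below 1e-8
(checked every few sweeps in the compiled engine — an equal-or-stricter
stop), with a hard cap of 500 sweeps and a variance floor of
1e-6·(sample variance + 1e-12).

The single deterministic start is a substantive choice, not merely a
reproducibility convenience. On *non-differential* probes the mixture
likelihood has many local maxima; solutions that split off a few extreme
samples score higher likelihoods but produce erratic, extreme mixing
weights. The start chosen here lands in a stable "balanced split" optimum
for such probes, which keeps the null distribution of the concordance
score (below) tight and reproducible. We verified against R's `mclust`
(model "E", G = 2) on identical data that our EM attains equal or higher
likelihoods essentially everywhere; the residual sensitivity of the *null
concordance spread* to this choice is a real property of the method and
is discussed under Limitations.

**Degeneracy.** If at convergence π < 1/(2n) or π > 1 − 1/(2n), or the
input had zero variance, one component is effectively empty: the fit is
flagged degenerate and its posteriors are the constant π. A minimum of
n = 4 samples is required.

## Correction of non-biological inter-probe correlation

Adjacent tiling-array probes are correlated for two reasons: shared
methylation status of the underlying fragment (*discrete*, the signal)
and experimental spatial effects — overlapping probes, fragment size,
amplification (*continuous*, a nuisance). Only the continuous part is
removed, one probe pair at a time along each chromosome:

1. **Centralise.** Subtract from each probe its fitted weighted component
   mean π·μ_m + (1−π)·μ_u (for a degenerate fit, the mean of the dominant
   component). A scalar shift; clustering and posteriors are unchanged.
2. **Strip the discrete part of the left probe.** The adjustment constant
   κ_d is the no-intercept regression coefficient of the *raw* intensity
   on the posterior, κ = Σ_j p_j m_j / Σ_j p_j², which for binary
   posteriors is exactly the mean raw intensity of the methylated group.
   The predictor is r_d = m̃_d − p_d·κ_d (m̃ centralised). Because the
   unmethylated state sits at M ≈ 0 on these arrays, this lowers the
   methylated group onto the unmethylated level at truly differential
   probes — the discrete component is removed *completely*, at every
   methylation frequency — whereas at non-differential probes (centred at
   0, fitted means straddling it) only about half of the fitted split is
   subtracted, so the predictor retains the continuous noise that the
   next step needs. The absolute zero of the M scale is what breaks the
   otherwise unavoidable trade-off between these two requirements; κ
   computed on centralised intensities would leave a residual group gap
   of π(μ_m−μ_u) and the regression below would then remove biological
   signal (at MF = 1 it destroys it almost entirely — we measured
   sensitivity collapsing from ~0.99 to ~0.04).
3. **Weighted regression.** Regress the right probe's centralised
   intensity on r_d by weighted least squares with clustering-certainty
   weights w_j = max(p_j, 1−p_j) ∈ [0.5, 1]; the residuals are the
   corrected intensity of the right probe.

The correction is one-pass (the predictor always comes from the *raw*
left neighbour, never an already-corrected row — under an AR(1) nuisance
this is exactly the first-order innovation filter) and never crosses a
chromosome boundary; the first probe of each chromosome passes through
unchanged. The mixture model is then refitted on the corrected matrix.

## Concordance and the mirrored empirical null

Agreement of methylation status between adjacent probes d, d+1 is scored
as

    c_d = (1/n) Σ_j [ p_{d,j} p_{d+1,j} + (1−p_{d,j})(1−p_{d+1,j}) ]

— the mean probability, across samples, that the two probes agree.
c_d ∈ [0,1]; it is 1 exactly when the posteriors are binary and identical,
0.5 when either probe carries no information, and symmetric under joint
relabelling of components. Under no differential methylation the score
distribution is symmetric about 0.5, so the null is estimated *without
labels* by mirroring: scores strictly below 0.5 plus their reflections
1−s form the null sample (scores exactly 0.5 join neither side; at least
20 sub-0.5 scores are required), and the calling threshold T_α is its
empirical (1−α) quantile with linear interpolation. Differential regions
only inflate the upper tail, so the estimate is conservative.

Pairs with c_d strictly above T_α are significant; maximal runs of at
least `min_scores` consecutive significant pairs within one chromosome
become DMRs (default 3, i.e. ≥ 4 probes; a run of k scores spans k+1
probes). Each region is summarised by its mean concordance, its mean
methylation frequency (the average fitted π̂ across its probes), the
per-sample mean posterior, and a differentiation class: *high* when the
mean frequency lies in [0.15, 0.85] (a substantial minority of samples
differs), *low* otherwise.

## Simulation design

The simulator generates matrices of 30,000 probes × 50 samples (25
"cases", 25 "controls"). The background of each sample is a stationary
AR(1) chain along the chromosome, N_i = ρ·N_{i−1} + e_i, with
**fixed innovation sd 0.4** and ρ ∈ {0, 0.3, 0.5, 0.7}, so the marginal
background sd grows from 0.40 at ρ=0 to 0.56 at ρ=0.7. Two considerations
fix this parameterisation. First, the M scale: an innovation sd of 0.4
corresponds to β-scale replicate noise of ≈ 0.07 — typical for tiling
arrays — and makes the methylated/unmethylated states (E = 2, i.e. β 0.5
vs 0.8) cleanly bimodal, which is the premise of the mixture model; with
marginal sd 1 the two states at E = 2 would merge into a unimodal blur
that no per-probe clustering could separate reliably. Second, fixing the
*innovation* rather than the *marginal* variance means higher spatial
correlation also brings higher marginal noise, so only the ρ = 0.7
scenarios become harder — the qualitative pattern the method displays.
The ρ-independent-marginal convention remains available
(`stationary_unit_variance=True`).

DMRs are 10-probe intervals placed uniformly at random without overlap
and with ≥ 1 probe gap (sampled exactly via the gap-composition
bijection), covering 5% or 20% of probes. Within each DMR an independent
random subset of round(MF·25) cases (half-way counts round up: MF = 0.1
means 3 of 25) receives the effect E ∈ {2, 4}; controls are never
methylated. All randomness derives from one integer seed;
identical configurations are bit-reproducible.

**What the generator does not emulate:** probe-affinity and GC bias,
probe-length and spacing irregularities, batch effects, missing values,
and β-distributed (rather than Gaussian-on-M) noise. Passing tests on
these simulations therefore demonstrate the statistical behaviour of the
pipeline under its own model assumptions, not performance on raw array
data, which additionally needs platform normalisation upstream.

## Benchmarks

The supervised comparators test each probe separately for a case/control
difference at α = 0.05: the pooled-variance two-sample t-test and the
Wilcoxon rank-sum test (normal approximation with tie and continuity
corrections). Sensitivity is the fraction of truly differential units
called, the false positive rate the fraction of truly non-differential
units called; units are probes for the supervised tests and adjacent
probe pairs for the concordance caller (a pair is a true positive only
when both probes lie in the same DMR; pairs straddling a region edge are
excluded from both denominators). Thresholds are re-estimated from each
simulated dataset's own sub-0.5 scores. Region-level false coverage is
the fraction of truly non-DMR probes inside called regions.

**Problem sizes.** The packaged acceptance script
(`scripts/acceptance.py`) runs the E = 2, proportion 0.2 grid
(ρ ∈ {0.3, 0.5, 0.7} × MF ∈ {0.1,…,1}) at 30,000 probes with 5 repeats
per scenario, and the no-DMR threshold study at 30,000 probes × 5
repeats per ρ. The test suite uses 15,000 probes × 3 repeats (grid) and
2 repeats (nulls); the per-pair rates it checks are insensitive to the
number of probes.

## Numerical choices

* Quantiles use linear interpolation between order statistics
  (plotting position (k−1)/(N−1)).
* Significance is strict (`c > T_α`); ties at the threshold are not
  significant.
* The WLS slope is set to 0 (intercept = weighted mean) when the weighted
  predictor variance is below 1e-12.
* κ = 0 when the posterior vector is identically zero.
* The compiled EM engine mirrors the reference numpy implementation sweep
  for sweep (same start, same updates); both are exposed, and the suite
  asserts their agreement and the monotone log-likelihood of the plain
  path.

## Known limitations

* **Null-threshold level.** The spread of the null concordance
  distribution — and with it the α = 0.05 threshold, ≈ 0.74–0.75 here —
  depends on which local optimum the per-probe EM selects on
  non-differential probes. Alternative defensible EM schemes shift it by
  ±0.05 (mclust's hierarchical initialisation gives ≈ 0.67–0.70;
  aggressive likelihood maximisation gives ≈ 0.78–0.80). Because the
  threshold is re-estimated per dataset, calling is self-calibrating, but
  the absolute threshold value should not be compared across different
  EM implementations.
* **High spatial correlation.** At ρ = 0.7 the corrected null retains a
  slight right skew that the mirrored null cannot capture, so the
  realised pair-level FPR at α = 0.05 rises to ≈ 0.08–0.09 (from ≈ 0.05
  at ρ ≤ 0.5), and clustered false flags inflate region-level false
  coverage accordingly. The `min_scores` filter remains the effective
  mitigation.
* The correction removes first-order (lag-1) continuous correlation only;
  longer-range nuisance structure is out of scope.
* The raw-scale adjustment constant presumes the unmethylated state lies
  near M = 0, as on log₂ enrichment arrays. Data on other scales should
  be shifted accordingly before calling.
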