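# Methods

## Problem and scope

The package quantifies cross-tissue sharing of smoking-associated DNA
methylation signals. One study (the "target": a lung-tumour cohort typed on
an Illumina 450k-style array) is analysed from raw two-channel intensities
through to per-CpG summary statistics; an external study (the "signature":
a large blood meta-analysis) arrives as a summary-statistics table. The
question is whether the external signature is over-represented among the
target study's significant CpGs, beyond what probe counts alone predict.

Everything runs on synthetic data with known ground truth; no external
download is required or supported. Real accessions for the tumour data
live at the GDC portal and are deliberately out of scope, as are
gene-ontology analysis, GWAS-catalog intersection, cell-type deconvolution
and IDAT parsing.

## Generative model (`synthdata`)

**Annotation.** Probes are assigned one of four CpG-island-context regions
(island / shore / shelf / open sea) multinomially with the full-array
proportions 0.316 / 0.233 / 0.094 / 0.357, and a configurable fraction
(default 6%, the approximate share of published cross-reactive probes on
the platform) is flagged cross-reactive.

**Cohort.** Smoking groups (never / current / former ≤ 15 y / former
> 15 y) are allocated by largest-remainder rounding of n × proportions, so
printed percentages reproduce printed group counts exactly; the default
proportions (15.6 / 23.3 / 34.6 / 26.4%) and covariate distributions (age
≈ N(65.3, 10²), 54.9% female, stage mix dominated by stage I) mirror a
typical lung-adenocarcinoma cohort of n = 390. Ten ancestry PCs are
standard normal; plates are uniform over a configurable count.

**Planted effects.** `n_shared` probes carry effects in both tissues (same
sign), plus disjoint lung-only and blood-only sets, all drawn from
non-cross-reactive probes. Signs are negative with probability 0.8
(smoking predominantly hypomethylates); magnitudes are |N(mean, sd)| on
the beta-fraction scale. Lung effects are attenuated ×0.6 in recent former
and ×0.3 in long-term former smokers, reflecting fading with quitting
time. Default lung |Δβ| ≈ 0.12 matches the 6–15% methylation differences
typical of genome-wide-significant smoking CpGs in lung tissue; blood
effects default smaller (≈ 0.05). Published studies do not pin these
magnitudes down, so they are free parameters of the generator, not
calibrated claims.

**Intensities.** Per probe a baseline beta comes from a bimodal mixture
(Beta(2,10) / Beta(10,2) / Beta(5,5) at 40/40/20%). Plate shifts and
per-sample biological noise act on the logit scale (keeping betas in (0,1)
without clipping); the smoking effect is added on the beta scale and
clipped at [10⁻³, 1−10⁻³]. Channel intensities are

    M = Gamma(shape k, mean α·β) + TruncNormal(µ_b, σ_b²),
    U = Gamma(shape k, mean α·(1−β)) + TruncNormal(µ_b, σ_b²),

with defaults α = 4000, µ_b = 500, σ_b = 100, k = 16. The
exponential-signal / normal-background convolution is the classical noob
model; a *single* exponential draw per observation would, however, make
M/(M+U) essentially Beta(1,1)-noisy (sd ≈ 0.29 at β = 0.5) and strongly
biased toward 0.5 — unlike the platform, where each reported intensity
averages over bead replicates. The gamma shape k plays that role (k = 1
recovers the pure exponential; the default 16 approximates bead-level
averaging) and is what makes group differences of Δβ ≈ 0.15 recoverable
to ±0.03 at 200 samples/group, as the tests require. Background draws are
truncated at zero rather than resampled (the generative convention).

Gap probes (default 1%) get a latent biallelic genotype at a uniform MAF
in [0.1, 0.5] under Hardy–Weinberg, producing three beta modes 0.3 apart.
A configurable fraction of probe × sample pairs (default 0.2%) is drawn
background-only, so detection failures exist. Out-of-band and
negative-control pools are pure background draws.

**Summary statistics.** Per probe, estimate = 100·Δβ_blood + N(0, SE²)
with SE = 100/√meta_n percent (default meta_n = 15,907, the scale of the
large adult-blood smoking meta-analyses); P is the two-sided normal tail of
estimate/SE, so null probes have exactly uniform P. meta_n = ∞ is the
noiseless limit; an exact-zero z is assigned P = 1 by convention.

## Preprocessing conventions (`preprocess`)

- **Detection P** = upper tail of M+U under Normal(m_neg, s_neg²), with
  m_neg the per-sample median of negative-control totals and s_neg the
  MAD × 1.4826. The platform vendor's exact formula is not public in the
  sources this package follows; this negative-control normal model is a
  documented stand-in with the right calibration (≈ 1% of pure-background
  pairs fail at the 0.01 cutoff). "Failing" means P ≥ cutoff throughout.
- **Sample QC**: dropped when log2(median M) and log2(median U) are *both*
  below 11 (raw intensities are in the thousands, so the threshold only
  makes sense on log2 medians; an OR rule is available by flag), or when
  more than 1% of probes fail detection at 0.01.
- **Duplicates**: one sample per subject, keeping the smallest detection
  failure fraction; ties break to the lexicographically smallest sample id.
- **Probe filter**: cross-reactive probes first, then probes failing
  detection in more than 10% of retained samples. Filtering is idempotent.
- **noob**: per sample, µ_b and σ_b are the mean and SD of the out-of-band
  pool; α = mean(in-band) − µ_b floored at 1. Each channel is replaced by
  the normal-exponential posterior mean
  E[S|X=x] = µ_sf + σ_b·φ(µ_sf/σ_b)/Φ(µ_sf/σ_b), µ_sf = x − µ_b − σ_b²/α,
  computed via the scaled complementary error function for stability at
  µ_sf ≪ 0, plus an offset of 15 — strictly positive output. Dye-bias
  equalisation is omitted (one simulated dye); the hook is the per-sample
  parameter map.
- **Beta** = M/(M+U+100); the offsets 15 and 100 are platform-convention
  defaults, both configurable.
- **Gap hunter**: sorted betas are split where consecutive differences
  exceed 5% of the beta scale; ≥ 2 groups flags the probe unless all
  non-largest groups together hold < 1% of samples (then the split is
  outlier-driven and the flag is demoted). Gap probes are flagged, never
  removed — downstream tables carry a Y/N column — though exclusion is
  available as a switch in the EWAS layer.

## EWAS model (`ewas`)

Regression is on beta values (not M-values) with treatment coding: never
smokers are the reference, and the three smoking dummies are the reported
contrasts. Covariates: sex, age, stage, plate, ten ancestry PCs; rows with
missing covariates are excluded and counted; degenerate single-level
factors emit no columns; rank deficiency is an error naming the collinear
columns. Estimates are reported as 100·Δβ (percent methylation).

Variance moderation follows the standard empirical-Bayes scheme for
microarrays: with per-probe residual variance s², df d, the prior
(d₀, s₀²) is moment-matched on e = ln s² − ψ(d/2) + ln(d/2) by solving
ψ′(d₀/2) = var(e) − mean ψ′(d/2) (trigamma inverse by Newton; d₀ = ∞ when
the right side is ≤ 0), and posterior variances are
s̃² = (d₀s₀² + ds²)/(d₀ + d). The moderated t = b/(s̃√v) has d₀ + d df.
Setting d₀ = 0 reproduces the ordinary OLS t exactly (tested); the full
implementation agrees with the Bioconductor reference implementation to
machine precision on a shared fixture (tested through Rscript). All-zero
variances are an error; isolated zeros are floored at the smallest
positive s².

λ is the median association χ²₁ divided by 0.4549364; P = 0 is rejected
with a suggestion to floor. BH q-values come from statsmodels and are
checked against a brute-force step-up oracle. The genome-wide threshold
convention is P < 10⁻⁷; the signature threshold P < 10⁻⁴; FDR < 0.05 is
the sensitivity mode.

The surrogate-variable model is deliberately simple: the top left singular
vectors of the model residual matrix (sample space), sign-fixed by making
each vector's largest-magnitude entry positive, appended to the design.
Full iterative SVA is not reimplemented — the preserved contract is the
sensitivity check itself, summarised by the Pearson correlation between
primary and augmented coefficient vectors. Exactly-zero residuals yield
zero vectors.

## Enrichment (`enrich`)

The universe N is the set of probes analysed in the target study after its
filters; the external signature is intersected with it (losses counted).
Fisher sidedness defaults to the one-sided "greater" (hypergeometric upper
tail), which is the convention that reproduces published cross-tissue
enrichment P-values at the reconstructed universe; a two-sided mode is
provided. The odds ratio is the sample odds ratio of the 2×2 table.
Expected overlaps are reported at one decimal place. Thresholds are strict
(P < t), with t ≥ 1 passing everything so the sweep's saturated end gives
k = |B| and P = 1.

The permutation null reassigns the target study's P-values across the
universe (a full permutation per replicate), recomputing the overlap at
the threshold; the empirical P uses the add-one estimator
(1 + #{k_perm ≥ k})/(n_perm + 1), which can never reach zero — the
"no permutation was as extreme" outcome is exactly the floor 1/(n_perm+1).

The region test computes G = 2Σ O_r ln(O_r/E_r) against the full-array
proportions (O_r = 0 contributes 0, the limit convention; zero expectation
with a positive count is an error), with df = 3 and a χ² P; per-region
two-sided one-sample z-tests use Yates continuity correction, the
convention that approximately reproduces published per-region P-values.
Stage-stratified enrichment refits the EWAS per stratum and reuses the
same overlap machinery; empty strata return n_A = 0 with P = 1.

## Problem sizes and reproducibility

All stochastic stages require integer seeds; fixed seeds give bit-identical
outputs (per-stage seeds are spawned from the master seed via
`SeedSequence`). The test suite and `scripts/acceptance.py` use these
standard problem sizes, chosen so each check has clear statistical meaning:

- analytic enrichment reproductions: universe N = 452,776
  (485,512 − 29,233 − 3,503), published set sizes, no simulation;
- null calibration: 6,000 probes × 150 samples for λ (the λ median has
  sd ≈ 2.3/√G, so G ≥ ~5,000 makes the [0.9, 1.1] band meaningful), and
  50 replicate 2,000-probe runs for the uniformity of enrichment P;
- planted sharing: 500-probe genome, 150 samples, 100 true lung probes,
  40 shared with a 60-probe blood signature, effects |N(0.15, 0.03²)| in
  lung and |N(0.08, 0.02²)| in blood — the adequately-powered regime in
  which both sides detect nearly all planted probes, so the observed
  overlap (≈ 35–40) clears the permutation maximum (≈ 22–27) with margin
  across seeds;
- prior recovery: 5,000 simulated variances from the two-layer model
  σ² ~ s₀²d₀/χ²_{d₀}, s² ~ σ²χ²_d/d (the sampling layer is essential: the
  moment estimator expects it, and feeding prior draws alone biases d₀
  upward by ≈ 0.7 at d₀ = 4).

## Limitations

The generator emulates the features the pipeline is sensitive to — channel
intensities with shared background, covariate and batch structure,
multi-modal SNP probes, detection dropouts, cross-study sharing with
directional consistency — but not others found in real 450k data: type
I/II chemistry differences (the design-type label is recorded, nothing
more), dye bias, probe-sequence effects, spatial chip artefacts,
cell-type heterogeneity, or correlated methylation along the genome
(probes are independent given the design). Passing tests therefore
establish the correctness and calibration of the statistical machinery,
not the biological fidelity of any particular simulated dataset. λ on
planted-effect runs exceeds 1 by construction (a fifth of the simulated
genome carries signal); the calibration claim applies to null runs only.
Concordance correlations on small overlap sets are noisy; they are
reported with n and omitted below n = 3.
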