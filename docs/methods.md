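# Methods

## The estimation problem

`mrmediate` dissects the causal effect of a molecular exposure (the
package's vocabulary and defaults target DNA-methylation probes, but
nothing restricts it to them) on a complex trait into a component
mediated by molecular mediators in *cis* — typically transcripts — and a
residual direct component, using only three sets of summary statistics
(exposure QTLs, mediator QTLs, outcome GWAS) and an external LD panel.
Because the three effect sets may come from three different cohorts,
this is a three-sample design: cross-sample covariances of the effect
estimates are zero, which simplifies both the estimators and their
standard errors.

All effects are placed on the per-SD scale by dividing z-scores by √n,
which fixes var(β) = 1/n exactly and makes effect sizes comparable
across traits. For binary outcomes supplied as log-odds, estimates are
interpretable on the liability scale.

## Estimators

**Total effect.** Generalized IVW over the exposure's instruments:
θ̂_T = (β_E′C⁻¹β_E)⁻¹ β_E′C⁻¹β_Y, with C the instruments' LD
correlation matrix. The standard error uses the Delta-method sandwich
with a diagonal Σ, Σ_ii = max(s², var(β_Yi)); s² is the C⁻¹-weighted
residual variance of the fit with m−1 degrees of freedom (for a single
instrument, s² := var(β_Y1)). The symmetric inverse square root C^(−1/2)
is taken by eigendecomposition rather than Cholesky so the sandwich is
invariant to instrument ordering.

**Direct effect.** MVMR over the pooled instrument set:
θ̂_D-vector = (B′C⁻¹B)⁻¹B′C⁻¹β_Y, with the exposure in the first column
of B and one column per selected mediator. Entries unreported in a
source table — common in significant-only mQTL releases — are exact
zeros, which keeps weak, heavily diluted effect estimates out of the
design matrix. Mediator direct effects (α_MY) are replaced by a
univariable mediator→outcome IVW estimate whenever a mediator retains at
least 3 of its own instruments, because the marginal contribution of
correlated mediators is better resolved univariably.

**Mediation proportion.** Per pair, MP = 1 − θ̂_D/θ̂_T, reported
unclamped (opposite-signed estimates legitimately push it outside
[0, 1]; no per-pair variance is reported since that would need
individual-level data). Group-level MPs are never averages of per-pair
MPs: θ̂_D is regressed on θ̂_T without intercept and the slope corrected
for regression dilution, γ̂_cor = γ̂/√(1 − ΣSE²(θ̂_T)/Σθ̂_T²);
MP̂ = 1 − γ̂_cor with a symmetric 95% CI from se(γ̂)/√(same factor).
The correction is undefined when the noise term reaches Σθ̂_T² — such
groups are skipped with a diagnostic. se(γ̂) uses the classical
homoskedastic no-intercept formula. Two groups are compared by
z = (γ̂_cor⁽¹⁾ − γ̂_cor⁽²⁾)/√(se₁² + se₂²); independence of the two
estimates is assumed, so p-values for overlapping pair sets are lenient.

Pairs whose exposure has no mediator passing the selection threshold are
"non-detectable": θ̂_D := θ̂_T, per-pair MP = 0. "Detectable"-mode group
estimates use only pairs with ≥1 selected mediator; "overall" mode adds
the non-detectable pairs (a more conservative, less selection-biased
measure) but always excludes pairs with no candidate transcript in the
cis window at all, as well as untestable pairs.

## Instrument processing

- Selection: greedy by ascending p-value among variants with p < 1e-6
  inside the cis window (±1 Mb), keeping a variant iff r² < 0.05 with
  everything already kept; exposures need ≥5 selected instruments.
- Steiger directionality filter at t_rev = −2 (one-sided p ≈ 0.023),
  applied exposure-vs-outcome, exposure-vs-each-selected-mediator and
  mediator-vs-outcome; ≥3 exposure instruments must survive or the pair
  is untestable.
- Mediator selection: transcripts with TSS within ±500 kb of the probe,
  tested by univariable exposure→transcript IVW; retained when
  p_EM < 0.01 (configurable; 0.05/0.001 as sensitivity settings).
- Pooling: mediator instruments are ordered by the sum over mediators of
  their within-mediator p-value ranks (ties: minimum p, then position)
  and greedily clumped at r² < 0.05 against the exposure instruments —
  which are never displaced — and each other.
- Screening pipeline: probes with a Bonferroni-significant total effect
  (p_T < 1e-6 ≈ 0.05/50,000) are distance-clumped at 1 Mb by ascending
  p_T (ties by position) before mediation; per-trait MPs need ≥10 pairs.
- Sensitivity modes: `top_mediator` (sole lowest-p_EM mediator),
  `uncorrelated` (mediators clumped at |r| < 0.3 on shared QTL-effect
  vectors, priority to lowest p_EM), `leave_top_iv` (strongest exposure
  instrument removed from both θ̂_T and θ̂_D), plus subsets with
  conditional F > 10 and with no Q-heterogeneity (p_HET > 0.01).

## Diagnostics

**Conditional F.** The exposure effect column of B is regressed
(C⁻¹-weighted) on the mediator columns; with residuals e and
coefficients δ,

F_cond = e′C⁻¹e / ((m − k)·σ_v²),  σ_v² = 1/n_E + δ′Rδ/n_M,

where R is the mediator phenotypic correlation matrix — identity by
default, since phenotypic correlations are rarely available; supplying
one gives the correlation-adjusted variant. With no mediators this is
the standard mean F-statistic n_E β′C⁻¹β/m, and it is 0 under perfect
exposure–mediator collinearity. Values ≤10 flag weak conditional
instrument strength. The exact published form of the Sanderson statistic
is not printed in the source literature; this construction is documented
here and pinned by its two reductions in the test suite.

**Heterogeneity Q.** Computed on decorrelated residuals
u = C^(−1/2)(β_Y − Bθ̂), Q = Σu_i²/Σ_ii, reducing to the standard
independent-instrument Q when C = I. Degrees of freedom follow the
reported convention: m−1 univariable, m−k multivariable.

**By-chance-LD pleiotropy null.** For a probe–transcript pair, the
transcript's multivariable eQTL effects β_multi = C_M⁻¹β_M are
reassigned to m_M random SNPs drawn from an r² < 0.5-pruned pool (same
region by default), implied marginal effects at the exposure
instruments computed as C_cross·β_multi, and the exposure→transcript MR
re-run; P_sim is the fraction of null replicates beating the real pair's
p-value. Desk-scale default is 1,000 replicates (the full-scale analysis
uses 100,000).

## Simulation engine

One replicate draws m_E independent exposure instruments with effects
rescaled to exactly h²_E; each of the N_med_pot potential mediators has
m_M own instruments rescaled to h²_M,direct; the causal pairs
(α_EM, α_MY) are bivariate normal with variances var_α and correlation
ρ for the N_med relevant mediators and zero otherwise. θ_M = Σα_EMα_MY,
θ_D = θ_M(1/MP − 1), θ_T = θ_D + θ_M, and β_Y = θ_D β_E + Σα_MY β_Mk.
Noise with variance 1/N is added per vector, after which exposure
effects of mediator instruments are re-zeroed, mimicking
significant-only mQTL reporting. Instruments are mutually independent
(C = I). Every potential mediator carries its own instruments: this is
what lets an over-lenient selection threshold admit non-mediators whose
weak instruments bias the fit, the behaviour the threshold sweep is
designed to show. One master seed drives per-replicate streams derived
by replicate index, so scenarios are bit-reproducible.

Scenario aggregation runs the full estimator chain per replicate
(θ̂_T; mediator selection at p_EM; MVMR θ̂_D with the non-detectable
fallback; conditional F) and pools the 500 replicates through the same
dilution-corrected slope used for real cohorts. `N_med,sig` counts
selected mediators that are truly relevant; the total selected count is
recorded separately. `mc_se_mp` is a leave-one-replicate-out jackknife
SE of the pooled MP — unlike the analytic homoskedastic SE it sees the
heteroskedastic replicate residuals and the reuse of the noisy total
effects inside the correction factor, and it is the appropriate yardstick
for parameter-recovery checks.

### Default parameters and calibration

| parameter | default | role |
|---|---|---|
| m_E, m_M | 10, 10 | instruments per exposure / per mediator |
| N_med_pot, N_med | 12, 2 | potential / truly relevant mediators |
| h²_E | 0.10 | exposure cis-heritability |
| h²_M,direct | 0.03 | mediator direct cis-heritability |
| var(α_EM), var(α_MY) | 0.075, 0.05 | causal effect-size variances |
| ρ | 0 | corr(α_EM, α_MY) |
| true MP | 0.35 | generative mediation proportion |
| N_E, N_M, N_Y | 30,000 | QTL/GWAS sample sizes |
| p_EM | 0.01 | mediator selection threshold |

Sample sizes mirror large whole-blood QTL consortia (~30k) and the
instrument counts and true-MP/mediator-count medians mirror what such
cohorts yield. h²_M,direct and var(α_EM) are not derivable from first
principles; they were calibrated once so that the engine operates in the
documented reference regime — a pooled MP̂ of roughly 33–35% under the
default scenario, on average slightly over 1 of the 2 relevant mediators
still detected when the mediator sample size drops to 3,000, and a
clearly reduced MP̂ at that sample size — and are exposed in
`SimulationConfig` like every other parameter. Mediator total
heritability is deliberately not renormalized after adding the mediated
α_EM·β_E component; only the direct part is rescaled.

## Synthetic region fixtures

`synthetic` writes file-level fixtures (LD matrix + index, mQTL, eQTL,
GWAS tables, truth sidecar) for cis regions with known ground truth.
LD is AR(1), r(i,j) = decay^|i−j| (default 0.9 over a 2-kb grid),
positive definite by construction; block structure can be emulated by
concatenating regions. Causal effects are drawn at SNP level and mapped
through the LD matrix to marginal effects, so the linear relation
β_Y = θ_D β_E + Σα_MY β_M holds row-wise exactly for the true marginals
regardless of which SNPs are selected as instruments. Exposure causal
SNPs spread ±60 SNPs around the probe (wide enough that r² < 0.05
pruning retains ~5–8 instruments at decay 0.9); transcript direct-causal
SNPs cluster within ±15 SNPs of the TSS, and default cohort TSS
placement keeps them out of LD reach of the exposure cluster so that
exposure→transcript MR is uncontaminated by LD leakage — blueprints can
deliberately overlap the clusters to study that contamination. The mQTL
table applies a p < 1e-6 reporting threshold (significant-only release
style) and the eQTL table an FDR-equivalent p < 1.8e-5, which exercises
the downstream set-to-zero rule. EAFs are shared across tables, with an
optional per-table perturbation to exercise the allele-frequency
harmonization filter and an optional palindromic fraction.

What the fixtures do not emulate: realistic MAF–LD coupling, strand
ambiguity beyond palindromes, sample overlap between the three studies,
population stratification, or real GoDMC/eQTLGen allele-coding quirks.
Passing end-to-end tests therefore demonstrates correctness of the
estimators and plumbing under the stated generative model, not
robustness to every real-data pathology.

## Harmonization

Tables are aligned to a common effect allele with beta-sign and AF flips
on swaps; allele-set mismatches are dropped, as are palindromic (A/T,
C/G) variants — no strand-flip inference is attempted — multi-allelic
records (duplicate IDs within a table), non-autosomal variants, and
variants whose oriented allele frequencies differ by more than 0.05
between any pair of datasets (a user-supplied reference AF substitutes
when a table lacks frequencies). In the screening pipeline each table is
oriented against the LD panel's allele coding individually, with the
GWAS table's frequencies as the AF reference, so that variants absent
from the significant-only mQTL release remain available to the design
matrix as zeros rather than being intersected away. Coordinates are
1-based and cis windows inclusive on both ends.

## Numerical choices

- All LD-matrix inversions clip eigenvalues below 1e-8 (uniformly), and
  C^(−1/2) is the symmetric eigendecomposition root.
- Collinear mediator columns are dropped greedily (rank-revealing
  Gram-Schmidt at relative tolerance 1e-10, exposure column always
  kept) and recorded on the results object.
- Underflowed normal p-values are clipped to the smallest positive
  float so p ∈ (0, 1] holds everywhere.
- p-value ties in greedy selections break by genomic position;
  rank-score ties break by an instrument's minimum p across mediators,
  then position.

## Known limitations

- The conditional-F construction is a documented reconstruction (see
  above), not a transcription of a published formula.
- The homoskedastic se(γ̂) slightly understates the spread of MP̂ across
  heterogeneous pairs; the jackknife `mc_se_mp` is provided for
  simulation work, but cohort CIs use the analytic form.
- Mediator selection at a hard p_EM threshold leaves a small downward
  bias in MP̂ that shrinks but never fully vanishes with information,
  because arbitrarily weak true mediators always exist under a normal
  effect-size prior.
- No MR-Egger/weighted-median (univariable) or robust MVMR estimators;
  no VCF/PLINK genotype handling or in-package LD estimation; no probe
  annotation or TSS-enrichment statistics beyond emitting distances.
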