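# mrmediate

Three-sample multivariable Mendelian randomization (3S-MVMR) for
quantifying how much of a molecular exposure's causal effect on a complex
trait is mediated by molecular mediators in *cis* — for example, how much
of a DNA-methylation (DNAm) probe's effect on a disease is propagated
through nearby transcript levels. The package works entirely from
QTL/GWAS summary statistics plus an LD reference panel; no
individual-level data are needed.

It is aimed at statistical geneticists and molecular epidemiologists
integrating mQTL, eQTL and GWAS summary data, and at methodologists who
want to study the bias properties of summary-statistic mediation
estimators through its built-in simulation engines.

## Model

For an exposure *E*, candidate mediators *M₁…M_k* and an outcome *Y*,
with standardized per-SD instrument effects (β = z/√n, so var(β) = 1/n):

- **Total effect** — IVW MR generalized to correlated instruments, with
  **C** the LD matrix of the instruments:

  θ̂_T = (β_E′ C⁻¹ β_E)⁻¹ β_E′ C⁻¹ β_Y

  with a Delta-method standard error using the sandwich
  (β_E′C⁻¹β_E)⁻¹ β_E′ C^(−1/2) Σ C^(−1/2) β_E (β_E′C⁻¹β_E)⁻¹, where
  Σ_ii = max(s², var(β_Yᵢ)).

- **Direct effect** — MVMR over the pooled exposure- and
  mediator-associated instruments, **B** the m×(k+1) effect matrix with
  the exposure in column one and effects unreported in a source table
  set to exact zeros:

  θ̂_D = first element of (B′ C⁻¹ B)⁻¹ B′ C⁻¹ β_Y

- **Mediation proportion** — per pair MP = 1 − θ̂_D/θ̂_T; for a group of
  pairs, θ̂_D is regressed on θ̂_T without intercept and the slope γ̂
  corrected for regression-dilution bias,

  γ̂_cor = γ̂ / √(1 − ΣSE²(θ̂_T)/Σθ̂_T²),   MP̂ = 1 − γ̂_cor,

  with group MPs compared by a z-test on the corrected slopes.

Instruments pass a Steiger directionality filter
(t = (|β_X| − |β_Z|)/√(var_X + var_Z) > −2, one-sided p ≈ 0.023) at each
step of the causal chain; diagnostics include Sanderson-style conditional
F-statistics of the exposure given the mediators and Cochran's Q
heterogeneity on LD-decorrelated residuals (df = m−1 univariable, m−k
multivariable).

## Worked example

A synthetic *cis* region with two true transcript mediators
(α_EM = 0.6/−0.4, α_MY = 0.15/0.1), a direct effect of 0.05 and hence a
true MP of 0.5:

```python
from mrmediate import (RegionBlueprint, TranscriptBlueprint,
                       generate_region_fixture, mediate_pair)

bp = RegionBlueprint(
    "demo", theta_D=0.05,
    transcripts=[TranscriptBlueprint("ENSG_A", 1_480_000, 0.6, 0.15),
                 TranscriptBlueprint("ENSG_B", 1_600_000, -0.4, 0.1)])
panel, mqtl, eqtl, gwas, truth = generate_region_fixture(bp, seed=11)
pair = mediate_pair(mqtl, eqtl, gwas, panel, bp.probe_pos)
print(f"theta_T = {pair.theta_T:.4f}  theta_D = {pair.theta_D:.4f}  "
      f"MP = {pair.mp_pair:.3f}")
```

prints

```
theta_T = 0.0981  theta_D = 0.0424  MP = 0.568
```

θ̂_T ≈ 0.098 recovers the true total effect 0.1; the MVMR direct effect
0.042 sits near the true 0.05, so the per-pair MP 0.57 matches the
generative 0.5 within its sampling error. Both mediators are selected
(p_EM < 0.01) and the conditional F of 58 indicates the exposure
instruments stay strong given the mediators.

The simulation engine reproduces the estimator's mild downward bias
under realistic sample sizes:

```python
from mrmediate import SimulationConfig, run_scenario
print(run_scenario(SimulationConfig(reps=500), seed=1).summary())
```

```
Scenario: true MP=0.35, N_med=2/12, reps=500
  MP_hat = 34.3% (95% CI: [33.7%-34.8%])
  mean N_med,sig = 1.72
  mean conditional F = 59.5
```

A command-line interface mirrors the library:
`mrmediate screen --config cfg.yaml`, `mrmediate scan`,
`mrmediate simulate`, `mrmediate pleiosim`, `mrmediate fixtures`.

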