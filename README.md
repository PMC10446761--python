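# lipidmr

Two-sample Mendelian randomization (MR) toolkit for studying how lipid
traits and lipid-lowering drug targets affect disease risk — built around
the lipid/apolipoprotein → sepsis setting, where circulating HDL-C and
ApoA-I appear protective and drug targets such as HMGCR (statins) and CETP
inhibitors are probed through cis genetic instruments.

It is a library first: you import it from Python, feed it GWAS summary
statistics (plain TSV), and get causal estimates with diagnostics. A thin
`lipidmr` command wraps the pipeline for shell use, and `examples/` holds
short narrative scripts, one per capability.

## What it computes

Given per-variant exposure effects β̂_Xj (per SD) and outcome effects β̂_Yj
(log-odds) for harmonized instruments j = 1…k with outcome standard errors
σ_Yj:

- **IVW** — weighted zero-intercept regression with weights w_j = 1/σ²_Yj:
  θ̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂²_Xj, fixed-effects SE (Σ w_j β̂²_Xj)^(-1/2);
  the multiplicative random-effects SE scales it by max(1, √(Q/(k−1))).
  Cochran's Q decides between the two: random effects when the Q test has
  p < 0.05.
- **MR-Egger** — the same regression with a free intercept; a non-zero
  intercept indicates directional pleiotropy.
- **PRESSO-style outlier test** — parametric bootstrap of the leave-one-out
  residual sum of squares; flagged outliers are removed and IVW re-run.
- **Instrument selection** — p < 5×10⁻⁸ (fallback 5×10⁻⁶), greedy LD
  clumping (r² < 0.001, 10,000 kb window), F = β²/SE² > 10, confounder
  screening, and ±100 kb gene windows (HMGCR, PCSK9, CETP, NPC1L1) for
  drug-target (cis) MR. For LDL-C-proxied drug targets the pharmacological
  odds ratio is the reciprocal 1/OR of the per-SD-increase OR.
- **Multivariable MR** — joint direct effects of several exposures
  (weighted multiple regression through the origin), conditional
  F-statistics for instrument strength, and MR-Lasso (L1-penalised
  per-variant intercepts) to flag invalid instruments.
- **Two-step mediation** — indirect effect β₁·β₂ with delta-method SE
  √(β₁²SE₂² + β₂²SE₁² + SE₁²SE₂²), direct effect by subtraction from the
  total, and the proportion mediated.
- **Synthetic GWAS generator** — two-sample summary statistics with LD
  blocks, a mediator path, directional/balanced pleiotropy and
  sample-size-scaled SEs, so every stage is testable against known truth.

## Worked example

`examples/03_mediation.py` decomposes the effect of CETP inhibition
(HDL-C-proxied, raises ApoA-I with OR 2.187, 95% CI 1.919–2.493) on sepsis
(ApoA-I → sepsis OR 0.863, 0.780–0.955; total effect OR 0.796):

```
indirect beta = -0.115 (p = 0.006)
direct beta   = -0.113
proportion mediated = 50.5%
```

The indirect effect −0.115 is the product of the two log-odds legs; its p
comes from the delta-method SE; about half of the protective total effect
(ln 0.796 = −0.228) flows through ApoA-I. The same script then recovers a
planted indirect effect (0.5 × 0.3 = 0.15) from simulated summary
statistics end-to-end.

`examples/01_forward_mr.py` runs the full selection + estimation chain on a
simulated study with a true causal effect of 0.2 log-odds per SD:

```
ivw_fe: k= 79  OR=1.219 (1.201-1.237)  p=2.50e-151  label=strong
 egger: k= 79  OR=1.186 (1.143-1.232)  p=1.44e-13   label=strong
true OR exp(0.2) = 1.221  (should fall inside the IVW interval)
```

See also `examples/02_drug_target_mr.py` (cis instruments and the
reciprocal-OR drug scale) and `examples/04_multivariable_mr.py`
(multivariable IVW, conditional F, MR-Lasso).

## Command line

```bash
lipidmr simulate --seed 3 --theta 0.2 --out-dir simdata
lipidmr tsmr --config simdata/config.yaml
lipidmr drug --config simdata/config.yaml --gene CETP --proxy HDL-C
lipidmr all  --config simdata/config.yaml
```

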