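# adiposeg

Segregation analysis of a latent adiposity trait in cohorts with and
without a first-degree family history of type 2 diabetes (FH+ / FH−), for
researchers studying the inheritance of obesity susceptibility.

The analysis asks whether adiposity *segregates* in T2DM families the way
a dominantly expressed major gene would, and if so, what risk-allele
frequencies that implies:

1. **Factor extraction.** Six body measurements (height, waist, hip, lean,
   bone and fat mass) are log-transformed, standardized, and reduced by
   maximum-likelihood factor analysis with varimax rotation to two
   orthogonal factors — *Frame* (skeletal size) and *Adiposity* (fat
   stores).  Individual scores use Bartlett's method.
2. **Adjustment.** Scores are adjusted for gender and age tertile
   (residuals from the additive model `trait ~ gender + age_tertile`).
3. **Segregation.** Adjusted *Adiposity* is binned by deciles of the
   pooled sample; per-decile relative risks RR_i = p_i(FH+)/p_i(FH−) get
   log-normal CIs, and the FH+ bin densities are fitted to an
   equal-variance bimodal normal density
   `(1−α)·φ(x; m₁, s) + α·φ(x; m₁+d₂, s)` by bounded least squares
   (L-BFGS-B, multistart).  Heritability is h² = 1 − s².
4. **Allele frequencies.** Under a dominant bi-allelic model at
   Hardy–Weinberg equilibrium, α = 2pq + q² inverts to
   q = 1 − √(1−α).  The FH− upper-mode fraction comes from the 8th-decile
   relative risk (α₋ = α₊/RR₈), and the frequency in unobserved
   T2DM-affected relatives from the spouse-pool relation
   q_T2DM = 2q₊ − q₋.
5. **Uncertainty.** Stratified bootstrap (resampling individuals within FH
   stratum, full pipeline re-run per draw) yields percentile CIs for every
   parameter.

Because the original participant-level data were never deposited, the
package ships a synthetic-cohort generator (`adiposeg.simulate`) that
reproduces the assumed data-generating structure — HWE genotypes, a
dominant carrier shift on latent Adiposity, a gendered Frame factor, and a
two-factor log-scale measurement model — with ground truth recorded, so
every stage is testable against known parameters.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
simulated cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_factor_extraction.py
python analysis/03_segregation_analysis.py
python analysis/04_allele_frequencies.py
python analysis/05_bootstrap_ci.py --draws 400 --seed 1
```

Factor extraction prints the rotated loading pattern — the skeletal
measures load on *Frame*, the fat-store measures on *Adiposity*:

```
varimax-rotated loadings (correlations with factors):
          Frame  Adiposity
height_m   0.91       0.02
waist_cm   0.38       0.76
hip_cm     0.20       0.78
lean_kg    0.93       0.27
bone_kg    0.92       0.30
fat_kg     0.00       0.89
variance explained: 81% (Frame 45%, Adiposity 36%)
```

Segregation analysis shows FH+ enrichment concentrated in the upper
deciles of adjusted *Adiposity* and the bimodal fit:

```
gender+age R^2 on Adiposity: 0.137
per-decile RR (FH+/FH-): [0.25 0.38 0.17 0.82 1.25 0.65 1.86 2.29 2.29 3.05]
RR in 8th decile: 2.29 [0.98, 5.35]
bimodal fit: m1=-0.09 d2=1.39 s=0.65 alpha=0.40 (degenerate=False)
```

Here α = 0.40 means the fit places 40% of this simulated FH+ group under
the upper mode (the generating value is 0.59; a single cohort of 80 is
noisy — the bootstrap CI below spans 0.21–0.74).  The allele-frequency
chain then inverts the fractions:

```
inputs: alpha_FH+ = 0.40, RR_8 = 2.29
  FH-   alpha = 0.17  q = 0.09
  FH+   alpha = 0.40  q = 0.22
  T2DM  alpha = 0.59  q = 0.36
T2DM risk in FH+: 20% (independent) to 40% (pleiotropic)
```

and the bootstrap reports point, median and percentile CI per parameter:

```
400 draws, 0 failed
parameter           point   median     2.5%    97.5%
alpha_fh_plus       0.399    0.534    0.208    0.736
q_fh_minus          0.091    0.099    0.025    0.336
q_fh_plus           0.225    0.317    0.110    0.486
q_t2dm              0.358    0.503    0.154    0.872
```

Real data can be analysed the same way: prepare a CSV with columns
`id,gender,age,fh,height_m,waist_cm,hip_cm,lean_kg,bone_kg,fat_kg`
(`gender` F/M, `fh` FH+/FH−), load it with `adiposeg.io.read_cohort`, and
run `adiposeg.full_pipeline(cohort, n_boot=1000, seed=...)` for a complete
JSON-serializable report.

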