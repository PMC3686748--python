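# Methods

## The model

`cytohier` analyses one assay panel at a time: ELISA cytokine
concentrations (TNF-α, IL-10; pg/ml) or qPCR cycle-threshold values
(cytokine and TLR transcripts; Ct cycles) measured on PBMCs from two age
groups (adult, foal), under four incubation conditions (Control, LPS,
PCSK, LPS+PCSK), with six subjects per group and triplicate wells per
subject × condition.

On the model scale — natural-log pg/ml for ELISA, Ct for qPCR — each
measurement is

```
y[g,c,i,r] = mu[g,c] + u[i] + v[i,c] + eps[g,c,i,r]
u[i]      ~ N(0, sigma2_subject)            # some horses react more
v[i,c]    ~ N(0, sigma2_subject_condition)  # horses react differently
                                            # to specific incubations
eps       ~ N(0, sigma2_resid)              # replicate/measurement noise
```

with one free mean per (age group, condition) cell — eight in the full
design, no intercept/contrast coding — so responses may differ freely
between groups. Each assay is fitted independently; nothing is shared
across genes or cytokines. The three variance components are shared
across age groups: that is the minimal model consistent with "one error
term per horse, one per incubation-within-horse", and with 6 subjects per
group there is little information to support separate ones.

Priors are weakly informative: `mu[g,c] ~ N(0, 100^2)` and the same
inverse-gamma prior on all three *variances* (not precisions), with
moments mean 1 and variance 10,000, i.e. `IG(shape 2.0001, scale 1.0001)`
from `ig_hyperparams(1, 10_000)`.

### Detection limits

ELISA kits report nothing reliable below their limit of detection
(15.6 pg/ml for TNF-α, 156.3 pg/ml for IL-10). Two regimes are
implemented, chosen per assay by how much of the data is affected:

* **substitute** — every sub-LOD value is set equal to the LOD. Used for
  TNF-α, where *all* control wells sit below the limit; treating them as
  exactly at the limit biases control means upward and therefore makes
  stimulation contrasts conservative.
* **censor** — sub-LOD values are treated as left-censored: the true
  concentration is unknown but likely below the limit. Used for IL-10,
  where only a couple of wells are affected. Censored rows keep the LOD as
  a placeholder value so tables stay rectangular; the `censored` flag, not
  the value, enters the likelihood.

The log transform is applied after the LOD rule, and transforms the
censoring bound alongside the values. Natural log is used throughout
(the base cancels from every significance call; folds back-transform with
`exp`).

## Sampling

All full conditionals are conjugate, so the sampler
(`cytohier.sampler.run_chains`) is a blocked Gibbs sampler:

1. censored values: draw from `N(mu + u + v, sigma2_resid)` truncated
   above at the log-LOD. The truncated draw inverts the normal CDF in log
   space (`log_ndtr` / `ndtri_exp`), which stays exact even when the bound
   is tens of standard deviations below the mean;
2. cell means, then subject effects, then subject-condition effects:
   vectorised normal updates (each block is conditionally independent);
3. the three variances: inverse-gamma updates, floored at 1e-10.

Defaults mirror the study configuration: 4 chains × 30,000 iterations,
first 10,000 discarded as burn-in, no thinning. A `--fast` profile
(4 × 3,000, burn-in 1,000) is used for simulation experiments; at the
study design size its retained draws are ample for cell-mean summaries
(all PSRF < 1.01 in practice).

Initial values are overdispersed — cell means from
`N(empirical cell mean, (2 × empirical sd)^2)`, variances from their
prior clipped to `[1e-3, 1e3]` — which is what makes the Gelman-Rubin
diagnostic meaningful. Each chain has its own seeded PCG64 stream;
identical configuration and seeds reproduce draws bit-for-bit, and every
CLI run records its seeds in a manifest.

A cell with no observations draws its mean from the prior and logs a
warning; a variance fixed to zero in `ModelSpec` disables that random
effect entirely (used by the oracle tests and available for degenerate
designs).

## Diagnostics and summaries

`psrf` implements the original (whole-chain, non-rank-normalised)
potential scale reduction factor: `sqrt(var+ / W)` with
`var+ = (n-1)/n W + B/n`; all-constant input returns 1.0 by convention,
and a split-chain variant is available behind a flag. The convergence
threshold is 1.1 and failing parameters produce warnings, never errors.

Summaries pool retained draws across chains: posterior mean, sd, and the
central 95% credible interval (BCI) from the 2.5/97.5 percentiles with
linear interpolation between order statistics (numpy's default rule).

## Contrasts and derived quantities

A contrast between two cells is computed draw-wise (`delta = mu_a - mu_b`
per retained draw), preserving posterior correlation; it is *significant*
when the 95% BCI of delta excludes zero — per-contrast, with no
multiplicity correction, matching the reporting convention the pipeline
reproduces. Fold changes back-transform the mean difference:
`exp(delta)` on the log-concentration scale, `2^(-delta)` on the Ct scale
(one cycle = one doubling; lower Ct = higher expression). The posterior
mean of the draw-wise folds is reported alongside; the headline value is
the back-transform of the mean difference, which is what matches fold
factors computed from mean Ct values. Reductions are reported as
"percent lower", `100 × (1 - fold)` for fold < 1.

`livak_ddct` implements the 2^(−ΔΔCt) housekeeping normalisation, and
`housekeeping_stability_check` runs all within-group condition contrasts
for housekeeping-gene fits (β-actin, GAPDH), where a stable gene should
produce no significant contrasts.

## The synthetic-data generator

`synthetic_data.generate_dataset` draws data exactly as the model assumes
they arise (cell mean + subject effect + subject-condition effect +
replicate noise, then `exp` to pg/ml and the LOD rule for ELISA panels).
It therefore validates the *statistical* pipeline — estimation,
censoring, diagnostics, calibration — not the assay: plate effects, PCR
efficiency differences, heteroscedastic low-concentration noise and
non-normal tails are deliberately absent, so passing tests say nothing
about those failure modes in real data.

Defaults reflect the study design: 6 subjects per group, triplicates, the
four conditions, and the two LOD regimes. The error scales default to
`sigma_subject = 0.5`, `sigma_subject_condition = 0.3`,
`sigma_resid = 0.4` (log-units / Ct cycles) — realistic magnitudes for
stimulated-PBMC panels, chosen once. `default_study_config` seeds the
true cell means with the two study-level values that are public (basal
control Ct means: TLR-2 22.98 adult / 21.92 foal; TLR-4 23.62 / 22.24);
all other cell means are clearly-labelled placeholders that echo the
reported direction and magnitude of effects (e.g. a markedly lower TNF-α
LPS response in foals) without being study estimates. With the IL-10
configuration the expected number of left-censored wells per panel is a
handful out of 144, matching the regime the censor rule exists for.

## Calibration behaviour and numerical choices

* **Recovery.** Repeated simulate-and-fit at the study design size
  (`recovery_experiment`, 50 replicates, fast chains) gives pooled 95%-BCI
  coverage of the eight cell means of ~98% and pooled signed bias
  indistinguishable from zero (|bias| well under 0.1 residual sd). Bias
  is reported pooled over cells × replicates; per-cell biases at 50
  replicates carry Monte-Carlo noise of the same order as any real bias
  and are reported for inspection, not tested.
* **Null calibration and conservatism.** With variance components known,
  the BCI-exclusion rule flags ~5% of null contrasts, as it should. With
  variances *estimated* at the 6+6 design under the mean-1 inverse-gamma
  prior, posterior variance components a good deal smaller than 1 are
  pulled upward, intervals widen, and the null exclusion rate drops to
  ~1-3%: the procedure as prescribed is conservative at this sample size
  (it under-calls significance, never over-calls). This direction of
  error is consistent with the analysis's own conservative framing and is
  asserted, not hidden, in the test suite.
* Degenerate inputs: `psrf` needs ≥ 2 chains and ≥ 2 draws; constant
  chains return 1.0; variance draws are floored at 1e-10; truncated
  draws at extreme bounds remain finite (log-space inversion);
  `censored_marginal_loglik` refuses instances beyond 3 observations /
  1 subject, since it is a quadrature oracle, not an estimator.

## Known limitations

* Variance components are shared across age groups; a group-specific
  extension would need informative priors at n = 6 per group.
* The LOD substitution rule biases affected cell means upward by
  construction; it is the right tool only when a whole cell sits below
  the limit.
* No model selection, no efficiency-corrected qPCR (Pfaffl), no
  multiplicity correction by default: the default 95% level mirrors the
  per-contrast convention of the original analysis. Every contrast
  function takes a `level` argument, so a Bonferroni-style family
  adjustment is one keyword away if wanted.
* The printed fold factors from mean Ct values are reproduced exactly;
  the study's own posterior estimates are not recomputable because the
  raw data were never deposited, and nothing here pretends otherwise.
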