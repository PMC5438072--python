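# Methods

## The kin-cohort survival model

Each genotyped subject contributes up to two *parent records*. For parent
record *i* with exit age `tau_i` (death age, or age when the offspring was
interviewed if still alive) and event indicator `delta_i` (1 = dead), the
hazard from age 40 is modelled as

    h(t | X_i, Z_i) = h0(t) * exp(beta * X_i + gamma' Z_i),

with `X_i` the *offspring's* dosage of the counted allele and `Z_i`
offspring-level covariates (centre, batch, deprivation, ancestry principal
components in real data; standard-normal stand-ins in simulation). Age is the
analysis time with common entry at 40, so risk sets need no delayed-entry
bookkeeping; fathers and mothers are always modelled separately and combined
afterwards by meta-analysis.

Because the parent is not genotyped, `X_i` proxies the parental dosage.
Under Hardy–Weinberg equilibrium with counted-allele frequency `p`, the
expected parental dosage is `p`, `0.5 + p`, `1 + p` for offspring dosage 0,
1, 2 — linear with slope exactly 1/2 for every `p`. Effects per offspring
allele are therefore half the per-parental-allele effects, and all reported
estimates (and standard errors) are doubled onto the parental scale at
reporting time only; internal scans stay on the offspring scale. Variance-
explained fractions are *not* doubled (they are properties of the
offspring-scale regression).

The doubling convention treats the log hazard ratio as exactly halved in
offspring units. Strictly, marginalising the proportional-hazards model over
the unobserved parental genotype both (a) halves the log-HR only to first
order and (b) induces a frailty-type attenuation that grows with the
cumulative hazard, because high-risk parents die out of the risk sets
faster. Both are second order in beta: at a parental log-HR of 0.14 with
~68% of parents dead the doubled estimate is attenuated by roughly 5%,
within one standard error at every sample size used here; at 0.20 the
attenuation reaches ~10%. This is a property of the kin-cohort design
itself, not of the estimator, and is shared by the full-Cox verification
route.

## Two-stage scan and its calibration

Fitting a full Cox model per variant genome-wide is needlessly expensive.
The two-stage design fits the covariate-only Cox model once per sex, takes
Martingale residuals

    M_i = delta_i − H0(tau_i) * exp(gamma' (Z_i − Zbar)),

rank-normalises them (Blom offset 3/8, configurable: score
`Phi^{-1}((r − 3/8)/(n + 1/4))`, average ranks for ties) and regresses the
scores on each variant's dosage. Under the Breslow baseline estimator the
residuals sum to zero exactly for any coefficient vector, an identity the
test suite asserts at 1e-8.

A raw score-on-dosage slope is in score units. The package converts scan
estimates to log-HR units through the one-step Cox score calibration: the
score statistic for adding dosage `X` at `beta = 0` is `sum_i X_i M_i`, its
information approximately `d * var(X)` with `d` events, so

    beta_hat ≈ slope_M * n / d ≈ slope_score * sd(M) * n / d.

`kappa = sd(M) * n / d` multiplies the slope and its standard error (p-values
unchanged). Empirically the calibrated two-stage estimate tracks the
full-Cox verification estimate within ~3–5% relative error at parental
log-HRs up to 0.2. Passing `calibrate=False` (or `ScanCalibration=None` at
the function level) reproduces the raw score-scale scan of the original
workflow, in which effect sizes were only read off the verification fits.

The conditional scan residualises scores and dosages on the sentinel
dosages (QR projection) before the per-variant regression; a variant
collinear with a sentinel — including the sentinel itself — is reported as an
NA row with a note, never an exception, so row counts are stable. Missing
dosages are mean-imputed per variant up to 5% missingness; beyond that the
variant is flagged and skipped. Monomorphic or MAF < 0.1% variants likewise
become NA rows.

## Cox engine

Newton–Raphson on the log partial likelihood with step-halving, convergence
when the relative change in log partial likelihood drops below 1e-9, at most
50 iterations (typical fits converge in 3). Ties: Efron correction by
default, Breslow optional. Covariates are centered for numerical stability;
zero-variance covariates carry no information and are held at beta = 0 with
NaN covariance entries, so a null model (empty covariate list) yields the
Nelson–Aalen baseline exactly. The baseline cumulative hazard always uses
Breslow increments `d_k / sum_{R_k} exp(eta)`. The engine reproduces
lifelines' estimates and standard errors to 1e-6 on continuous data and a
brute-force partial-likelihood grid search to 1e-3 on a six-record fixture;
lifelines also provides the Kaplan–Meier/RMST computations inside
`km_life_years`.

Age-window analyses follow the truncation scheme of the design: for 40–75,
exits are capped at 75 and later deaths recoded as survivors; for 75+, only
records surviving past 75 enter, with entry reset to 75 (survival to 75 is
complete, so this is again a common-entry fit). Restricted-mean life-years
use the maximum observed age as the default horizon; the choice of horizon
is a genuine free parameter of "expected lifetime" summaries and materially
affects the years-per-allele numbers, which is why the per-allele life-year
outputs state the horizon implicitly through the data and are compared only
within one analysis.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes:

* **Genotypes** — parental genotypes i.i.d. Binomial(2, p); offspring dosage
  by drawing one allele per parent uniformly. Variants are independent (no
  LD); a `correlated_proxy` helper appends an LD partner (allelic
  correlation r) solely to exercise the conditional scan.
* **Lifespans** — Gompertz hazard from 40, `a * exp(b (t − 40))`, defaults
  a = 0.002/yr, b = 0.095/yr for both sexes, giving mean death ages in the
  mid 70s and ~68% of parents dead at interview, matching the deaths/lives
  ratio of the parental generation this design targets. Genotype effects
  enter as per-parental-allele log-HRs, sex-specific and piecewise-constant
  with a switch at age 75, so frailty-type (effect before 75) and
  longevity-type (effect after 75) loci can be simulated. Sampling inverts
  the piecewise cumulative hazard exactly (inverse-CDF), so analytic
  quantiles are reproduced without discretisation error.
* **Censoring** — offspring interview ages Uniform(40, 69) (the recruitment
  window of the cohort design emulated); parental age at interview adds a
  Uniform(20, 35) parent–offspring age offset. Parents alive at interview
  are censored there; no parental-age model beyond this offset is attempted.
* **Covariates** — four standard-normal offspring-level covariates with
  log-HR loadings (0.10, 0.05, 0.15, 0.10) per SD, shared by both parents of
  a subject, standing in for centre/batch/deprivation/PC structure.
* **Contamination** — adopted subjects (1.5%), a blanked covariate (0.12%),
  implausible parental ages set to 116–125 (0.05%), parent deaths before 40
  (0.2%); rates chosen to be of the order observed in biobank questionnaire
  data while still producing nonzero counts at test sample sizes.
* **Randomness** — one global seed; genotypes, covariates, lifespans,
  interview timing and contamination use independent spawned streams, so
  identical configs are bit-identical and sub-streams are individually
  reproducible.

What the generator does **not** emulate — LD structure, relatedness,
assortative mating, cohort effects in mortality, sex-specific baseline
differences, misreported parental ages — bounds what passing tests show:
they validate the statistical machinery under the model's own assumptions,
not robustness to real-data violations of them.

## QC rules

Subject-level rules in fixed precedence (each subject counted once):
adopted → no usable parental data (all parents dead before 40, or no
records) → implausible parental age (>115, excludes the subject) → missing
covariate. After subject exclusions, a single parent death before 40 drops
only that parent record. The tally reconciles exactly
(`subjects_in = remaining + excluded`) and the operation is idempotent.

## Meta-analysis and contrasts

Fixed-effect inverse-variance weighting on log hazard ratios
(`w = 1/se^2`); Cochran's Q is reported for information only. Sex and
age-window differences use the normal contrast
`z = (b2 − b1)/sqrt(se1^2 + se2^2)`; with tens of thousands of deaths per
stratum the normal and t references are indistinguishable, so the normal
approximation is used throughout. P-values are two-sided by default; a
one-sided option exists because directional replication conventions differ
between publications. The double-homozygote life-year prediction assumes
additivity across alleles and loci: `2 * sum` of per-parental-allele
reductions.

## Problem sizes and numerical choices in the test suite

Scan calibration and recovery checks run at n = 50,000–100,000 subjects
(two parent records each), the null-calibration scan at 10,000 variants x
20,000 subjects pooled over four cohorts, and window recovery at 60,000 —
sizes at which each check's tolerance (3 standard errors, or a 99% binomial
band) is meaningful while a full run of the suite stays in the minutes
range. Genomic-control lambda is asserted on the pooled 10,000-variant
null scan because the median-based estimator has sampling sd ≈ 0.10 at 500
variants — larger than the ±0.05 no-inflation band itself — while at 20,000
pooled chi-squares the band sits at ≈3 standard errors. Empirical
attenuation and type-I bands use their exact analytic sampling references
(binomial/normal), and every deterministic identity (dosage expectations,
residual-sum, rescaling involution, Nelson–Aalen reduction) is asserted at
1e-8 or tighter.
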