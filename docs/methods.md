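# Methods

## Setting and model

The package analyses a small pharmacogenetic cohort: subjects with
systemic sclerosis, each genotyped at a handful of candidate
pharmacovariants (here a thiopurine-pathway pair in *TPMT*, the folate
variant *MTHFR* C677T, and the transporter variant *SLCO1B1* T521C),
grouped by prescribed therapy (azathioprine, methotrexate, both, or
other medication) and followed for five binary severe outcomes:
pulmonary fibrosis, kidney insufficiency, elevated right-ventricle
systolic pressure (RVSP > 35 mmHg, strict inequality), hypocomplementemic
urticarial vasculitis, and an FVC/DLCO ratio above 1.6 (strict).

All association inference uses the **dominant genetic model**: subjects
homozygous for the normal-function (major) allele form the referent
group (code 0); carriers of one or two minor alleles are the exposed
group (code 1). The referent is defined by enzymatic function recorded
in the variant panel, not by sample frequency. For each marker ×
outcome × stratum cell we fit

    logit P(Y = 1) = β₀ + β₁·G            (unadjusted)
    logit P(Y = 1) = β₀ + β₁·G + β₂·age + β₃·male   (adjusted)

with G the dominant code, age in years untransformed and sex coded
female = 0. The reported effect is OR = exp(β̂₁) with the Wald 95%
interval exp(β̂₁ ± z₀.₉₇₅·SE), z₀.₉₇₅ fixed at 1.959964, and a two-sided
Wald p-value. The exposure OR is invariant to the sex coding choice.
The four analysis strata are the whole cohort plus the AZA, MTX and
Other therapy strata; by default the few combination-therapy (AZA+MTX)
subjects are counted in **both** the AZA and MTX strata and never in
Other (`--stratum-policy exclusive` removes them from both single-drug
strata instead). No multiplicity correction is applied to the primary
inference (per-cell α = 0.05); a Benjamini–Hochberg column is emitted as
clearly supplementary output.

### Estimation, convergence, degeneracy

The maximum-likelihood fit uses Newton iterations (statsmodels) with
relative-change tolerance 1e-8 and at most 100 iterations; standard
errors come from the inverse observed information at the optimum. Cells
are flagged **non-estimable** (NaN estimates, explanatory note, never an
exception) when the stratum is empty after completeness filtering, has
zero or all events, has no genotype variation, or exhibits perfect or
quasi-complete separation. Separation is detected from statsmodels'
separation diagnostics plus two conservative bounds: |coefficient| > 15
on the log-odds scale or a standard error > 50 — values finite data
cannot meaningfully support. An optional Firth-penalized fit (Jeffreys
prior, modified score with hat-diagonal correction, step-halving) is
available behind an explicit `firth` flag for separated cells; it is
never used silently.

Missing genotypes are excluded per variant (complete case within each
association); nothing is imputed, and `n_used` is recorded per cell.
Subjects with missing age are excluded from adjusted models only.

## Genotype QC

Allele frequencies count minor alleles over non-missing calls. The
Hardy-Weinberg test is the three-class goodness-of-fit chi-square with
expectations (n·p̂², 2n·p̂q̂, n·q̂²) from the observed allele frequency,
zero-expectation classes skipped, referred to χ²(1) (one estimated
parameter), no continuity correction.

Two variants observed to be perfectly concordant under dominant coding
(every subject with both calls has identical codes — the TPMT *3A
haplotype pattern) are collapsed into one merged marker so downstream
analyses run once. The merged marker is named `<gene>*haplotype` unless
a name is configured, and inherits the gene, alleles and β of the first
member; per subject its call is the first member's, falling back to the
second. Concordance over zero overlapping calls is vacuous: the merge
is refused with a warning, since perfect LD cannot be asserted from no
data.

## Cohort summary and between-group tests

The therapy-group summary reports n, % of the **full cohort** (the
convention under which group percentages of a characteristic sum to its
cohort percentage), women, median age with IQR (linear-interpolation
quantiles, the definition consistent with fractional published quartiles
such as 53.25), and per-outcome counts. Binary characteristics are
compared across groups with the chi-square test (no continuity
correction) when every expected cell is ≥ 5, otherwise the Fisher exact
test — scipy's hypergeometric test for 2×2, and for 2×k a full
enumeration over tables with the observed margins, summing conditional
probabilities ≤ that of the observed table (log-factorial arithmetic;
feasible for the cohort sizes this package targets, with a chi-square
fallback and warning beyond n = 500). Degenerate tables (zero margin)
report p = 1 with a flag.

## Polygenic risk score

Each variant contributes points xᵢ ∈ {0, 0.5, 1} for 0/1/2 minor
alleles, and the score is the normalized weighted mean

    score = Σᵢ βᵢ·xᵢ / Σᵢ βᵢ,

with non-negative GWAS-style weights βᵢ (β measures impact toward
reduced enzymatic efficiency; negative weights are rejected). The
score is therefore bounded in [0, 1], monotone in each dose, invariant
to rescaling the weights, and reduces to the mean of the points under
equal weights. Missing calls drop out with the weight sum renormalized
over the variants actually used (recorded as `n_variants_used`). The
shipped weight set is an **illustrative example** (TPMT haplotype 0.9,
SLCO1B1 0.45, MTHFR 0.3) — plausible relative magnitudes, not published
estimates; real analyses should supply their own weights file.

Score distributions are compared between subjects with and without each
outcome, per stratum, with the two-sided Mann-Whitney U test: exact
enumeration when both groups have ≤ 8 observations and the pooled
sample is tie-free, otherwise the tie-corrected normal approximation
**with** continuity correction. The continuity correction is a
deliberate choice: it is R `wilcox.test`'s convention, and across 100
seeded 8-vs-8 tie-free draws the corrected approximation stays within
0.011 of the exact p-value where the uncorrected version deviates by up
to 0.046. A comparison with an empty group is reported as a NaN
p-value with an explanatory note (e.g. no subject in a stratum
developed the outcome), mirroring how such cells must appear in a
published matrix; two identical constant samples give U = n₁n₂/2 and
p = 1.

## Synthetic cohort generator

The generator is the package's stand-in for individual-level patient
data, which the motivating study does not publish. It emulates:

- **Genotypes** under Hardy-Weinberg equilibrium (two independent
  Bernoulli(q) alleles per variant), with each configured perfect-LD
  pair realized from a single latent genotype copied to both loci, so
  concordance is exact in every replicate.
- **Demographics**: sex ~ Bernoulli(female fraction); age normal with
  location at the configured median and scale (q₃−q₁)/(2·z₀.₇₅),
  resampled below 18 years (a symmetric distribution cannot also match
  an asymmetric published IQR; the width is matched, the asymmetry is
  not); therapy multinomial.
- **Outcomes**: independent Bernoulli draws per outcome from the forward
  logistic model logit P = intercept + Σ log-OR·G + β_age·age +
  β_male·male — the inferential model run generatively. Outcomes are
  conditionally independent given covariates; no outcome-outcome
  correlation is planted because none is modelled downstream.
- **Missingness**: completely at random at a configurable rate,
  default 0 (the motivating study genotyped every subject at every
  variant).

Defaults encode the study-like conditions: n = 102, ~85.3% women, age
median 59.5 (IQR 53.25–63), therapy shares 16/43/3/40 ths, European-like
minor-allele frequencies (0.032/0.032/0.365/0.16), outcome prevalences
between 5.9% and 38.2%, planted dominant effects inside the published
0.6–2.1 OR range, and mild age (+0.02/yr log-odds) and male (+0.3)
effects with intercepts offset so marginal prevalences stay near target.
All randomness flows through one seeded NumPy PCG64 generator; a fixed
seed gives bit-identical cohorts and fixture files (no time-based
entropy). `GroundTruth` echoes the configuration plus realized
frequencies and prevalences for parameter-recovery comparisons.

What passing tests on these cohorts do **not** show: robustness to
population stratification or relatedness, non-MCAR missingness,
correlated outcomes, measurement error in age or outcome adjudication,
or real LD structure beyond the perfect-concordance special case — none
of which the generator emulates.

A separate deterministic constructor (`margins_cohort`) builds a cohort
reproducing exact per-group margins (sizes, women, outcome counts) for
summarizer checks; within groups the joint distribution is arbitrary by
construction.

## Validation experiments and problem sizes

`sscpgx.experiments` packages the validation battery (run full-size by
`scripts/acceptance.py`, reduced in `analysis/06_validation.py`):

- **Oracle equivalence** — on 200 random non-degenerate 2×2 tables the
  fitted single-covariate logistic OR is compared with the closed-form
  cross-product ratio ad/bc and the Wald CI with the Woolf form
  √(1/a+1/b+1/c+1/d); agreement is at numerical precision (~1e-14).
- **Parameter recovery** — 500 cohorts of n = 5,000 with a planted
  adjusted OR of 1.95 (MAF 0.365, prevalence 0.2, age and sex effects
  active): mean recovered log-OR within ±0.03 of truth and CI coverage
  within [0.93, 0.97].
- **Null calibration** — 2,000 replicates each: the exposure Wald test
  (n = 500, MAF 0.3, prevalence 0.2) and the PRS Mann-Whitney
  comparison (scores from the four-variant panel, outcome independent)
  both reject at α = 0.05 within [0.035, 0.065].

These problem sizes keep each experiment to a few minutes on one core
while leaving Monte-Carlo standard errors (≈0.005 on log-OR means and
rejection rates) small relative to the asserted bands.

## Known limitations

- Wald inference is first-order; in very sparse strata (the 16-subject
  AZA arm with a rare variant) intervals are wide and cells frequently
  non-estimable — faithfully reported rather than repaired, unless the
  Firth option is requested.
- The 2×k Fisher enumeration is exponential in k; it is intended for
  the 2×4 tables of this design.
- The PRS is a fixed-panel weighted score; no genome-wide construction
  (clumping, thresholding, shrinkage) is provided.
- The generator's age distribution matches median and IQR width, not
  skew; therapy assignment is independent of genotype and outcome
  (no confounding by indication is planted).
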