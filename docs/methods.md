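# Methods

## The severity gradient

The package operationalises the continuum-of-morbidity idea for registries
that predate dedicated near-miss data collection: rather than the full WHO
clinical/laboratory/management near-miss criteria, it grades records with
*proxy* criteria available in routine perinatal registries.  Classification
walks a fixed precedence ladder and stops at the first match:

1. **MD** — death status recorded as death at the facility or during
   transport/referral.  Not configurable.
2. **MNM** — any of: eclampsia or magnesium sulfate for eclampsia; cardiac
   disease; renal disease; hospital stay > 7 days; or blood transfusion
   *jointly with* haemorrhage (any trimester or postpartum).
3. **PLTC** — any of: abruptio placentae, ectopic pregnancy, uterine
   rupture, postpartum haemorrhage, puerperal sepsis or infection, severe
   preeclampsia without magnesium sulfate, severe hypertension, any blood
   transfusion, placenta previa with haemorrhage, another severe condition.
4. **LSMM** — anaemia, HIV+, diabetes, antenatal admission, ovular
   infection, urinary tract infection, another maternal condition, retained
   placenta, or referral.
5. **NONE** otherwise.

Precedence makes the five classes mutually exclusive and exhaustive, and
adding a more severe condition can never lower a record's class (a tested
invariant).  Criteria are data, not code: YAML rule lists (`is_present`,
`greater_than`, `equals`; OR across rules, AND within a combined group)
validated against the schema, so sites can add criteria they record.

**Transfusion/haemorrhage reading.**  Proxy criterion lists overlap: "any
blood transfusion" and "postpartum haemorrhage" appear at the PLTC level
while "transfusion (any amount) and haemorrhage" defines the near-miss
level.  The shipped default requires transfusion AND haemorrhage jointly
for MNM, leaving transfusion alone at PLTC — otherwise the PLTC transfusion
rule could never fire.  The single-criterion reading is selectable by
moving one rule in the config; a test pins this behaviour.

**Missingness.**  Condition flags are tri-state; a missing state never
satisfies a criterion.  A registry can only act on recorded diagnoses, so
classification is deliberately conservative under incompleteness; no
imputation is attempted anywhere.

**History vs index-pregnancy events.**  Eclampsia, cardiac and renal
disease exist both as previous-condition fields (`prev_*`) and as index
event flags; the schema keeps them separate and only the event flags feed
the classifier.

**Hospital stay.**  `hospital_stay_days` is the total facility stay for the
childbirth admission; whether antepartum days should count toward the
"> 7 days" criterion is genuinely open, so the threshold lives in the
editable config rather than in code.

## Indicators

With live births LB (records with a live-born infant) and women N:

- MMR = 100,000 · MD / LB; MNMR, SMOR, PLTCR, LSMMR, AMMR = 1,000 · count / LB
- class percentage = 100 · count / N
- morbidity-to-death ratio = (AMM − MD) / MD — survivors with any degree of
  morbidity per maternal death; undefined (reported as null) when MD = 0.

Unrounded values are retained; display rounding is 1 decimal for ratios,
1–2 decimals for percentages, nearest integer for the morbidity-to-death
ratio.  LB ≤ N is *not* enforced (multiple gestation could violate it in
other registries); a warning is emitted instead.  Zero live births is an
error.

## Cluster-corrected chi-square

Records cluster by country (the PSU).  For each cross-tabulation the
package computes the Pearson X² and divides it by a first-order design
effect: the mean, over informative table cells, of

    deff_cell = Var_PSU(p̂) / (p̂(1−p̂)/n),

where Var_PSU is the with-replacement PSU linearisation
`G/(G−1) · Σ_g (x_g − p̂ n_g)² / n²`.  The corrected statistic is referred
to the chi-square distribution on the unchanged degrees of freedom.  With
one cluster the design effect is fixed at 1, so the corrected test equals
the classical Pearson test exactly (tested against a closed-form oracle).
Degenerate tables (a zero margin) return a flagged not-defined result.
Known limitation: with few PSUs the estimated design effect is noisy
(coefficient of variation ≈ √(2/(G−1))), so calibration is verified under a
many-cluster i.i.d. null (50 PSUs, type-I error within Monte-Carlo bounds
of 0.05 over 2,000 replicates); no second-order (Satterthwaite) correction
is implemented.  Missing values are excluded per variable and the missing
fraction reported with each table.

## Prevalence ratios

The analysis population for outcome class k is {k} ∪ {NONE}; complete-case
on the model variables.  Crude PR from the 2×2 counts uses the Katz
log-normal CI (cross-checked against an independent relative-risk
implementation).  Adjusted PRs come from a log-link binomial GLM on all
covariates simultaneously; because that likelihood often fails near the
boundary, a modified-Poisson estimator (log-link Poisson with robust
sandwich variance) is the fallback — both target prevalence ratios
directly, avoiding the odds-ratio inflation of logistic coefficients for
common outcomes.  With PSU labels the covariance is the cluster sandwich
and CI critical values are t(G−1) rather than normal quantiles — the
standard small-G correction, without which 12-PSU intervals undercover
(~93% instead of ~95-96% in the package's own coverage simulations).
Fitting is deterministic: tolerance 1e-8, at most 100 iterations;
separation or non-convergence yields flagged not-defined entries.
Reference levels default to: age 20–24, white ethnicity, secondary+
literacy, married/stable partner, multipara, > 4 prenatal visits, no risk
exposure, no previous C-section, spontaneous onset, vaginal delivery.

A saturated one-covariate log-binomial fit reproduces the count-based crude
PR exactly (tested at 1e-6), which is the package's internal consistency
oracle between the two routes.

## Synthetic registries

The generator emulates a multi-country registry extract: 12 clusters by
default, a severity mixture equal to the observed count fractions
(MD 0.00144, MNM 0.03087, PLTC 0.15453, LSMM 0.19322, NONE 0.61994),
covariate prevalences matching the no-morbidity profile of the source
tables, per-field MCAR missingness at the footnote rates (0.4% age up to
31.1% risk exposure), the neonatal near-miss gradient 4.9/6.4/5.2/14.5/
13.1% (NONE→MD) and class-conditional stillbirth rates 1.9–4.9%.

Class assignment uses an exact multiplicative-risk model: for each
morbidity class, p = base · exp(Σ covariate log-PR effects), remainder to
NONE.  Configured effects are therefore recoverable on the risk scale; a
config whose worst-case class probabilities exceed 1 is rejected before
generation.  Note one subtlety of the outcome-vs-no-morbidity design: when
an exposure raises *all* morbidity classes (as the default
previous-condition effect does), the reference group shrinks among the
exposed and the estimated conditional PR exceeds the marginal risk ratio —
e.g. a risk-scale effect of 2.49 on MNM appears as ≈ 3.3 against the
no-morbidity group.  Parameter-recovery experiments therefore place the
effect on a single class, where the conditioning distortion is negligible
(< 0.1%).

Criterion flags are set so the classifier provably returns the intended
class (one mechanism drawn per record, plus co-occurring lower-grade flags
that precedence absorbs), and criterion fields are never masked, keeping
label fidelity at exactly 100% by construction — a deliberate choice so
that classification errors in tests always indicate bugs, not simulation
noise.  A `mask_criterion_fields` switch lifts this for robustness
experiments.  Optional per-cluster log shifts on class risks
(`cluster_effect_sd`) and on covariate prevalences (`covariate_cluster_sd`)
induce intra-cluster correlation for design-effect and sandwich-variance
tests.  A single `numpy.random.default_rng(seed)` stream makes cohorts
byte-reproducible.

**What the generator does not emulate:** real between-country heterogeneity
patterns (magnitudes are free parameters, unknown in the source), MAR/MNAR
missingness, multiple gestation, record linkage across pregnancies, and
criterion misrecording.  Passing tests therefore demonstrate correctness of
the pipeline's logic and calibration of its statistics under MCAR and known
truth — not robustness to informative missingness or miscoding.

## Problem sizes and simulation designs

Chosen as the package's own verification budget: label-fidelity and
partition checks at n = 20,000 over three seeds; mixture convergence at
n = 100,000 (3 binomial SEs); adjusted-PR recovery at n = 50,000 with 12
clusters and effects log 2.0 / log 1.3 on the near-miss class, with
exposure prevalences set to 0.3 so the log-PR standard error (~0.05) sits
well inside the ±10% acceptance band; null CI coverage over 500 replicates
of n = 3,000 (threshold ≥ 93%); corrected-test calibration over 2,000
i.i.d.-null replicates of 50 × 40 records.

## Known limitations

- Proxy criteria under-identify near miss relative to organ-dysfunction
  criteria; the classifier is only as good as its configured rule lists.
- No cause-of-death attribution, no survey weights, no country-stratified
  estimation (single-registry design), no multiple-testing adjustment
  (tests are reported at α = 0.05 individually).
- Adjusted PRs from different model families (log-binomial vs
  modified-Poisson fallback) can differ slightly in finite samples; the
  family used is always reported.
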