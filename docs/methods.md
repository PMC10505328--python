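# Methods

This note documents the models and procedures implemented in `hlmetsig`,
the choices made where the design was genuinely open, and what the
synthetic studies do and do not demonstrate.

## Healthy-lifestyle score

Each of the eight components is mapped to 1 / 0.5 / 0 points by
threshold predicates; the total lies on {0, 0.5, …, 8} and is
dichotomized at 4 points (≥ 4 = high). Smoking is categorical (never /
former / current → 1 / 0.5 / 0). The remaining cut-offs are shipped as a
default YAML configuration implementing a 2018 WCRF/AICR-style
operationalization (`src/hlmetsig/data/hl_components.yaml`) and are fully
user-overridable; numeric rules are evaluated high-first and interval
endpoints are **inclusive toward the healthier level** (150 min/week of
activity scores 1, not 0.5). Alcohol thresholds are sex-specific
(0 g/day → 1; up to 14 g/day women / 28 g/day men → 0.5).

Participant exclusions are applied in a fixed order — missing
FFQ/lifestyle data, implausible energy intake (strict inequalities:
a woman at exactly 3500 kcal/day is retained), then ≥ 20 % missing
metabolite values — with each participant counted under the first rule it
triggers, so the per-rule counts reconcile with the final sample size.
Note the asymmetry, kept deliberately: the *participant*-level
missingness cut-off is inclusive (≥ 20 % excluded) while the
*metabolite*-level filter is strict (> 20 % removed, exactly 20 %
retained).

## Metabolomics preprocessing

Order of operations: pooled-reference standardization → metabolite
filtering → imputation → inverse-normal transform. Filtering precedes
imputation so no high-missingness column is ever imputed; the transform
is applied last so downstream models see marginally normal columns. The
orderings of imputation and transformation are both defensible; the
completed-matrix-then-transform order was chosen because the rank-based
transform makes the imputed values' scale irrelevant downstream.

* **Standardization.** Each participant value is divided by the value of
  the nearest pooled reference in injection order and multiplied by the
  per-metabolite median over all references. Ties in run-order distance
  break toward the *earlier* injection. A reference with a missing or
  zero value for some metabolite is skipped in favour of the next
  nearest; a metabolite with no usable reference is flagged unusable
  rather than silently passed through.
* **Filtering.** Internal standards first, then metabolites missing in
  more than 20 % of participants, survivor order preserved.
* **Imputation.** missForest-style: initialize missing entries at column
  means, visit columns in increasing-missingness order, regress each on
  all others with a random forest (default 100 trees, `sqrt` feature
  subsampling) and replace its missing entries with predictions; stop
  when the relative change of the imputed values rises (returning the
  previous iterate), falls below `tol`, or at `max_iter` (default 10).
  Deterministic given the seed. On an exactly linear rank-one toy the
  tree ensemble imputes to within ~5–10 % RMSE of the column scale —
  piecewise-constant trees do not interpolate linear relations exactly,
  which is the known price of this imputer.
* **Transform.** Blom variant of the rank-based inverse-normal
  transform, Φ⁻¹((rank − 3/8)/(n + 1/4)), average ranks for ties, missing
  entries left missing; the 3/8 offset is the most common convention in
  metabolomics pipelines. A constant column maps to all zeros with a
  warning.

## Signature derivation

The penalized objective is `L + λ[(1−α)/2‖β‖² + α‖β‖₁]` with `L` the mean
squared error / 2 (linear) or the mean negative log-likelihood of the
logit model (logistic). Fits use scikit-learn's coordinate descent
(`ElasticNet`/`enet_path`; closed-form ridge for α = 0, least squares for
λ = 0) and SAGA for the logistic family, with the penalty
reparameterized to this objective (λ = sklearn's `alpha`, α = `l1_ratio`;
`C = 1/(nλ)` for logistic). Predictors are standardized to unit variance
internally for the penalty; coefficients are reported on the input scale.
After a SAGA fit the unpenalized intercept is polished by 1-D Newton on
its score equation — SAGA's step size shrinks with the penalty and can
otherwise leave the intercept short at extreme λ.

* **λ path**: 100 log-spaced values from λ_max (the smallest λ giving an
  all-zero fit, `max_j |⟨x_j, y−ȳ⟩|/(n·α)` with α floored at 0.001 so
  pure ridge gets a finite path) down to 0.001·λ_max. Path length and
  ratio are conventions, config-exposed.
* **λ selection**: K-fold CV (default K = 10); loss is MSE (linear) or
  mean binomial deviance (logistic); per-λ SE = SD over folds / √K;
  `lambda.1se` = largest λ whose mean CV error is within one SE of the
  minimum. This parsimony rule is the pipeline's main sparsity control.
* **α selection** (optional): leave-group-out CV with 10 random subsets
  over the grid 0, 0.1, …, 1, inner λ at `lambda.1se`, scored by held-out
  MSE (linear) or accuracy (logistic); ties break toward smaller α.
  Defaults when not trained: α = 0.1 (continuous response) and α = 0.6
  (dichotomous), the conventional reference values for this workflow.
* **Replication**: R = 10 replicates, each a fresh K-fold split →
  `lambda.1se` → whole-data refit at that λ. `coef_avg` averages over all
  replicates *including zeros*, mirroring selection instability as
  shrinkage; the signature is the set selected in all R replicates
  (threshold config-exposed).

## Validation

Pearson r with the Fisher-z interval `tanh(atanh(r) ± z/√(n−3))`
(at r = 0.5, n = 1833 this gives (0.4649, 0.5336)); ROC AUC as the
Mann–Whitney statistic with ties at ½ and a seeded class-stratified
bootstrap percentile interval (2000 resamples). The CI methods are
package choices; neither quantity's interval method is dictated by the
workflow itself.

## Case-cohort survival analysis

`expand_barlow` turns a design (all cases + subcohort, overlap recorded
once with both roles) into counting-process records: subcohort non-cases
contribute (entry, t] at weight 1/f; subcohort cases additionally split
at t − ε, carrying weight 1/f before and weight 1 with the event after;
non-subcohort cases contribute only (t − ε, t] at weight 1. ε is half the
smallest positive gap between distinct event times, capped at half the
earliest event time. f is estimated as subcohort size / full-cohort size
(a single f; per-stratum sampling is out of scope).

The weighted partial likelihood is maximized by lifelines'
`CoxPHFitter` through its left-truncation interface (`entry_col`), with
Breslow tie handling, baseline stratification by center × arm, and the
robust sandwich variance clustered by participant id — all records of
one participant form one cluster. At f = 1 this reproduces an ordinary
unweighted Cox fit to machine precision (verified to 1e−6 in tests).

The three covariate models: (1) signature + age + sex + propensity
scores; (2) + education, family history of CHD, hypercholesterolemia,
cholesterol-lowering medication, hypertension, antihypertensive
treatment, energy intake, plus prevalent diabetes for the CVD outcome;
(3) + self-reported HL in the form matching the signature. One-year
analyses drop participants whose follow-up ended at or before the visit
and left-truncate the rest at t = 1; the sampling fraction is kept
unchanged (the subcohort remains a random sample of the year-1 risk set
up to the cases removed, a standard approximation). Propensity scores
come from a multinomial logistic regression of arm on the model-2
covariate set (weak ridge by default, stabilized refit on separation),
entering as the two non-reference predicted probabilities.

Arm-interaction tests compare weighted partial log-likelihoods with and
without the arm × signature product term, one MedDiet arm vs control at
a time, referring 2Δll to χ²(1). Because the Barlow likelihood is a
pseudo-likelihood this is a *pseudo*-LRT; a robust Wald p for the
product term is reported alongside, and the simulations show the two
agree closely at these sample sizes. These models stratify by center
only, since arm enters as a covariate.

## Synthetic studies: what they emulate

`SimConfig` defaults describe the reference study conditions: ~1500
elderly participants (ages 55–80, ~58 % women, four centers, three
equal arms), 385 metabolites in equicorrelated blocks of 5 (ρ = 0.3), 20
signal metabolites, 2 % missingness, a protective hazard (log HR −0.6
per SD of HL), administrative censoring at 6 years with baseline hazard
0.02 (≈ 11 % events), and a 30 % subcohort.

Adherence levels are i.i.d. categorical over {0, 0.5, 1} with
probabilities (0.3, 0.4, 0.3) per component — giving HL mean 4.0 and SD
√(8 × 0.15) ≈ 1.10 — and raw component values are drawn uniformly inside
the scoring region of the drawn level, so re-scoring reproduces the
levels exactly. Log-abundance of metabolite j is
`m_j + loading_j·s_i + ε`, with `s` the standardized HL score,
block-equicorrelated unit noise, and log-normal output (abundances are
positive, as the ratio-based standardization requires); internal
standards are near-constant spiked columns, pooled references are noisy
copies of the geometric grand mean injected every 20 records. Event
times are exponential (Weibull behind a config switch) with hazard
`h₀·exp(logHR·s_i)`.

For the recovery experiments the per-metabolite loading is sized in
closed form: with m signal metabolites in distinct blocks and unit
noise, the equal-weight signature correlates
`mℓ/√(m²ℓ² + m)` with s, so ℓ = r/√(m(1−r²)) — for the target r = 0.5
with m = 20, ℓ ≈ 0.129. The measured signature–HL correlation at study
scale is ≈ 0.51, confirming the calibration. Recovery runs use complete
matrices (no missingness) to isolate selection performance from
imputation error, and train α by leave-group-out CV as the protocol
prescribes; with a 20-of-385 sparse truth the trained α lands at 0.8–1.0
and the every-replicate signature attains sensitivity 1.0 at a false
discovery proportion ≈ 0.2. At ridge-leaning α (0.1) the `lambda.1se`
support is much wider (FDP > 0.5): α genuinely matters for support
recovery, which is why the protocol trains it. Selected "false"
discoveries are typically block neighbours of signal metabolites, which
the elastic net uses with small opposite-sign coefficients to cancel
shared noise — they are false against the planted loadings but genuinely
predictive, a phenomenon real metabolomics signatures share.

What the generator does **not** emulate: FFQ item-level structure,
biologically named metabolites and their pathway correlations,
batch/plate effects beyond a smooth reference-correctable drift,
informative missingness (missingness is MAR by construction), competing
risks, and covariate-dependent treatment assignment (arms are
randomized, as in the target design). Passing recovery tests therefore
demonstrates correctness of the machinery under a faithful but idealized
data-generating process, not field performance on real cohorts.

## Problem sizes and numerical conventions

The reference experiments (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: exclusion fixtures at n = 1882; the
399-metabolite filter fixture at n = 250 participants; 200 case-cohort
simulations at n = 3000, f = 0.3; signature recovery over 5 seeds at
n = 1500, p = 385; null cohorts over 10 seeds at n = 200, p = 100. The
module test suite uses smaller versions of the same designs. Solver
agreement tolerances are 1e−6 against closed forms; Cox full-cohort
equivalence is 1e−6 in log HR (exponential times are tie-free almost
surely, so Breslow and Efron coincide). Degenerate inputs fail loudly:
constant responses in CV, single-class labels in AUC, fully missing
columns in imputation, constant product terms in the interaction test.
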