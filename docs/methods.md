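# Methods

This note records the modelling conventions, defaults, and numerical
choices behind `salpnet`, and what the synthetic-data generator does and
does not emulate.

## Cohort construction

**Encounter grouping.** Claims carry no encounter identifier, so one is
derived: outpatient lines group by (enrollee, service date); inpatient
lines group by (enrollee, admission), where an admission is a maximal run
of consecutive inpatient service dates. This is the minimal claims-native
definition; it cannot distinguish two same-day outpatient visits to
different facilities.

**Candidate encounters.** A sterilization candidate needs a tubal-ligation
or salpingectomy procedure code *and* a sterilization-encounter diagnosis,
and must carry no abortion or ectopic-pregnancy diagnosis. Setting class
is structural: postpartum iff inpatient with a delivery code, interval iff
outpatient. Inpatient encounters without a delivery code, or encounters
mixing settings, go to an explicit rejects stream rather than being
silently dropped.

**Operating surgeon.** The physician billing the sterilization procedure;
if several bill it, the one with the most interaction-days with the
patient, then the lowest physician id. Surgeons outside {OB/GYN, urology}
are treated as implausible and excluded.

**Exclusion cascade** (order fixed, attrition telescopes): age 18–49 at
the encounter; continuous insurance coverage over the prior 365 days
(missing enrollment is its own row; *continuous* means no gap of one day
or more — no administrative grace period, a deliberately strict reading);
diagnosis exclusions over the prior 12 months **and** the encounter
itself (surgical history — hysterectomy / prior ligation / absent organs;
tube or ovary disorders; cancer or elevated risk); a salpingectomy or
oophorectomy procedure in the 12 months strictly *before* the encounter
date; surgeon identity/specialty. All intervals are half-open
`[start, end)`; dates are ISO-8601.

**Age.** Claims carry birth year only; age uses a July-1 mid-year
convention. Band edges (18–29, 30–34, 35–39, 40–49) are closed on both
sides at whole years.

**Diagnosis-coded covariates.** BMI class and smoking come from diagnosis
codes in the 12 months through the encounter. Claims only code the
abnormal, so absence maps to BMI `<25` and non-smoker. (That convention is
what makes a `<25` share above 60% plausible in claims cohorts — it is a
coding artifact, not measured anthropometry.) Comorbidity burden is the
count of *distinct* diagnosis groups from a small configurable
Elixhauser-style map, classed 0 / 1 / ≥2. A full Elixhauser engine is out
of scope; the mapping is a declared stand-in, overridable per run.

**Code dictionary.** All code sets (procedures, diagnoses, deliveries,
BMI bands, comorbidity groups) live in one dataclass with a small shipped
default inventory; any set can be replaced wholesale from YAML. The
defaults are deliberately minimal and plausible, not a reproduction of any
proprietary appendix.

## Network construction

Links are (patient, physician) pairs weighted by interaction-days
(distinct service dates — multiple lines on one date count once),
restricted to OB/GYN, urology, and primary care. Each patient is capped at
her top-8 physicians by interaction-days, ties to ascending physician id
so results are unique. **Capping happens before the node and edge
thresholds** (order changes degrees; fixed here). The projection keeps
physicians with ≥ 4 distinct patients and joins pairs sharing ≥ 2
patients, edge weight = shared-patient count; both thresholds are asserted
post-construction. Graphs are built independently per HRR; a physician
billing in several HRRs is assigned by plurality of claim lines, ties to
the lowest HRR id, with a warning.

Modularity uses edge weights by default (unweighted mode behind a flag),
and `modularity()` implements the formula directly so library partitions
can be checked independently. Community detection is seeded Louvain
(networkx backend); the seed only affects sweep order, and community
labels are canonicalized by each community's smallest member so output is
stable. The resolution parameter is exposed but fixed at 1 (classic
modularity). Network density is `2E_c / (n_c (n_c − 1))` on the induced
subgraph, undefined (NaN) for singletons.

## Peer exposure

A surgeon's baseline rate is OS count over eligible T1 sterilizations;
`baseline_nonuser` means ≥ 1 eligible T1 sterilization and zero OS. Peers
are *other* same-network physicians with ≥ 5 eligible T1 sterilizations —
volume is the only criterion; a zero-rate peer still counts. The exposure
is the unweighted physician-level mean of peers' rates (no volume
weighting), undefined when the peer set is empty, in which case the
surgeon leaves the analysis. Quartile breakpoints are the 25th/50th/75th
percentiles (linear interpolation) of the surgeon-level exposure
distribution, pooled across both setting samples by default (flag to
separate); intervals are closed on the right, so a value exactly on a
breakpoint takes the lower quartile. Breakpoints are rounded only for
display, never for assignment. A surgeon with no T1 sterilizations has no
rate and no nonuser status and is excluded — the nonuser restriction
presupposes baseline activity.

## Outcome model

Patient-level logistic regression with a surgeon random intercept nested
in a network random intercept. Fixed effects: the exposure quartile
(always, Q1 reference) plus covariates passing univariate screening at
P < .2 (χ² for categorical, Wilcoxon rank-sum for the surgeon-volume
count, which enters linearly). Reference levels are the first-listed
level of each characteristic (age 18–29, vaginal delivery, BMI <25,
non-smoker, 0 comorbidities, Midwest, SDI <25, non-metro, year 2020).

**Estimation.** Nesting makes the joint random-effect Hessian arrowhead
per network (diagonal surgeon block plus one border row), so the inner
Newton solve, log-determinant, and linear algebra are O(n) and vectorized.
On top of that machinery two marginal-likelihood approximations exist:

- `laplace`: classic Laplace at the joint mode — what `lme4::glmer` does
  with two grouping factors. A test pins this path to `glmer` on a
  simulated dataset (coefficients, SEs, variance components, log-likelihood
  all agree to ~3 decimals).
- `agq` (default): nested adaptive Gauss–Hermite quadrature, 7 points per
  level. Conditional on the network intercept the surgeons are
  independent, so the likelihood factorizes into an inner per-surgeon 1-D
  integral (re-centered at the conditional mode by vectorized Newton
  steps) and an outer per-network 1-D integral (centered at the Laplace
  mode, scaled by the arrowhead Schur complement). This is the estimator
  family used by multilevel-logistic tooling such as Stata's `melogit`.

The quadrature default is a deliberate design choice: with binary
outcomes and realistic cluster sizes (≈ 8–16 encounters per surgeon) the
Laplace approximation biases variance components downward by roughly
5–10%, which propagates into the variance decomposition; the nested
structure makes full quadrature cheap enough (≈ 2 s at n ≈ 5,000) that
there is no reason to accept that bias in final fits. Laplace remains the
default inside the parametric bootstrap, where speed matters and the
bias largely cancels between point estimate and resamples.

Optimization is L-BFGS-B over (β, log σ²_s, log σ²_n), Laplace pass first
and AGQ refinement from its optimum; log-variances are bounded in
[log 1e-8, log 1e4] and a solution at the lower bound is flagged as a
boundary estimate. Standard errors come from the central-difference
observed information; ORs and 95% CIs are exact exponentials of
coefficient ± 1.96·SE (Wald, no small-sample correction). Degenerate
inputs (constant outcome, single network, surgeon in two networks)
raise immediately.

**Variance decomposition.** From the null model (intercept + both random
intercepts): patient share = (π²/3)/T, surgeon share = σ²_s/T, network
share = σ²_n/T, T = σ²_s + σ²_n + π²/3 ≈ σ²_s + σ²_n + 3.2899 — the
standard latent-threshold convention for logistic models. Shares sum to 1
by construction. CIs are percentile intervals from a parametric bootstrap
(default B = 200): outcomes resimulated from the fitted null model on the
observed grouping structure, refit, decomposed; failed or degenerate
replicates are dropped with a warning.

**Density interaction.** The main model plus a network-density main
effect and quartile × density terms, with a joint 3-df Wald test.
Constant density is rejected as inestimable; a non-positive-definite or
exploding Wald covariance (typical when only a handful of networks carry
the density signal) raises rather than reporting a spurious P value.

## Synthetic-data generator

The generator targets *structure*, not marginals: it emulates the shape
of a two-era commercial-claims sterilization study — physicians of three
specialties in planted communities nested in HRRs, patients whose visits
follow a stochastic block model (home community with probability
`p_within` = 0.9, another same-HRR community with `p_between` = 0.08,
anywhere otherwise), sterilization encounters in two settings with
claims-native procedure/diagnosis codes, covariate category frequencies
set to published cohort proportions (e.g. 92.3% cesarean, 61.8% BMI <25),
and a planted logistic outcome model for follow-up encounters of
baseline-nonuser surgeons with quartile effects (default log 1.3, log 1.7,
log 2.17), surgeon and network variance components (0.5 each), and a few
nonzero covariate effects (cesarean +0.8; years 2021/2022 +0.25/+0.5;
South −0.4; most-deprived SDI −0.3).

Baseline surgeon behaviour is a mixture: a configured fraction (0.6) of
strict nonusers (rate exactly 0 — these form the analyzable follow-up
sample) and users with Beta(1.2, 6) rates (mean ≈ 0.17). The Beta
parameters are arbitrary — surgeon-level baseline rate distributions are
not published — and are flagged as such; only their support matters for
the pipeline's logic. Planted exposure quartiles are computed from
realized baseline rates within *true* communities among peers meeting the
volume rule, excluding design-excluded encounters, so a correct pipeline
can recover them exactly when community recovery is exact.

Randomness flows from one global seed through named substreams (CRC-keyed
`SeedSequence`s), so adding a later generation stage never perturbs
earlier draws and identical configs are bit-identical. Enrollment is
continuous by construction with a small dropout rate (0.02) that plants
coverage gaps to exercise the continuity filter; exclusion diagnoses are
planted at configured rates (≈ 0.02 each) to exercise the cascade.

Default world size (2 HRRs × 4 communities × 30 physicians, 1,600
sharing patients, ≈ 8 sterilizing OB/GYNs per community at ≈ 9 baseline
and 8 follow-up procedures each) was chosen so that community graphs are
sparse enough for density to vary (≈ 0.3–0.5) yet volumes clear the
5-procedure peer rule — mirroring the dozen-sterilizers-per-network scale
of published cohorts while staying runnable in seconds.

**What passing tests do not show.** The generator draws covariates
independently of each other and of the network, uses a tiny code
inventory, ignores geography, billing noise, physician turnover, and
temporal trends in adoption. Recovery results certify the *estimators and
plumbing*, not robustness to real-data messiness such as confounded
exposure, informative coverage gaps, or miscoding.

## Calibration study

The estimator calibration study uses 100 seeded replicates of ~5,000
encounters arranged as 52 networks × 12 surgeons × 8 encounters — many
networks with about a dozen sterilizing surgeons each, the scale reported
for real patient-sharing cohorts — with β_Q4 = log 2.17, both variances
0.5, and balanced surgeon-level quartiles drawn directly from the model
(the claims plumbing would only add noise around the quantity being
calibrated). Under these conditions the AGQ estimator shows |bias| <
0.05 on β_Q4, 95% CI coverage within [0.92, 0.98], and variance-component
means within Monte-Carlo error of truth.

## Known limitations

- The encounter grouper cannot separate same-day outpatient encounters at
  different facilities, and transfers between hospitals merge into one
  admission.
- Louvain is a heuristic; quality is certified exhaustively only for
  small graphs (≤ 6 nodes) plus planted-structure recovery, and the
  non-overlapping partition is an assumption, not a finding.
- The Wald intervals carry no small-cluster correction; with few networks
  the network-variance share is noisy and its bootstrap interval wide.
- Surgeon volume enters the model linearly; log or categorical codings
  are configurable upstream but not tested as defaults.
- The density-interaction test needs real variation in density across
  many networks; on small worlds it (correctly) refuses to answer.
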