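# Methods

## The phenotyping problem

Post-HCT ARDS cohorts are small (a few hundred patients at best), the
candidate phenotype-defining variables are a mix of roughly symmetric
vitals and heavily right-skewed laboratory values, several variables have
missing entries, and the scientific questions are: how many latent
phenotypes does the admission data support, how stable is the
classification, can a handful of variables reproduce it, and do the
phenotypes differ in outcome? `phenolca` implements that workflow as a
library plus CLI, with a synthetic cohort generator standing in for the
(non-public) patient data.

## Synthetic cohort generator

`cohort.default_cohort_params()` encodes a two-phenotype reference cohort
of 166 patients (fixed class sizes 81 and 85, not multinomial draws, so
fixtures are exact):

- Variables reported as mean (sd) in the source cohort tables are sampled
  normal; variables reported as median (IQR) are sampled lognormal with
  `mu = ln(median)` and `sigma = ln(Q3/Q1) / (2 * 0.6745)`, which
  reproduces the printed median and quartiles exactly. PCO2 is in mm Hg
  (the source prints both mm Hg and kPa in different places; the tabled
  unit wins).
- Binary variables (allogeneic transplant, male sex) are Bernoulli with
  the printed per-class frequencies (0.704/0.459 and 0.543/0.553).
- Within a class, variables are independent by default. A within-class
  correlation hook (a Gaussian copula over the continuous block) exists;
  we verified that plausible physiological correlation blocks make the
  discriminating variables partially redundant and *weaken* class
  recovery, so independence is both the simpler and the more faithful
  emulation of the analysis' observed behaviour.
- Survival is exponential per class with hazards calibrated so that
  90-day mortality is 72.8% (class 1) and 48.2% (class 2):
  `lambda_c = -ln(1 - q_c)/90`, i.e. 0.01446 and 0.00731 per day, an
  implied hazard ratio of 0.505 for class 2 vs class 1. Follow-up is
  administratively censored at day 90.
- Ventilator days, hospital days and time from transplant to ARDS are
  lognormal per class (matched to the reported medians/IQRs; the hospital
  length-of-stay parameters are a clinical-plausibility choice since no
  marginal is printed), capped at time alive. Syndrome flags (PERDS, IPS,
  DAH) are independent Bernoulli draws at the reported per-class rates —
  they are generated attributes for downstream description, never inputs
  to clustering.
- Missingness: each class-defining cell is blanked independently at the
  variable-specific rates reported for the source cohort (albumin 23.5%,
  glucose 6.6%, bicarbonate 5.4%, ..., bilirubin 0.6%; 13 of the 21
  roster variables carry a nonzero rate). An optional missing-at-random
  mode concentrates the missingness in rows above the median of a chosen
  covariate. Outcome columns are never blanked.

The hidden `true_class` column is retained purely for test assertions and
is excluded from every analysis input.

What the generator does *not* emulate: within-class correlation of real
physiology, measurement rounding, site effects, informative missingness
tied to unobserved severity, and competing risks. Tests passing on this
generator therefore demonstrate the *software* behaves as specified under
the assumed data-generating model, not that the clinical findings would
replicate on new patients.

## Imputation

`impute.mice_impute` is a chained-equations imputer over the
class-defining block only (outcomes are deliberately excluded to avoid
leaking outcome information into class discovery). Variables are visited
in order of ascending missingness; continuous variables use predictive
mean matching (OLS predictions, donor pool of 5, donor drawn uniformly),
binary variables a ridge-stabilized logistic draw. Defaults m = 5
completed tables and 10 cycles are declared conventions (the source
analysis does not state them).

The clustering stage consumes a single *consensus* completed table
(`impute.consensus_table`): observed cells untouched, imputed continuous
cells averaged over the m tables, imputed binary cells majority-voted.
Pooling removes the single-chain draw noise that would otherwise leak
into the mixture likelihood (worth several BIC units of class-count
margin at n = 166) while still reflecting every chain — one canonical
dataset carrying both within- and between-imputation information. The
sensitivity check (`imputation_assignment_stability`) refits the latent
class model on each completed table separately and reports mean pairwise
per-patient agreement after optimal label matching.

## Latent class engine

`engine.standardize` z-scores the roster (dropping the collinear pH and
minute-ventilation columns when present) and records means/sds for
inverse transforms. Lognormal-family variables are log-transformed before
scaling: the source analysis only says the data were scaled, but
z-scoring raw heavily skewed labs leaves within-class distributions so
non-Gaussian that a mixture spends components on tails instead of
classes; log-then-scale is standard practice and makes the generator's
within-class model exactly the fitted model.

The mixture likelihood is mixed-mode: Gaussian for continuous columns
(structures: spherical/diagonal/full × equal/varying; default
diagonal-varying, the analogue of mclust's VVI) and Bernoulli for binary
columns. Binary indicators are *not* given Gaussian variances: a free
per-component variance on a 0/1 column creates degenerate
likelihood spikes (a component that captures one level of a binary
variable drives that variance to the floor), and under honest multi-start
optimization those spikes dominate the likelihood and hijack model
selection. The Bernoulli term is the classical latent-class treatment and
removes the degeneracy. `n_params` follows the usual counts, e.g.
`(k-1) + kd + kd` for diagonal-varying Gaussians, plus one probability
per binary column per class.

EM details: each start uses an emEM-style initialization (Biernacki,
Celeux & Govaert): several greedy-k-means++ Lloyd partitions are softened
into responsibilities (0.95/0.05), run through a short EM burst, and the
candidate with the best short-run likelihood launches the single full EM
trajectory. This matters because at n = 166 the likelihood surface has
near-tied local optima; naive single k-means starts occasionally converge
to a rival basin a few nats below the global one, while emEM starts land
on the dominant solution essentially always — which is what makes the
multi-start sensitivity analysis (20 independent single-start fits,
identical classifications) reproducible rather than lucky. Best of
`n_starts = 20` starts by log-likelihood; convergence when the per-cycle
gain drops below `tol = 1e-6`; variance floor `1e-6` on (z-scored)
Gaussian variances and `1e-3` clipping of Bernoulli probabilities;
component weights below `1/(10n)` flag the fit degenerate;
non-convergence sets a flag rather than raising. Inner refit loops
(bootstrap LRT replicates, cross-validation folds, Monte Carlo stability)
use lighter init/tolerance profiles — a likelihood-ratio replicate needs
~1-nat accuracy, not full polish. Fits are bit-reproducible given the
seed, and hard labels are the posterior argmax with ties to the lowest
class index.

## Model selection

All metrics use the lower-is-better BIC convention `-2 log L + p ln n`.
`bic_dispersion` is the sd of BIC across single-start refits with
distinct initializations on the *same* data — an optimization-stability
measure, which is exactly 0 for the closed-form one-class fit (a
bootstrap-resampling sd could not be 0 there).

The parsimony index is implemented as `entropy / (k * ln BIC)`: the form
that reproduces every printed value of the reference model-characteristics
table (an in-text "×100" variant does not).

The VLMR-style test of `k` vs `k-1` has two modes. The analytic
Lo–Mendell–Rubin approximation divides `LR = 2(ll_k - ll_{k-1})` by
`1 + 1/((q_k - q_{k-1}) ln n)` and refers it to chi-square with
`q_k - q_{k-1}` df. That reference is known to be anti-conservative for
overfitted mixtures under a strong optimizer, so the *default* for
pipeline gating is the parametric bootstrap LRT: simulate from the
(k-1)-class fit, refit both class counts, report
`(1 + #{LR_b >= LR_obs}) / (B + 1)` with `B = 49` (39 in the reduced
pipeline profile; note `B >= 39` is required for a p-value below 0.05 to
be attainable). Bootstrap refits use deliberately light optimizer
settings (3 starts, tol 1e-3) — the LR only needs ~1-nat accuracy — and
its type-I error calibration is itself verified by simulation in the
test suite.

`select_model` is a pure function of the metric table: candidates must
have BIC within 20 of the minimum (differences below roughly twice the
refit sd observed in practice are treated as not decisive), smallest
class at least 5% of the cohort, a significant VLMR against `k-1`
(skipped for k = 1) and a non-significant VLMR for `k+1` (skipped when
unavailable); the smallest candidate wins, and an empty candidate set
falls back to the global BIC minimizer with a logged warning.

## Stability

`monte_carlo_stability` is row bootstrap → refit → classify the original
cohort → match labels to the reference fit (Hungarian assignment on the
confusion matrix) → per-patient agreement, kappa and ARI; non-convergent
replicates are dropped and counted. The scheme is recorded in the report
because "Monte Carlo classification stability" is not operationally
standardized. `multi_start_sensitivity` runs independent single-start
fits and reports all-pairs agreement — on the default cohort all 20
starts classify identically (agreement 1.0, kappa 1.0, ARI 1.0).

## Parsimonious model

Greedy forward selection against the full-model labels: at each step the
candidate subset is refit as the same mixture family (not a supervised
classifier, so the reduced model can assign classes prospectively),
classes are matched to the reference on training folds, and stratified
5-fold cross-validated agreement decides the next variable (ties by
roster order). Both cross-validated and in-sample trajectories are
recorded. On the default cohort the leukocyte count (the dominant
discriminator) enters within the first three steps and six variables
reach ≥0.90 cross-validated accuracy; which moderate-effect variables
fill the remaining slots varies by seed, as expected when several
variables carry similar information.

## Outcomes

Death is the event and day 90 administrative censoring. Kaplan–Meier
estimation and the Cox model (Efron ties, Wald CI, explicit reference
class) are delegated to `lifelines`; the log-rank test is the standard
observed-minus-expected chi-square. Free days follow the usual critical
care convention: death in the window scores 0, as does occupancy of the
entire window. EASIX is `creatinine × LDH / platelets` (medians of
patient-level EASIX differ from the ratio of medians, so a cohort EASIX
summary cannot be checked against component medians). `class_summary`
screens each continuous variable per class with Shapiro–Wilk (alpha 0.05)
to choose t-test vs Wilcoxon presentation, uses chi-square for binary
variables, and reports pooled-sd standardized mean differences; the
screen's decisions are recorded per run. Comparisons are unadjusted by
design — the goal is description of the phenotypes' natural history, not
causal contrast.

## Pipeline, seeds, problem sizes

`pipeline.run_pipeline` executes generate/load → impute → standardize →
fit k = 1..6 → metric table → select → stability → parsimonious →
outcomes, writing CSV/JSON artifacts and a manifest. One global seed fans
out to named substreams (synthetic, impute, em, vlmr, stability,
parsimonious) so any stage can be re-run in isolation; re-running a
config is byte-identical.

Default problem sizes are chosen to keep a full desk run in seconds to
minutes: 20 EM starts, 20 dispersion refits, 49 bootstrap LRT replicates,
200 Monte Carlo stability replicates, m = 5 imputations. The test suite
uses the same machinery at reduced replicate counts (e.g. 39 bootstrap
replicates, 200-replicate type-I simulations at n = 120, d = 3) chosen so
the checks retain their statistical meaning.

## Known limitations

- The Bernoulli/Gaussian mixed likelihood treats binary and continuous
  variables asymmetrically; an analysis that forces binaries through
  scaled Gaussians will not reproduce it (deliberately — see above).
- The analytic LMR mode is provided for completeness but is poorly
  calibrated at these sample sizes; prefer the bootstrap mode.
- With 21 free-variance dimensions at n = 166 the k = 1 vs k = 2 BIC
  margin is only a few dozen units; the composite rule (not raw BIC
  minimization) is what makes class-count recovery reliable.
- The generator's independence assumption understates the redundancy of
  real clinical variables; parsimonious-model variable *identity* (beyond
  the dominant discriminators) should not be over-interpreted.
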