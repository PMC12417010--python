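# phenolca

Latent class phenotyping of acute respiratory distress syndrome (ARDS)
after hematopoietic cell transplantation (HCT).

ARDS developing after stem cell transplantation is clinically
heterogeneous: it spans peri-engraftment respiratory distress (PERDS),
idiopathic pneumonia syndrome (IPS), diffuse alveolar hemorrhage (DAH) and
infection-associated lung injury, and these presentations are hard to
distinguish at ICU admission. `phenolca` implements a complete,
reproducible pipeline for discovering and characterizing clinical
phenotypes in such cohorts from routinely collected ICU-admission data —
and, because no public patient-level data set exists for this population,
ships a calibrated synthetic cohort generator so every stage is testable.

It is aimed at biostatisticians and critical-care researchers who want a
transparent, scriptable alternative to an ad hoc `mclust`-based analysis:
every stage (imputation, fitting, selection, stability, outcome
comparison) is a plain Python function with a seeded random stream.

## The model

Patients are described by a vector of `d = 21` class-defining variables
measured at intubation (19 continuous, 2 binary: transplant type and sex).
The latent class model is a finite mixture with `k` components,

    p(x) = sum_c  pi_c * prod_j N(x_j | mu_cj, sigma_cj^2)
                 * prod_b Bernoulli(x_b | theta_cb)

i.e. class-conditional independence with diagonal (optionally spherical or
full, tied or varying) Gaussians for continuous variables and Bernoulli
terms for binary indicators. Skewed laboratory variables are
log-transformed and all columns z-scored before fitting. Models with
`k = 1..6` classes are fitted by multi-start EM and compared with a
composite rule:

- **BIC** `-2 log L + p ln n` (lower is better) and its percent change
  between consecutive `k`;
- **BIC dispersion** across random-start refits (optimization stability);
- **relative entropy** `1 - sum_i sum_c -p_ic ln p_ic / (n ln k)`
  (classification certainty);
- **parsimony index** `entropy / (k ln BIC)`;
- **VLMR-style likelihood-ratio test** of `k` vs `k-1` (parametric
  bootstrap by default, the analytic Lo–Mendell–Rubin approximation as an
  alternative);
- a smallest-class-size floor.

Downstream, the package assesses classification stability (bootstrap
Monte Carlo and multi-start sensitivity with optimally matched labels,
Cohen's kappa and adjusted Rand index), derives a parsimonious
six-variable classifier by greedy forward selection, and compares
outcomes between phenotypes (Kaplan–Meier, log-rank, Cox proportional
hazards, ventilator-/hospital-free days, EASIX).

## Worked example

```python
from phenolca import cohort, engine, selection, stability

params = cohort.default_cohort_params()        # 21-variable roster, 81/85
table  = cohort.generate_cohort(params, seed=1)

data = engine.standardize(
    table, cohort.class_defining_names(params),
    binary=cohort.binary_names(params),
    log_vars=cohort.log_scale_names(params))

metrics, fits = selection.compute_selection_metrics(data, k_max=6, seed=0)
print(metrics[["bic", "entropy", "parsimony_index", "vlmr_p"]].round(3))
sel = selection.select_model(metrics, n=data.n)
print("selected k =", sel.k)
```

prints (seed 1):

```
        bic  entropy  parsimony_index  vlmr_p
k
1  9607.230    0.000            0.000     NaN
2  9611.189    0.827            0.045    0.02
3  9736.175    0.875            0.032    0.16
4  9854.628    0.893            0.024    0.18
5  9997.909    0.898            0.019    0.68
6  9926.708    0.905            0.016    0.02
selected k = 2
```

The two-class model is selected: its BIC sits within refit noise of the
minimum, the VLMR test against one class is decisive (p = 0.02, the
smallest value a 49-replicate bootstrap can report) while three classes
add nothing (p = 0.16), and the parsimony index peaks at `k = 2`. The
fitted classes recover the generator's two phenotypes: one class with
preserved blood counts, higher PCO2 and bilirubin, the other with
profound cytopenia and fever.

The same analysis from the shell:

```sh
phenolca simulate --seed 1 --out cohort_out
phenolca run --seed 1 --out run_out
phenolca assign run_out/model.json cohort_out/cohort.csv
```

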