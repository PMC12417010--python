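"""Mixture engine: standardization, parameter counts, EM correctness."""

import math

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from phenolca import engine
from phenolca.engine import (
    MixtureFit,
    ScaledMatrix,
    em_fit,
    log_density,
    n_params,
    responsibilities,
    standardize,
)

from conftest import as_scaled, two_gaussians


class TestStandardize:
    def test_columns_have_mean_zero_sd_one(self, scaled166):
        np.testing.assert_allclose(scaled166.values.mean(axis=0), 0,
                                   atol=1e-9)
        np.testing.assert_allclose(scaled166.values.std(axis=0), 1,
                                   atol=1e-9)

    def test_default_roster_has_21_columns(self, scaled166):
        assert scaled166.d == 21
        assert "allogeneic" in scaled166.binary
        assert "male" in scaled166.binary

    def test_collinear_variables_are_pruned(self, cohort166, roster):
        t = cohort166.copy()
        t["ph"] = 7.3 + 0.01 * t["bicarbonate"]
        data = standardize(t, roster + ["ph"])
        assert "ph" not in data.columns
        assert data.pruned == ("ph",)

    def test_constant_column_raises(self, cohort166, roster):
        t = cohort166.copy()
        t["wbc"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(t, roster)

    def test_missing_cells_raise(self, cohort166, roster):
        t = cohort166.copy()
        t.loc[0, "wbc"] = np.nan
        with pytest.raises(ValueError, match="completed"):
            standardize(t, roster)

    def test_binary_block_recovered_exactly(self, scaled166, cohort166):
        _, xb, _, _ = scaled166.blocks()
        np.testing.assert_array_equal(
            xb[:, 0], cohort166["allogeneic"].to_numpy())


class TestNParams:
    @pytest.mark.parametrize("k,d,structure,expected", [
        (1, 21, "diagonal-varying", 42),
        (2, 21, "diagonal-varying", 85),
        (2, 21, "full-varying", 505),
        (2, 21, "diagonal-equal", 1 + 42 + 21),
        (3, 4, "spherical-varying", 2 + 12 + 3),
        (2, 5, "full-equal", 1 + 10 + 15),
    ])
    def test_closed_form_counts(self, k, d, structure, expected):
        assert n_params(k, d, structure) == expected

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError):
            n_params(2, 3, "banana")


class TestEMFit:
    def test_single_component_matches_analytic_mle(self):
        X, _ = two_gaussians(n=80, sep=0.0, d=3, seed=1)
        data = as_scaled(X)
        fit = em_fit(data, 1, n_starts=1, seed=0)
        np.testing.assert_allclose(fit.means[0], data.values.mean(axis=0),
                                   atol=1e-9)
        np.testing.assert_allclose(fit.covariances[0],
                                   data.values.var(axis=0), rtol=1e-8)
        # closed-form Gaussian log-likelihood at the MLE
        ll = -0.5 * data.n * (data.d * math.log(2 * math.pi)
                              + np.log(fit.covariances[0]).sum() + data.d)
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-4)

    def test_well_separated_classes_recovered_exactly(self):
        X, labels = two_gaussians(n=200, sep=6.0, seed=2)
        data = as_scaled(X)
        fit = em_fit(data, 2, n_starts=5, seed=3)
        # brute-force per-point density comparison oracle
        oracle = np.empty(200, dtype=int)
        for i, x in enumerate(data.values):
            dens = [
                fit.weights[c] * np.prod(
                    np.exp(-0.5 * (x - fit.means[c]) ** 2
                           / fit.covariances[c])
                    / np.sqrt(2 * np.pi * fit.covariances[c]))
                for c in range(2)
            ]
            oracle[i] = int(np.argmax(dens))
        np.testing.assert_array_equal(fit.labels, oracle)
        acc = max((fit.labels == labels).mean(), (fit.labels != labels).mean())
        assert acc == 1.0

    def test_loglikelihood_monotone(self, scaled166):
        fit = em_fit(scaled166, 3, n_starts=3, seed=4)
        trace = np.asarray(fit.ll_trace)
        assert (np.diff(trace) > -1e-8).all()

    def test_bit_reproducible(self, scaled166):
        a = em_fit(scaled166, 2, n_starts=5, seed=42)
        b = em_fit(scaled166, 2, n_starts=5, seed=42)
        np.testing.assert_array_equal(a.posteriors, b.posteriors)
        assert a.log_likelihood == b.log_likelihood

    def test_posterior_rows_sum_to_one(self, fit2):
        np.testing.assert_allclose(fit2.posteriors.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert fit2.weights.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_array_equal(fit2.labels,
                                      fit2.posteriors.argmax(axis=1))

    def test_matches_sklearn_likelihood_on_continuous_data(self):
        """Independent cross-check: on continuous-only data the engine's
        diagonal-varying model is sklearn's 'diag' GaussianMixture."""
        X, _ = two_gaussians(n=300, sep=3.0, d=4, seed=5)
        data = as_scaled(X)
        ours = em_fit(data, 2, n_starts=10, seed=6, tol=1e-8)
        best = -np.inf
        for rs in range(10):
            gm = GaussianMixture(2, covariance_type="diag", reg_covar=1e-6,
                                 random_state=rs, max_iter=500, tol=1e-8)
            gm.fit(data.values)
            best = max(best, gm.score(data.values) * data.n)
        assert ours.log_likelihood == pytest.approx(best, abs=0.05)

    def test_structure_family_nesting(self, scaled166):
        """More flexible structures can only raise the best likelihood."""
        lls = {
            s: em_fit(scaled166, 2, structure=s, n_starts=5,
                      seed=7).log_likelihood
            for s in ("spherical-equal", "diagonal-equal", "diagonal-varying")
        }
        assert lls["spherical-equal"] <= lls["diagonal-equal"] + 1e-6
        assert lls["diagonal-equal"] <= lls["diagonal-varying"] + 1e-6

    def test_parameter_recovery_at_both_sample_sizes(self, params):
        """Per-class means of the most discriminating variables land within
        3 standard errors of the generating values."""
        import dataclasses

        from phenolca import cohort as cohort_mod
        from phenolca.stability import match_classes

        top5 = ["wbc", "platelets", "temperature", "glucose", "pf_ratio"]
        by_name = {s.name: s for s in params.variable_specs}
        for n_per, seed in (((81, 85), 31), ((1000, 1000), 32)):
            p = dataclasses.replace(params, n_per_class=n_per)
            t = cohort_mod.generate_cohort(p, seed)
            data = standardize(t, cohort_mod.class_defining_names(params),
                               binary=cohort_mod.binary_names(params),
                               log_vars=cohort_mod.log_scale_names(params))
            fit = em_fit(data, 2, n_starts=20, seed=seed)
            truth = t["true_class"].to_numpy() - 1
            perm = match_classes(truth, fit.labels, 2)
            cont_cols = [c for c in data.columns if c not in data.binary]
            for name in top5:
                j = cont_cols.index(name)
                js = data.columns.index(name)
                spec = by_name[name]
                for c in (0, 1):
                    fitted = (fit.means[list(perm).index(c)][j]
                              * data.sds[js] + data.means[js])
                    se = spec.scale[c] / math.sqrt(n_per[c])
                    assert abs(fitted - spec.loc[c]) < 3 * se + 0.02, (
                        name, c, n_per)


class TestLogDensity:
    def test_standard_normal_closed_form(self):
        fit = MixtureFit(
            k=1, structure="diagonal-varying", columns=("a", "b"),
            binary_columns=(), weights=np.array([1.0]),
            means=np.zeros((1, 2)), covariances=np.ones((1, 2)),
            bernoulli=np.zeros((1, 0)), bin_means=np.array([]),
            bin_sds=np.array([]), log_likelihood=0.0, n_params=4)
        assert log_density(fit, np.zeros(2)) == pytest.approx(
            -math.log(2 * math.pi), abs=1e-12)

    def test_matches_bruteforce_component_sum(self):
        rng = np.random.default_rng(8)
        X, _ = two_gaussians(n=50, sep=2.0, d=3, seed=8)
        data = as_scaled(X)
        fit = em_fit(data, 3, n_starts=3, seed=9)
        pts = rng.standard_normal((20, 3))
        for x in pts:
            brute = sum(
                fit.weights[c] * np.prod(
                    np.exp(-0.5 * (x - fit.means[c]) ** 2
                           / fit.covariances[c])
                    / np.sqrt(2 * np.pi * fit.covariances[c]))
                for c in range(3))
            assert log_density(fit, x) == pytest.approx(math.log(brute),
                                                        abs=1e-10)

    def test_responsibilities_normalize(self, fit2, scaled166):
        R = responsibilities(fit2, scaled166.values)
        np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch_raises(self, fit2):
        with pytest.raises(ValueError, match="dimension"):
            log_density(fit2, np.zeros(3))


class TestSerialization:
    def test_json_round_trip_preserves_scoring(self, fit2, scaled166):
        doc = engine.fit_to_json(fit2)
        back = engine.fit_from_json(doc)
        np.testing.assert_allclose(
            log_density(back, scaled166.values[:10]),
            log_density(fit2, scaled166.values[:10]), atol=1e-12)
        np.testing.assert_array_equal(
            engine.predict_labels(back, scaled166.values), fit2.labels)
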