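"""Shared fixtures: the default synthetic cohort and reference fits."""

import numpy as np
import pytest

from phenolca import cohort, engine


@pytest.fixture(scope="session")
def params():
    return cohort.default_cohort_params()


@pytest.fixture(scope="session")
def roster(params):
    return cohort.class_defining_names(params)


@pytest.fixture(scope="session")
def binary_vars(params):
    return cohort.binary_names(params)


@pytest.fixture(scope="session")
def log_vars(params):
    return cohort.log_scale_names(params)


@pytest.fixture(scope="session")
def cohort166(params):
    """One complete default cohort (no missingness injected)."""
    return cohort.generate_cohort(params, seed=1)


@pytest.fixture(scope="session")
def scaled166(cohort166, roster, binary_vars, log_vars):
    return engine.standardize(cohort166, roster, binary=binary_vars,
                              log_vars=log_vars)


@pytest.fixture(scope="session")
def fit2(scaled166):
    """Reference two-class fit on the default cohort."""
    return engine.em_fit(scaled166, 2, n_starts=20, seed=11)


@pytest.fixture(scope="session")
def true_labels(cohort166):
    return cohort166["true_class"].to_numpy() - 1


def two_gaussians(n=200, sep=6.0, d=2, seed=0, weights=(0.5, 0.5)):
    """Two spherical Gaussian clusters separated by ``sep`` pooled sds."""
    rng = np.random.default_rng(seed)
    n1 = int(round(n * weights[0]))
    labels = np.repeat([0, 1], [n1, n - n1])
    X = rng.standard_normal((n, d))
    X[labels == 1, 0] += sep
    return X, labels


def as_scaled(X, prefix="v"):
    """Wrap a raw continuous matrix as an already-standardized ScaledMatrix."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return engine.ScaledMatrix(
        values=(X - mu) / sd,
        columns=tuple(f"{prefix}{j}" for j in range(X.shape[1])),
        means=mu,
        sds=sd,
    )
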