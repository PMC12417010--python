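"""Latent class (finite mixture) engine.

Fits mixed-mode latent class models by EM with multi-start: continuous
variables follow class-conditional Gaussians (spherical, diagonal or full
covariance; tied across classes or varying), binary variables follow
class-conditional Bernoulli distributions. This is the classical latent
class likelihood for mixed clinical tables and avoids the degenerate
variance-collapse solutions that arise when 0/1 indicators are given free
Gaussian variances.

The public data container is :class:`ScaledMatrix`: every column —
including binary indicators — is z-scored, with column means and sds
retained so the engine can recover the 0/1 coding internally and so fits
can be applied to new data.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular


def _logsumexp_rows(lp: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp of an n x k matrix (hot path in EM)."""
    m = lp.max(axis=1)
    return m + np.log(np.exp(lp - m[:, None]).sum(axis=1))

__all__ = [
    "ScaledMatrix",
    "MixtureFit",
    "standardize",
    "n_params",
    "em_fit",
    "log_density",
    "responsibilities",
    "predict_labels",
    "sample_from_fit",
    "fit_to_json",
    "fit_from_json",
]

STRUCTURES = (
    "spherical-equal", "spherical-varying",
    "diagonal-equal", "diagonal-varying",
    "full-equal", "full-varying",
)

#: additive floor on Gaussian variances (z-scored scale)
VAR_FLOOR = 1e-6
#: Bernoulli probabilities are clipped away from {0, 1}
PROB_FLOOR = 1e-3
LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ScaledMatrix:
    """Column-standardized analysis matrix with its inverse transform."""

    values: np.ndarray  # n x d; every column has mean 0, sd 1
    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    binary: tuple[str, ...] = ()
    log_transformed: tuple[str, ...] = ()
    pruned: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def fingerprint(self) -> str:
        return hashlib.sha1(
            np.ascontiguousarray(self.values).tobytes()
        ).hexdigest()[:16]

    def column_index(self, names) -> np.ndarray:
        return np.array([self.columns.index(c) for c in names], dtype=int)

    def select(self, names) -> "ScaledMatrix":
        """Restrict to a subset of columns (keeps scaling metadata)."""
        idx = self.column_index(names)
        return ScaledMatrix(
            values=self.values[:, idx],
            columns=tuple(names),
            means=self.means[idx],
            sds=self.sds[idx],
            binary=tuple(c for c in names if c in self.binary),
            log_transformed=tuple(c for c in names if c in self.log_transformed),
            pruned=self.pruned,
        )

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Split into (continuous z-scores, binary 0/1, cont idx, bin idx)."""
        bin_idx = self.column_index(self.binary) if self.binary else np.array([], dtype=int)
        cont_idx = np.array([i for i in range(self.d) if i not in set(bin_idx)], dtype=int)
        xc = self.values[:, cont_idx]
        xb = self.values[:, bin_idx] * self.sds[bin_idx] + self.means[bin_idx]
        xb = np.round(xb)
        return xc, xb, cont_idx, bin_idx


def standardize(
    table: pd.DataFrame,
    variables,
    binary=(),
    log_vars=(),
    prune=("ph", "minute_ventilation"),
) -> ScaledMatrix:
    """Z-score a completed table's class-defining block.

    ``log_vars`` are log-transformed before scaling (skewed labs).
    ``prune`` names are dropped from the roster if present (collinear
    variables removed from class definition) and recorded.
    """
    roster = [v for v in variables if v not in prune]
    pruned = tuple(v for v in variables if v in prune)
    X = table[roster].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("standardize requires a completed table (no missing cells)")
    log_idx = [roster.index(v) for v in log_vars if v in roster]
    X[:, log_idx] = np.log(X[:, log_idx])
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    zero = sds <= 0
    if zero.any():
        bad = [roster[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero-variance column(s): {bad}")
    return ScaledMatrix(
        values=(X - means) / sds,
        columns=tuple(roster),
        means=means,
        sds=sds,
        binary=tuple(v for v in binary if v in roster),
        log_transformed=tuple(v for v in log_vars if v in roster),
        pruned=pruned,
    )


def n_params(k: int, d: int, structure: str) -> int:
    """Free-parameter count of a d-dimensional Gaussian mixture."""
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    if k < 1 or d < 1:
        raise ValueError("k and d must be >= 1")
    shape, tie = structure.split("-")
    per_comp = {"spherical": 1, "diagonal": d, "full": d * (d + 1) // 2}[shape]
    cov = per_comp if tie == "equal" else k * per_comp
    return (k - 1) + k * d + cov


def _n_params_mixed(k: int, d_cont: int, d_bin: int, structure: str) -> int:
    shape, tie = structure.split("-")
    per_comp = {"spherical": 1, "diagonal": d_cont,
                "full": d_cont * (d_cont + 1) // 2}[shape]
    cov = (per_comp if tie == "equal" else k * per_comp) if d_cont else 0
    return (k - 1) + k * d_cont + cov + k * d_bin


@dataclass
class MixtureFit:
    """Fitted latent class model for one class count k."""

    k: int
    structure: str
    columns: tuple[str, ...]
    binary_columns: tuple[str, ...]
    weights: np.ndarray              # (k,)
    means: np.ndarray                # (k, d_cont), z-scored scale
    #: (k, d_cont) variances for spherical/diagonal structures,
    #: (k, d_cont, d_cont) matrices for full structures
    covariances: np.ndarray
    bernoulli: np.ndarray            # (k, d_bin)
    bin_means: np.ndarray            # scaling of binary columns
    bin_sds: np.ndarray
    log_likelihood: float
    n_params: int
    posteriors: np.ndarray | None = None
    labels: np.ndarray | None = None
    converged: bool = True
    degenerate: bool = False
    n_iter: int = 0
    seed: int = 0
    n_starts: int = 1
    ll_trace: list = field(default_factory=list)
    data_fingerprint: str = ""

    @property
    def d_cont(self) -> int:
        return self.means.shape[1]

    @property
    def d_bin(self) -> int:
        return self.bernoulli.shape[1]


# ---------------------------------------------------------------------------
# EM internals
# ---------------------------------------------------------------------------

def _component_logpdf(xc: np.ndarray, xb: np.ndarray, weights, means,
                      covs, probs, diagonal: bool | None = None) -> np.ndarray:
    """n x k matrix of log(pi_c) + log p(x | component c).

    ``covs`` is (k, d) of variances when ``diagonal`` is true, else
    (k, d, d) full matrices (auto-detected from ndim by default).
    """
    n = xc.shape[0] if xc.size else xb.shape[0]
    k = len(weights)
    lp = np.tile(np.log(np.maximum(weights, 1e-300)), (n, 1))
    d_cont = means.shape[1]
    if diagonal is None:
        diagonal = np.asarray(covs).ndim == 2
    if d_cont:
        if diagonal:
            var = np.asarray(covs)          # (k, d)
            inv = 1.0 / var
            # sum_j (x_j - mu_j)^2 / var_j, expanded to avoid the n*k*d cube
            quad = ((xc * xc) @ inv.T - 2.0 * xc @ (means * inv).T
                    + (means * means * inv).sum(axis=1)[None, :])
            lp += -0.5 * (d_cont * LOG2PI + np.log(var).sum(axis=1)[None, :]
                          + quad)
        else:
            for c in range(k):
                chol = np.linalg.cholesky(covs[c])
                sol = solve_triangular(chol, (xc - means[c]).T, lower=True)
                lp[:, c] += -0.5 * (d_cont * LOG2PI
                                    + 2.0 * np.log(np.diagonal(chol)).sum()
                                    + (sol * sol).sum(axis=0))
    if probs.shape[1]:
        logp = np.log(probs)
        log1p = np.log(1.0 - probs)
        lp += xb @ (logp - log1p).T + log1p.sum(axis=1)[None, :]
    return lp


def _m_step(xc, xb, R, structure):
    """Returns (weights, means, covs, probs); covs is (k, d) of variances
    for spherical/diagonal shapes and (k, d, d) for full."""
    n, d_cont = xc.shape
    k = R.shape[1]
    shape, tie = structure.split("-")
    Nk = R.sum(axis=0) + 1e-300
    weights = Nk / n
    means = (R.T @ xc) / Nk[:, None] if d_cont else np.zeros((k, 0))
    if d_cont and shape == "full":
        covs = np.zeros((k, d_cont, d_cont))
        for c in range(k):
            dev = xc - means[c]
            covs[c] = (R[:, c, None] * dev).T @ dev / Nk[c]
        if tie == "equal":
            covs[:] = np.einsum("k,kij->ij", Nk / n, covs)
        covs += VAR_FLOOR * np.eye(d_cont)
    else:
        var = (R.T @ (xc * xc)) / Nk[:, None] - means ** 2 if d_cont else (
            np.zeros((k, 0)))
        if d_cont and shape == "spherical":
            var = np.tile(var.mean(axis=1, keepdims=True), (1, d_cont))
        if d_cont and tie == "equal":
            var = np.tile((Nk / n) @ var, (k, 1))
        covs = np.maximum(var, VAR_FLOOR)
    if xb.shape[1]:
        probs = np.clip((R.T @ xb) / Nk[:, None], PROB_FLOOR, 1.0 - PROB_FLOOR)
    else:
        probs = np.zeros((k, 0))
    return weights, means, covs, probs


def _kmeans_once(X: np.ndarray, k: int, rng: np.random.Generator,
                 n_iter: int = 50) -> tuple[np.ndarray, float]:
    """One greedy-k-means++ Lloyd optimization; returns (labels, inertia).

    Greedy seeding draws several candidates per center and keeps the one
    that most reduces the potential.
    """
    n = X.shape[0]
    n_cand = 2 + int(math.log(k + 1))
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        p = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        cand_idx = rng.choice(n, size=n_cand, p=p)
        best = None
        for ci in cand_idx:
            nd2 = np.minimum(d2, ((X - X[ci]) ** 2).sum(axis=1))
            pot = nd2.sum()
            if best is None or pot < best[0]:
                best = (pot, ci, nd2)
        _, ci, d2 = best
        centers[c] = X[ci]
    labels = np.zeros(n, dtype=int)
    for it in range(n_iter):
        dist = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        new = dist.argmin(axis=1)
        if (new == labels).all() and it > 0:
            break
        labels = new
        for c in range(k):
            m = labels == c
            if m.any():
                centers[c] = X[m].mean(axis=0)
    dist = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
    return labels, float(dist.min(axis=1).sum())


def em_fit(
    data: ScaledMatrix,
    k: int,
    structure: str = "diagonal-varying",
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    init_candidates: int = 8,
    init_cycles: int = 15,
) -> MixtureFit:
    """Best-of-``n_starts`` EM fit of a k-class model.

    Each start builds several greedy-k-means++ candidate partitions (on
    the full scaled matrix), scores each by the model log-likelihood after
    one EM cycle, and launches a single EM trajectory from the best — the
    emEM-style initialization of Biernacki, Celeux & Govaert, which makes
    individual starts land reliably in the dominant basin. Convergence
    when the log-likelihood gain of a full EM cycle drops below ``tol``.
    Deterministic given ``seed``. Non-convergence and degenerate component
    weights (below 1/(10n)) are flagged, not raised.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    xc, xb, cont_idx, bin_idx = data.blocks()
    n = data.n
    if n <= k:
        raise ValueError("need more observations than classes")
    best = None
    ss = np.random.SeedSequence(entropy=(seed, k))
    for child in ss.spawn(max(1, n_starts)):
        rng = np.random.default_rng(child)
        if k == 1:
            R = np.ones((n, 1))
        else:
            best_init = None
            for _ in range(max(1, init_candidates)):
                # emEM: rank candidate partitions by short-run ll
                labels0, _ = _kmeans_once(data.values, k, rng)
                R0 = np.full((n, k), 0.05 / max(1, k - 1))
                R0[np.arange(n), labels0] = 0.95
                ll0 = -np.inf
                for _cycle in range(init_cycles):
                    w0, m0, c0, p0 = _m_step(xc, xb, R0, structure)
                    lp0 = _component_logpdf(xc, xb, w0, m0, c0, p0)
                    norm0 = _logsumexp_rows(lp0)
                    R0 = np.exp(lp0 - norm0[:, None])
                    ll0 = float(norm0.sum())
                if best_init is None or ll0 > best_init[0]:
                    best_init = (ll0, R0)
            R = best_init[1]
        trace = []
        ll_old = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            weights, means, covs, probs = _m_step(xc, xb, R, structure)
            lp = _component_logpdf(xc, xb, weights, means, covs, probs)
            norm = _logsumexp_rows(lp)
            ll = float(norm.sum())
            R = np.exp(lp - norm[:, None])
            trace.append(ll)
            if ll - ll_old < tol:
                converged = True
                break
            ll_old = ll
        if best is None or ll > best[0]:
            best = (ll, weights, means, covs, probs, R, converged, it, trace)
    ll, weights, means, covs, probs, R, converged, it, trace = best
    labels = R.argmax(axis=1)
    fit = MixtureFit(
        k=k,
        structure=structure,
        columns=data.columns,
        binary_columns=data.binary,
        weights=weights,
        means=means,
        covariances=covs,
        bernoulli=probs,
        bin_means=data.means[bin_idx],
        bin_sds=data.sds[bin_idx],
        log_likelihood=ll,
        n_params=_n_params_mixed(k, xc.shape[1], xb.shape[1], structure),
        posteriors=R,
        labels=labels,
        converged=converged,
        degenerate=bool((weights < 1.0 / (10.0 * n)).any()),
        n_iter=it,
        seed=seed,
        n_starts=n_starts,
        ll_trace=trace,
        data_fingerprint=data.fingerprint,
    )
    return fit


# ---------------------------------------------------------------------------
# Scoring fitted models
# ---------------------------------------------------------------------------

def _split_points(fit: MixtureFit, X: np.ndarray):
    bin_set = set(fit.binary_columns)
    bin_idx = np.array([i for i, c in enumerate(fit.columns) if c in bin_set],
                       dtype=int)
    cont_idx = np.array([i for i, c in enumerate(fit.columns) if c not in bin_set],
                        dtype=int)
    xc = X[:, cont_idx]
    xb = np.round(X[:, bin_idx] * fit.bin_sds + fit.bin_means)
    return xc, xb


def log_density(fit: MixtureFit, point: np.ndarray) -> float | np.ndarray:
    """ln sum_c pi_c p(point | c); accepts one d-vector or an n x d matrix."""
    pt = np.atleast_2d(np.asarray(point, dtype=float))
    if pt.shape[1] != len(fit.columns):
        raise ValueError(
            f"dimension mismatch: point has {pt.shape[1]} columns, "
            f"model has {len(fit.columns)}")
    xc, xb = _split_points(fit, pt)
    lp = _component_logpdf(xc, xb, fit.weights, fit.means,
                           fit.covariances, fit.bernoulli)
    out = _logsumexp_rows(lp)
    return float(out[0]) if np.asarray(point).ndim == 1 else out


def responsibilities(fit: MixtureFit, X: np.ndarray) -> np.ndarray:
    """Posterior class-membership probabilities for rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    xc, xb = _split_points(fit, X)
    lp = _component_logpdf(xc, xb, fit.weights, fit.means,
                           fit.covariances, fit.bernoulli)
    return np.exp(lp - _logsumexp_rows(lp)[:, None])


def predict_labels(fit: MixtureFit, X: np.ndarray) -> np.ndarray:
    """Hard assignments (argmax posterior; ties go to the lowest index)."""
    return responsibilities(fit, X).argmax(axis=1)


def sample_from_fit(fit: MixtureFit, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows from the fitted model, on the scaled-matrix scale."""
    comp = rng.choice(fit.k, size=n, p=fit.weights / fit.weights.sum())
    d = len(fit.columns)
    X = np.empty((n, d))
    bin_set = set(fit.binary_columns)
    bin_idx = [i for i, c in enumerate(fit.columns) if c in bin_set]
    cont_idx = [i for i, c in enumerate(fit.columns) if c not in bin_set]
    for c in range(fit.k):
        m = comp == c
        if not m.any():
            continue
        nc = int(m.sum())
        if cont_idx:
            cov = fit.covariances[c]
            if cov.ndim == 1:
                X[np.ix_(m, cont_idx)] = (
                    fit.means[c] + np.sqrt(cov) * rng.standard_normal(
                        (nc, len(cont_idx))))
            else:
                X[np.ix_(m, cont_idx)] = rng.multivariate_normal(
                    fit.means[c], cov, size=nc, method="cholesky")
        if bin_idx:
            b = rng.binomial(1, fit.bernoulli[c], size=(nc, len(bin_idx)))
            X[np.ix_(m, bin_idx)] = (b - fit.bin_means) / fit.bin_sds
    return X


def synthetic_matrix_like(fit: MixtureFit, values: np.ndarray) -> ScaledMatrix:
    """Wrap model-simulated values in a ScaledMatrix shell for refitting."""
    d = len(fit.columns)
    means = np.zeros(d)
    sds = np.ones(d)
    bin_set = set(fit.binary_columns)
    for i, c in enumerate(fit.columns):
        if c in bin_set:
            j = list(fit.binary_columns).index(c)
            means[i] = fit.bin_means[j]
            sds[i] = fit.bin_sds[j]
    return ScaledMatrix(values=values, columns=fit.columns, means=means,
                        sds=sds, binary=fit.binary_columns)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def fit_to_json(fit: MixtureFit) -> dict:
    return {
        "k": fit.k,
        "structure": fit.structure,
        "columns": list(fit.columns),
        "binary_columns": list(fit.binary_columns),
        "weights": fit.weights.tolist(),
        "means": fit.means.tolist(),
        "covariances": fit.covariances.tolist(),
        "bernoulli": fit.bernoulli.tolist(),
        "bin_means": fit.bin_means.tolist(),
        "bin_sds": fit.bin_sds.tolist(),
        "log_likelihood": fit.log_likelihood,
        "n_params": fit.n_params,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "seed": fit.seed,
        "n_starts": fit.n_starts,
        "data_fingerprint": fit.data_fingerprint,
    }


def fit_from_json(doc: dict) -> MixtureFit:
    if isinstance(doc, str):
        doc = json.loads(doc)
    return MixtureFit(
        k=doc["k"],
        structure=doc["structure"],
        columns=tuple(doc["columns"]),
        binary_columns=tuple(doc["binary_columns"]),
        weights=np.asarray(doc["weights"], dtype=float),
        means=np.asarray(doc["means"], dtype=float).reshape(doc["k"], -1),
        covariances=np.asarray(doc["covariances"], dtype=float),
        bernoulli=np.asarray(doc["bernoulli"], dtype=float).reshape(doc["k"], -1),
        bin_means=np.asarray(doc["bin_means"], dtype=float),
        bin_sds=np.asarray(doc["bin_sds"], dtype=float),
        log_likelihood=doc["log_likelihood"],
        n_params=doc["n_params"],
        converged=doc["converged"],
        n_iter=doc["n_iter"],
        seed=doc["seed"],
        n_starts=doc["n_starts"],
        data_fingerprint=doc.get("data_fingerprint", ""),
    )
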