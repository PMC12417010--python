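"""Mixture model selection: BIC suite, entropy, parsimony index, VLMR.

Implements the composite class-count selection used for the two-phenotype
model: BIC (lower is better, -2*ll + p*ln n), percent change in BIC
between consecutive class counts, BIC dispersion across random-start
refits, normalized posterior entropy, the parsimony index
entropy / (k * ln BIC), a Vuong-Lo-Mendell-Rubin style likelihood-ratio
test of k vs k-1 classes (analytic LMR approximation or parametric
bootstrap), and a deterministic composite selection rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (
    MixtureFit,
    ScaledMatrix,
    em_fit,
    sample_from_fit,
    synthetic_matrix_like,
)

__all__ = [
    "bic",
    "bic_percent_change",
    "relative_entropy",
    "parsimony_index",
    "bic_dispersion",
    "vlmr_test",
    "compute_selection_metrics",
    "select_model",
    "SelectionResult",
]


def bic(log_likelihood: float, n_params: int, n: int) -> float:
    """Bayesian Information Criterion, lower-is-better convention."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * log_likelihood + n_params * math.log(n)


def fit_bic(fit: MixtureFit, n: int) -> float:
    return bic(fit.log_likelihood, fit.n_params, n)


def bic_percent_change(bic_prev: float, bic_curr: float) -> float:
    """100 * (prev - curr) / prev; positive means the BIC improved."""
    if bic_prev == 0:
        raise ZeroDivisionError("bic_prev must be nonzero")
    return 100.0 * (bic_prev - bic_curr) / bic_prev


def relative_entropy(posterior: np.ndarray) -> float:
    """Normalized classification certainty in [0, 1].

    1 - (sum of posterior Shannon entropies) / (n * ln k); 1 means crisp
    assignment, 0 means uniform posteriors. Defined as 0 for k = 1.
    """
    P = np.asarray(posterior, dtype=float)
    n, k = P.shape
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    if k == 1:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(1.0 + plogp.sum() / (n * math.log(k)))


def parsimony_index(entropy: float, k: int, bic_value: float) -> float:
    """entropy / (k * ln BIC): rewards separation, penalizes complexity."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if bic_value <= 1.0:
        raise ValueError("BIC must exceed 1 for a positive log")
    return entropy / (k * math.log(bic_value))


def bic_dispersion(
    data: ScaledMatrix,
    k: int,
    n_refits: int = 20,
    seed: int = 0,
    structure: str = "diagonal-varying",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """Sd of BIC across single-start EM refits with distinct initializations.

    Measures optimization stability on the *same* data (a multimodal
    likelihood produces spread). The one-class fit is closed form, so its
    dispersion is exactly 0.
    """
    if n_refits < 2:
        raise ValueError("n_refits must be >= 2")
    if k == 1:
        return 0.0
    seeds = np.random.SeedSequence(entropy=(seed, 99)).generate_state(n_refits)
    vals = [
        fit_bic(em_fit(data, k, structure, n_starts=1, seed=int(s % (2 ** 31)),
                       tol=tol, max_iter=max_iter), data.n)
        for s in seeds
    ]
    return float(np.std(vals, ddof=1))


def vlmr_test(
    fit_k: MixtureFit,
    fit_km1: MixtureFit,
    n: int,
    mode: str = "bootstrap",
    n_boot: int = 49,
    seed: int = 0,
    n_starts: int = 3,
    tol: float = 1e-3,
    max_iter: int = 200,
    init_candidates: int = 2,
    init_cycles: int = 5,
) -> float:
    """p-value for k classes vs k-1 classes.

    ``mode='lmr'``: Lo-Mendell-Rubin adjusted LRT — the raw statistic
    LR = 2 (ll_k - ll_{k-1}) is shrunk by the correction factor
    1 + 1 / ((q_k - q_{k-1}) ln n) and referred to a chi-square with
    q_k - q_{k-1} degrees of freedom.

    ``mode='bootstrap'``: parametric bootstrap LRT — simulate ``n_boot``
    datasets from the (k-1)-class fit, refit both class counts on each,
    and report (1 + #{LR_b >= LR_obs}) / (n_boot + 1). Well calibrated
    for mixture boundary testing; the default for pipeline gating.
    """
    if fit_km1.k != fit_k.k - 1:
        raise ValueError("comparison must be k vs k-1")
    if fit_k.data_fingerprint and fit_km1.data_fingerprint and (
            fit_k.data_fingerprint != fit_km1.data_fingerprint):
        raise ValueError("fits were computed on different data")
    lr = 2.0 * (fit_k.log_likelihood - fit_km1.log_likelihood)
    dq = fit_k.n_params - fit_km1.n_params
    if mode == "lmr":
        if lr <= 0:
            return 1.0
        corr = 1.0 + 1.0 / (dq * math.log(n))
        return float(stats.chi2.sf(lr / corr, df=dq))
    if mode != "bootstrap":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, fit_k.k)))
    exceed = 0
    for b in range(n_boot):
        sim = sample_from_fit(fit_km1, n, rng)
        simdata = synthetic_matrix_like(fit_km1, sim)
        s = int(rng.integers(2 ** 31))
        f0 = em_fit(simdata, fit_km1.k, fit_km1.structure, n_starts=n_starts,
                    seed=s, tol=tol, max_iter=max_iter,
                    init_candidates=init_candidates, init_cycles=init_cycles)
        f1 = em_fit(simdata, fit_k.k, fit_k.structure, n_starts=n_starts,
                    seed=s, tol=tol, max_iter=max_iter,
                    init_candidates=init_candidates, init_cycles=init_cycles)
        if 2.0 * (f1.log_likelihood - f0.log_likelihood) >= lr:
            exceed += 1
    return (1.0 + exceed) / (n_boot + 1.0)


def compute_selection_metrics(
    data: ScaledMatrix,
    k_max: int = 6,
    structure: str = "diagonal-varying",
    n_starts: int = 20,
    seed: int = 0,
    n_refits: int = 20,
    vlmr_mode: str = "bootstrap",
    n_boot: int = 49,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[pd.DataFrame, dict[int, MixtureFit]]:
    """Fit 1..k_max classes and assemble the per-k metric table.

    Returns (metrics table, fits). The table has one row per k with
    columns: bic, bic_percent_change, bic_sd, entropy, parsimony_index,
    smallest_class_size, vlmr_p, class_sizes, converged.
    """
    n = data.n
    fits: dict[int, MixtureFit] = {}
    rows = []
    for k in range(1, k_max + 1):
        fit = em_fit(data, k, structure, n_starts=n_starts, seed=seed,
                     tol=tol, max_iter=max_iter)
        fits[k] = fit
        b = fit_bic(fit, n)
        ent = relative_entropy(fit.posteriors)
        sizes = np.bincount(fit.labels, minlength=k)
        vp = np.nan
        if k > 1:
            vp = vlmr_test(fit, fits[k - 1], n, mode=vlmr_mode,
                           n_boot=n_boot, seed=seed)
        rows.append({
            "k": k,
            "bic": b,
            "bic_percent_change": np.nan if k == 1 else bic_percent_change(
                rows[-1]["bic"], b),
            "bic_sd": bic_dispersion(data, k, n_refits=n_refits, seed=seed,
                                     structure=structure, tol=max(tol, 1e-5),
                                     max_iter=max_iter),
            "entropy": ent,
            "parsimony_index": parsimony_index(ent, k, b),
            "smallest_class_size": int(sizes.min()),
            "class_sizes": "/".join(str(int(s)) for s in sorted(sizes)[::-1]),
            "vlmr_p": vp,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows).set_index("k"), fits


@dataclass
class SelectionResult:
    k: int
    candidates: list[int]
    fallback: bool
    trace: list[str] = field(default_factory=list)


def select_model(
    metrics: pd.DataFrame,
    min_class_fraction: float = 0.05,
    bic_tolerance: float = 20.0,
    alpha: float = 0.05,
    n: int | None = None,
) -> SelectionResult:
    """Deterministic composite class-count selection.

    A class count k is a candidate when (i) its BIC lies within
    ``bic_tolerance`` of the minimum, (ii) its smallest class holds at
    least ``min_class_fraction`` of the cohort, (iii) the VLMR test of k
    vs k-1 is significant at ``alpha`` (skipped for k = 1), and (iv) the
    VLMR test of k+1 vs k is *not* significant (skipped when
    unavailable). Among candidates the smallest k wins. If no candidate
    survives, the global BIC minimizer is returned with a warning trace.
    """
    if metrics.empty:
        raise ValueError("empty metrics table")
    ks = list(metrics.index)
    if n is None:
        n = int(metrics["class_sizes"].iloc[0].split("/")[0]) if (
            "class_sizes" in metrics) else 0
        if n == 0:
            n = int(metrics["smallest_class_size"].max())
    bic_min = metrics["bic"].min()
    trace: list[str] = []
    candidates = []
    for k in ks:
        row = metrics.loc[k]
        ok = True
        if row["bic"] > bic_min + bic_tolerance:
            trace.append(f"k={k}: BIC {row['bic']:.2f} beyond tolerance")
            ok = False
        if row["smallest_class_size"] < min_class_fraction * n:
            trace.append(f"k={k}: smallest class below {min_class_fraction:.0%}")
            ok = False
        vp = row.get("vlmr_p", np.nan)
        if k > 1 and np.isfinite(vp) and vp >= alpha:
            trace.append(f"k={k}: VLMR vs k-1 not significant (p={vp:.3f})")
            ok = False
        if (k + 1) in ks:
            vnext = metrics.loc[k + 1].get("vlmr_p", np.nan)
            if np.isfinite(vnext) and vnext < alpha:
                trace.append(f"k={k}: VLMR for k+1 still significant "
                             f"(p={vnext:.3f})")
                ok = False
        if ok:
            candidates.append(int(k))
    if candidates:
        return SelectionResult(k=min(candidates), candidates=candidates,
                               fallback=False, trace=trace)
    k_best = int(metrics["bic"].idxmin())
    trace.append(f"no candidate satisfied the rule; falling back to the "
                 f"global BIC minimizer k={k_best}")
    return SelectionResult(k=k_best, candidates=[], fallback=True, trace=trace)
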