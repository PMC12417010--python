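"""Classification stability: label matching, agreement statistics, and
Monte Carlo / multi-start stability of latent class assignments.

All agreement statistics are label-permutation invariant: hard labels from
two fits are aligned with an optimal one-to-one class matching (Hungarian
algorithm on the confusion matrix) before per-patient agreement and
Cohen's kappa are computed; the adjusted Rand index needs no matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .engine import MixtureFit, ScaledMatrix, em_fit, predict_labels

__all__ = [
    "match_classes",
    "apply_permutation",
    "adjusted_rand_index",
    "cohen_kappa",
    "StabilityReport",
    "monte_carlo_stability",
    "multi_start_sensitivity",
]


def match_classes(labels_a: np.ndarray, labels_b: np.ndarray, k: int) -> np.ndarray:
    """Permutation ``perm`` maximizing agreement of ``perm[labels_b]`` with a.

    Labels must be integers in [0, k). Solved as an assignment problem on
    the k x k confusion matrix.
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if a.size and (a.max() >= k or b.max() >= k or a.min() < 0 or b.min() < 0):
        raise ValueError(f"labels outside [0, {k})")
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (b, a), 1)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm


def apply_permutation(perm: np.ndarray, labels: np.ndarray) -> np.ndarray:
    return np.asarray(perm)[np.asarray(labels, dtype=int)]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement of two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def cohen_kappa(labels_a, labels_b) -> float:
    """(p_o - p_e) / (1 - p_e) from the confusion matrix.

    Labels are assumed matched to a common indexing; raises on the
    degenerate case p_e = 1 (both labelings constant and identical
    in marginal distribution).
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = a.size
    cats = np.union1d(a, b)
    idx = {c: i for i, c in enumerate(cats)}
    conf = np.zeros((len(cats), len(cats)))
    np.add.at(conf, ([idx[x] for x in a], [idx[x] for x in b]), 1)
    po = np.trace(conf) / n
    pe = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if pe >= 1.0 - 1e-12:
        raise ZeroDivisionError("degenerate marginals: chance agreement is 1")
    return float((po - pe) / (1.0 - pe))


@dataclass
class StabilityReport:
    n_replicates: int
    agreements: np.ndarray
    kappas: np.ndarray
    aris: np.ndarray
    n_failed: int = 0
    method: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def mean_agreement(self) -> float:
        return float(np.mean(self.agreements))

    @property
    def sd_agreement(self) -> float:
        return float(np.std(self.agreements, ddof=1)) if len(
            self.agreements) > 1 else 0.0

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.kappas))

    @property
    def mean_ari(self) -> float:
        return float(np.mean(self.aris))

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
            "method": self.method,
            "mean_agreement": self.mean_agreement,
            "sd_agreement": self.sd_agreement,
            "mean_kappa": self.mean_kappa,
            "mean_ari": self.mean_ari,
        }


def _pair_stats(ref: np.ndarray, other: np.ndarray, k: int):
    perm = match_classes(ref, other, k)
    aligned = apply_permutation(perm, other)
    agree = float(np.mean(aligned == ref))
    try:
        kap = cohen_kappa(ref, aligned)
    except ZeroDivisionError:
        kap = 1.0 if agree == 1.0 else 0.0
    return agree, kap, adjusted_rand_index(ref, other)


def monte_carlo_stability(
    data: ScaledMatrix,
    k: int,
    n_sims: int = 1000,
    seed: int = 0,
    reference: MixtureFit | None = None,
    structure: str = "diagonal-varying",
    n_starts: int = 5,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> StabilityReport:
    """Bootstrap-refit-reclassify stability of the k-class assignment.

    Each replicate resamples patients with replacement, refits the model
    on the resample, classifies the *original* cohort under the refit,
    aligns classes to the reference fit and records per-patient agreement.
    Replicates whose refit fails to converge are dropped and counted.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if reference is None:
        reference = em_fit(data, k, structure, n_starts=max(n_starts, 10),
                           seed=seed, tol=tol, max_iter=max_iter)
    ref_labels = reference.labels
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 7)))
    agreements, kappas, aris = [], [], []
    failed = 0
    n = data.n
    for _ in range(n_sims):
        idx = rng.integers(n, size=n)
        boot = ScaledMatrix(
            values=data.values[idx], columns=data.columns, means=data.means,
            sds=data.sds, binary=data.binary,
            log_transformed=data.log_transformed, pruned=data.pruned)
        refit = em_fit(boot, k, structure, n_starts=n_starts,
                       seed=int(rng.integers(2 ** 31)), tol=tol,
                       max_iter=max_iter, init_candidates=2, init_cycles=5)
        if not refit.converged:
            failed += 1
            continue
        labels = predict_labels(refit, data.values)
        agree, kap, ari = _pair_stats(ref_labels, labels, k)
        agreements.append(agree)
        kappas.append(kap)
        aris.append(ari)
    return StabilityReport(
        n_replicates=len(agreements),
        agreements=np.asarray(agreements),
        kappas=np.asarray(kappas),
        aris=np.asarray(aris),
        n_failed=failed,
        method="nonparametric row bootstrap, refit, reclassify original",
    )


def multi_start_sensitivity(
    data: ScaledMatrix,
    k: int,
    n_starts: int = 20,
    seed: int = 0,
    structure: str = "diagonal-varying",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> StabilityReport:
    """Pairwise agreement of ``n_starts`` independent single-start fits.

    Checks that the EM solution is a global optimum rather than a lucky
    local one: a stable likelihood surface yields identical classifications
    (agreement 1.0, kappa 1.0, ARI 1.0) from every start.
    """
    if n_starts < 2:
        raise ValueError("n_starts must be >= 2")
    seeds = np.random.SeedSequence(entropy=(seed, 13)).generate_state(n_starts)
    fits = [
        em_fit(data, k, structure, n_starts=1, seed=int(s % (2 ** 31)),
               tol=tol, max_iter=max_iter)
        for s in seeds
    ]
    agreements, kappas, aris = [], [], []
    for i in range(n_starts):
        for j in range(i + 1, n_starts):
            agree, kap, ari = _pair_stats(fits[i].labels, fits[j].labels, k)
            agreements.append(agree)
            kappas.append(kap)
            aris.append(ari)
    return StabilityReport(
        n_replicates=len(agreements),
        agreements=np.asarray(agreements),
        kappas=np.asarray(kappas),
        aris=np.asarray(aris),
        method=f"{n_starts} independent single-start EM fits, all pairs",
        extras={"log_likelihoods": [f.log_likelihood for f in fits]},
    )
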