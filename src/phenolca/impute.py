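"""Multiple imputation by chained equations (MICE) for the class-defining
variable block, plus the cross-imputation class-assignment stability check.

Continuous variables are imputed by predictive mean matching (PMM): an OLS
model of the variable on all other class-defining variables predicts both
observed and missing cases; each missing cell receives the observed value
of one of the ``n_donors`` cases with the closest predictions. Binary
variables are imputed by a logistic-regression probability draw. Outcome
columns never enter the imputation models (class discovery must not leak
outcome information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .stability import apply_permutation, match_classes

__all__ = ["ImputedSet", "mice_impute", "consensus_table",
           "imputation_assignment_stability"]


@dataclass
class ImputedSet:
    """m completed copies of a cohort table plus the missingness mask."""

    m: int
    tables: list[pd.DataFrame]
    mask: pd.DataFrame  # True where the cell was imputed
    variables: list[str]

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def _logistic_irls(X, y, ridge=1e-4, n_iter=25):
    """Ridge-stabilized logistic fit (IRLS); small design matrices only."""
    Xd = np.column_stack([np.ones(len(X)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(n_iter):
        p = _sigmoid(Xd @ beta)
        W = np.maximum(p * (1 - p), 1e-6)
        H = (Xd * W[:, None]).T @ Xd + ridge * np.eye(Xd.shape[1])
        g = Xd.T @ (y - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    return beta


def mice_impute(
    table: pd.DataFrame,
    variables,
    binary=(),
    m: int = 5,
    n_cycles: int = 10,
    seed: int = 0,
    n_donors: int = 5,
) -> ImputedSet:
    """Chained-equations imputation of ``variables`` in ``table``.

    Cycles over the variables in order of ascending missingness. Returns
    ``m`` completed tables; observed cells are bitwise identical to the
    input in every one. Deterministic given ``seed``.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    variables = list(variables)
    sub = table[variables].astype(float)
    if not all(np.issubdtype(sub[v].dtype, np.number) for v in variables):
        raise ValueError("non-numeric cells in imputation block")
    mask = sub.isna()
    for v in variables:
        if mask[v].all():
            raise ValueError(f"variable {v!r} is 100% missing")
    order = sorted(variables, key=lambda v: (mask[v].sum(), variables.index(v)))
    with_missing = [v for v in order if mask[v].any()]
    bin_set = set(binary)

    ss = np.random.SeedSequence(entropy=(seed, 17))
    tables = []
    for chain_seed in ss.spawn(m):
        rng = np.random.default_rng(chain_seed)
        X = sub.to_numpy(copy=True)
        miss = mask.to_numpy()
        # initial fill: random draws from the observed margin
        for j, v in enumerate(variables):
            mj = miss[:, j]
            if mj.any():
                obs = X[~mj, j]
                X[mj, j] = rng.choice(obs, size=int(mj.sum()), replace=True)
        if with_missing:
            for _ in range(n_cycles):
                for v in with_missing:
                    j = variables.index(v)
                    mj = miss[:, j]
                    others = [jj for jj in range(len(variables)) if jj != j]
                    A = X[:, others]
                    y = X[:, j]
                    if v in bin_set:
                        beta = _logistic_irls(A[~mj], y[~mj])
                        p = _sigmoid(np.column_stack(
                            [np.ones(int(mj.sum())), A[mj]]) @ beta)
                        X[mj, j] = (rng.random(int(mj.sum())) < p).astype(float)
                    else:
                        Ad = np.column_stack([np.ones(len(A)), A])
                        beta, *_ = np.linalg.lstsq(Ad[~mj], y[~mj], rcond=None)
                        pred = Ad @ beta
                        obs_pred = pred[~mj]
                        obs_y = y[~mj]
                        for i in np.flatnonzero(mj):
                            dist = np.abs(obs_pred - pred[i])
                            pool = np.argsort(dist, kind="stable")[:n_donors]
                            X[i, j] = obs_y[pool[rng.integers(len(pool))]]
        out = table.copy()
        out[variables] = X
        tables.append(out)
    return ImputedSet(m=m, tables=tables, mask=mask, variables=variables)


def consensus_table(imputed: ImputedSet, binary=()) -> pd.DataFrame:
    """One completed table pooling the m imputations.

    Observed cells are untouched; imputed continuous cells take the mean
    across the m tables and imputed binary cells the majority vote (ties
    resolved toward the first table). This is the single analysis dataset
    that carries both within- and between-imputation information into the
    clustering stage; per-imputation fits remain available as the
    sensitivity analysis.
    """
    out = imputed.tables[0].copy()
    bin_set = set(binary)
    for v in imputed.variables:
        miss = imputed.mask[v].to_numpy()
        if not miss.any():
            continue
        stack = np.column_stack(
            [t[v].to_numpy(dtype=float)[miss] for t in imputed.tables])
        if v in bin_set:
            frac = stack.mean(axis=1)
            first = stack[:, 0]
            pooled = np.where(np.isclose(frac, 0.5), first,
                              (frac > 0.5).astype(float))
        else:
            pooled = stack.mean(axis=1)
        col = out[v].to_numpy(dtype=float)
        col[miss] = pooled
        out[v] = col
    return out


def imputation_assignment_stability(
    imputed: ImputedSet,
    k: int,
    binary=(),
    log_vars=(),
    structure: str = "diagonal-varying",
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """Mean pairwise per-patient agreement of class assignments across the
    m completed tables (classes aligned to the first table's fit)."""
    labels = []
    for t in imputed.tables:
        data = engine.standardize(t, imputed.variables, binary=binary,
                                  log_vars=log_vars)
        fit = engine.em_fit(data, k, structure, n_starts=n_starts, seed=seed,
                            tol=tol, max_iter=max_iter)
        labels.append(fit.labels)
    aligned = [labels[0]]
    for lab in labels[1:]:
        perm = match_classes(labels[0], lab, k)
        aligned.append(apply_permutation(perm, lab))
    agreements = [
        float(np.mean(aligned[i] == aligned[j]))
        for i in range(len(aligned))
        for j in range(i + 1, len(aligned))
    ]
    return float(np.mean(agreements))
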