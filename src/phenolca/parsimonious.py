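"""Greedy derivation of a reduced-variable phenotype classifier.

Starting from the full-model class assignments, forward selection adds at
each step the variable whose candidate-subset mixture best reproduces the
reference labels under stratified cross-validation. The reduced model is a
refit of the same mixture family on the selected subset — not a supervised
classifier — so it can assign classes prospectively without reference
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import MixtureFit, ScaledMatrix, em_fit, predict_labels
from .impute import ImputedSet
from . import engine
from .stability import apply_permutation, cohen_kappa, match_classes

__all__ = ["ParsimoniousFit", "greedy_forward_selection",
           "accuracy_across_imputations"]


@dataclass
class ParsimoniousFit:
    selected: list[str]
    cv_accuracy: list[float]          # per step
    cv_kappa: list[float]
    insample_accuracy: list[float]
    k: int
    structure: str
    reference_fingerprint: str = ""
    final_fit: MixtureFit | None = None

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "cv_accuracy": self.cv_accuracy,
            "cv_kappa": self.cv_kappa,
            "insample_accuracy": self.insample_accuracy,
            "k": self.k,
            "structure": self.structure,
            "reference_fingerprint": self.reference_fingerprint,
        }


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for i, ix in enumerate(idx):
            folds[i % n_folds].append(int(ix))
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def _subset_cv_accuracy(data: ScaledMatrix, cols: list[str],
                        reference: np.ndarray, k: int, folds,
                        structure: str, n_starts: int, seed: int,
                        tol: float, max_iter: int):
    """Cross-validated agreement of a subset mixture with reference labels.

    Classes are matched to the reference on the training rows only, then
    held-out rows are scored.
    """
    sub = data.select(cols)
    pred = np.empty(data.n, dtype=int)
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(data.n, dtype=bool)
        train_mask[test_idx] = False
        train = ScaledMatrix(values=sub.values[train_mask], columns=sub.columns,
                             means=sub.means, sds=sub.sds, binary=sub.binary,
                             log_transformed=sub.log_transformed)
        fit = em_fit(train, k, structure, n_starts=n_starts,
                     seed=seed * 1000 + fi, tol=tol, max_iter=max_iter,
                     init_candidates=3, init_cycles=5)
        perm = match_classes(reference[train_mask], fit.labels, k)
        pred[test_idx] = apply_permutation(
            perm, predict_labels(fit, sub.values[test_idx]))
    acc = float(np.mean(pred == reference))
    try:
        kap = cohen_kappa(reference, pred)
    except ZeroDivisionError:
        kap = 1.0 if acc == 1.0 else 0.0
    return acc, kap


def _subset_insample_accuracy(data: ScaledMatrix, cols, reference, k,
                              structure, n_starts, seed, tol, max_iter):
    sub = data.select(cols)
    fit = em_fit(sub, k, structure, n_starts=n_starts, seed=seed,
                 tol=tol, max_iter=max_iter, init_candidates=3,
                 init_cycles=5)
    perm = match_classes(reference, fit.labels, k)
    return float(np.mean(apply_permutation(perm, fit.labels) == reference)), fit


def greedy_forward_selection(
    data: ScaledMatrix,
    reference_labels: np.ndarray,
    max_vars: int = 6,
    n_folds: int = 5,
    seed: int = 0,
    k: int = 2,
    structure: str = "diagonal-varying",
    n_starts: int = 4,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> ParsimoniousFit:
    """Forward variable selection against full-model class assignments.

    At each step every unselected variable is evaluated by refitting the
    k-class mixture on the candidate subset and scoring cross-validated
    agreement with ``reference_labels``; the best variable is added (ties
    broken by roster order). Returns the ordered selection with the
    accuracy/kappa trajectory.
    """
    if max_vars < 1:
        raise ValueError("max_vars must be >= 1")
    if max_vars > data.d:
        raise ValueError("max_vars exceeds the number of variables")
    reference = np.asarray(reference_labels, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 23)))
    folds = _stratified_folds(reference, n_folds, rng)
    selected: list[str] = []
    cv_accuracy, cv_kappa, insample = [], [], []
    remaining = list(data.columns)
    final_fit = None
    for _ in range(max_vars):
        best = None
        for cand in remaining:
            acc, kap = _subset_cv_accuracy(
                data, selected + [cand], reference, k, folds, structure,
                n_starts, seed, tol, max_iter)
            if best is None or acc > best[0] + 1e-12:
                best = (acc, kap, cand)
        acc, kap, chosen = best
        selected.append(chosen)
        remaining.remove(chosen)
        cv_accuracy.append(acc)
        cv_kappa.append(kap)
        ins, final_fit = _subset_insample_accuracy(
            data, selected, reference, k, structure, n_starts, seed, tol,
            max_iter)
        insample.append(ins)
    return ParsimoniousFit(
        selected=selected,
        cv_accuracy=cv_accuracy,
        cv_kappa=cv_kappa,
        insample_accuracy=insample,
        k=k,
        structure=structure,
        reference_fingerprint=data.fingerprint,
        final_fit=final_fit,
    )


def accuracy_across_imputations(
    imputed: ImputedSet,
    fit: ParsimoniousFit,
    binary=(),
    log_vars=(),
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> dict:
    """Re-score the selected-variable model against each imputation's
    full-model labels (classes matched per imputation)."""
    accs, kappas = [], []
    for t in imputed.tables:
        full = engine.standardize(t, imputed.variables, binary=binary,
                                  log_vars=log_vars)
        ref_fit = em_fit(full, fit.k, fit.structure, n_starts=n_starts,
                         seed=seed, tol=tol, max_iter=max_iter)
        sub_fit = em_fit(full.select(fit.selected), fit.k, fit.structure,
                         n_starts=n_starts, seed=seed, tol=tol,
                         max_iter=max_iter)
        perm = match_classes(ref_fit.labels, sub_fit.labels, fit.k)
        aligned = apply_permutation(perm, sub_fit.labels)
        accs.append(float(np.mean(aligned == ref_fit.labels)))
        try:
            kappas.append(cohen_kappa(ref_fit.labels, aligned))
        except ZeroDivisionError:
            kappas.append(1.0 if accs[-1] == 1.0 else 0.0)
    return {"accuracy": accs, "kappa": kappas}
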