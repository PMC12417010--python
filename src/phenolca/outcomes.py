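"""Phenotype characterization and outcome comparison.

Per-class summary tables with appropriate two-sample tests, standardized
mean differences, the Endothelial Activation and Stress Index (EASIX),
Kaplan-Meier survival with log-rank comparison, Cox proportional hazards,
and ventilator-/hospital-free day scoring. Death is the event; day 90 is
administrative censoring. Comparisons are intentionally unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "HazardComparison",
    "km_estimate",
    "logrank_test",
    "proportional_hazards",
    "free_days",
    "easix",
    "class_summary",
]


@dataclass
class SurvivalCurve:
    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray
    variance: np.ndarray      # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "survival": self.survival.tolist(),
            "ci_lower": self.ci_lower.tolist(),
            "ci_upper": self.ci_upper.tolist(),
            "at_risk": self.at_risk.tolist(),
            "events": self.events.tolist(),
        }


@dataclass
class HazardComparison:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    reference: str
    statistic: float
    ties_method: str = "efron"

    def to_dict(self) -> dict:
        return {
            "hazard_ratio": self.hazard_ratio,
            "ci_95": [self.ci_lower, self.ci_upper],
            "p_value": self.p_value,
            "reference": self.reference,
            "ties_method": self.ties_method,
        }


def km_estimate(times, events, follow_up_days: int | None = 90) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood variance."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if follow_up_days is not None:
        e = np.where(t > follow_up_days, 0, e)
        t = np.minimum(t, follow_up_days)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_table = kmf.event_table.iloc[1:] if 0.0 not in t else kmf.event_table
    grid = event_table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = event_table["at_risk"].to_numpy()
    observed = event_table["observed"].to_numpy()
    censored = event_table["censored"].to_numpy()
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > observed,
                         observed / (at_risk * (at_risk - observed)), 0.0)
    var = surv ** 2 * np.cumsum(terms)
    ci = kmf.confidence_interval_survival_function_
    lo = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    return SurvivalCurve(times=grid, at_risk=at_risk, events=observed,
                         censored=censored, survival=surv, variance=var,
                         ci_lower=lo, ci_upper=hi)


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    groups = np.unique(g)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    res = _lifelines_logrank(t[g == groups[0]], t[g == groups[1]],
                             e[g == groups[0]], e[g == groups[1]])
    return float(res.test_statistic), float(res.p_value)


def proportional_hazards(times, events, group_labels,
                         reference=None) -> HazardComparison:
    """Cox model hazard ratio of the non-reference vs the reference group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    groups = list(np.unique(g))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if reference is None:
        reference = groups[0]
    other = [x for x in groups if x != reference][0]
    for grp in groups:
        if e[g == grp].sum() == 0:
            raise ValueError(f"group {grp!r} has no events "
                             "(monotone partial likelihood)")
    df = pd.DataFrame({"time": t, "event": e,
                       "group": (g == other).astype(int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    return HazardComparison(
        hazard_ratio=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - 1.959964 * se)),
        ci_upper=float(np.exp(beta + 1.959964 * se)),
        p_value=float(cph.summary.loc["group", "p"]),
        reference=str(reference),
        statistic=float(beta / se),
    )


def free_days(alive_at_window_end: bool, occupied_days: float,
              window: int = 28) -> int:
    """Days alive and free of the ventilator/hospital within the window.

    Patients who died in the window, or who were occupied the entire
    window, score 0.
    """
    if occupied_days < 0:
        raise ValueError("occupied_days must be non-negative")
    if occupied_days > window:
        raise ValueError("occupied_days exceeds the window")
    if not alive_at_window_end:
        return 0
    return int(window - occupied_days)


def easix(creatinine: float, ldh: float, platelets: float) -> float:
    """Endothelial Activation and Stress Index:
    (creatinine [mg/dL] x LDH [IU/L]) / platelets [1e9/L]."""
    if platelets <= 0:
        raise ValueError("platelets must be positive")
    return creatinine * ldh / platelets


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[~np.isnan(x)])
    return len(vals) <= 2 and np.isin(vals, (0.0, 1.0)).all()


def class_summary(cohort: pd.DataFrame, labels, variables=None,
                  alpha_normality: float = 0.05) -> pd.DataFrame:
    """Per-variable two-class comparison table.

    Continuous variables are screened for normality (Shapiro-Wilk per
    class); normal ones are summarized mean (sd) and compared by t-test,
    skewed ones median (IQR) and compared by Wilcoxon rank-sum; binary
    variables are count (%) with a chi-square test. A standardized mean
    difference (class 1 minus class 2, pooled sd) is reported throughout.
    """
    lab = np.asarray(labels)
    classes = np.unique(lab)
    if len(classes) != 2:
        raise ValueError("class_summary compares exactly two classes")
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in ("patient_id", "true_class")
                     and np.issubdtype(cohort[c].dtype, np.number)]
    rows = []
    for v in variables:
        x = cohort[v].to_numpy(dtype=float)
        x1 = x[lab == classes[0]]
        x2 = x[lab == classes[1]]
        x1 = x1[~np.isnan(x1)]
        x2 = x2[~np.isnan(x2)]
        if len(x1) == 0 or len(x2) == 0:
            raise ValueError(f"empty class for variable {v!r}")
        m1, m2 = x1.mean(), x2.mean()
        s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
        pooled = np.sqrt(((len(x1) - 1) * s1 ** 2 + (len(x2) - 1) * s2 ** 2)
                         / max(len(x1) + len(x2) - 2, 1))
        smd = 0.0 if pooled == 0 else (m1 - m2) / pooled
        if _is_binary(x):
            n1, n2 = int(x1.sum()), int(x2.sum())
            tab = np.array([[n1, len(x1) - n1], [n2, len(x2) - n2]])
            if (tab.sum(axis=0) == 0).any():
                p = 1.0
            else:
                p = float(stats.chi2_contingency(tab, correction=False)[1])
            rows.append({
                "variable": v, "test": "chi-square",
                "class1": f"{n1} ({100 * n1 / len(x1):.1f}%)",
                "class2": f"{n2} ({100 * n2 / len(x2):.1f}%)",
                "class1_value": 100 * n1 / len(x1),
                "class2_value": 100 * n2 / len(x2),
                "p_value": p, "smd": smd,
            })
            continue
        normal = True
        for xs in (x1, x2):
            if len(np.unique(xs)) < 3:
                normal = False
                break
            if stats.shapiro(xs[:5000]).pvalue < alpha_normality:
                normal = False
                break
        if normal:
            p = float(stats.ttest_ind(x1, x2, equal_var=False).pvalue)
            rows.append({
                "variable": v, "test": "t-test",
                "class1": f"{m1:.1f} ({s1:.2f})",
                "class2": f"{m2:.1f} ({s2:.2f})",
                "class1_value": m1, "class2_value": m2,
                "p_value": p, "smd": smd,
            })
        else:
            p = float(stats.mannwhitneyu(x1, x2,
                                         alternative="two-sided").pvalue)
            q1 = np.percentile(x1, (50, 25, 75))
            q2 = np.percentile(x2, (50, 25, 75))
            rows.append({
                "variable": v, "test": "wilcoxon",
                "class1": f"{q1[0]:.1f} ({q1[1]:.1f}, {q1[2]:.1f})",
                "class2": f"{q2[0]:.1f} ({q2[1]:.1f}, {q2[2]:.1f})",
                "class1_value": q1[0], "class2_value": q2[0],
                "p_value": p, "smd": smd,
            })
    return pd.DataFrame(rows).set_index("variable")
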