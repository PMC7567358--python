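"""Discriminative-performance validation: AUC/DeLong, Kaplan-Meier, log-rank.

The score's ability to separate 1-year decedents from survivors is measured
with the c-statistic (tie-aware Mann-Whitney AUC).  Confidence intervals
and paired score comparisons use DeLong's nonparametric structural
components; the paired comparison is reported as a 1-df chi-square (the
squared standardized AUC difference).  Survival by risk class uses the
product-limit estimator and the k-sample log-rank test (lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "RocResult",
    "auc",
    "auc_ci_delong",
    "compare_auc_paired",
    "bootstrap_auc_ci",
    "km_estimate",
    "logrank",
    "validation_report",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float | None
    ci_high: float | None
    n_pos: int
    n_neg: int


def _check_binary(outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    outcome = np.asarray(outcome).astype(int)
    pos = outcome == 1
    neg = outcome == 0
    if not pos.any() or not neg.any():
        raise ValueError("AUC needs both cases and controls in the outcome")
    return pos, neg


def _midrank_auc(score: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> float:
    # Mann-Whitney with ties counting half, via midranks:
    # AUC = (mean rank of cases - (m+1)/2) / n
    ranks = stats.rankdata(score)
    m, n = int(pos.sum()), int(neg.sum())
    return float((ranks[pos].mean() - (m + 1) / 2.0) / n)


def auc(score, outcome) -> RocResult:
    """Tie-aware c-statistic: P(score_case > score_control) + 0.5 P(tie)."""
    score = np.asarray(score, dtype=float)
    pos, neg = _check_binary(outcome)
    return RocResult(_midrank_auc(score, pos, neg), None, None,
                     int(pos.sum()), int(neg.sum()))


def _delong_components(score: np.ndarray, pos: np.ndarray, neg: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components V10 (cases), V01 (controls)."""
    x = score[pos]
    y = score[neg]
    m, n = len(x), len(y)
    all_ranks = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    a = float((all_ranks[:m].mean() - (m + 1) / 2.0) / n)
    v10 = (all_ranks[:m] - rx) / n            # per-case placement values
    v01 = 1.0 - (all_ranks[m:] - ry) / m      # per-control placement values
    return a, v10, v01


def _delong_var(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci_delong(score, outcome, level: float = 0.95) -> RocResult:
    """DeLong variance, normal-approximation CI truncated to [0, 1]."""
    score = np.asarray(score, dtype=float)
    pos, neg = _check_binary(outcome)
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("DeLong CI needs at least 2 cases and 2 controls")
    a, v10, v01 = _delong_components(score, pos, neg)
    var = _delong_var(v10, v01)
    if var == 0.0:
        warnings.warn("degenerate DeLong variance; CI collapses to the point estimate",
                      stacklevel=2)
        return RocResult(a, a, a, len(v10), len(v01))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return RocResult(a, max(0.0, a - half), min(1.0, a + half), len(v10), len(v01))


def compare_auc_paired(score_a, score_b, outcome) -> tuple[float, float]:
    """DeLong paired AUC comparison on the same patients.

    Returns ``(chi_square, p)`` where the statistic is the squared
    standardized AUC difference (1 df), so a score compared with any
    strictly monotone transform of itself gives exactly 0.
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    if score_a.shape != score_b.shape:
        raise ValueError("paired scores must align")
    pos, neg = _check_binary(outcome)
    aa, v10a, v01a = _delong_components(score_a, pos, neg)
    ab, v10b, v01b = _delong_components(score_b, pos, neg)
    m, n = len(v10a), len(v01a)
    cov10 = np.cov(v10a, v10b, ddof=1) if m > 1 else np.zeros((2, 2))
    cov01 = np.cov(v01a, v01b, ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = (cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]) / m \
        + (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n
    diff = aa - ab
    if var_diff <= 0:
        chi2 = 0.0 if diff == 0 else np.inf
    else:
        chi2 = diff ** 2 / var_diff
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def bootstrap_auc_ci(score, outcome, level: float = 0.95, n_boot: int = 2000,
                     seed: int = 0) -> RocResult:
    """Percentile bootstrap CI for the AUC (alternative to DeLong)."""
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    pos, neg = _check_binary(outcome)
    a = _midrank_auc(score, pos, neg)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(pos)
    idx_neg = np.flatnonzero(neg)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(idx_pos, len(idx_pos)),
                               rng.choice(idx_neg, len(idx_neg))])
        s = score[take]
        p = np.concatenate([np.ones(len(idx_pos), bool), np.zeros(len(idx_neg), bool)])
        stats_[b] = _midrank_auc(s, p, ~p)
    lo, hi = np.quantile(stats_, [(1 - level) / 2, 0.5 + level / 2])
    return RocResult(a, float(lo), float(hi), len(idx_pos), len(idx_neg))


def km_estimate(survival: pd.DataFrame, classes) -> dict:
    """Product-limit survival curve per risk class.

    *survival* needs ``time`` and ``event``; *classes* is the per-patient
    class label (aligned).  Returns ``{class: DataFrame(time, at_risk,
    survival)}`` ordered by class label.
    """
    classes = np.asarray(classes)
    out: dict = {}
    for cls in np.unique(classes):
        mask = classes == cls
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(survival.loc[mask, "time"], survival.loc[mask, "event"])
        tbl = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        out[cls] = pd.DataFrame({
            "time": tbl.index.to_numpy(),
            "at_risk": tbl["at_risk"].to_numpy(),
            "survival": surv.reindex(tbl.index).to_numpy(),
        })
    return out


def logrank(survival: pd.DataFrame, classes) -> tuple[float, int, float]:
    """k-sample log-rank test across risk classes: (chi_square, df, p)."""
    classes = np.asarray(classes)
    k = len(np.unique(classes))
    if k < 2:
        raise ValueError("log-rank needs at least two classes")
    res = multivariate_logrank_test(survival["time"], classes, survival["event"])
    return float(res.test_statistic), k - 1, float(res.p_value)


def validation_report(scores: pd.DataFrame, survival: pd.DataFrame,
                      comparators: pd.DataFrame | None = None,
                      level: float = 0.95) -> dict:
    """One-stop report: AUC + CI, per-class KM summary, log-rank, comparisons.

    *scores* needs ``patient_id, score, risk_class``; *survival* needs
    ``patient_id, time, event``; *comparators* may carry extra pre-computed
    score columns (e.g. a diagnosis-based comorbidity index) keyed by
    ``patient_id``, each compared to the score with the paired DeLong test.
    """
    merged = scores.merge(survival, on="patient_id")
    outcome = merged["event"].to_numpy()
    roc = auc_ci_delong(merged["score"], outcome, level)
    chi2_lr, df, p_lr = logrank(merged, merged["risk_class"])
    km = km_estimate(merged, merged["risk_class"])
    report = {
        "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
        "n_pos": roc.n_pos, "n_neg": roc.n_neg,
        "logrank": {"chi_square": chi2_lr, "df": df, "p": p_lr},
        "km_final_survival": {int(c): float(tbl["survival"].iloc[-1])
                              for c, tbl in km.items()},
        "comparisons": {},
    }
    if comparators is not None:
        comp = merged.merge(comparators, on="patient_id")
        for col in comparators.columns:
            if col == "patient_id":
                continue
            chi2_c, p_c = compare_auc_paired(comp["score"], comp[col], comp["event"])
            other = auc_ci_delong(comp[col], comp["event"], level)
            report["comparisons"][col] = {
                "auc": other.auc, "ci_low": other.ci_low, "ci_high": other.ci_high,
                "chi_square": chi2_c, "p": p_c,
            }
    return report
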