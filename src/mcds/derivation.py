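"""Weight re-derivation: L1-penalized Cox selection + post-selection refit.

The pipeline that produced the published weights, reusable on any cohort:

1. candidate covariates = age (years), sex indicator, one binary flag per
   chronic condition;
2. LASSO-penalized Cox partial likelihood (Breslow ties) over a decreasing
   penalty grid, 10-fold cross-validation of the partial-likelihood
   deviance (Verweij & Van Houwelingen), penalty chosen by the
   one-standard-error rule;
3. unpenalized Cox refit on the selected covariates (default; the penalized
   coefficients can be used instead) and the x10-and-round weight
   transform applied to the condition coefficients.  Age and sex may be
   selected but never receive weights.

The path fitting is delegated to scikit-survival's coordinate-descent
coxnet; the CV loss, the one-SE rule, the refit and the transform live
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from statsmodels.duration.hazard_regression import PHReg

from .scoring import WeightTable

__all__ = [
    "PenalizedCoxFit",
    "cox_partial_loglik",
    "fit_lasso_cox",
    "extract_weights",
    "split_train_test",
    "derive_weights",
]


def cox_partial_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                       beta: np.ndarray) -> float:
    """Breslow-ties Cox partial log-likelihood at a fixed coefficient vector.

    Each death contributes eta_i - log(sum of exp(eta_j) over subjects still
    at risk at its time); tied deaths share the same risk-set denominator.
    """
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    order = np.argsort(-np.asarray(time, dtype=float), kind="stable")
    t_sorted = np.asarray(time, dtype=float)[order]
    eta_sorted = eta[order]
    # running logsumexp over subjects with t >= current t (descending order)
    big = eta_sorted.max()
    log_denom_all = np.log(np.cumsum(np.exp(eta_sorted - big))) + big
    # risk set of a subject includes everyone with time >= its time (ties included)
    idx_last = np.searchsorted(-t_sorted, -t_sorted, side="right") - 1
    log_denom = log_denom_all[idx_last]
    ev_sorted = np.asarray(event)[order].astype(bool)
    return float(np.sum(eta_sorted[ev_sorted] - log_denom[ev_sorted]))


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels (0..n_folds-1), events and non-events spread evenly."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(event), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(np.asarray(event) == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


@dataclass
class PenalizedCoxFit:
    """LASSO-Cox path with cross-validated deviance and the selected penalties."""

    covariates: list[str]
    lambda_grid: np.ndarray                 # decreasing
    coefficient_path: np.ndarray            # (covariate, lambda)
    cv_mean: np.ndarray                     # mean CV deviance per lambda
    cv_se: np.ndarray                       # SE over folds per lambda
    lambda_min: float
    lambda_1se: float
    dropped_constant: list[str] = field(default_factory=list)
    refit_coefficients: pd.Series | None = None

    @property
    def _i_1se(self) -> int:
        return int(np.argmin(np.abs(self.lambda_grid - self.lambda_1se)))

    def coefficients_at_1se(self) -> pd.Series:
        return pd.Series(self.coefficient_path[:, self._i_1se], index=self.covariates)

    @property
    def selected_set(self) -> list[str]:
        c = self.coefficients_at_1se()
        return c.index[c != 0].tolist()

    def n_nonzero(self) -> np.ndarray:
        return (self.coefficient_path != 0).sum(axis=0)

    def report(self) -> dict:
        """JSON-serializable summary of the path and the selection."""
        return {
            "covariates": self.covariates,
            "lambda_grid": self.lambda_grid.tolist(),
            "n_nonzero": self.n_nonzero().tolist(),
            "cv_mean_deviance": self.cv_mean.tolist(),
            "cv_se_deviance": self.cv_se.tolist(),
            "lambda_min": self.lambda_min,
            "lambda_1se": self.lambda_1se,
            "selected_set": self.selected_set,
            "dropped_constant": self.dropped_constant,
            "refit_coefficients": (None if self.refit_coefficients is None
                                   else self.refit_coefficients.to_dict()),
        }


def fit_lasso_cox(X: pd.DataFrame, survival: pd.DataFrame, n_folds: int = 10,
                  seed: int = 0, *, n_lambdas: int = 100,
                  lambda_min_ratio: float = 0.001) -> PenalizedCoxFit:
    """LASSO Cox path + stratified K-fold CV deviance + one-SE selection.

    *X* is the covariate frame (rows aligned with *survival*, which needs
    ``time`` and ``event`` columns).  The grid runs from the smallest
    penalty that zeroes every coefficient down to ``lambda_min_ratio`` times
    it, log-spaced.  The CV loss at each penalty is the partial-likelihood
    deviance computed as -2*(pl_full(beta_k) - pl_without_fold(beta_k)) for
    the model beta_k fit without fold k; fold assignment is stratified by
    event status and reproducible from *seed*.
    """
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in the training data; cannot fit a Cox model")
    if len(X) != len(survival):
        raise ValueError("X and survival must have the same number of rows")

    Xv = X.to_numpy(dtype=float)
    const = Xv.std(axis=0) == 0
    dropped = list(X.columns[const])
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}", stacklevel=2)
        X = X.loc[:, ~const]
        Xv = Xv[:, ~const]
    covariates = list(X.columns)

    y = Surv.from_arrays(event.astype(bool), time)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_lambdas,
                                  alpha_min_ratio=lambda_min_ratio, tol=1e-7,
                                  normalize=True)
    path.fit(Xv, y)
    grid = np.asarray(path.alphas_)           # decreasing
    coef_path = np.asarray(path.coef_)        # (p, n_lambda)

    fold = _stratified_folds(event, n_folds, seed)
    dev = np.empty((n_folds, len(grid)))
    for k in range(n_folds):
        tr = fold != k
        if event[tr].sum() == 0:
            raise ValueError(f"fold {k} leaves no events for training")
        mk = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=grid, tol=1e-7,
                                    normalize=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mk.fit(Xv[tr], Surv.from_arrays(event[tr].astype(bool), time[tr]))
        ck = np.asarray(mk.coef_)
        # coxnet may truncate the path; reuse the last fitted coefficients
        if ck.shape[1] < len(grid):
            pad = np.repeat(ck[:, -1:], len(grid) - ck.shape[1], axis=1)
            ck = np.hstack([ck, pad])
        for j in range(len(grid)):
            pl_full = cox_partial_loglik(Xv, time, event, ck[:, j])
            pl_train = cox_partial_loglik(Xv[tr], time[tr], event[tr], ck[:, j])
            dev[k, j] = -2.0 * (pl_full - pl_train)

    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    # grid is decreasing: the most parsimonious admissible model is the
    # largest lambda whose mean CV deviance is within one SE of the minimum
    admissible = np.flatnonzero(cv_mean <= threshold)
    i_1se = int(admissible.min())

    return PenalizedCoxFit(
        covariates=covariates,
        lambda_grid=grid,
        coefficient_path=coef_path,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=float(grid[i_min]),
        lambda_1se=float(grid[i_1se]),
        dropped_constant=dropped,
    )


def extract_weights(fit: PenalizedCoxFit, survival: pd.DataFrame, X: pd.DataFrame,
                    refit: bool = True, *, condition_names=None,
                    ties: str = "breslow") -> WeightTable:
    """Weight table from a penalized fit.

    With ``refit=True`` (default) an unpenalized Cox model is refit on the
    selected covariates and its coefficients are transformed; otherwise the
    penalized coefficients at the one-SE penalty are transformed directly.
    Covariates named in *condition_names* (default: everything except
    ``age`` and ``sex``) receive weights; the rest (age, sex) are reported
    in ``fit.refit_coefficients`` but never weighted.
    """
    selected = fit.selected_set
    if not selected:
        raise ValueError("the one-SE model selected no covariates; nothing to weight")
    if condition_names is None:
        condition_names = [c for c in fit.covariates if c not in ("age", "sex")]

    if refit:
        Xs = X[selected].to_numpy(dtype=float)
        model = PHReg(survival["time"].to_numpy(dtype=float), Xs,
                      status=survival["event"].to_numpy(dtype=int), ties=ties)
        try:
            res = model.fit(disp=False)
        except Exception as exc:  # pragma: no cover - convergence failures
            raise RuntimeError(f"unpenalized Cox refit failed: {exc}") from exc
        coefs = pd.Series(res.params, index=selected)
    else:
        coefs = fit.coefficients_at_1se()[selected]

    fit.refit_coefficients = coefs
    cond = coefs[[c for c in selected if c in condition_names]]
    return WeightTable.from_coefficients(cond)


def split_train_test(patient_ids, fraction: float = 0.8, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Reproducible random split of patient ids into train/test.

    Sizes are ``round(fraction*n)`` and the remainder; the split is
    disjoint, exhaustive and a pure function of *seed*.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ids = np.asarray(patient_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    return ids[perm[:n_train]], ids[perm[n_train:]]


def derive_weights(X: pd.DataFrame, survival: pd.DataFrame, *, n_folds: int = 10,
                   seed: int = 0, refit: bool = True,
                   condition_names=None) -> tuple[WeightTable, PenalizedCoxFit]:
    """Full pipeline: LASSO path -> CV -> one-SE -> (refit) -> weight table."""
    fit = fit_lasso_cox(X, survival, n_folds=n_folds, seed=seed)
    table = extract_weights(fit, survival, X, refit=refit,
                            condition_names=condition_names)
    return table, fit
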