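"""Complexity selection by stratified cross-validation and permutation significance.

The DNF complexity grid is every (K, M) with K*M <= 4, i.e. eight settings
from the single predictor (1, 1) to the 2-by-2 model (2, 2).  The complexity
with the lowest mean cross-validated weighted error is selected (ties broken
toward parsimony).  Significance of the selected model is assessed by
permuting the assembled out-of-fold prediction vector: the weighted error of
a permuted prediction has expectation exactly 0.5 under class-normalized
weights, and the observed error's left-tail probability is the p-value, with
a generalized-Pareto tail refinement for small p.  Across a drug panel,
Benjamini-Hochberg q-values control the FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import genpareto
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .dataset import WeightedDataset, weighted_error
from .ilp import DNFClassifier, SolveResult, fit_dnf

__all__ = [
    "COMPLEXITY_GRID", "CVReport", "SignificanceResult",
    "stratified_folds", "cross_validate", "permutation_null",
    "tail_pvalue", "fdr_qvalues", "significance_test", "DNFComplexityCV",
]

log = logging.getLogger(__name__)

#: all (K, M) with K * M <= 4
COMPLEXITY_GRID = [(1, 1), (1, 2), (1, 3), (1, 4), (2, 1), (2, 2), (3, 1), (4, 1)]


def stratified_folds(y, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``n_folds`` class-stratified test folds.

    If a class has fewer members than ``n_folds``, the fold count is reduced
    to the minority class size (with a logged warning).
    """
    y = np.asarray(y)
    min_class = min(int((y == 1).sum()), int((y == 0).sum()))
    if min_class < 2:
        raise ValueError("both classes need >= 2 members for cross-validation")
    if min_class < n_folds:
        log.warning("reducing folds from %d to minority class size %d",
                    n_folds, min_class)
        n_folds = min_class
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class CVReport:
    """Cross-validation summary over the complexity grid."""

    complexity_errors: dict            # (K, M) -> mean fold error
    selected: tuple                    # (K, M) with the lowest CV error
    fold_assignment: np.ndarray        # test-fold index per sample
    fold_models: dict                  # (K, M) -> [SolveResult per fold]
    cv_predictions: dict               # (K, M) -> assembled out-of-fold y'
    oof_errors: dict = field(default_factory=dict)  # (K, M) -> error of assembled y'

    @property
    def selected_cv_error(self) -> float:
        return self.complexity_errors[self.selected]

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "cv_errors": {f"{k}x{m}": e for (k, m), e in self.complexity_errors.items()},
            "oof_errors": {f"{k}x{m}": e for (k, m), e in self.oof_errors.items()},
        }


def cross_validate(dataset: WeightedDataset, complexities=None, n_folds: int = 10,
                   seed: int = 0, *, tpr_min=None, tnr_min=None,
                   continuous_constraints: bool = False,
                   time_limit_s: float = 3600.0, solver: str = "auto") -> CVReport:
    """Stratified K-fold CV of the DNF ILP over a complexity grid.

    Per fold, training weights are re-normalized per class to 0.5 before
    fitting, and test weights are re-normalized the same way, so every fold
    error lives on the common [0, 1] scale.  The mean fold error selects the
    complexity; ties go to the lowest K*M, then the lowest K.

    An infeasible fold fit (possible under operating-point constraints)
    contributes the worst-case error 1.0 for that fold.
    """
    if complexities is None:
        complexities = COMPLEXITY_GRID
    assignment = stratified_folds(dataset.y, n_folds=n_folds, seed=seed)
    n_folds_eff = assignment.max() + 1

    complexity_errors: dict = {}
    fold_models: dict = {}
    cv_predictions: dict = {}
    oof_errors: dict = {}
    for (k, m) in complexities:
        fold_errs = []
        results = []
        oof = np.zeros(dataset.n, dtype=np.int8)
        for fold in range(n_folds_eff):
            train = np.flatnonzero(assignment != fold)
            test = np.flatnonzero(assignment == fold)
            ds_train = dataset.subset(train)
            res = fit_dnf(ds_train, k, m, tpr_min=tpr_min, tnr_min=tnr_min,
                          continuous_constraints=continuous_constraints,
                          time_limit_s=time_limit_s, solver=solver)
            results.append(res)
            if not res.feasible:
                fold_errs.append(1.0)
                continue
            ds_test = dataset.subset(test)
            pred = res.best.predict(ds_test.X)
            fold_errs.append(weighted_error(pred, ds_test.y, ds_test.w))
            oof[test] = pred
        complexity_errors[(k, m)] = float(np.mean(fold_errs))
        fold_models[(k, m)] = results
        cv_predictions[(k, m)] = oof
        oof_errors[(k, m)] = weighted_error(oof, dataset.y, dataset.w)

    selected = min(complexity_errors,
                   key=lambda km: (complexity_errors[km], km[0] * km[1], km[0]))
    return CVReport(complexity_errors=complexity_errors, selected=selected,
                    fold_assignment=assignment, fold_models=fold_models,
                    cv_predictions=cv_predictions, oof_errors=oof_errors)


def permutation_null(y_pred, y, w, n_perm: int = 10_000, seed: int = 0,
                     batch: int = 2000) -> np.ndarray:
    """Weighted errors of uniformly permuted copies of a prediction vector.

    Only the positions of the predicted ones matter, so each permutation is
    drawn as a uniform subset of positions; with class-normalized weights
    the null mean is exactly 0.5.
    """
    y_pred = np.asarray(y_pred)
    y = np.asarray(y)
    w = np.asarray(w, dtype=float)
    n = len(y)
    m = int(y_pred.sum())
    # error = base + sum over predicted-one positions of delta
    cost1 = np.where(y == 0, w, 0.0)   # cost of predicting 1
    cost0 = np.where(y == 1, w, 0.0)   # cost of predicting 0
    base = cost0.sum()
    delta = cost1 - cost0
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m] if m > 0 else None
        if m == 0:
            out[done:done + b] = base
        else:
            out[done:done + b] = base + delta[idx].sum(axis=1)
        done += b
    return out


def tail_pvalue(null_errors, observed: float, refine_below: float | None = None,
                n_tail: int = 250) -> float:
    """Left-tail p-value of an observed error against a permutation null.

    Empirical p = (1 + #{null <= observed}) / (n + 1).  When the empirical
    estimate is smaller than ``refine_below`` (default 10 / n), the lower
    tail is refitted with a generalized Pareto distribution on the
    exceedances below the ``n_tail``-th smallest null value, and the GPD
    tail estimate is returned; on a degenerate fit the empirical value is
    kept.  Always > 0.
    """
    null = np.asarray(null_errors, dtype=float)
    n = len(null)
    if n == 0:
        raise ValueError("empty permutation null")
    emp = (1.0 + np.count_nonzero(null <= observed)) / (n + 1.0)
    if refine_below is None:
        refine_below = 10.0 / n
    if emp >= refine_below or n <= n_tail:
        return float(emp)
    lowest = np.partition(null, n_tail)[: n_tail + 1]
    u = float(np.max(lowest))          # tail threshold
    exc = u - null[null < u]
    if observed >= u or len(exc) < 10 or np.ptp(exc) < 1e-15:
        return float(emp)
    try:
        shape, _, scale = genpareto.fit(exc, floc=0.0)
        tail = genpareto.sf(u - observed, shape, loc=0.0, scale=scale)
        p = (len(exc) / n) * float(tail)
    except Exception:  # pragma: no cover - solver hiccups
        log.warning("GPD tail fit failed; falling back to empirical p")
        return float(emp)
    if not np.isfinite(p) or p <= 0:
        # observed lies outside the fitted tail's support; the empirical
        # add-one estimate is the defensible bound
        return float(emp)
    return float(min(p, emp))


def fdr_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SignificanceResult:
    observed_error: float
    p_value: float
    q_value: float | None
    n_permutations: int

    @property
    def significant(self) -> bool | None:
        if self.q_value is None:
            return None
        return self.p_value < 0.01 and self.q_value < 0.01

    def to_dict(self) -> dict:
        return {"observed_error": self.observed_error, "p": self.p_value,
                "q": self.q_value, "n_permutations": self.n_permutations,
                "significant": self.significant}


def significance_test(report: CVReport, dataset: WeightedDataset,
                      n_perm: int = 10_000, seed: int = 0) -> SignificanceResult:
    """Permutation test of the selected complexity's out-of-fold predictions.

    The assembled out-of-fold prediction vector is permuted against the
    class-normalized weighted labels; the observed error is the weighted
    error of that same vector on the full dataset.  The q-value is filled in
    later by :func:`fdr_qvalues` across a panel.
    """
    pred = report.cv_predictions[report.selected]
    observed = weighted_error(pred, dataset.y, dataset.w)
    null = permutation_null(pred, dataset.y, dataset.w, n_perm=n_perm, seed=seed)
    p = tail_pvalue(null, observed)
    return SignificanceResult(observed_error=float(observed), p_value=p,
                              q_value=None, n_permutations=n_perm)


class DNFComplexityCV:
    """Estimator that selects DNF complexity by stratified CV, then refits.

    Mirrors the grid-search pattern: ``fit`` runs the CV over the complexity
    grid, picks the (K, M) with the lowest mean fold error, and refits a
    :class:`DNFClassifier` (with a solution pool) on the full data.

    Attributes (after ``fit``)
    ----------
    cv_report_ : CVReport
    best_complexity_ : (K, M)
    best_estimator_ : DNFClassifier
    model_, error_ : the refit model and its training error
    """

    def __init__(self, complexities=None, n_folds: int = 10, seed: int = 0, *,
                 tpr_min=None, tnr_min=None, continuous_constraints: bool = False,
                 pool_size: int = 25, pool_gap: float = 0.1,
                 time_limit_s: float = 3600.0, solver: str = "auto"):
        self.complexities = complexities
        self.n_folds = n_folds
        self.seed = seed
        self.tpr_min = tpr_min
        self.tnr_min = tnr_min
        self.continuous_constraints = continuous_constraints
        self.pool_size = pool_size
        self.pool_gap = pool_gap
        self.time_limit_s = time_limit_s
        self.solver = solver

    _param_names = ("complexities", "n_folds", "seed", "tpr_min", "tnr_min",
                    "continuous_constraints", "pool_size", "pool_gap",
                    "time_limit_s", "solver")

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "DNFComplexityCV":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, sample_weight=None) -> "DNFComplexityCV":
        if isinstance(X, WeightedDataset):
            ds = X
        else:
            ds = DNFClassifier()._as_dataset(X, y, sample_weight)
        self.cv_report_ = cross_validate(
            ds, complexities=self.complexities, n_folds=self.n_folds,
            seed=self.seed, tpr_min=self.tpr_min, tnr_min=self.tnr_min,
            continuous_constraints=self.continuous_constraints,
            time_limit_s=self.time_limit_s, solver=self.solver)
        k, m = self.cv_report_.selected
        self.best_complexity_ = (k, m)
        est = DNFClassifier(
            k=k, m=m, tpr_min=self.tpr_min, tnr_min=self.tnr_min,
            continuous_constraints=self.continuous_constraints,
            pool_size=self.pool_size, pool_gap=self.pool_gap,
            time_limit_s=self.time_limit_s, solver=self.solver)
        est.fit(ds)
        self.best_estimator_ = est
        self.model_ = est.model_
        self.error_ = est.error_
        return self

    def predict(self, X) -> np.ndarray:
        return self.best_estimator_.predict(X)

    def score(self, X, y, sample_weight=None) -> float:
        return self.best_estimator_.score(X, y, sample_weight)
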