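"""Probing the ROC space with hard sensitivity/specificity constraints.

Instead of thresholding one model's score, a separate constrained DNF is
inferred at every grid point (TPR_min, TNR_min): the constraints are hard
lower bounds in the ILP, so a returned model is guaranteed to meet them on
the training data.  Each grid point selects its own complexity by CV.  The
non-dominated solutions (max achieved TPR, min achieved FPR) form a Pareto
front analogous to an ROC curve along which the model itself changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import WeightedDataset
from .dnf import DNFModel, evaluate_dnf
from .importance import fi_vector
from .select import COMPLEXITY_GRID, cross_validate

__all__ = ["OperatingPointSolution", "probe_grid", "pareto_front",
           "group_fi_summary", "grid_points"]

log = logging.getLogger(__name__)


@dataclass
class OperatingPointSolution:
    """A constrained DNF fit at one (TPR_min, TNR_min) grid point."""

    tpr_min: float
    tnr_min: float
    feasible: bool
    model: DNFModel | None = None
    complexity: tuple | None = None
    achieved_tpr: float | None = None
    achieved_fpr: float | None = None
    cv_error: float | None = None

    def to_dict(self, feature_names=None) -> dict:
        from .dnf import format_dnf
        return {
            "tpr_min": self.tpr_min, "tnr_min": self.tnr_min,
            "feasible": self.feasible,
            "K": None if self.complexity is None else self.complexity[0],
            "M": None if self.complexity is None else self.complexity[1],
            "model": None if self.model is None else (
                format_dnf(self.model, feature_names) if feature_names else repr(self.model)),
            "achieved_tpr": self.achieved_tpr, "achieved_fpr": self.achieved_fpr,
            "cv_error": self.cv_error,
        }


def grid_points(step: float = 0.05):
    """The (TPR_min, TNR_min) lattice {0, step, ..., 1}^2."""
    axis = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return [(float(a), float(b)) for a in axis for b in axis]


def _achieved_rates(model: DNFModel, dataset: WeightedDataset):
    pred = evaluate_dnf(model, dataset.X)
    pos = dataset.y == 1
    neg = ~pos
    tpr = float(pred[pos].sum() / pos.sum())
    fpr = float(pred[neg].sum() / neg.sum())
    return tpr, fpr


def probe_grid(dataset: WeightedDataset, step: float = 0.05, complexities=None,
               n_folds: int = 10, seed: int = 0, *,
               continuous_constraints: bool = False,
               time_limit_s: float = 3600.0,
               solver: str = "auto") -> list[OperatingPointSolution]:
    """Constrained DNF inference over the full ROC grid.

    At each grid point the complexity is selected by constrained CV among
    the settings whose full-data constrained fit is feasible; points where
    every complexity is infeasible are returned with ``feasible=False``.
    Infeasibility is monotone in the bounds, which is used to prune the
    sweep: once (a, b) is infeasible, every (a' >= a, b' >= b) is too.
    """
    from .ilp import fit_dnf

    if complexities is None:
        complexities = COMPLEXITY_GRID
    solutions = []
    infeasible_points: list[tuple[float, float]] = []
    for tpr_min, tnr_min in grid_points(step):
        if any(tpr_min >= a and tnr_min >= b for a, b in infeasible_points):
            solutions.append(OperatingPointSolution(tpr_min, tnr_min, feasible=False))
            continue
        full_fits = {}
        for (k, m) in complexities:
            res = fit_dnf(dataset, k, m, tpr_min=tpr_min, tnr_min=tnr_min,
                          continuous_constraints=continuous_constraints,
                          time_limit_s=time_limit_s, solver=solver)
            if res.feasible:
                full_fits[(k, m)] = res
        if not full_fits:
            infeasible_points.append((tpr_min, tnr_min))
            solutions.append(OperatingPointSolution(tpr_min, tnr_min, feasible=False))
            continue
        report = cross_validate(
            dataset, complexities=list(full_fits), n_folds=n_folds, seed=seed,
            tpr_min=tpr_min, tnr_min=tnr_min,
            continuous_constraints=continuous_constraints,
            time_limit_s=time_limit_s, solver=solver)
        km = report.selected
        model = full_fits[km].best
        tpr, fpr = _achieved_rates(model, dataset)
        solutions.append(OperatingPointSolution(
            tpr_min=tpr_min, tnr_min=tnr_min, feasible=True, model=model,
            complexity=km, achieved_tpr=tpr, achieved_fpr=fpr,
            cv_error=report.selected_cv_error))
    return solutions


def pareto_front(solutions) -> list[OperatingPointSolution]:
    """Solutions not dominated in (maximize achieved TPR, minimize achieved FPR).

    A solution is dominated if another is at least as good on both rates and
    strictly better on one; exact ties are all kept.
    """
    feasible = [s for s in solutions if s.feasible and s.achieved_tpr is not None]
    front = []
    for s in feasible:
        dominated = any(
            (o.achieved_tpr >= s.achieved_tpr and o.achieved_fpr <= s.achieved_fpr)
            and (o.achieved_tpr > s.achieved_tpr or o.achieved_fpr < s.achieved_fpr)
            for o in feasible)
        if not dominated:
            front.append(s)
    return front


def group_fi_summary(entries, rule: str = "high_specificity"):
    """Mean per-feature FI of qualifying front solutions, split by polarity.

    Parameters
    ----------
    entries : iterable of (OperatingPointSolution, WeightedDataset)
        Typically the Pareto-front solutions of several related drugs, each
        paired with the dataset it was fitted on.
    rule : {"high_specificity", "high_sensitivity"}
        high_specificity keeps solutions with achieved FPR < 0.10;
        high_sensitivity keeps solutions with achieved TPR > 0.90.

    Returns
    -------
    dict with "mutant" and "wildtype" arrays (length P): the mean FI a
    feature carries through positive literals (mutation indicative) and
    negated literals (wild-type indicative), averaged over all qualifying
    solutions.
    """
    if rule == "high_specificity":
        keep = lambda s: s.achieved_fpr is not None and s.achieved_fpr < 0.10
    elif rule == "high_sensitivity":
        keep = lambda s: s.achieved_tpr is not None and s.achieved_tpr > 0.90
    else:
        raise ValueError("rule must be 'high_specificity' or 'high_sensitivity'")

    qualifying = [(s, ds) for s, ds in entries if s.feasible and keep(s)]
    if not qualifying:
        log.warning("no solutions qualify under rule %r", rule)
        return {"mutant": np.array([]), "wildtype": np.array([]), "n_solutions": 0}

    p = qualifying[0][1].p
    mut = np.zeros((len(qualifying), p))
    wt = np.zeros((len(qualifying), p))
    for i, (s, ds) in enumerate(qualifying):
        fi = fi_vector(s.model, ds).scores
        pos_feats = {l.feature_index for d in s.model.disjuncts for l in d if not l.negated}
        neg_feats = {l.feature_index for d in s.model.disjuncts for l in d if l.negated}
        for f in pos_feats:
            mut[i, f] = fi[f]
        for f in neg_feats:
            wt[i, f] = fi[f]
    return {"mutant": mut.mean(axis=0), "wildtype": wt.mean(axis=0),
            "n_solutions": len(qualifying)}
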