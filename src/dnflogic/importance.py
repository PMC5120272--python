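"""Feature-importance (FI) scores for DNF models.

The importance of a feature in a fitted model is the increase in weighted
training error when the feature is neutralized out of the model: a literal
sharing its disjunct with others is forced satisfied (dropped from the
conjunction); a literal standing alone forces its disjunct false (the
disjunct is dropped).  Features absent from the model score 0.  On the
class-normalized weight scale FI scores lie in [0, 0.5].

Model-complexity-specific (MCS) FI averages per-model FI over the optimal
and pooled suboptimal models of one complexity, counting only the models
that contain the feature ("non-zero average").  Aggregated FI extends the
non-zero average over every complexity whose CV error does not exceed the
single-predictor (1, 1) CV error, including the models fitted on the CV
training folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .binarize import binarize
from .dataset import WeightedDataset, weighted_error
from .dnf import DNFModel, evaluate_dnf
from .ilp import SolveResult, fit_dnf

__all__ = ["FIVector", "fi_score", "fi_vector", "mcs_fi", "aggregated_fi",
           "threshold_robustness"]

log = logging.getLogger(__name__)


@dataclass
class FIVector:
    """Per-feature importance scores with their provenance."""

    scores: np.ndarray
    provenance: str                 # "single_model" | "mcs" | "aggregated"
    complexity: tuple | None = None


def _neutralize(model: DNFModel, feature: int) -> DNFModel | None:
    """Remove a feature from a model per the leave-out rule; None = constant false."""
    new_disjuncts = []
    for d in model.disjuncts:
        rest = [l for l in d if l.feature_index != feature]
        if len(rest) == len(d):
            new_disjuncts.append(d)        # feature not in this disjunct
        elif rest:
            new_disjuncts.append(rest)     # shared disjunct: literal forced satisfied
        # else: feature alone in the disjunct -> disjunct forced false, dropped
    if not new_disjuncts:
        return None
    return DNFModel(new_disjuncts)


def fi_score(model: DNFModel, feature: int, dataset: WeightedDataset) -> float:
    """Error increase when ``feature`` is neutralized out of ``model``."""
    if feature not in model.features:
        return 0.0
    base = weighted_error(evaluate_dnf(model, dataset.X), dataset.y, dataset.w)
    reduced = _neutralize(model, feature)
    if reduced is None:
        pred = np.zeros(dataset.n, dtype=np.int8)
    else:
        pred = evaluate_dnf(reduced, dataset.X)
    return weighted_error(pred, dataset.y, dataset.w) - base


def fi_vector(model: DNFModel, dataset: WeightedDataset) -> FIVector:
    """FI of every feature in the dataset for one model."""
    scores = np.zeros(dataset.p)
    for f in model.features:
        scores[f] = fi_score(model, f, dataset)
    return FIVector(scores=scores, provenance="single_model")


def _fi_with_mask(model: DNFModel, dataset: WeightedDataset):
    """(clipped FI vector, membership mask) for averaging across models.

    Suboptimal pool models can show a negative raw FI (neutralizing a
    feature may lower their error); importance is floored at 0 so averaged
    scores stay on the [0, 0.5] scale.  Membership is tracked separately so
    a present-but-zero feature still counts in the average.
    """
    scores = np.zeros(dataset.p)
    mask = np.zeros(dataset.p, dtype=bool)
    for f in model.features:
        scores[f] = max(fi_score(model, f, dataset), 0.0)
        mask[f] = True
    return scores, mask


def _masked_average(vectors, masks, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean over the vectors whose mask marks the feature present."""
    if not vectors:
        return np.zeros(p), np.zeros(p, dtype=bool)
    stack = np.stack(vectors)
    present = np.stack(masks)
    counts = present.sum(axis=0)
    sums = (stack * present).sum(axis=0)
    means = np.divide(sums, counts, out=np.zeros(p), where=counts > 0)
    return means, counts > 0


def mcs_fi(pool: SolveResult | list, dataset: WeightedDataset,
           complexity: tuple | None = None) -> FIVector:
    """Model-complexity-specific FI: non-zero average over a solution pool.

    ``pool`` may be a :class:`SolveResult` or a list of ``(model, dataset)``
    pairs (used for CV-fold models evaluated on their own training folds).
    """
    if isinstance(pool, SolveResult):
        pairs = [(m, dataset) for m, _ in pool.pool]
    else:
        pairs = pool
    pairs_fi = [_fi_with_mask(m, ds) for m, ds in pairs]
    scores, _ = _masked_average([s for s, _ in pairs_fi],
                                [mk for _, mk in pairs_fi], dataset.p)
    return FIVector(scores=scores, provenance="mcs", complexity=complexity)


def aggregated_fi(entries, baseline_cv_error: float, p: int) -> FIVector:
    """Non-zero average of MCS FI over complexities at or below the baseline.

    Parameters
    ----------
    entries : iterable of (complexity, cv_error, contributions)
        ``contributions`` is a list of ``(model, dataset)`` pairs: the
        full-data pool models paired with the full dataset, plus each CV
        training-fold model paired with its training-fold dataset.
    baseline_cv_error : float
        CV error of the single-predictor (1, 1) complexity; complexities
        with cv_error <= baseline contribute.
    p : int
        Number of features.
    """
    mcs_vectors, mcs_masks = [], []
    for complexity, cv_error, contributions in entries:
        if cv_error > baseline_cv_error + 1e-12:
            continue
        pairs_fi = [_fi_with_mask(m, ds) for m, ds in contributions]
        scores, mask = _masked_average([s for s, _ in pairs_fi],
                                       [mk for _, mk in pairs_fi], p)
        mcs_vectors.append(scores)
        mcs_masks.append(mask)
    scores, _ = _masked_average(mcs_vectors, mcs_masks, p)
    return FIVector(scores=scores, provenance="aggregated")


def panel_aggregated_fi(dataset: WeightedDataset, cv_report, full_fits: dict) -> FIVector:
    """Assemble :func:`aggregated_fi` inputs from a CV report and full-data fits.

    ``full_fits`` maps (K, M) to the full-data :class:`SolveResult` (with its
    solution pool); fold models come from the report, each evaluated on its
    own training fold.
    """
    entries = []
    baseline = cv_report.complexity_errors.get((1, 1))
    if baseline is None:
        raise ValueError("CV report lacks the (1, 1) baseline complexity")
    fold_ids = cv_report.fold_assignment
    for km, cv_err in cv_report.complexity_errors.items():
        contributions = [(m, dataset) for m, _ in full_fits[km].pool]
        for fold, res in enumerate(cv_report.fold_models[km]):
            if not res.feasible:
                continue
            train = np.flatnonzero(fold_ids != fold)
            contributions.append((res.best, dataset.subset(train)))
        entries.append((km, cv_err, contributions))
    return aggregated_fi(entries, baseline, dataset.p)


def _mean_pairwise_pearson(vectors: list[np.ndarray]) -> float:
    cors = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            a, b = vectors[i], vectors[j]
            if np.std(a) < 1e-15 or np.std(b) < 1e-15:
                warnings.warn("zero-variance FI vector: correlation undefined",
                              stacklevel=2)
                cors.append(np.nan)
            else:
                cors.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(cors))


def threshold_robustness(X, z, ci_low=None, ci_high=None,
                         t_values=(0.03, 0.05, 0.07), mode: str = "weighted",
                         complexity: tuple | None = None, *,
                         pool_size: int = 25, pool_gap: float = 0.1,
                         n_folds: int = 10, seed: int = 0,
                         time_limit_s: float = 3600.0, solver: str = "auto") -> float:
    """Mean pairwise Pearson correlation of MCS FI vectors across thresholds.

    For each binarization tail parameter t the response is re-thresholded,
    the dataset re-weighted (``mode`` selects sample-specific or uniform
    class weights), and the DNF re-fitted at a fixed complexity — the one
    selected by CV at the central t if ``complexity`` is None.  Robustness
    is the average correlation of the resulting FI vectors.
    """
    from .dataset import compute_weights
    from .select import cross_validate

    X = np.asarray(X)
    z = np.asarray(z, dtype=float)
    t_values = list(t_values)
    if len(t_values) < 2:
        raise ValueError("need at least 2 threshold values")

    if complexity is None:
        t_mid = t_values[len(t_values) // 2]
        res = binarize(z, ci_low, ci_high, t=t_mid, seed=seed)
        y, w = compute_weights(z, res.b, mode="weighted")
        ds = WeightedDataset(X=X, y=y, w=w, z=z)
        report = cross_validate(ds, n_folds=n_folds, seed=seed,
                                time_limit_s=time_limit_s, solver=solver)
        complexity = report.selected

    k, m = complexity
    vectors = []
    for t in t_values:
        res = binarize(z, ci_low, ci_high, t=t, seed=seed)
        y, w = compute_weights(z, res.b, mode=mode)
        ds = WeightedDataset(X=X, y=y, w=w, z=z)
        fit = fit_dnf(ds, k, m, pool_size=pool_size, pool_gap=pool_gap,
                      time_limit_s=time_limit_s, solver=solver)
        vectors.append(mcs_fi(fit, ds, complexity=(k, m)).scores)
    return _mean_pairwise_pearson(vectors)
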