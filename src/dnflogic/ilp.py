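"""Minimal-weighted-error DNF synthesis as an integer linear program.

Decision variables: for each disjunct slot k and feature p, binaries s_pk
(select the positive literal x_p) and s'_pk (select the negated literal).
Auxiliary variables t_nk (AND-gate output of disjunct k on sample n) and
y'_n (OR of the t_nk) are fully determined by the selection variables
through two-sided linear constraints, so they can be left continuous in
[0, 1] and still take integral values at any feasible point.  The objective
is the class-normalized weighted misclassification

    sum_{y_n=1} w_n (1 - y'_n)  +  sum_{y_n=0} w_n y'_n .

Samples with identical feature rows share their gate variables; their
weights are pooled into the objective and constraint coefficients, which
shrinks the program substantially on panels with many duplicate profiles.

Solutions near the optimum ("solution pool") are gathered by iterated
re-solving with no-good cuts that exclude every disjunct-slot permutation
of each model already found.

Solved with the HiGHS branch-and-cut backend of :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .dataset import WeightedDataset, weighted_error
from .dnf import DNFModel, Literal, evaluate_dnf

__all__ = ["SolveResult", "solve_ilp", "enumerate_bruteforce", "fit_dnf",
           "enumeration_size", "DNFClassifier", "COMPLEXITY_CAP"]

#: K*M above this triggers a search-space warning (not an error).
COMPLEXITY_CAP = 4

_OBJ_TOL = 1e-9


@dataclass
class SolveResult:
    """Outcome of one DNF inference.

    ``pool`` contains the optimal model first, then distinct suboptimal
    models in order of increasing error, all within ``pool_gap`` of the
    optimum (when status is "optimal").
    """

    best: DNFModel | None
    best_error: float
    pool: list = field(default_factory=list)  # [(DNFModel, error), ...]
    status: str = "optimal"                   # optimal|feasible|infeasible|time_limit
    gap: float = 0.0

    @property
    def feasible(self) -> bool:
        return self.best is not None

    def to_dict(self, feature_names=None) -> dict:
        from .dnf import format_dnf
        def render(m):
            if feature_names is None:
                return repr(m)
            return format_dnf(m, feature_names)
        return {
            "status": self.status,
            "error": self.best_error if self.feasible else None,
            "gap": self.gap,
            "model": render(self.best) if self.feasible else None,
            "pool": [{"model": render(m), "error": e} for m, e in self.pool],
        }


def _aggregate_rows(X, y, w):
    """Collapse duplicate feature rows; pool class weights and counts per row."""
    Xu, inverse = np.unique(np.asarray(X, dtype=np.int8), axis=0, return_inverse=True)
    r = Xu.shape[0]
    pw = np.zeros(r)   # pooled weight of positives per unique row
    nw = np.zeros(r)   # pooled weight of negatives
    npos = np.zeros(r, dtype=int)
    nneg = np.zeros(r, dtype=int)
    y = np.asarray(y)
    w = np.asarray(w, dtype=float)
    np.add.at(pw, inverse[y == 1], w[y == 1])
    np.add.at(nw, inverse[y == 0], w[y == 0])
    np.add.at(npos, inverse[y == 1], 1)
    np.add.at(nneg, inverse[y == 0], 1)
    return Xu, pw, nw, npos, nneg


class _Program:
    """Sparse MILP under construction; variable layout documented in build()."""

    def __init__(self):
        self.rows, self.cols, self.vals = [], [], []
        self.lb, self.ub = [], []
        self.nrow = 0

    def add(self, cols, vals, lo, hi):
        self.rows.extend([self.nrow] * len(cols))
        self.cols.extend(cols)
        self.vals.extend(vals)
        self.lb.append(lo)
        self.ub.append(hi)
        self.nrow += 1

    def constraint(self, nvar):
        A = sparse.coo_matrix(
            (self.vals, (self.rows, self.cols)), shape=(self.nrow, nvar)
        ).tocsc()
        return LinearConstraint(A, np.array(self.lb), np.array(self.ub))


def _build(Xu, pw, nw, npos, nneg, K, M, tpr_min, tnr_min, continuous, cuts):
    """Assemble objective, constraints and integrality for the DNF MILP.

    Variable layout: s[p,k] at k*P+p; s'[p,k] at PK+k*P+p;
    t[r,k] at 2PK+k*R+r; y'[r] at 2PK+RK+r.
    """
    R, P = Xu.shape
    n_sel = P * K
    t0 = 2 * n_sel
    yp0 = t0 + R * K
    nvar = yp0 + R

    def s(p, k):
        return k * P + p

    def sneg(p, k):
        return n_sel + k * P + p

    def t(r, k):
        return t0 + k * R + r

    def yp(r):
        return yp0 + r

    prog = _Program()

    for k in range(K):
        # a feature and its negation never share a disjunct
        for p in range(P):
            prog.add([s(p, k), sneg(p, k)], [1, 1], -np.inf, 1)
        # between 1 and M literals per disjunct (empty AND would be constant true)
        allsel = [s(p, k) for p in range(P)] + [sneg(p, k) for p in range(P)]
        prog.add(allsel, [1] * (2 * P), 1, M)

    # AND gates: t_rk = 1 iff every selected literal holds on row r
    for k in range(K):
        for r in range(R):
            violated = []  # selection vars whose literal row r fails
            for p in range(P):
                if Xu[r, p] == 0:
                    violated.append(s(p, k))
                else:
                    violated.append(sneg(p, k))
            for v in violated:
                prog.add([t(r, k), v], [1, 1], -np.inf, 1)
            prog.add([t(r, k)] + violated, [1] + [1] * len(violated), 1, np.inf)

    # OR gate: y'_r = max_k t_rk
    for r in range(R):
        for k in range(K):
            prog.add([t(r, k), yp(r)], [1, -1], -np.inf, 0)
        prog.add([yp(r)] + [t(r, k) for k in range(K)],
                 [1] + [-1] * K, -np.inf, 0)

    # operating-point constraints
    if tpr_min is not None and tpr_min > 0:
        if continuous:
            prog.add([yp(r) for r in range(R)], list(pw), 0.5 * tpr_min, np.inf)
        else:
            tot = npos.sum()
            prog.add([yp(r) for r in range(R)], list(npos.astype(float)),
                     tpr_min * tot, np.inf)
    if tnr_min is not None and tnr_min > 0:
        if continuous:
            prog.add([yp(r) for r in range(R)], list(nw),
                     -np.inf, 0.5 * (1.0 - tnr_min))
        else:
            tot = nneg.sum()
            prog.add([yp(r) for r in range(R)], list(nneg.astype(float)),
                     -np.inf, (1.0 - tnr_min) * tot)

    # no-good cuts excluding previously found selection assignments
    for assignment in cuts:
        cols, vals = [], []
        rhs = 1
        for idx in range(2 * n_sel):
            if assignment[idx]:
                cols.append(idx)
                vals.append(-1)
                rhs -= 1
            else:
                cols.append(idx)
                vals.append(1)
        prog.add(cols, vals, rhs, np.inf)

    c = np.zeros(nvar)
    c[yp0:] = nw - pw
    const = pw.sum()

    integrality = np.zeros(nvar)
    integrality[: 2 * n_sel] = 1
    return c, const, prog.constraint(nvar), integrality, nvar


def _extract_model(x, P, K):
    """Read the selection variables of a MILP solution into a DNFModel."""
    disjuncts = []
    for k in range(K):
        lits = []
        for p in range(P):
            if x[k * P + p] > 0.5:
                lits.append(Literal(p, False))
            if x[P * K + k * P + p] > 0.5:
                lits.append(Literal(p, True))
        disjuncts.append(lits)
    return DNFModel(disjuncts)


def _selection_vector(model: DNFModel, P: int, K: int, perm) -> tuple:
    """0/1 tuple over (s, s') for the model with disjunct slots permuted by perm."""
    vec = [0] * (2 * P * K)
    for slot, d_idx in enumerate(perm):
        for lit in model.disjuncts[d_idx]:
            if lit.negated:
                vec[P * K + slot * P + lit.feature_index] = 1
            else:
                vec[slot * P + lit.feature_index] = 1
    return tuple(vec)


def solve_ilp(dataset: WeightedDataset, K: int, M: int, *,
              tpr_min: float | None = None, tnr_min: float | None = None,
              continuous_constraints: bool = False,
              time_limit_s: float = 3600.0,
              pool_size: int = 1, pool_gap: float = 0.1,
              mip_gap: float = 1e-6) -> SolveResult:
    """Infer the minimal-weighted-error (K, M)-DNF for a weighted dataset.

    Parameters
    ----------
    dataset : WeightedDataset
    K, M : int
        Number of disjuncts / max literals per disjunct.
    tpr_min, tnr_min : float, optional
        Lower bounds on sensitivity and specificity.  By default these count
        samples; with ``continuous_constraints`` they bound the weighted
        (continuous) rates instead.
    pool_size : int
        Collect up to this many distinct models within ``pool_gap`` relative
        error of the optimum (1 = optimal model only).
    time_limit_s : float
        Per-solve wall-clock limit handed to the solver.

    Returns
    -------
    SolveResult
    """
    if K < 1 or M < 1:
        raise ValueError("K and M must be >= 1")
    if K * M > COMPLEXITY_CAP:
        warnings.warn(
            f"K*M = {K * M} exceeds the usual complexity cap {COMPLEXITY_CAP}; "
            "the search space grows combinatorially", stacklevel=2)
    Xu, pw, nw, npos, nneg = _aggregate_rows(dataset.X, dataset.y, dataset.w)
    P = Xu.shape[1]

    cuts: list[tuple] = []
    pool: list[tuple[DNFModel, float]] = []
    seen: set = set()
    best_error = None
    status = "optimal"
    gap = 0.0

    while len(pool) < pool_size:
        c, const, lin, integrality, nvar = _build(
            Xu, pw, nw, npos, nneg, K, M, tpr_min, tnr_min,
            continuous_constraints, cuts)
        res = milp(c=c, constraints=lin, integrality=integrality,
                   bounds=Bounds(0, 1),
                   options={"time_limit": time_limit_s, "mip_rel_gap": mip_gap,
                            "disp": False})
        if res.status == 2 or res.x is None:  # infeasible (or no incumbent)
            if best_error is None:
                st = "infeasible" if res.status == 2 else "time_limit"
                return SolveResult(best=None, best_error=np.inf, pool=[],
                                   status=st, gap=np.inf)
            break
        model = _extract_model(res.x, P, K)
        error = float(const + c @ res.x)
        # re-evaluate through the logic layer; guards against solver tolerance
        error_check = weighted_error(evaluate_dnf(model, dataset.X),
                                     dataset.y, dataset.w)
        if abs(error - error_check) > 1e-6:
            error = error_check
        if best_error is None:
            best_error = error
            if res.status == 1:
                status = "time_limit"
            gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
        elif error > best_error * (1.0 + pool_gap) + _OBJ_TOL:
            break
        key = model.canonical()
        if key not in seen:
            seen.add(key)
            pool.append((model, error))
        # exclude this assignment and all slot permutations of it
        for perm in itertools.permutations(range(K)):
            cuts.append(_selection_vector(model, P, K, perm))
        cuts = list(dict.fromkeys(cuts))
        if len(pool) >= pool_size:
            break

    pool.sort(key=lambda me: me[1])
    return SolveResult(best=pool[0][0], best_error=pool[0][1], pool=pool,
                       status=status, gap=gap)


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle


def _candidate_disjuncts(P: int, M: int):
    """All non-contradictory literal sets of size 1..M over P features."""
    literals = [Literal(p, neg) for p in range(P) for neg in (False, True)]
    out = []
    for m in range(1, M + 1):
        for combo in itertools.combinations(literals, m):
            feats_pos = {l.feature_index for l in combo if not l.negated}
            feats_neg = {l.feature_index for l in combo if l.negated}
            if feats_pos & feats_neg:
                continue
            out.append(frozenset(combo))
    return out


def enumeration_size(P: int, K: int, M: int) -> int:
    """Number of candidate DNFs an exhaustive search would evaluate."""
    from math import comb
    d = sum(comb(P, m) * 2 ** m for m in range(1, M + 1))
    return comb(d + K - 1, K)


def enumerate_bruteforce(dataset: WeightedDataset, K: int, M: int, *,
                         tpr_min: float | None = None,
                         tnr_min: float | None = None,
                         continuous_constraints: bool = False,
                         pool_size: int = 1, pool_gap: float = 0.1,
                         max_candidates: int = 10_000_000) -> SolveResult:
    """Exact DNF optimum by exhaustive enumeration (test oracle for small P).

    Enumerates every unordered combination (with repetition) of K candidate
    disjuncts, evaluates each model's weighted error, filters by the
    operating-point constraints, and returns the minimum.  Independent of
    the ILP code path except for the shared model/error primitives.  With
    ``pool_size`` > 1 the lowest-error distinct models within ``pool_gap``
    relative error of the optimum are collected as well.
    """
    disjuncts = _candidate_disjuncts(dataset.p, M)
    d = len(disjuncts)
    from math import comb
    n_models = comb(d + K - 1, K)
    if n_models > max_candidates:
        raise ValueError(
            f"{n_models} candidate models exceed the enumeration cap; "
            "use the ILP solver instead")

    X = dataset.X
    y = np.asarray(dataset.y)
    w = np.asarray(dataset.w, dtype=float)
    pos = y == 1
    neg = ~pos
    n_pos = int(pos.sum())
    n_neg = int(neg.sum())

    clause = np.empty((d, dataset.n), dtype=bool)
    for i, dj in enumerate(disjuncts):
        v = np.ones(dataset.n, dtype=bool)
        for lit in dj:
            v &= lit.evaluate(X)
        clause[i] = v

    # per-clause statistics shared by the vectorized paths
    Cf = clause.astype(np.float64)
    base = w[pos].sum()                       # error of the all-negative predictor
    delta = np.where(neg, w, -w)              # error change when a sample is predicted 1
    s_err = Cf @ delta                        # per-clause error offset
    tp_c = clause[:, pos].sum(axis=1).astype(float)
    tn_loss_c = clause[:, neg].sum(axis=1).astype(float)   # false positives
    tpw_c = Cf[:, pos] @ w[pos]
    fpw_c = Cf[:, neg] @ w[neg]

    def _feasible_mask(tp, fp, tpw, fpw):
        ok = np.ones(np.shape(tp), dtype=bool)
        if tpr_min is not None and tpr_min > 0:
            if continuous_constraints:
                ok &= tpw >= 0.5 * tpr_min - 1e-12
            else:
                ok &= tp >= tpr_min * n_pos - 1e-12
        if tnr_min is not None and tnr_min > 0:
            if continuous_constraints:
                ok &= (0.5 - fpw) >= 0.5 * tnr_min - 1e-12
            else:
                ok &= (n_neg - fp) >= tnr_min * n_neg - 1e-12
        return ok

    if K == 1:
        errors = base + s_err
        ok = _feasible_mask(tp_c, tn_loss_c, tpw_c, fpw_c)
        combos = [(i,) for i in range(d)]
        errors_list = errors
    elif K == 2:
        # OR of two clauses via inclusion-exclusion on the AND overlap
        ii, jj = np.triu_indices(d)
        T_err = (Cf * delta) @ Cf.T
        errors_list = base + s_err[ii] + s_err[jj] - T_err[ii, jj]
        tp2 = Cf[:, pos] @ Cf[:, pos].T
        fp2 = Cf[:, neg] @ Cf[:, neg].T
        tpw2 = (Cf[:, pos] * w[pos]) @ Cf[:, pos].T
        fpw2 = (Cf[:, neg] * w[neg]) @ Cf[:, neg].T
        ok = _feasible_mask(tp_c[ii] + tp_c[jj] - tp2[ii, jj],
                            tn_loss_c[ii] + tn_loss_c[jj] - fp2[ii, jj],
                            tpw_c[ii] + tpw_c[jj] - tpw2[ii, jj],
                            fpw_c[ii] + fpw_c[jj] - fpw2[ii, jj])
        combos = list(zip(ii.tolist(), jj.tolist()))
    else:
        unconstrained = not ((tpr_min is not None and tpr_min > 0)
                             or (tnr_min is not None and tnr_min > 0))
        combos, errs, oks = [], [], []
        for combo in itertools.combinations_with_replacement(range(d), K):
            yp = clause[combo[0]].copy()
            for i in combo[1:]:
                yp |= clause[i]
            err = base + delta[yp].sum()
            combos.append(combo)
            errs.append(err)
            if not unconstrained:
                oks.append(bool(_feasible_mask(
                    float(yp[pos].sum()), float(yp[neg].sum()),
                    w[pos & yp].sum(), w[neg & yp].sum())))
        errors_list = np.asarray(errs)
        ok = (np.ones(len(combos), dtype=bool) if unconstrained
              else np.asarray(oks, dtype=bool))

    if not ok.any():
        return SolveResult(best=None, best_error=np.inf, pool=[],
                           status="infeasible", gap=np.inf)
    idx_ok = np.flatnonzero(ok)
    order = idx_ok[np.argsort(errors_list[idx_ok], kind="stable")]
    best_err = float(errors_list[order[0]])
    feasible = [(float(errors_list[i]), combos[i]) for i in
                order[: max(pool_size * 32, 64)]]
    pool: list[tuple[DNFModel, float]] = []
    seen: set = set()
    for err, combo in feasible:
        if err > best_err * (1.0 + pool_gap) + _OBJ_TOL and pool:
            break
        model = DNFModel([disjuncts[i] for i in combo])
        key = model.canonical()
        if key in seen:
            continue
        seen.add(key)
        pool.append((model, err))
        if len(pool) >= max(pool_size, 1):
            break
    return SolveResult(best=pool[0][0], best_error=pool[0][1],
                       pool=pool, status="optimal")


#: below this many candidate models, exhaustive search beats the MILP solver
_AUTO_ENUMERATION_CAP = 100_000


def fit_dnf(dataset: WeightedDataset, K: int, M: int, *,
            tpr_min: float | None = None, tnr_min: float | None = None,
            continuous_constraints: bool = False,
            time_limit_s: float = 3600.0,
            pool_size: int = 1, pool_gap: float = 0.1,
            mip_gap: float = 1e-6, solver: str = "auto") -> SolveResult:
    """Exact (K, M)-DNF inference, dispatching to the cheaper exact route.

    Both routes return the global optimum; for small feature counts the
    exhaustive search is faster than building and solving the MILP, so
    ``solver="auto"`` enumerates when the candidate-model count is below
    100k and uses the ILP otherwise.  ``solver="ilp"`` / ``"enumerate"``
    force a route.
    """
    if solver == "auto":
        solver = ("enumerate"
                  if enumeration_size(dataset.p, K, M) <= _AUTO_ENUMERATION_CAP
                  else "ilp")
    if solver == "enumerate":
        return enumerate_bruteforce(
            dataset, K, M, tpr_min=tpr_min, tnr_min=tnr_min,
            continuous_constraints=continuous_constraints,
            pool_size=pool_size, pool_gap=pool_gap)
    if solver == "ilp":
        return solve_ilp(
            dataset, K, M, tpr_min=tpr_min, tnr_min=tnr_min,
            continuous_constraints=continuous_constraints,
            time_limit_s=time_limit_s, pool_size=pool_size,
            pool_gap=pool_gap, mip_gap=mip_gap)
    raise ValueError(f"solver must be 'auto', 'ilp' or 'enumerate', got {solver!r}")


# ---------------------------------------------------------------------------
# estimator interface


class DNFClassifier:
    """Scikit-learn style classifier inferring a (K, M)-DNF rule by ILP.

    Parameters
    ----------
    k, m : int
        DNF complexity: number of disjuncts, max literals per disjunct.
    tpr_min, tnr_min : float, optional
        Minimum sensitivity / specificity enforced as hard ILP constraints.
    continuous_constraints : bool
        Enforce the weighted (continuous) versions of the rate constraints.
    pool_size, pool_gap : int, float
        Near-optimal solution pool: up to ``pool_size`` distinct models within
        relative gap ``pool_gap``.
    time_limit_s : float
        Solver wall-clock limit per ILP.

    Attributes (after ``fit``)
    ----------
    model_ : DNFModel
    error_ : float           weighted training error
    pool_ : list[(DNFModel, float)]
    status_ : str
    gap_ : float
    """

    def __init__(self, k: int = 1, m: int = 1, *, tpr_min: float | None = None,
                 tnr_min: float | None = None, continuous_constraints: bool = False,
                 pool_size: int = 1, pool_gap: float = 0.1,
                 time_limit_s: float = 3600.0, mip_gap: float = 1e-6,
                 solver: str = "auto"):
        self.k = k
        self.m = m
        self.tpr_min = tpr_min
        self.tnr_min = tnr_min
        self.continuous_constraints = continuous_constraints
        self.pool_size = pool_size
        self.pool_gap = pool_gap
        self.time_limit_s = time_limit_s
        self.mip_gap = mip_gap
        self.solver = solver

    _param_names = ("k", "m", "tpr_min", "tnr_min", "continuous_constraints",
                    "pool_size", "pool_gap", "time_limit_s", "mip_gap", "solver")

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "DNFClassifier":
        for kk, v in params.items():
            if kk not in self._param_names:
                raise ValueError(f"invalid parameter {kk!r}")
            setattr(self, kk, v)
        return self

    def _as_dataset(self, X, y, sample_weight) -> WeightedDataset:
        if isinstance(X, WeightedDataset):
            return X
        X = np.asarray(X)
        y = np.asarray(y)
        if sample_weight is None:
            from .dataset import CLASS_WEIGHT
            sample_weight = np.where(y == 1, CLASS_WEIGHT / max(int((y == 1).sum()), 1),
                                     CLASS_WEIGHT / max(int((y == 0).sum()), 1))
        else:
            from .dataset import renormalize_weights
            sample_weight = renormalize_weights(y, sample_weight)
        return WeightedDataset(X=X, y=y, w=np.asarray(sample_weight, dtype=float))

    def fit(self, X, y=None, sample_weight=None) -> "DNFClassifier":
        ds = self._as_dataset(X, y, sample_weight)
        res = fit_dnf(
            ds, self.k, self.m, tpr_min=self.tpr_min, tnr_min=self.tnr_min,
            continuous_constraints=self.continuous_constraints,
            time_limit_s=self.time_limit_s, pool_size=self.pool_size,
            pool_gap=self.pool_gap, mip_gap=self.mip_gap, solver=self.solver)
        self.n_features_in_ = ds.p
        self.result_ = res
        self.status_ = res.status
        self.gap_ = res.gap
        if not res.feasible:
            self.model_ = None
            self.error_ = np.inf
            self.pool_ = []
            return self
        self.model_ = res.best
        self.error_ = res.best_error
        self.pool_ = res.pool
        return self

    def predict(self, X) -> np.ndarray:
        if getattr(self, "model_", None) is None:
            raise RuntimeError("classifier is not fitted or the fit was infeasible")
        if isinstance(X, WeightedDataset):
            X = X.X
        return evaluate_dnf(self.model_, np.asarray(X))

    def score(self, X, y, sample_weight=None) -> float:
        """1 minus the class-normalized weighted error (higher is better)."""
        ds = self._as_dataset(X, y, sample_weight)
        return 1.0 - weighted_error(self.predict(ds.X), ds.y, ds.w)
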