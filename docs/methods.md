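# Methods

## Model

A DNF model Θ over P binary features is an OR of K disjuncts, each a
conjunction of 1..M literals (a feature or its negation; a disjunct never
contains both polarities of one feature, and never is empty — an empty
conjunction would be constant-true, so smaller effective K is reached by
fitting the smaller complexity instead).  Θ predicts `y′_n = 1` iff some
disjunct is satisfied on row n.  The fitted objective is the weighted
misclassification `Σ w_n |y′_n − y_n|` with per-class weight normalization
(each class sums to 0.5), so errors live on [0, 1], random prediction has
expectation exactly 0.5, and a model and its complemented prediction have
errors summing to 1.

## Binarization of the continuous response

Four steps, controlled by the tail parameter `t ∈ (0, 1)`, default 0.05:

1. **Upsampling.** Each measurement contributes 1000 draws from
   `N(value, sd²)` with `sd` the mean distance to its CI bounds.  Missing
   or degenerate CIs fall back to a floor of 0.1 response units
   (configurable) so no kernel collapses.
2. **Density.** Fixed-bandwidth (0.5) Gaussian KDE, evaluated by FFT on a
   512-point uniform grid spanning the cloud, renormalized to unit
   trapezoidal integral.  Derivatives are central finite differences;
   zero crossings are located by sign change with linear interpolation.
3. **Resistant population.** The density mode μ (grid argmax) is the
   resistant mean.  The divide θ is the largest stationary point below μ
   (rule i), else the largest inflection with `f″ = 0, f‴ > 0` (rule ii),
   else the range minimum (rule iii); rules i–ii additionally require
   `f(θ) < 0.8·f(μ)` and at least `mass_min` (default 0.01, configurable)
   of the density mass left of θ — there must be some population to split
   off.  σ is the median distance from μ of cloud points in [θ, μ],
   floored at 1e−3 to keep the quantile finite.
4. **Threshold.** `b = μ + σ·Φ⁻¹(t)`.  `z < b` is sensitive; ties are
   resistant.  `b` is strictly increasing in `t`, and shifting all inputs
   by a constant shifts `b` by the same constant (up to grid resolution).

Weighted mode sets `w_n ∝ |z_n − b|` per class; `binary_only` mode uses
uniform within-class weights `1/(2·N_class)` so both modes share the same
error scale.  A sample exactly at the threshold keeps weight 0 (it cannot
affect the objective) and counts as resistant.

## Exact inference

Two exact routes, used interchangeably:

* **ILP.** Binary selection variables `s_pk, s′_pk` choose literals per
  disjunct (constraints: `s + s′ ≤ 1`, `1 ≤ Σ ≤ M`); gate variables
  `t_nk` (AND) and `y′_n` (OR) are linearized two-sidedly
  (`t_nk ≤ 1 − s` for each violated selected literal;
  `t_nk ≥ 1 − Σ violated`; `y′ ≥ t_k`; `y′ ≤ Σ t_k`), which pins them to
  their logical values at any feasible point, so they stay continuous in
  [0, 1] without harming exactness.  Samples with identical feature rows
  share gates, with weights pooled into objective/constraint
  coefficients — a large reduction on sparse mutation panels.  Solved by
  HiGHS via `scipy.optimize.milp` (relative MIP gap 1e−6, objective
  comparisons at 1e−9, default wall limit 3600 s; on timeout the
  incumbent is returned with status `time_limit`).
* **Enumeration.** All unordered K-combinations (with repetition) of
  admissible disjuncts, evaluated vectorially (K = 1 by one matrix
  product; K = 2 by inclusion–exclusion on the pairwise AND-overlap
  matrix).  It is the test oracle for the ILP and, below 100k candidate
  models, also the faster production route (`solver="auto"`).

Operating-point constraints are hard lower bounds: count-based
(`Σ_{y=1} y′ ≥ TPR_min·N⁺`, `Σ_{y=0}(1−y′) ≥ TNR_min·N⁻`) or, optionally,
weighted ("continuous") versions with 0.5 replacing the class counts.
Infeasibility is data, reported as such.

The near-optimal pool collects up to `pool_size` (default 25) distinct
models within relative gap `pool_gap` (default 0.1) of the optimum.  The
ILP route re-solves with no-good cuts excluding every disjunct-slot
permutation of each found model (K ≤ 4 means ≤ 24 cuts per model), so the
pool is permutation-deduplicated; the enumeration route reads the pool off
its sorted error list.  Pool membership can differ between routes when
errors tie, but pool errors agree.

## Complexity selection and significance

Complexity grid: all (K, M) with `K·M ≤ 4` (eight settings).  Stratified
10-fold CV (scikit-learn `StratifiedKFold`, shuffled, seeded; folds reduce
to the minority-class size when needed).  Fold training and test weights
are re-normalized per class to 0.5 so every fold error lives on the same
[0, 1] scale; the per-complexity CV error is the mean over folds, and ties
select the lowest `K·M`, then the lowest K (parsimony).  Under
operating-point constraints an infeasible fold fit contributes the
worst-case error 1.0, and a complexity whose full-data constrained fit is
infeasible is excluded; a grid point with no feasible complexity is
flagged infeasible.

Significance: the out-of-fold prediction vector of the selected
complexity, assembled over all samples, is permuted uniformly
(vectorized: only the positions of the predicted ones matter), giving a
null with mean exactly 0.5.  The p-value is the add-one empirical
left-tail probability; below 10/n_perm it is refined by a generalized
Pareto fit (MLE, location 0) to the exceedances under the 250th-smallest
null value, falling back to the empirical value when the observation lies
outside the fitted support or the fit degenerates.  Panel-wide q-values
are Benjamini–Hochberg (parameter-free and conservative; the FDR method is
configurable).  A model is called significant at p < 0.01 and q < 0.01.

Known property: because the pipeline selects the best of ~2P candidate
literals (and eight complexities) on the same dataset before testing,
the permutation p-value of the *selected* model is anti-conservative
under a global null — a dataset-level chance feature–label correlation
survives into every CV fold and is invisible to permutations of the
final prediction vector.  The acceptance suite measures this directly
(~6% of 100 null drugs called significant at the nominal 1%); it is a
property of the procedure, not of the implementation, and is the reason
the type-I acceptance check fails.  Interpret panel-wide significance
counts accordingly.

## Feature importance

`fi(a)` = error of the model with feature a neutralized minus the model's
error, computed on the model's own training data (full fit or training
fold).  Neutralization: a literal sharing its disjunct is dropped (forced
satisfied); a lone literal drops its disjunct (forced false); a model with
no disjuncts left predicts all-negative.  Negated literals follow the same
rule.  Features absent from a model score 0; for a training-optimal model
`fi ≥ 0`, and all scores are ≤ 0.5.  Suboptimal pool models can show
negative raw differences; these are floored at 0 when averaging, with
model membership tracked explicitly so a present-but-zero feature still
counts in the mean.

MCS FI: per-feature mean over the models of one complexity's pool (and,
where used, its fold models) that contain the feature.  Aggregated FI: the
same membership-aware mean of MCS vectors over every complexity whose CV
error is at or below the (1, 1) baseline, including CV-fold models fitted
with their fold-training weights.  Threshold robustness is the mean
pairwise Pearson correlation (over all P features, zeros included) of MCS
FI vectors refitted at `t ∈ {0.03, 0.05, 0.07}` at the complexity selected
at `t = 0.05` with weighted mode; a zero-variance FI vector yields NaN
with a warning.

Caveat observed in the recovery experiments: aggregated FI always includes
the (1, 1) baseline pool, where any pooled single-literal model f scores
`fi = 0.5 − err(f)` (large when the baseline is weak), while an individual
literal inside a good M-literal conjunction has a small marginal score
(removing it leaves an (M−1)-conjunction that is nearly as good).  For
planted high-order conjunctions this lets pooled non-planted features
outrank planted literals — the reason the planted-top-FI acceptance check
fails for the pure-conjunction complexities (1, 2), (1, 3) and (1, 4)
(increasingly with M) while CV-error recovery itself passes everywhere.

## ROC probing

The (TPR_min, TNR_min) lattice `{0, 0.05, …, 1}²` (441 points at the
default step) is swept with constrained fits; each point selects its
complexity by constrained CV.  Infeasibility is monotone in the bounds and
is used to prune the sweep.  Achieved TPR/FPR are reported from the
full-data constrained fit (the CV error is stored alongside).  The Pareto
front keeps solutions not dominated in (higher TPR, lower FPR), ties
included.  Group FI summaries average per-solution FI over qualifying
front solutions (FPR < 0.10 for high-specificity, TPR > 0.90 for
high-sensitivity), split by literal polarity into mutation-indicative and
wild-type-indicative contributions.

## Synthetic panels

The generator emulates one drug of a cell-line panel: `X` is i.i.d.
Bernoulli per feature (default frequency 0.10, the 5–15% range typical of
cancer gene mutations), the sensitive component is a planted DNF of the
mutations (or, for null drugs, an independent coin with a given sensitive
fraction), flipped with a label-noise probability (default 0.02), and the
response is drawn from `N(−1, 1)` for sensitive and `N(3, 1)` for
resistant samples (log-µM units; 4 sd separation), with ±0.3 CIs and an
optional missing-data mask (missing responses are dropped, never imputed).

Defaults and experiment conditions, chosen once as realistic panel
conditions:

* Recovery experiments: n = 300 per drug, 20 seeds per complexity; a
  planted (K, M) model uses K disjoint M-literal positive conjunctions
  with per-feature frequency `(0.10/K)^{1/M}` so the planted prevalence
  stays near 10% for every complexity.
* Null panels: 100 drugs, sensitive fraction 0.10, permutation count 10⁴.
* Robustness comparison: 20 drugs with overlapping components
  (sensitive mean 1.0, i.e. 2 sd separation) and 5% label noise — with a
  4-sd gap virtually no samples sit near the threshold, so both weighting
  modes would be trivially robust and the comparison uninformative;
  overlap is also what real panels show.  Ties count against the
  weighted mode.
* The acceptance script scales some of these down (24 solver-oracle
  instances, 40 null drugs, 10 recovery/robustness drugs, a 0.25-step ROC
  grid over two complexities) to keep a full from-scratch run at a few
  minutes on one CPU.

What the synthetic panels do **not** emulate: linkage/correlation between
mutation features, tumor-type population structure, heteroscedastic or
heavy-tailed IC50 noise, outlier samples (which the weighting is known to
amplify), and measurement missingness correlated with response.  Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the generator's assumptions, not performance on real
panels.

## Numerical choices and degenerate inputs

* Objective/error comparisons at 1e−9; solver integrality/optimality at
  1e−6; class-weight sums validated to 1e−9.
* Single-class data refuse to fit (undefined problem); a class with all
  samples exactly at the threshold falls back to uniform weights for that
  class.
* KDE on identical points returns the single kernel bump; enumeration
  refuses above a 10⁷-candidate cap and points to the ILP.
* Empty permutation null raises; p-values are always > 0.

## Limitations

Beyond the two documented acceptance failures (selection-induced type-I
inflation; aggregated-FI dilution for high-order conjunctions): solve time
grows combinatorially in K·M and with feature correlation; correlated
features spread importance arbitrarily among themselves; outliers in the
continuous response dominate the weights (detect and remove them first);
and the method presumes the response is meaningfully bimodal — on unimodal
data rule iii places the divide at the range minimum and the "sensitive"
class is just the low tail.
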