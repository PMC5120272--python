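"""Threshold selection for continuous dose-response values.

Drug-response panels typically show a resistant majority mode and a sensitive
minority tail at lower values.  The threshold b separating the classes is
found by a four-step heuristic:

1. *Upsampling* — each measurement with its confidence interval defines a
   normal distribution (mean = value, sd = mean distance of value to CI
   bounds); a fixed number of draws per sample builds a point cloud.
2. *Density estimation* — Gaussian-kernel density on the cloud (fixed
   bandwidth), normalized to unit mass over the cloud's range.
3. *Resistant-population model* — the density mode mu is the resistant mean;
   a divide theta left of mu is found from stationary points (rule i),
   inflections (rule ii) or the range minimum (rule iii); the resistant sd
   sigma is the median distance from mu of cloud points in [theta, mu].
4. *Threshold* — b is the t-quantile of Normal(mu, sigma^2); samples with
   value < b are called sensitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm
from statsmodels.nonparametric.kde import KDEUnivariate

__all__ = [
    "BinarizationResult", "ResponseBinarizer", "binarize",
    "upsample", "estimate_density", "find_theta",
    "fit_resistant_population", "threshold_from_tail",
]


@dataclass
class BinarizationResult:
    """Threshold plus the diagnostics of the heuristic that produced it."""

    b: float
    t: float
    mu: float
    sigma: float
    theta: float
    rule_used: str          # "i" | "ii" | "iii"
    grid: np.ndarray
    f: np.ndarray

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("grid")
        d.pop("f")
        return json.dumps(d, indent=2)


def upsample(values, ci_low=None, ci_high=None, draws_per_sample: int = 1000,
             seed: int = 0, sd_floor: float = 0.1) -> np.ndarray:
    """Draw ``draws_per_sample`` points per measurement from its CI-derived normal.

    The per-sample sd is the mean of |value - ci_low| and |ci_high - value|;
    missing or degenerate CIs fall back to ``sd_floor`` (response units).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if ci_low is None or ci_high is None:
        sd = np.full(n, sd_floor)
    else:
        ci_low = np.asarray(ci_low, dtype=float)
        ci_high = np.asarray(ci_high, dtype=float)
        if len(ci_low) != n or len(ci_high) != n:
            raise ValueError("CI vectors must match values in length")
        sd = 0.5 * (np.abs(values - ci_low) + np.abs(ci_high - values))
        sd = np.where(np.isfinite(sd), sd, sd_floor)
        sd = np.maximum(sd, sd_floor)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=values[:, None], scale=sd[:, None],
                       size=(n, draws_per_sample))
    return draws.ravel()


def estimate_density(points, bandwidth: float = 0.5, grid_size: int = 512):
    """Fixed-bandwidth Gaussian KDE on a uniform grid over the data range.

    Returns (grid, f) with f >= 0 and unit trapezoidal integral.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points for density estimation")
    lo, hi = points.min(), points.max()
    if hi - lo < 1e-12:
        # all mass at one point: a single kernel bump
        lo, hi = lo - 4 * bandwidth, hi + 4 * bandwidth
        grid = np.linspace(lo, hi, grid_size)
        f = norm.pdf(grid, loc=points[0], scale=bandwidth)
    else:
        kde = KDEUnivariate(points)
        kde.fit(kernel="gau", bw=bandwidth, fft=True, gridsize=grid_size, cut=0)
        grid = np.linspace(lo, hi, grid_size)
        f = np.interp(grid, kde.support, kde.density)
    f = np.clip(f, 0.0, None)
    f = f / np.trapezoid(f, grid)
    return grid, f


def _zero_crossings(x, g):
    """Locations where g changes sign, linearly interpolated; exact zeros kept."""
    out = []
    for i in range(len(g) - 1):
        a, b = g[i], g[i + 1]
        if a == 0.0:
            out.append(x[i])
        elif a * b < 0:
            out.append(x[i] + (x[i + 1] - x[i]) * (-a) / (b - a))
    if g[-1] == 0.0:
        out.append(x[-1])
    return np.array(out)


def find_theta(grid, f, mu: float, mass_min: float = 0.01):
    """Locate the sensitive/resistant divide theta left of the mode mu.

    Rule i: the largest stationary point of f below mu with
    f(theta) < 0.8 f(mu) and at least ``mass_min`` density mass left of it.
    Rule ii (if i fails): the largest inflection with f'' = 0, f''' > 0
    under the same constraints.  Rule iii: the range minimum.
    """
    grid = np.asarray(grid)
    f = np.asarray(f)
    h = grid[1] - grid[0]
    f_mu = np.interp(mu, grid, f)
    d1 = np.gradient(f, h)
    d2 = np.gradient(d1, h)
    d3 = np.gradient(d2, h)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * h)])

    def admissible(theta):
        if theta >= mu:
            return False
        if np.interp(theta, grid, f) >= 0.8 * f_mu:
            return False
        return np.interp(theta, grid, cum) >= mass_min

    for rule, signal, extra in (("i", d1, None), ("ii", d2, d3)):
        cands = _zero_crossings(grid, signal)
        if extra is not None:
            cands = cands[np.interp(cands, grid, extra) > 0]
        cands = [c for c in cands if admissible(c)]
        if cands:
            return float(max(cands)), rule
    return float(grid[0]), "iii"


def fit_resistant_population(points, theta: float, mu: float,
                             sigma_floor: float = 1e-3) -> float:
    """Resistant-population sd: median distance from mu of points in [theta, mu]."""
    points = np.asarray(points, dtype=float)
    sel = points[(points >= theta) & (points <= mu)]
    if len(sel) == 0:
        raise ValueError("no data points in [theta, mu]; cannot estimate sigma")
    return float(max(np.median(mu - sel), sigma_floor))


def threshold_from_tail(mu: float, sigma: float, t: float) -> float:
    """b such that the Normal(mu, sigma^2) CDF at b equals t."""
    if not 0 < t < 1:
        raise ValueError(f"t must be in (0, 1), got {t}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(mu + sigma * norm.ppf(t))


def binarize(values, ci_low=None, ci_high=None, t: float = 0.05, seed: int = 0,
             draws_per_sample: int = 1000, bandwidth: float = 0.5,
             grid_size: int = 512, mass_min: float = 0.01,
             sd_floor: float = 0.1, sigma_floor: float = 1e-3) -> BinarizationResult:
    """Run the full four-step heuristic; see the module docstring."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("need at least 2 distinct values to binarize")
    cloud = upsample(values, ci_low, ci_high, draws_per_sample=draws_per_sample,
                     seed=seed, sd_floor=sd_floor)
    grid, f = estimate_density(cloud, bandwidth=bandwidth, grid_size=grid_size)
    mu = float(grid[np.argmax(f)])
    theta, rule = find_theta(grid, f, mu, mass_min=mass_min)
    sigma = fit_resistant_population(cloud, theta, mu, sigma_floor=sigma_floor)
    b = threshold_from_tail(mu, sigma, t)
    return BinarizationResult(b=b, t=t, mu=mu, sigma=sigma, theta=theta,
                              rule_used=rule, grid=grid, f=f)


class ResponseBinarizer:
    """Scikit-learn style transformer wrapping :func:`binarize`.

    ``fit`` estimates the threshold from continuous values (+ optional CIs);
    ``transform`` maps values to 0/1 class labels (1 = below threshold).
    """

    def __init__(self, t: float = 0.05, draws_per_sample: int = 1000,
                 bandwidth: float = 0.5, grid_size: int = 512,
                 mass_min: float = 0.01, sd_floor: float = 0.1,
                 sigma_floor: float = 1e-3, seed: int = 0):
        self.t = t
        self.draws_per_sample = draws_per_sample
        self.bandwidth = bandwidth
        self.grid_size = grid_size
        self.mass_min = mass_min
        self.sd_floor = sd_floor
        self.sigma_floor = sigma_floor
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "t", "draws_per_sample", "bandwidth", "grid_size",
            "mass_min", "sd_floor", "sigma_floor", "seed")}

    def set_params(self, **params) -> "ResponseBinarizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, z, ci_low=None, ci_high=None) -> "ResponseBinarizer":
        res = binarize(z, ci_low, ci_high, t=self.t, seed=self.seed,
                       draws_per_sample=self.draws_per_sample,
                       bandwidth=self.bandwidth, grid_size=self.grid_size,
                       mass_min=self.mass_min, sd_floor=self.sd_floor,
                       sigma_floor=self.sigma_floor)
        self.result_ = res
        self.b_ = res.b
        self.mu_ = res.mu
        self.sigma_ = res.sigma
        self.theta_ = res.theta
        self.rule_used_ = res.rule_used
        return self

    def transform(self, z) -> np.ndarray:
        if not hasattr(self, "b_"):
            raise RuntimeError("ResponseBinarizer is not fitted")
        return (np.asarray(z, dtype=float) < self.b_).astype(np.int8)

    def fit_transform(self, z, ci_low=None, ci_high=None) -> np.ndarray:
        return self.fit(z, ci_low, ci_high).transform(z)
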