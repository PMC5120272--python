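"""Synthetic drug-response panels with planted DNF structure.

Emulates the structure of a cell-line panel: a sparse binary mutation
matrix (per-feature Bernoulli rates in the 5-15% range typical of cancer
gene mutations), and a bimodal continuous response in log-concentration
units — a resistant majority mode and a sensitive minority mode whose
membership is determined by a planted DNF model of the mutations, with
optional component-flip noise and missing measurements.  Every draw is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dnf import DNFModel, Literal, evaluate_dnf, parse_dnf

__all__ = ["SynthConfig", "SyntheticPanel", "generate_panel"]


def _default_model() -> DNFModel:
    return DNFModel([[Literal(0)], [Literal(1)]])  # x0 | x1


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate a typical single-drug panel.

    Response units are natural-log µM concentration: the resistant mode sits
    at ``mu_resistant`` and the sensitive mode ``4 * sd_component`` below it,
    a clearly bimodal separation.  ``feature_freqs`` defaults to 10%
    mutation frequency per gene.
    """

    n_samples: int = 300
    n_features: int = 10
    planted_model: DNFModel | None = field(default_factory=_default_model)
    feature_freqs: float | np.ndarray = 0.1
    mu_resistant: float = 3.0
    mu_sensitive: float = -1.0
    sd_component: float = 1.0
    ci_halfwidth: float = 0.3
    label_noise: float = 0.02
    missing_rate: float = 0.0
    sensitive_fraction: float = 0.1   # used only when planted_model is None
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.planted_model, str):
            names = [f"x{j}" for j in range(self.n_features)]
            self.planted_model = parse_dnf(self.planted_model, names)
        for rate_name in ("label_noise", "missing_rate", "sensitive_fraction"):
            v = getattr(self, rate_name)
            if not 0 <= v <= 1:
                raise ValueError(f"{rate_name} must be in [0, 1]")
        if self.mu_sensitive >= self.mu_resistant:
            raise ValueError("sensitive mode must lie below the resistant mode")
        if self.planted_model is not None:
            if max(self.planted_model.features, default=-1) >= self.n_features:
                raise ValueError("planted model references a feature beyond n_features")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_model"] = repr(self.planted_model)
        if isinstance(self.feature_freqs, np.ndarray):
            d["feature_freqs"] = self.feature_freqs.tolist()
        return d


@dataclass
class SyntheticPanel:
    """One simulated drug: mutation matrix, response values, and the truth."""

    X: np.ndarray
    z: np.ndarray                # NaN where the measurement is missing
    ci_low: np.ndarray
    ci_high: np.ndarray
    sample_ids: list
    feature_names: list
    ground_truth: DNFModel
    components: np.ndarray       # 1 = sensitive component (after label noise)
    config: SynthConfig

    @property
    def measured(self) -> np.ndarray:
        """Indices of samples with a recorded response value."""
        return np.flatnonzero(np.isfinite(self.z))

    def to_dataset(self, b: float, mode: str = "weighted"):
        """Threshold measured samples at b into a WeightedDataset (no imputation)."""
        from .dataset import WeightedDataset
        idx = self.measured
        return WeightedDataset.from_continuous(
            self.X[idx], self.z[idx], b, mode=mode,
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=self.feature_names)


def generate_panel(config: SynthConfig) -> SyntheticPanel:
    """Draw one synthetic drug panel from the generator model.

    X ~ Bernoulli(feature_freqs); the sensitive component is the planted DNF
    evaluated on X, flipped independently with probability ``label_noise``;
    z ~ Normal(component mean, sd_component^2); CIs are z +/- ci_halfwidth;
    a ``missing_rate`` fraction of responses is masked to NaN.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_features
    freqs = np.broadcast_to(np.asarray(config.feature_freqs, dtype=float), (p,))
    X = (rng.random((n, p)) < freqs).astype(np.int8)

    if config.planted_model is None:
        # null drug: response component independent of the features
        comp = rng.random(n) < config.sensitive_fraction
    else:
        comp = evaluate_dnf(config.planted_model, X).astype(bool)
    flip = rng.random(n) < config.label_noise
    comp = comp ^ flip

    mu = np.where(comp, config.mu_sensitive, config.mu_resistant)
    z = rng.normal(mu, config.sd_component)
    ci_low = z - config.ci_halfwidth
    ci_high = z + config.ci_halfwidth

    if config.missing_rate > 0:
        missing = rng.random(n) < config.missing_rate
        z = np.where(missing, np.nan, z)
        ci_low = np.where(missing, np.nan, ci_low)
        ci_high = np.where(missing, np.nan, ci_high)

    return SyntheticPanel(
        X=X, z=z, ci_low=ci_low, ci_high=ci_high,
        sample_ids=[f"CL{i:04d}" for i in range(n)],
        feature_names=[f"x{j}" for j in range(p)],
        ground_truth=config.planted_model,
        components=comp.astype(np.int8), config=config)


def planted_config(K: int, M: int, n_samples: int = 300, seed: int = 0,
                   target_prevalence: float = 0.10, **overrides) -> SynthConfig:
    """A generator config whose planted model has the given complexity.

    The planted DNF is K disjuncts of M positive literals each over disjoint
    features.  Per-feature mutation frequencies are calibrated so the
    sensitive component keeps a prevalence near ``target_prevalence``
    (the 5-15% range typical of drug-response panels) regardless of the
    AND/OR structure: each M-literal conjunction fires with probability
    ``target_prevalence / K`` approximately, i.e. per-feature frequency
    (target_prevalence / K) ** (1 / M).
    """
    model = DNFModel([
        [Literal(k * M + j) for j in range(M)] for k in range(K)
    ])
    freq = float((target_prevalence / K) ** (1.0 / M))
    n_features = max(10, K * M + 2)
    freqs = np.full(n_features, 0.1)
    freqs[: K * M] = freq
    return SynthConfig(n_samples=n_samples, n_features=n_features,
                       planted_model=model, feature_freqs=freqs, seed=seed,
                       **overrides)
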