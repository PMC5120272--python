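"""Weighted binary datasets: labels and sample weights from continuous response.

The continuous response z (e.g. natural-log IC50 in µM) is thresholded at b:
samples with z < b are the sensitive class (y = 1), samples with z >= b the
resistant class (y = 0).  The distance |z - b| becomes the misclassification
penalty, normalized so each class carries total weight 0.5.  On this scale a
random predictor has expected weighted error 0.5 and errors live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["WeightedDataset", "compute_weights", "weighted_error", "renormalize_weights"]

CLASS_WEIGHT = 0.5  # each class carries half the total unit weight


def compute_weights(z, b: float, mode: str = "weighted"):
    """Binarize a continuous response at b and build class-normalized weights.

    Parameters
    ----------
    z : array-like
        Continuous response values, lower = sensitive.
    b : float
        Binarization threshold; y = 1 iff z < b (ties are resistant).
    mode : {"weighted", "binary_only"}
        "weighted": w_n proportional to |z_n - b|, each class summing to 0.5.
        "binary_only": uniform within class, w_n = 1 / (2 * class size), so
        both modes share the same error scale.

    Returns
    -------
    y : int8 array
    w : float array summing to 1
    """
    z = np.asarray(z, dtype=float)
    y = (z < b).astype(np.int8)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "both classes must be non-empty after thresholding; "
            f"got {n_pos} sensitive / {n_neg} resistant at b={b!r}"
        )
    w = np.empty_like(z)
    if mode == "weighted":
        dist = np.abs(z - b)
        for cls in (0, 1):
            mask = y == cls
            total = dist[mask].sum()
            if total == 0:
                # all class members sit exactly on the threshold: fall back
                # to uniform so the class still carries its 0.5
                w[mask] = CLASS_WEIGHT / mask.sum()
            else:
                w[mask] = CLASS_WEIGHT * dist[mask] / total
    elif mode == "binary_only":
        w[y == 1] = CLASS_WEIGHT / n_pos
        w[y == 0] = CLASS_WEIGHT / n_neg
    else:
        raise ValueError(f"mode must be 'weighted' or 'binary_only', got {mode!r}")
    return y, w


def renormalize_weights(y, w):
    """Rescale weights so each class again sums to 0.5 (e.g. inside a CV fold)."""
    y = np.asarray(y)
    w = np.asarray(w, dtype=float).copy()
    for cls in (0, 1):
        mask = y == cls
        if not mask.any():
            raise ValueError("cannot renormalize: a class is empty")
        total = w[mask].sum()
        if total == 0:
            w[mask] = CLASS_WEIGHT / mask.sum()
        else:
            w[mask] *= CLASS_WEIGHT / total
    return w


def weighted_error(y_pred, y, w) -> float:
    """Weighted misclassification w^T |y_pred - y| (in [0, 1] when class-normalized)."""
    y_pred = np.asarray(y_pred)
    y = np.asarray(y)
    w = np.asarray(w, dtype=float)
    if not (len(y_pred) == len(y) == len(w)):
        raise ValueError("y_pred, y and w must have equal length")
    return float(w @ np.abs(y_pred.astype(float) - y.astype(float)))


@dataclass
class WeightedDataset:
    """Binary feature matrix with class-normalized sample weights.

    Attributes
    ----------
    X : (N, P) 0/1 array
    y : (N,) 0/1 labels (1 = sensitive)
    w : (N,) weights; each class sums to 0.5
    z : (N,) raw continuous response (same units as the input phenotype)
    sample_ids, feature_names : identifiers
    """

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    z: np.ndarray | None = None
    sample_ids: Sequence[str] | None = None
    feature_names: Sequence[str] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y).astype(np.int8)
        self.w = np.asarray(self.w, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("X must be strictly 0/1")
        if len(self.y) != n or len(self.w) != n:
            raise ValueError("y and w must match the number of rows of X")
        if (self.w < 0).any():
            raise ValueError("weights must be nonnegative")
        for cls in (0, 1):
            s = self.w[self.y == cls].sum()
            if abs(s - CLASS_WEIGHT) > 1e-9:
                raise ValueError(f"class {cls} weight sums to {s}, expected 0.5")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if self.feature_names is None:
            self.feature_names = [f"x{j}" for j in range(p)]
        if len(self.sample_ids) != n or len(self.feature_names) != p:
            raise ValueError("identifier lengths do not match X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_continuous(cls, X, z, b: float, mode: str = "weighted",
                        sample_ids=None, feature_names=None) -> "WeightedDataset":
        """Build a dataset by thresholding z at b and weighting by |z - b|."""
        y, w = compute_weights(z, b, mode=mode)
        return cls(X=np.asarray(X), y=y, w=w, z=np.asarray(z, dtype=float),
                   sample_ids=sample_ids, feature_names=feature_names)

    def subset(self, idx) -> "WeightedDataset":
        """Row subset with weights re-normalized per class to 0.5."""
        idx = np.asarray(idx)
        y = self.y[idx]
        w = renormalize_weights(y, self.w[idx])
        return WeightedDataset(
            X=self.X[idx], y=y, w=w,
            z=None if self.z is None else self.z[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=self.feature_names,
        )
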