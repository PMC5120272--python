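"""Disjunctive-normal-form (DNF) models over binary features.

A DNF model is an OR of AND-clauses ("disjuncts"); each disjunct conjoins
literals, where a literal is a binary feature or its negation.  The model
complexity is written (K, M): K disjuncts, at most M literals per disjunct.
These are the rule models inferred by the ILP in :mod:`dnflogic.ilp`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Literal", "DNFModel", "evaluate_dnf", "format_dnf", "parse_dnf"]


@dataclass(frozen=True, order=True)
class Literal:
    """A binary feature reference, possibly negated.

    Attributes
    ----------
    feature_index : int
        Column index into the feature matrix.
    negated : bool
        If True the literal is satisfied when the feature is 0.
    """

    feature_index: int
    negated: bool = False

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        col = np.asarray(X)[:, self.feature_index].astype(bool)
        return ~col if self.negated else col


class DNFModel:
    """An OR of AND-clauses over binary features.

    Parameters
    ----------
    disjuncts : sequence of iterables of Literal
        Each disjunct must be non-empty and may not contain a literal
        together with its negation.

    Notes
    -----
    Disjuncts are stored as frozensets; two models are equal iff they
    contain the same multiset of disjuncts (order-insensitive).
    """

    def __init__(self, disjuncts: Sequence[Iterable[Literal]]):
        frozen = []
        for d in disjuncts:
            ds = frozenset(d)
            if not ds:
                raise ValueError("empty disjunct: an empty conjunction is vacuously true")
            indices = [lit.feature_index for lit in ds]
            pos = {lit.feature_index for lit in ds if not lit.negated}
            neg = {lit.feature_index for lit in ds if lit.negated}
            if pos & neg:
                raise ValueError(
                    f"disjunct contains a feature and its negation: {sorted(pos & neg)}"
                )
            if any(i < 0 for i in indices):
                raise ValueError("negative feature index")
            frozen.append(ds)
        if not frozen:
            raise ValueError("model must contain at least one disjunct")
        self.disjuncts: list[frozenset[Literal]] = frozen

    @property
    def k(self) -> int:
        """Number of disjuncts."""
        return len(self.disjuncts)

    @property
    def m(self) -> int:
        """Size of the largest disjunct."""
        return max(len(d) for d in self.disjuncts)

    @property
    def features(self) -> set[int]:
        """Indices of all features appearing in the model."""
        return {lit.feature_index for d in self.disjuncts for lit in d}

    def predict(self, X: np.ndarray) -> np.ndarray:
        return evaluate_dnf(self, X)

    def canonical(self) -> tuple:
        """Order-free canonical form, usable as a dict key."""
        return tuple(sorted(
            (tuple(sorted((l.feature_index, l.negated) for l in d)) for d in self.disjuncts)
        ))

    def __eq__(self, other) -> bool:
        return isinstance(other, DNFModel) and self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:
        body = " | ".join(
            "(" + " & ".join(
                ("~x%d" % l.feature_index) if l.negated else ("x%d" % l.feature_index)
                for l in sorted(d)
            ) + ")"
            for d in self.disjuncts
        )
        return f"DNFModel<{body}>"


def evaluate_dnf(model: DNFModel, X: np.ndarray) -> np.ndarray:
    """Evaluate a DNF model row-wise on a binary matrix.

    Returns the 0/1 vector y' with y'_n = OR over disjuncts of the AND of
    the disjunct's literals on row n.
    """
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    p = X.shape[1]
    if any(l.feature_index >= p for d in model.disjuncts for l in d):
        raise IndexError("literal feature index out of range for X")
    out = np.zeros(X.shape[0], dtype=bool)
    for d in model.disjuncts:
        clause = np.ones(X.shape[0], dtype=bool)
        for lit in d:
            clause &= lit.evaluate(X)
        out |= clause
    return out.astype(np.int8)


def _literal_str(lit: Literal, feature_names: Sequence[str]) -> str:
    name = feature_names[lit.feature_index]
    return f"~{name}" if lit.negated else name


def format_dnf(model: DNFModel, feature_names: Sequence[str]) -> str:
    """Render a model as e.g. ``"BRAF | (CDKN2A & ~SMAD4)"``.

    Literals inside a disjunct are sorted by feature name with negations
    last; disjuncts are sorted by their rendered text, so output is
    deterministic. Multi-literal disjuncts are parenthesized.
    """
    parts = []
    for d in model.disjuncts:
        lits = sorted(d, key=lambda l: (l.negated, feature_names[l.feature_index]))
        body = " & ".join(_literal_str(l, feature_names) for l in lits)
        parts.append(f"({body})" if len(lits) > 1 else body)
    return " | ".join(sorted(parts))


_TOKEN = re.compile(r"\s*(~|¬|\||&|\(|\)|[^\s~¬|&()]+)")


def parse_dnf(text: str, feature_names: Sequence[str]) -> DNFModel:
    """Parse the ``format_dnf`` grammar back into a model.

    Disjuncts are separated by ``|``, literals within a disjunct by ``&``;
    negation is ``~`` (``¬`` accepted); parentheses around disjuncts are
    optional and may not nest across ``|``.
    """
    index = {name: i for i, name in enumerate(feature_names)}
    if len(index) != len(feature_names):
        raise ValueError("feature names must be unique")
    disjuncts = []
    for clause in text.split("|"):
        clause = clause.strip()
        if clause.startswith("(") and clause.endswith(")"):
            clause = clause[1:-1]
        lits = []
        for atom in clause.split("&"):
            atom = atom.strip()
            negated = False
            while atom[:1] in ("~", "¬"):
                negated = not negated
                atom = atom[1:].strip()
            if atom not in index:
                raise ValueError(f"unknown feature name: {atom!r}")
            lits.append(Literal(index[atom], negated))
        disjuncts.append(lits)
    return DNFModel(disjuncts)
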