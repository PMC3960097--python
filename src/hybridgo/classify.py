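"""One-vs-rest linear SVM scoring and multi-label decision schemes.

For an M-location problem, M independent binary SVMs with a linear kernel
are trained; a protein residing in locations {2, 5} is a positive example
for machines 2 and 5 and a negative example for the rest.  Scores are raw
(uncalibrated) decision values.

Two decision schemes turn the M scores into a label set:

* **fixed** — predict every class with a positive score; if none is
  positive, fall back to the top-scoring class.
* **adaptive** — when the top score is positive, predict every class whose
  score reaches a per-protein threshold ``min(1, theta * max(s))``; the
  unit cap keeps the top class itself always included.  When no score is
  positive, fall back to the top class.  ``theta`` in [0, 1] is tuned by
  cross-validation on the exact-match rate (OAA).

Both schemes always return a non-empty label set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "OvrSvmModel",
    "DecisionConfig",
    "train_ovr",
    "scores",
    "decide_fixed",
    "decide_adaptive",
    "decide",
    "tune_theta",
]

LabelSet = frozenset


@dataclass(frozen=True)
class DecisionConfig:
    """Decision scheme: ``fixed`` (zero threshold) or ``adaptive`` with theta."""

    scheme: str = "adaptive"
    theta: float | None = None

    def __post_init__(self):
        if self.scheme not in ("fixed", "adaptive"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "adaptive":
            if self.theta is None:
                raise ValueError("adaptive scheme requires theta")
            if not 0.0 <= self.theta <= 1.0:
                raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        elif self.theta is not None:
            raise ValueError("theta is only meaningful for the adaptive scheme")


@dataclass
class OvrSvmModel:
    """M per-class linear decision functions in primal (weights, bias) form."""

    weights: np.ndarray          # (M, D)
    biases: np.ndarray           # (M,)
    n_classes: int
    feature_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def to_json(self, stream: IO[str]) -> None:
        json.dump({
            "n_classes": self.n_classes,
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "feature_meta": self.feature_meta,
        }, stream)

    @classmethod
    def from_json(cls, stream: IO[str]) -> "OvrSvmModel":
        d = json.load(stream)
        return cls(np.asarray(d["weights"], dtype=float),
                   np.asarray(d["biases"], dtype=float),
                   int(d["n_classes"]), d.get("feature_meta", {}))


def _as_matrix(vectors: Sequence) -> np.ndarray:
    rows = [np.asarray(getattr(v, "values", v), dtype=float).ravel()
            for v in vectors]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent vector lengths: {sorted(lengths)}")
    return np.vstack(rows)


def train_ovr(vectors: Sequence, labels: Sequence[frozenset[int]], n_classes: int,
              C: float = 1.0, feature_meta: dict | None = None,
              allow_missing_classes: bool = False) -> OvrSvmModel:
    """Train M binary linear SVMs, one per class (one-vs-rest).

    ``labels`` are 1-based label sets.  A class with no positive example
    cannot be trained: by default this raises a ValueError naming the
    class; with ``allow_missing_classes`` (used for degenerate
    cross-validation folds) the class scorer degrades to the constant -1,
    so the class is never predicted except by the argmax fallback.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    X = _as_matrix(vectors)
    if len(labels) != X.shape[0]:
        raise ValueError("labels and vectors differ in length")
    W = np.zeros((n_classes, X.shape[1]))
    b = np.zeros(n_classes)
    for m in range(1, n_classes + 1):
        y = np.array([1 if m in ls else -1 for ls in labels])
        if not (y == 1).any():
            if allow_missing_classes:
                import logging
                logging.getLogger(__name__).warning(
                    "class %d has no positive example; scorer fixed at -1", m)
                W[m - 1] = 0.0
                b[m - 1] = -1.0
                continue
            raise ValueError(f"class {m} has no positive training example")
        if not (y == -1).any():
            # all proteins carry class m: the scorer degenerates to "always in"
            W[m - 1] = 0.0
            b[m - 1] = 1.0
            continue
        svm = SVC(kernel="linear", C=C)
        svm.fit(X, y)
        # SVC orders classes ascending, so decision_function > 0 <=> class +1
        W[m - 1] = svm.coef_.ravel()
        b[m - 1] = float(svm.intercept_[0])
    return OvrSvmModel(W, b, n_classes, feature_meta or {})


def scores(model: OvrSvmModel, v) -> np.ndarray:
    """Raw decision value of each per-class SVM for one feature vector."""
    x = np.asarray(getattr(v, "values", v), dtype=float).ravel()
    if len(x) != model.n_features:
        raise ValueError(f"vector length {len(x)} != model basis "
                         f"length {model.n_features}")
    return model.weights @ x + model.biases


def _argmax_label(s: np.ndarray) -> LabelSet:
    # ties break toward the smallest class index (np.argmax takes the first max)
    return frozenset({int(np.argmax(s)) + 1})


def decide_fixed(s: Sequence[float]) -> LabelSet:
    """Predict all classes with positive score; argmax fallback if none."""
    s = np.asarray(s, dtype=float)
    positive = frozenset(int(m) + 1 for m in np.flatnonzero(s > 0))
    return positive if positive else _argmax_label(s)


def decide_adaptive(s: Sequence[float], theta: float) -> LabelSet:
    """Per-protein threshold min(1, theta * max(s)); argmax fallback otherwise."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    s = np.asarray(s, dtype=float)
    smax = float(s.max())
    if smax <= 0.0:
        return _argmax_label(s)
    threshold = min(1.0, theta * smax)
    chosen = frozenset(int(m) + 1 for m in np.flatnonzero(s >= threshold))
    # the top class always satisfies s_max >= min(1, theta*s_max) for theta<=1
    return chosen if chosen else _argmax_label(s)


def decide(s: Sequence[float], cfg: DecisionConfig) -> LabelSet:
    if cfg.scheme == "fixed":
        return decide_fixed(s)
    return decide_adaptive(s, cfg.theta)


def tune_theta(X: Sequence, labels: Sequence[frozenset[int]], n_classes: int,
               grid: Sequence[float], folds: int = 5, C: float = 1.0,
               seed: int = 0) -> float:
    """Pick theta maximizing cross-validated exact-match rate (OAA).

    Fold assignment is a seeded permutation; folds where some class loses
    all positives are skipped with a warning.  Ties on OAA break toward the
    smallest theta.
    """
    from .evaluate import EvalPair, multilabel_metrics  # local: avoid cycle

    if not grid:
        raise ValueError("theta grid is empty")
    grid = sorted(grid)
    if len(grid) == 1:
        return grid[0]
    Xm = _as_matrix(X)
    n = Xm.shape[0]
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n) % folds

    pairs_per_theta: dict[float, list] = {t: [] for t in grid}
    for f in range(folds):
        test_idx = np.flatnonzero(assignment == f)
        train_idx = np.flatnonzero(assignment != f)
        if len(test_idx) == 0 or len(train_idx) == 0:
            continue
        train_labels = [labels[i] for i in train_idx]
        covered = set().union(*train_labels) if train_labels else set()
        if covered != set(range(1, n_classes + 1)):
            import logging
            logging.getLogger(__name__).warning(
                "fold %d lacks positives for some class; skipped", f)
            continue
        model = train_ovr(Xm[train_idx], train_labels, n_classes, C=C)
        for i in test_idx:
            s = scores(model, Xm[i])
            for t in grid:
                pairs_per_theta[t].append(
                    EvalPair(labels[i], decide_adaptive(s, t)))

    best_theta, best_oaa = grid[0], -1.0
    for t in grid:
        pairs = pairs_per_theta[t]
        if not pairs:
            continue
        oaa = multilabel_metrics(pairs, n_classes).oaa
        if oaa > best_oaa:
            best_theta, best_oaa = t, oaa
    return best_theta
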