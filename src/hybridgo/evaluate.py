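"""Multi-label performance metrics and leave-one-out cross-validation.

Per-protein (macro-averaged) metrics over true label sets L_i and predicted
sets Mhat_i, with M the number of locations:

    Accuracy  = mean |L ∩ Mhat| / |L ∪ Mhat|
    Precision = mean |L ∩ Mhat| / |Mhat|
    Recall    = mean |L ∩ Mhat| / |L|
    F1        = mean 2 |L ∩ Mhat| / (|L| + |Mhat|)
    HL        = mean |L Δ Mhat| / M              (Hamming loss; lower is better)

Two measures specific to multi-location localization:

* **OLA** (overall locative accuracy) treats each (protein, location) pair
  as one *locative protein*: a protein with k true locations contributes k
  locative entries, and an entry is a hit when its location appears in the
  prediction.  OLA = Σ|L ∩ Mhat| / Σ|L|.
* **OAA** (overall actual accuracy) is the exact-match rate: a protein
  counts only when Mhat = L exactly.  It is the strictest of the metrics:
  a degenerate predictor that outputs all M locations for every protein
  reaches OLA = 1 while its OAA is 0 (unless some true set is the full set).

LOOCV singles out each protein in turn, rebuilds the feature bases from the
remaining N-1 proteins (or reuses a dataset-wide term space under
``global_term_space``), trains, and scores the left-out protein.  The
gene-product similarity matrix depends only on the ontology and the IC
corpus, never on fold membership, so it is computed once and sliced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import DecisionConfig, decide, scores, train_ovr
from .datasets import ProteinRecord
from .features import build_term_space, frequency_vector
from .ontology import GoDag, IcTable
from .semsim import GoTermSet, TermSimConfig, protein_sim

logger = logging.getLogger(__name__)

__all__ = [
    "EvalPair",
    "MetricsReport",
    "multilabel_metrics",
    "locative_count",
    "pairwise_protein_sim",
    "loocv",
]


@dataclass(frozen=True)
class EvalPair:
    """True and predicted label sets for one protein; both non-empty."""

    true: frozenset[int]
    predicted: frozenset[int]

    def __post_init__(self):
        if not self.true or not self.predicted:
            raise ValueError("label sets must be non-empty")


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    hamming_loss: float
    ola: float
    oaa: float
    n_actual: int
    n_locative: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "accuracy", "precision", "recall", "f1", "hamming_loss",
            "ola", "oaa", "n_actual", "n_locative")}

    def __str__(self) -> str:
        rows = [
            ("OAA", self.oaa), ("OLA", self.ola), ("Accuracy", self.accuracy),
            ("Precision", self.precision), ("Recall", self.recall),
            ("F1", self.f1), ("HL", self.hamming_loss),
        ]
        lines = [f"{name:<10s} {val:.4f}" for name, val in rows]
        lines.append(f"{'proteins':<10s} {self.n_actual}")
        lines.append(f"{'locative':<10s} {self.n_locative}")
        return "\n".join(lines)


def locative_count(label_sets: Sequence[frozenset[int]]) -> int:
    """Number of locative proteins: Σ_i |L_i|.

    A protein residing in k locations contributes k locative entries; this
    is the OLA denominator and the per-location benchmark row total.
    """
    return int(sum(len(ls) for ls in label_sets))


def multilabel_metrics(pairs: Sequence[EvalPair], n_classes: int) -> MetricsReport:
    """Compute the full multi-label metric suite over evaluation pairs."""
    if not pairs:
        raise ValueError("no evaluation pairs")
    valid = set(range(1, n_classes + 1))
    for p in pairs:
        if not (p.true <= valid and p.predicted <= valid):
            raise ValueError(f"label outside 1..{n_classes}: {p}")

    acc = prec = rec = f1 = hl = 0.0
    exact = 0
    hits = 0
    locative = 0
    for p in pairs:
        inter = len(p.true & p.predicted)
        union = len(p.true | p.predicted)
        acc += inter / union
        prec += inter / len(p.predicted)
        rec += inter / len(p.true)
        f1 += 2.0 * inter / (len(p.true) + len(p.predicted))
        hl += len(p.true ^ p.predicted) / n_classes
        exact += int(p.true == p.predicted)
        hits += inter
        locative += len(p.true)
    n = len(pairs)
    return MetricsReport(
        accuracy=acc / n, precision=prec / n, recall=rec / n, f1=f1 / n,
        hamming_loss=hl / n, ola=hits / locative, oaa=exact / n,
        n_actual=n, n_locative=locative,
    )


def pairwise_protein_sim(records: Sequence[ProteinRecord], dag: GoDag,
                         ic: IcTable, cfg: TermSimConfig) -> np.ndarray:
    """Symmetric N x N gene-product similarity matrix over a protein list."""
    sets = [GoTermSet(r.terms) for r in records]
    n = len(sets)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = protein_sim(dag, ic, sets[i], sets[j], cfg)
            S[i, j] = S[j, i] = s
    return S


def _feature_matrix(records: Sequence[ProteinRecord], space, sim_block,
                    feature: str, l2_normalize: bool) -> np.ndarray:
    """Stack feature rows: frequency block, SS block, or their concatenation."""
    blocks = []
    if feature in ("freq", "hybrid"):
        F = np.vstack([
            frequency_vector(r, space, l2_normalize=l2_normalize).values
            for r in records])
        blocks.append(F)
    if feature in ("ss", "hybrid"):
        S = np.asarray(sim_block, dtype=float)
        if l2_normalize:
            norms = np.linalg.norm(S, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            S = S / norms
        blocks.append(S)
    return np.hstack(blocks)


def loocv(records: Sequence[ProteinRecord], dag: GoDag, ic: IcTable,
          n_classes: int, feature: str = "hybrid",
          sim_cfg: TermSimConfig | None = None,
          decision: DecisionConfig | None = None, C: float = 1.0,
          global_term_space: bool = False, l2_normalize: bool = False,
          ) -> tuple[MetricsReport, list[tuple[str, frozenset[int], frozenset[int]]]]:
    """Leave-one-out cross-validation of the whole pipeline.

    ``feature`` is one of ``freq``, ``ss``, ``hybrid``.  With
    ``global_term_space`` the term space W is built once from the full
    dataset instead of per fold — the historical benchmark protocol, which
    leaks the test protein's terms into W (the vocabulary only, not its
    label), at the benefit of a fixed feature dimensionality.

    Returns the aggregate metrics and per-protein
    ``(accession, true, predicted)`` triples in input order.
    """
    if len(records) < 2:
        raise ValueError("LOOCV needs at least 2 proteins")
    if feature not in ("freq", "ss", "hybrid"):
        raise ValueError(f"unknown feature kind {feature!r}")
    sim_cfg = sim_cfg or TermSimConfig("SS2")
    decision = decision or DecisionConfig("fixed")

    label_counts = {m: 0 for m in range(1, n_classes + 1)}
    for r in records:
        for m in r.labels:
            label_counts[m] += 1
    for m, c in label_counts.items():
        if c < 2:
            logger.warning("class %d has %d positive(s); its folds degenerate",
                           m, c)

    sim = None
    if feature in ("ss", "hybrid"):
        sim = pairwise_protein_sim(records, dag, ic, sim_cfg)
    global_space = build_term_space(list(records)) if global_term_space else None

    n = len(records)
    predictions = []
    pairs = []
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        train = [records[j] for j in train_idx]
        covered = set().union(*(r.labels for r in train))
        if covered != set(range(1, n_classes + 1)):
            logger.warning("fold %d: class(es) %s vanish from training",
                           i, sorted(set(range(1, n_classes + 1)) - covered))
        space = global_space if global_term_space else build_term_space(train)
        sim_train = sim[np.ix_(train_idx, train_idx)] if sim is not None else None
        sim_test = sim[np.ix_([i], train_idx)] if sim is not None else None
        Xtr = _feature_matrix(train, space, sim_train, feature, l2_normalize)
        Xte = _feature_matrix([records[i]], space, sim_test, feature, l2_normalize)
        model = train_ovr(Xtr, [r.labels for r in train], n_classes, C=C,
                          allow_missing_classes=True)
        pred = decide(scores(model, Xte[0]), decision)
        predictions.append((records[i].accession, records[i].labels, pred))
        pairs.append(EvalPair(records[i].labels, pred))
    return multilabel_metrics(pairs, n_classes), predictions
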