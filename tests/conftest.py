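"""Shared fixtures: toy DAGs, annotation corpora, and brute-force oracles.

The oracles deliberately avoid the package's graph and similarity code:
ancestor closure is computed by boolean matrix powers, information content
by explicit set propagation, and the similarity measures by direct formula
evaluation over exhaustively enumerated common ancestors.
"""

from __future__ import annotations

import math
from itertools import product as iproduct

import numpy as np
import pytest

from hybridgo.ontology import AnnotationCorpus, GoDag


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_ancestors(terms: list[str], edges: list[tuple[str, str]],
                    x: str, include_self: bool = False) -> set[str]:
    """Reachability via boolean adjacency-matrix powers (child -> parent)."""
    idx = {t: i for i, t in enumerate(terms)}
    n = len(terms)
    A = np.zeros((n, n), dtype=bool)
    for c, p in edges:
        A[idx[c], idx[p]] = True
    reach = A.copy()
    for _ in range(n):
        reach = reach | (reach @ A)
    out = {terms[j] for j in range(n) if reach[idx[x], j]}
    if include_self:
        out.add(x)
    return out


def brute_ic(terms, edges, annotations: list[tuple[str, str]]):
    """p and ic by explicit propagation of product sets to all ancestors."""
    per_term: dict[str, set[str]] = {t: set() for t in terms}
    for product, term in annotations:
        for t in brute_ancestors(terms, edges, term, include_self=True):
            per_term[t].add(product)
    total = len({g for g, _ in annotations})
    p = {t: len(s) / total for t, s in per_term.items() if s}
    ic = {t: -math.log(v) for t, v in p.items()}
    return p, ic


def brute_term_sim(terms, edges, p, ic, x, y, measure):
    """Direct formula evaluation with exhaustive common-ancestor enumeration."""
    common = (brute_ancestors(terms, edges, x, True)
              & brute_ancestors(terms, edges, y, True))
    common = {c for c in common if c in ic}
    if not common:
        return 0.0
    mica = max(common, key=lambda c: (ic[c], c))
    if measure == "resnik":
        return ic[mica]
    if measure == "SS1":
        denom = ic[x] + ic[y]
        return 0.0 if denom == 0 else 2 * ic[mica] / denom
    if measure == "SS2":
        return 1.0 / (1.0 + ic[x] + ic[y] - 2 * ic[mica])
    if measure == "SS3":
        denom = ic[x] + ic[y]
        lin = 0.0 if denom == 0 else 2 * ic[mica] / denom
        return lin * (1.0 - p[mica])
    raise ValueError(measure)


def brute_set_sim(terms, edges, p, ic, src, dst, measure):
    """Best-match average, one direction, by exhaustive evaluation."""
    return sum(max(brute_term_sim(terms, edges, p, ic, x, y, measure)
                   for y in dst) for x in src) / len(src)


def all_label_sets(n_classes: int):
    """Every non-empty subset of {1..n_classes}."""
    out = []
    for mask in range(1, 2 ** n_classes):
        out.append(frozenset(m + 1 for m in range(n_classes)
                             if mask & (1 << m)))
    return out


def label_set_pairs(n_classes: int):
    return list(iproduct(all_label_sets(n_classes), repeat=2))


# ---------------------------------------------------------------------------
# fixture DAGs

T1_TERMS = ["r", "a", "b", "c", "d"]
T1_EDGES = [("c", "a"), ("d", "a"), ("a", "r"), ("b", "r")]
#: 10 distinct products, direct annotations a:2, c:3, d:2, b:3
T1_ANNOTATIONS = (
    [(f"g{i}", "a") for i in range(1, 3)]
    + [(f"g{i}", "c") for i in range(3, 6)]
    + [(f"g{i}", "d") for i in range(6, 8)]
    + [(f"g{i}", "b") for i in range(8, 11)]
)

DIAMOND_TERMS = ["r", "a", "b", "c"]
DIAMOND_EDGES = [("c", "a"), ("c", "b"), ("a", "r"), ("b", "r")]


def build_dag(terms, edges, taxonomy="CC") -> GoDag:
    dag = GoDag()
    for t in terms:
        dag.terms.add(t)
        dag.isa.add_node(t)
        dag.taxonomy[t] = taxonomy
    for c, p in edges:
        dag.isa.add_edge(c, p)
    dag.validate()
    return dag


@pytest.fixture
def t1_dag() -> GoDag:
    return build_dag(T1_TERMS, T1_EDGES)


@pytest.fixture
def t1_corpus() -> AnnotationCorpus:
    return AnnotationCorpus(records=list(T1_ANNOTATIONS))


@pytest.fixture
def t1_ic(t1_dag, t1_corpus):
    from hybridgo.ontology import compute_ic
    return compute_ic(t1_dag, t1_corpus)


@pytest.fixture
def diamond_dag() -> GoDag:
    return build_dag(DIAMOND_TERMS, DIAMOND_EDGES)
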