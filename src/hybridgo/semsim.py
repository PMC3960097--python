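"""Term-level and gene-product-level GO semantic similarity.

Term-level measures are information-content based.  All of them reduce to
the information content of the *most informative common ancestor* (MICA) —
the shared 'is-a' ancestor with maximal IC, Resnik's quantity:

    sim_Resnik(x, y) = ic(MICA(x, y))
    sim_Lin(x, y)    = 2 ic(MICA) / (ic(x) + ic(y))            (SS1)
    sim_Jiang(x, y)  = transform(ic(x) + ic(y) - 2 ic(MICA))   (SS2)
    sim_RS(x, y)     = sim_Lin(x, y) * (1 - p(MICA))           (SS3)

Jiang-Conrath is natively a distance; the default similarity transform is
``1/(1+d)``, which maps d = 0 to 1.  Terms from different taxonomies share
no 'is-a' ancestor, so every measure returns 0 for cross-taxonomy pairs.

Gene-product-level similarity between two term sets is the *best-match
average*: each term of one set is matched with its most similar term in the
other set, the matches are averaged per direction, and the two directions
are combined by an arithmetic mean (a symmetric continuous measure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

from .ontology import GoDag, IcTable, ancestors

__all__ = [
    "Measure",
    "TermSimConfig",
    "GoTermSet",
    "mica",
    "sim_resnik",
    "sim_lin",
    "sim_jiang",
    "sim_rs",
    "term_similarity",
    "directional_set_sim",
    "protein_sim",
]

#: canonical measure names; SS1 = Lin, SS2 = Jiang, SS3 = relevance (RS)
MEASURES = ("SS1", "SS2", "SS3")
Measure = str


@dataclass(frozen=True)
class TermSimConfig:
    """Selects the term-level measure and the Jiang distance transform."""

    measure: Measure = "SS2"
    jiang_transform: Callable[[float], float] | None = None

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}, got {self.measure!r}")

    def transform(self, d: float) -> float:
        if self.jiang_transform is not None:
            return self.jiang_transform(d)
        return 1.0 / (1.0 + d)


class GoTermSet(frozenset):
    """A protein's de-duplicated GO term set (the set G_i).

    Term multiplicities matter only for frequency features; similarity works
    on the distinct-term set.
    """

    def __new__(cls, terms: Iterable[str]):
        obj = super().__new__(cls, terms)
        if not obj:
            raise ValueError("a GO term set must be non-empty")
        return obj


def _check_term(dag: GoDag, ic: IcTable, t: str) -> None:
    if t not in dag.terms:
        raise KeyError(t)
    if not ic.defined(t):
        raise ValueError(f"term {t} has no annotation mass; IC undefined")


def mica(dag: GoDag, ic: IcTable, x: str, y: str) -> tuple[str | None, float]:
    """Most informative common ancestor of x and y and its IC.

    The ancestor sets are self-inclusive, so ``mica(x, x) = (x, ic(x))``.
    Cross-taxonomy pairs share no ancestor: returns ``(None, 0.0)``.
    Ties on IC break lexicographically for determinism.
    """
    _check_term(dag, ic, x)
    _check_term(dag, ic, y)
    common = (ancestors(dag, x, include_self=True)
              & ancestors(dag, y, include_self=True))
    common = {c for c in common if ic.defined(c)}
    if not common:
        return None, 0.0
    best = max(common, key=lambda c: (ic.ic[c], c))
    return best, ic.ic[best]


def sim_resnik(dag: GoDag, ic: IcTable, x: str, y: str) -> float:
    """Resnik similarity: IC of the MICA.  Base quantity of SS1-SS3."""
    return mica(dag, ic, x, y)[1]


def sim_lin(dag: GoDag, ic: IcTable, x: str, y: str) -> float:
    """Lin similarity (SS1) in [0, 1]; 0 when both terms carry no IC."""
    a, ic_mica = mica(dag, ic, x, y)
    denom = ic.ic[x] + ic.ic[y]
    if denom == 0.0:
        return 0.0  # both roots: no shared information content
    return 2.0 * ic_mica / denom


def sim_jiang(dag: GoDag, ic: IcTable, x: str, y: str,
              cfg: TermSimConfig | None = None) -> float:
    """Jiang-Conrath similarity (SS2): transform of the IC distance."""
    a, ic_mica = mica(dag, ic, x, y)
    if a is None:
        return 0.0  # cross-taxonomy: no common ancestor
    d = ic.ic[x] + ic.ic[y] - 2.0 * ic_mica
    cfg = cfg or TermSimConfig("SS2")
    return cfg.transform(d)


def sim_rs(dag: GoDag, ic: IcTable, x: str, y: str) -> float:
    """Relevance similarity (SS3): Lin weighted by 1 - p(MICA).

    The (1 - p) factor downweights pairs whose shared ancestor is common
    (annotation-frequent), so sim_rs <= sim_lin always.
    """
    a, _ = mica(dag, ic, x, y)
    lin = sim_lin(dag, ic, x, y)
    if a is None:
        return 0.0
    return lin * (1.0 - ic.p[a])


def term_similarity(dag: GoDag, ic: IcTable, x: str, y: str,
                    cfg: TermSimConfig) -> float:
    """Dispatch on the configured measure (SS1=Lin, SS2=Jiang, SS3=RS)."""
    if cfg.measure == "SS1":
        return sim_lin(dag, ic, x, y)
    if cfg.measure == "SS2":
        return sim_jiang(dag, ic, x, y, cfg)
    return sim_rs(dag, ic, x, y)


def directional_set_sim(dag: GoDag, ic: IcTable, src: GoTermSet, dst: GoTermSet,
                        cfg: TermSimConfig) -> float:
    """Best-match average in one direction.

    Mean over x in ``src`` of the maximum similarity of x to any y in
    ``dst``.  Not symmetric in general; see :func:`protein_sim`.
    """
    if not src or not dst:
        raise ValueError("term sets must be non-empty")
    total = 0.0
    for x in src:
        total += max(term_similarity(dag, ic, x, y, cfg) for y in dst)
    return total / len(src)


def protein_sim(dag: GoDag, ic: IcTable, gi: GoTermSet, gj: GoTermSet,
                cfg: TermSimConfig) -> float:
    """Symmetric gene-product similarity: mean of the two directional values."""
    forward = directional_set_sim(dag, ic, gi, gj, cfg)
    backward = directional_set_sim(dag, ic, gj, gi, cfg)
    return 0.5 * (forward + backward)
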