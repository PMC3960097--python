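"""Gene Ontology structure, ancestor queries, and information content.

The Gene Ontology (GO) organizes terms describing cellular components (CC),
biological processes (BP) and molecular functions (MF) in three disjoint
directed acyclic graphs.  Only the 'is-a' subsumption relation is used for
semantic-similarity analysis; other relations (``part_of`` etc.) are parsed
and retained for inspection but never traversed.

Information content is the standard Resnik/Lord construction: an annotation
corpus is propagated up the 'is-a' hierarchy (the *true-path rule*: a gene
product annotated to a term is implicitly annotated to every ancestor), the
per-term probability ``p(c)`` is the fraction of distinct gene products of
the taxonomy reaching the term, and ``ic(c) = -ln p(c)``.  The natural
logarithm is used throughout; the base cancels in Lin's ratio measure and
only sets the scale of Resnik and Jiang-Conrath values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "AnnotationCorpus",
    "IcTable",
    "OboParseError",
    "OboIntegrityError",
    "parse_obo",
    "ancestors",
    "compute_ic",
]


class OboParseError(ValueError):
    """A stanza or tag line could not be interpreted; carries the line number."""


class OboIntegrityError(ValueError):
    """The parsed structure violates a DAG invariant (e.g. an 'is-a' cycle)."""


@dataclass
class GoDag:
    """GO terms plus the 'is-a' graph restricted to non-obsolete terms.

    Attributes
    ----------
    terms:
        All non-obsolete term identifiers.
    isa:
        Directed graph with one edge per ``child is_a parent`` assertion,
        oriented child -> parent.  Acyclic by construction.
    taxonomy:
        term-id -> namespace label (``CC``/``BP``/``MF`` or as declared).
    obsolete:
        Identifiers of obsolete terms; excluded from ``terms`` and from all
        similarity computations.
    other_relations:
        (child, parent, relation) triples for non-'is-a' relations; stored
        for completeness, unused by similarity.
    """

    terms: set[str] = field(default_factory=set)
    isa: nx.DiGraph = field(default_factory=nx.DiGraph)
    taxonomy: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    other_relations: list[tuple[str, str, str]] = field(default_factory=list)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def parents(self, term: str) -> set[str]:
        if term not in self.terms:
            raise KeyError(term)
        return set(self.isa.successors(term))

    def roots(self) -> set[str]:
        """Terms with no 'is-a' parent (one per taxonomy in a well-formed DAG)."""
        return {t for t in self.terms if self.isa.out_degree(t) == 0}

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.isa):
            cycle = nx.find_cycle(self.isa)
            raise OboIntegrityError(f"'is-a' graph contains a cycle: {cycle}")


def _new_stanza() -> dict:
    return {"id": None, "is_a": [], "relationship": [], "namespace": None,
            "is_obsolete": False, "kind": None}


def parse_obo(stream: IO[str] | Iterable[str]) -> GoDag:
    """Parse an OBO 1.2/1.4 flat file into a :class:`GoDag`.

    Only ``is_a:`` tag lines create graph edges.  ``relationship:`` lines
    are kept in ``other_relations``.  Obsolete terms are recorded but carry
    no edges.  Raises :class:`OboParseError` with the offending line number
    on malformed input and :class:`OboIntegrityError` if the resulting
    'is-a' graph is cyclic.
    """
    dag = GoDag()
    stanza = None
    n_terms_seen = 0

    def flush(st: dict) -> None:
        nonlocal n_terms_seen
        if st is None or st["kind"] != "Term":
            return
        tid = st["id"]
        n_terms_seen += 1
        if st["is_obsolete"]:
            dag.obsolete.add(tid)
            logger.warning("obsolete term %s dropped from the term set", tid)
            return
        dag.terms.add(tid)
        dag.isa.add_node(tid)
        if st["namespace"]:
            dag.taxonomy[tid] = st["namespace"]
        for parent in st["is_a"]:
            dag.isa.add_edge(tid, parent)
        for rel, target in st["relationship"]:
            dag.other_relations.append((tid, target, rel))

    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"line {lineno}: malformed stanza header {line!r}")
            flush(stanza)
            stanza = _new_stanza()
            stanza["kind"] = line[1:-1]
            continue
        if stanza is None or stanza["kind"] is None:
            continue  # header block (format-version etc.)
        if ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {line!r}")
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if tag == "id":
            if not value:
                raise OboParseError(f"line {lineno}: empty id")
            stanza["id"] = value
        elif tag == "is_a":
            stanza["is_a"].append(value.split()[0])
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(
                    f"line {lineno}: malformed relationship {value!r}")
            stanza["relationship"].append((parts[0], parts[1]))
        elif tag == "namespace":
            stanza["namespace"] = _canonical_namespace(value)
        elif tag == "is_obsolete":
            stanza["is_obsolete"] = value.lower() == "true"
        # all other tags (name, def, synonym, xref, ...) are ignored
    flush(stanza)

    if n_terms_seen == 0:
        raise OboParseError("no [Term] stanza found")

    missing = [p for _, p in dag.isa.edges if p not in dag.terms]
    for p in sorted(set(missing)):
        # tolerate forward references to terms absent from the file
        dag.terms.add(p)
        dag.isa.add_node(p)
    dag.validate()
    return dag


_NAMESPACE_ALIASES = {
    "cellular_component": "CC",
    "biological_process": "BP",
    "molecular_function": "MF",
}


def _canonical_namespace(value: str) -> str:
    return _NAMESPACE_ALIASES.get(value, value)


def ancestors(dag: GoDag, term: str, include_self: bool = False) -> set[str]:
    """Transitive 'is-a' ancestor closure of ``term``.

    With ``include_self`` the term itself is a member, so that the common
    ancestor set of a term with itself contains the term.
    """
    if term not in dag.terms:
        raise KeyError(term)
    out = nx.descendants(dag.isa, term)  # edges point child -> parent
    if include_self:
        out = out | {term}
    return out


@dataclass
class AnnotationCorpus:
    """Direct (gene-product, term) annotations used to estimate p(c).

    ``records`` hold direct annotations only; propagation to ancestors
    happens in :func:`compute_ic`.  Duplicate (product, term) pairs are
    harmless: each product is counted at most once per term.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def products(self) -> set[str]:
        return {g for g, _ in self.records}


@dataclass
class IcTable:
    """Per-term annotation probability and information content.

    ``count`` is the propagated distinct-product count.  Terms never reached
    by any annotation have no entry: their probability is undefined and the
    similarity layer rejects them rather than smoothing.
    """

    p: dict[str, float] = field(default_factory=dict)
    ic: dict[str, float] = field(default_factory=dict)
    count: dict[str, int] = field(default_factory=dict)

    def defined(self, term: str) -> bool:
        return term in self.p

    def to_tsv(self, stream: IO[str]) -> None:
        stream.write("term\tcount\tp\tic\n")
        for t in sorted(self.p):
            stream.write(f"{t}\t{self.count[t]}\t{self.p[t]:.10g}\t{self.ic[t]:.10g}\n")


def compute_ic(dag: GoDag, corpus: AnnotationCorpus,
               evidence_filter: None = None) -> IcTable:
    """Estimate p(c) and ic(c) = -ln p(c) from a corpus with true-path propagation.

    Each gene product annotated to a term counts toward that term and every
    'is-a' ancestor, once per term.  The denominator of p(c) is the number of
    distinct annotated gene products in c's taxonomy.
    """
    per_term_products: dict[str, set[str]] = {}
    for product, term in corpus.records:
        if term not in dag.terms:
            raise KeyError(f"corpus term {term!r} absent from the DAG")
        for t in ancestors(dag, term, include_self=True):
            per_term_products.setdefault(t, set()).add(product)

    # distinct annotated products per taxonomy (root count = taxonomy total)
    tax_products: dict[str, set[str]] = {}
    for product, term in corpus.records:
        tax = dag.taxonomy.get(term, "")
        tax_products.setdefault(tax, set()).add(product)

    table = IcTable()
    for term, prods in per_term_products.items():
        tax = dag.taxonomy.get(term, "")
        denom = len(tax_products.get(tax, set()))
        if denom == 0:
            continue
        p = len(prods) / denom
        table.count[term] = len(prods)
        table.p[term] = p
        table.ic[term] = -math.log(p)
    return table
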