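"""GO-term retrieval: GAF annotations, BLAST homolog lists, and the cascade.

A query protein's GO terms are looked up in a GOA-derived index by its own
accession first.  When that fails (novel proteins), the accessions of its
BLAST homologs are tried in order of increasing E-value until one has GOA
entries.  BLAST itself is not executed here — its tabular (outfmt 6) output
is consumed — which keeps the pipeline hermetic; a subprocess wrapper for
end users can shell out to ``blastp`` and feed the result to
:func:`parse_blast_tab`.

Term multiplicities are preserved: one GAF association line contributes one
occurrence, which is what the frequency features count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

__all__ = [
    "GoaIndex",
    "HomologList",
    "RetrievalResult",
    "RetrievalFailure",
    "parse_gaf",
    "parse_blast_tab",
    "parse_fasta_accessions",
    "retrieve_terms",
]

GAF_COLUMNS = 17
_BLAST_COLUMNS = 12


@dataclass
class GoaIndex:
    """accession -> GO term list with multiplicity (one entry per GAF line)."""

    terms: dict[str, list[str]] = field(default_factory=dict)

    def lookup(self, accession: str) -> list[str]:
        return self.terms.get(accession, [])


@dataclass
class HomologList:
    """Ranked homologs of one query, ascending E-value, truncated at k_max."""

    query: str
    accessions: list[str] = field(default_factory=list)
    evalues: list[float] = field(default_factory=list)
    k_max: int = 100


@dataclass
class RetrievalResult:
    accession: str
    terms: list[str]
    provenance: str  # "self" or "homolog:<rank>" (1-based)


class RetrievalFailure(LookupError):
    """Every key in the cascade missed the GOA index."""

    def __init__(self, tried: list[str]):
        super().__init__(f"no GOA entry for any of {tried}")
        self.tried = tried


def parse_gaf(stream: IO[str] | Iterable[str],
              exclude_evidence: set[str] | None = None) -> GoaIndex:
    """Parse GAF 2.1/2.2 into a :class:`GoaIndex`.

    Keys come from column 2 (DB object ID), terms from column 5 (GO ID).
    ``exclude_evidence`` drops association lines whose evidence code
    (column 7) is in the set — e.g. ``{"IEA"}`` to keep only curated
    annotations.  By default all evidence codes are kept.
    """
    index = GoaIndex()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < GAF_COLUMNS:
            raise ValueError(
                f"line {lineno}: expected {GAF_COLUMNS} tab-separated columns, "
                f"got {len(cols)}")
        accession, go_id, evidence = cols[1], cols[4], cols[6]
        if exclude_evidence and evidence in exclude_evidence:
            continue
        index.terms.setdefault(accession, []).append(go_id)
    return index


def parse_blast_tab(stream: IO[str] | Iterable[str], k_max: int = 100,
                    drop_self_hits: bool = False) -> list[HomologList]:
    """Parse BLAST tabular output (outfmt 6) into per-query homolog lists.

    Hits are sorted by ascending E-value (column 11); equal E-values keep
    their input order (BLAST's own bitscore ordering).  ``drop_self_hits``
    removes hits whose subject equals the query accession.
    """
    per_query: dict[str, list[tuple[float, int, str]]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < _BLAST_COLUMNS:
            raise ValueError(
                f"line {lineno}: expected {_BLAST_COLUMNS} columns, got {len(cols)}")
        query, subject = cols[0], cols[1]
        try:
            evalue = float(cols[10])
        except ValueError as e:
            raise ValueError(f"line {lineno}: non-numeric E-value {cols[10]!r}") from e
        if drop_self_hits and subject == query:
            continue
        if query not in per_query:
            per_query[query] = []
            order.append(query)
        per_query[query].append((evalue, lineno, subject))

    out = []
    for query in order:
        hits = sorted(per_query[query], key=lambda h: (h[0], h[1]))[:k_max]
        out.append(HomologList(
            query=query,
            accessions=[s for _, _, s in hits],
            evalues=[e for e, _, _ in hits],
            k_max=k_max,
        ))
    return out


def parse_fasta_accessions(stream: IO[str] | Iterable[str]) -> list[str]:
    """Accessions from FASTA headers, in file order.

    The accession is the header token before the first whitespace; the
    UniProt ``sp|ACC|NAME`` / ``tr|ACC|NAME`` dialect yields the middle
    field.  No sequence is parsed — bookkeeping only.
    """
    accs = []
    for raw in stream:
        if not raw.startswith(">"):
            continue
        token = raw[1:].split()[0] if raw[1:].split() else ""
        parts = token.split("|")
        if len(parts) >= 3 and parts[0] in ("sp", "tr"):
            accs.append(parts[1])
        else:
            accs.append(token)
    return accs


def retrieve_terms(accession: str | None, homologs: HomologList | None,
                   goa: GoaIndex) -> RetrievalResult:
    """Retrieval cascade: self accession first, then homologs by rank.

    Returns the first non-empty GO term multiset with its provenance.
    Raises :class:`RetrievalFailure` (carrying every key tried) if the
    cascade is exhausted — in practice GOA coverage of homologs makes this
    rare enough that no back-up feature set is provided.
    """
    if accession is None and homologs is None:
        raise ValueError("need an accession or a homolog list")
    tried: list[str] = []
    if accession is not None:
        terms = goa.lookup(accession)
        if terms:
            return RetrievalResult(accession, list(terms), "self")
        tried.append(accession)
    if homologs is not None:
        for rank, hom in enumerate(homologs.accessions[:homologs.k_max], start=1):
            terms = goa.lookup(hom)
            if terms:
                return RetrievalResult(accession or homologs.query, list(terms),
                                       f"homolog:{rank}")
            tried.append(hom)
    raise RetrievalFailure(tried)
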