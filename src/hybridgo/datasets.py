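"""The protein record flowing through every pipeline stage, plus TSV I/O.

A dataset row is ``accession <TAB> terms <TAB> labels`` where ``terms`` is a
semicolon-joined GO term list *with multiplicity* (the frequency features
need counts) and ``labels`` is a semicolon-joined list of 1-based class
indices.  Lines starting with '#' are comments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable

__all__ = ["ProteinRecord", "read_dataset_tsv", "write_dataset_tsv"]


@dataclass
class ProteinRecord:
    """One protein: accession, retrieved GO term multiset G_i, true label set."""

    accession: str
    terms: list[str] = field(default_factory=list)
    labels: frozenset[int] = field(default_factory=frozenset)

    @property
    def term_counts(self) -> Counter:
        return Counter(self.terms)

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(self.terms)


def read_dataset_tsv(stream: IO[str]) -> list[ProteinRecord]:
    records = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields, "
                             f"got {len(parts)}")
        acc, terms, labels = parts
        records.append(ProteinRecord(
            accession=acc,
            terms=[t for t in terms.split(";") if t],
            labels=frozenset(int(x) for x in labels.split(";") if x),
        ))
    return records


def write_dataset_tsv(records: Iterable[ProteinRecord], stream: IO[str]) -> None:
    stream.write("#accession\tterms\tlabels\n")
    for r in records:
        stream.write(f"{r.accession}\t{';'.join(r.terms)}\t"
                     f"{';'.join(str(x) for x in sorted(r.labels))}\n")
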