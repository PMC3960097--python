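"""Frequency, semantic-similarity and hybrid feature vectors.

Three vector families represent a protein:

* **Frequency vector** — occurrence counts of each term of the training
  term space W (distinct terms of the training set, lexicographically
  ordered), analogous to term frequencies in document retrieval.
* **SS vector** — the gene-product semantic similarity of the protein to
  each training protein, one coordinate per basis protein.
* **Hybrid vector** — the concatenation [frequency ; SS].  Hybrid1/2/3
  pair the frequency block with the SS1 (Lin) / SS2 (Jiang) / SS3 (RS)
  similarity block respectively.

No rescaling is applied by default: counts stay raw integers and the SS
block stays on its native [0, 1] scale.  ``l2_normalize_blocks`` optionally
normalizes each block to unit Euclidean length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import ProteinRecord
from .ontology import GoDag, IcTable
from .semsim import GoTermSet, TermSimConfig, protein_sim

logger = logging.getLogger(__name__)

__all__ = [
    "TermSpace",
    "FrequencyVector",
    "SsVector",
    "HybridVector",
    "BasisMismatchError",
    "build_term_space",
    "frequency_vector",
    "ss_vector",
    "hybrid_vector",
]


class BasisMismatchError(ValueError):
    """Two feature objects were built against different bases."""


@dataclass(frozen=True)
class TermSpace:
    """Ordered list W of the distinct GO terms of a training dataset."""

    terms: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("term space contains duplicates")

    def __len__(self) -> int:
        return len(self.terms)

    def index(self) -> dict[str, int]:
        return {t: u for u, t in enumerate(self.terms)}


@dataclass
class FrequencyVector:
    values: np.ndarray  # non-negative counts, length |W|
    basis: TermSpace

    def __post_init__(self):
        if len(self.values) != len(self.basis):
            raise BasisMismatchError("frequency vector length != |W|")


@dataclass
class SsVector:
    values: np.ndarray  # similarities in [0,1], length = #basis proteins
    basis: tuple[str, ...]  # training-protein accessions, fixed order
    measure: str

    def __post_init__(self):
        if len(self.values) != len(self.basis):
            raise BasisMismatchError("SS vector length != basis size")


@dataclass
class HybridVector:
    freq: FrequencyVector
    ss: SsVector

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.freq.values, self.ss.values])

    def __len__(self) -> int:
        return len(self.freq.values) + len(self.ss.values)


def build_term_space(train: list[ProteinRecord]) -> TermSpace:
    """Distinct terms of the training set, lexicographically ordered.

    The order is deterministic so serialized models are reproducible.
    """
    if not train:
        raise ValueError("cannot build a term space from an empty training set")
    for r in train:
        if not r.terms:
            raise ValueError(f"protein {r.accession} has an empty term multiset")
    w = sorted({t for r in train for t in r.terms})
    return TermSpace(tuple(w))


def frequency_vector(p: ProteinRecord, space: TermSpace,
                     l2_normalize: bool = False) -> FrequencyVector:
    """Term-occurrence counts of ``p`` over W; out-of-space terms are ignored.

    Novel test proteins may carry terms unseen in training; these cannot be
    represented and are dropped with a log message (never an error).
    """
    if len(space) == 0:
        raise ValueError("term space is empty")
    idx = space.index()
    v = np.zeros(len(space), dtype=float)
    dropped = 0
    for t in p.terms:
        u = idx.get(t)
        if u is None:
            dropped += 1
        else:
            v[u] += 1.0
    if dropped:
        logger.info("%s: %d term occurrence(s) outside the term space ignored",
                    p.accession, dropped)
    if l2_normalize:
        n = np.linalg.norm(v)
        if n > 0:
            v = v / n
    return FrequencyVector(v, space)


def ss_vector(p: ProteinRecord, basis: list[ProteinRecord], dag: GoDag,
              ic: IcTable, cfg: TermSimConfig,
              l2_normalize: bool = False) -> SsVector:
    """Similarity of ``p`` to each basis protein, in basis order."""
    if not basis:
        raise ValueError("SS basis is empty")
    gp = GoTermSet(p.terms)
    v = np.array([protein_sim(dag, ic, gp, GoTermSet(b.terms), cfg)
                  for b in basis], dtype=float)
    if l2_normalize:
        n = np.linalg.norm(v)
        if n > 0:
            v = v / n
    return SsVector(v, tuple(b.accession for b in basis), cfg.measure)


def hybrid_vector(f: FrequencyVector, s: SsVector,
                  expected_space: TermSpace | None = None,
                  expected_basis: tuple[str, ...] | None = None) -> HybridVector:
    """Concatenate the two blocks; both keep their own basis, no rescaling.

    When the expected training bases are supplied (e.g. from a serialized
    model), mismatched blocks raise :class:`BasisMismatchError`.
    """
    if expected_space is not None and f.basis != expected_space:
        raise BasisMismatchError("frequency block built on a different term space")
    if expected_basis is not None and s.basis != tuple(expected_basis):
        raise BasisMismatchError("SS block built on a different protein basis")
    return HybridVector(f, s)
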