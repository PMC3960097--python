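"""Synthetic ontologies, annotation corpora and multi-label protein datasets.

Everything downstream of data retrieval — IC estimation, similarity,
features, classification, evaluation — is exercised on generated inputs
shaped like the real ones:

* a rooted 'is-a' DAG (a random tree per branch plus redundant shortcut
  edges, acyclic by index construction) with one designated *signature
  subtree* per subcellular-location class and spare *noise* branches;
* an annotation corpus giving every term at least one directly annotated
  gene product, so information content is defined everywhere;
* a protein dataset in which a protein residing in locations S draws terms
  from the signature subtree of each class in S (each signature term kept
  with probability ``signature_strength``) plus uniform noise terms from
  the non-signature branches.

Label-set sizes follow the benchmark-style multiplicity profile: most
proteins are single-location, and multi-location proteins carry two or
(rarely) three labels.  The default ``multi_label_fraction`` of 0.20
mirrors the roughly one-in-five prevalence typical of curated
multi-location datasets; among multi-label proteins the 2:3-location split
defaults to 39:3.

A separate *complementarity scenario* builds a dataset in which the two
feature families carry disjoint information: one label factor is coded
purely in term multiplicity (invisible to the set-based similarity), the
other purely in which related-but-protein-unique leaf terms appear
(invisible to term-frequency coordinates, whose basis never contains a
left-out protein's private leaf).  Only their combination resolves both
factors.

Same config (including seed) always reproduces the same outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import ProteinRecord, write_dataset_tsv
from .ontology import AnnotationCorpus, GoDag, IcTable, compute_ic

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "make_dag",
    "make_dataset",
    "make_complementarity_scenario",
    "signature_subtrees",
    "write_obo",
    "write_gaf",
    "write_blast_tab",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class SynthConfig:
    n_terms: int = 60
    dag_depth: int = 4
    n_classes: int = 4
    n_proteins: int = 60
    multi_label_fraction: float = 0.20
    signature_strength: float = 1.0
    noise_terms_per_protein: int = 0
    seed: int = 0
    #: among multi-label proteins, relative weight of 2- vs 3-location sets
    multiplicity_split: tuple[float, float] = (39.0, 3.0)

    def __post_init__(self):
        if self.n_terms < 3 or self.n_classes < 1 or self.n_proteins < 1:
            raise ValueError("counts must be >= 1 (n_terms >= 3)")
        if not 0.0 <= self.multi_label_fraction <= 1.0:
            raise ValueError("multi_label_fraction must be in [0, 1]")
        if not 0.0 <= self.signature_strength <= 1.0:
            raise ValueError("signature_strength must be in [0, 1]")


def _tid(i: int) -> str:
    return f"GO:{i:07d}"


def make_dag(cfg: SynthConfig) -> tuple[GoDag, AnnotationCorpus]:
    """Random rooted 'is-a' DAG plus a corpus annotating every term.

    The root's first ``n_classes`` children head the signature subtrees;
    two further children head noise branches.  Remaining terms attach to a
    random existing term subject to the depth cap, and redundant shortcut
    edges to a deeper ancestor are added with small probability (the graph
    stays acyclic: every edge points to an earlier-created term).
    """
    n_branches = cfg.n_classes + 2
    if cfg.n_terms < 1 + n_branches:
        raise ValueError(
            f"n_terms={cfg.n_terms} cannot host {cfg.n_classes} signature "
            f"subtrees plus noise branches (need >= {1 + n_branches})")
    if cfg.dag_depth < 2:
        raise ValueError("dag_depth must be >= 2")
    rng = np.random.default_rng(cfg.seed)

    dag = GoDag()
    root = _tid(1)
    depth = {root: 0}
    dag.terms.add(root)
    dag.isa.add_node(root)
    dag.taxonomy[root] = "CC"

    for b in range(n_branches):
        t = _tid(2 + b)
        dag.terms.add(t)
        dag.isa.add_edge(t, root)
        dag.taxonomy[t] = "CC"
        depth[t] = 1

    attachable = [_tid(2 + b) for b in range(n_branches)]
    for i in range(2 + n_branches, cfg.n_terms + 1):
        t = _tid(i)
        candidates = [u for u in attachable if depth[u] < cfg.dag_depth]
        if not candidates:
            candidates = attachable
        parent = candidates[rng.integers(len(candidates))]
        dag.terms.add(t)
        dag.isa.add_edge(t, parent)
        dag.taxonomy[t] = "CC"
        depth[t] = depth[parent] + 1
        attachable.append(t)
        if rng.random() < 0.15:
            # redundant shortcut to a strict ancestor of the parent
            hop = parent
            anc = []
            while True:
                ups = list(dag.isa.successors(hop))
                if not ups:
                    break
                hop = ups[0]
                anc.append(hop)
            if anc:
                dag.isa.add_edge(t, anc[rng.integers(len(anc))])
    dag.validate()

    corpus = AnnotationCorpus()
    product = 0
    for i in range(1, cfg.n_terms + 1):
        for _ in range(1 + int(rng.poisson(1.0))):
            product += 1
            corpus.records.append((f"P{product:05d}", _tid(i)))
    return dag, corpus


def signature_subtrees(dag: GoDag, n_classes: int) -> list[set[str]]:
    """Per-class signature term sets: the subtree under each designated branch."""
    root = sorted(dag.roots())[0]
    children = sorted(dag.isa.predecessors(root))
    if len(children) < n_classes:
        raise ValueError(f"DAG has {len(children)} root branches, "
                         f"need {n_classes} signature subtrees")
    import networkx as nx
    subtrees = []
    for head in children[:n_classes]:
        members = nx.ancestors(dag.isa, head) | {head}  # edges child -> parent
        subtrees.append(set(members))
    return subtrees


def _draw_label_set(rng: np.random.Generator, cfg: SynthConfig) -> frozenset[int]:
    w2, w3 = cfg.multiplicity_split
    p1 = 1.0 - cfg.multi_label_fraction
    p2 = cfg.multi_label_fraction * w2 / (w2 + w3)
    p3 = cfg.multi_label_fraction * w3 / (w2 + w3)
    k = int(rng.choice([1, 2, 3], p=[p1, p2, p3]))
    k = min(k, cfg.n_classes)
    members = rng.choice(np.arange(1, cfg.n_classes + 1), size=k, replace=False)
    return frozenset(int(m) for m in members)


def make_dataset(cfg: SynthConfig, dag: GoDag) -> list[ProteinRecord]:
    """Class-structured multi-label proteins over the DAG's signature subtrees.

    The first ``2 * n_classes`` proteins are single-label, two per class, so
    every class keeps positives in any leave-one-out fold; the remainder
    follow the multiplicity profile.  With ``signature_strength = 1`` and no
    noise, a protein's terms are exactly the union of its classes' signature
    subtrees — classes are perfectly separable by term presence.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    subtrees = signature_subtrees(dag, cfg.n_classes)
    signature_union = set().union(*subtrees)
    root = sorted(dag.roots())[0]
    noise_pool = sorted(dag.terms - signature_union - {root})

    records = []
    for i in range(cfg.n_proteins):
        if i < 2 * cfg.n_classes:
            labels = frozenset({i // 2 + 1})
        else:
            labels = _draw_label_set(rng, cfg)
        terms: list[str] = []
        for m in sorted(labels):
            sig = sorted(subtrees[m - 1])
            kept = [t for t in sig if rng.random() < cfg.signature_strength]
            if not kept:
                kept = [sig[rng.integers(len(sig))]]
            terms.extend(kept)
        if cfg.noise_terms_per_protein:
            if noise_pool:
                picks = rng.integers(len(noise_pool),
                                     size=cfg.noise_terms_per_protein)
                terms.extend(noise_pool[k] for k in picks)
            else:
                logger.warning("no non-signature terms available for noise")
        records.append(ProteinRecord(f"SYN{i + 1:04d}", terms, labels))
    return records


def make_complementarity_scenario(
        n_proteins: int = 48, seed: int = 0,
) -> tuple[GoDag, IcTable, list[ProteinRecord], int]:
    """Dataset whose two label factors live in disjoint feature channels.

    Every protein carries exactly two locations: one of {1, 2} and one of
    {3, 4}.  The {1, 2} factor is *multiplicity-coded*: both classes use
    the same marker term, once for class 1 and three times for class 2 —
    identical as a set, so gene-product similarity (which de-duplicates)
    cannot see it, while term frequencies can.  The {3, 4} factor is
    *similarity-coded*: each protein carries a private leaf under the
    class-3 or class-4 subtree; the leaf never occurs in any other protein,
    so the frequency basis of a leave-one-out training set cannot represent
    it, while shared high-IC subtree parents make within-class similarity
    high and cross-class similarity zero.

    Returns (dag, ic_table, records, n_classes=4).
    """
    rng = np.random.default_rng(seed)
    dag = GoDag()
    root = "GO:0000001"
    marker = "GO:0000002"
    base = "GO:0000003"
    head3, head4 = "GO:0000004", "GO:0000005"
    for t in (root, marker, base, head3, head4):
        dag.terms.add(t)
        dag.taxonomy[t] = "CC"
        dag.isa.add_node(t)
    for t in (marker, base, head3, head4):
        dag.isa.add_edge(t, root)

    leaves3, leaves4 = [], []
    nxt = 6
    for i in range(n_proteins):
        l3 = f"GO:{nxt:07d}"; nxt += 1
        l4 = f"GO:{nxt:07d}"; nxt += 1
        for leaf, head, bucket in ((l3, head3, leaves3), (l4, head4, leaves4)):
            dag.terms.add(leaf)
            dag.taxonomy[leaf] = "CC"
            dag.isa.add_edge(leaf, head)
            bucket.append(leaf)
    dag.validate()

    # corpus: one product per leaf, a little direct mass on the shallow terms,
    # and a large background of products annotated only at the root.  The
    # background deepens every term's IC, which keeps the information content
    # of the subtree heads comparable to that of the leaves — sibling leaves
    # then score high (their shared head carries most of their information)
    # while cross-subtree leaves still share only the root (similarity 0).
    corpus = AnnotationCorpus()
    product = 0
    for leaf in leaves3 + leaves4:
        product += 1
        corpus.records.append((f"P{product:05d}", leaf))
    for t in (marker, base, head3, head4):
        for _ in range(2):
            product += 1
            corpus.records.append((f"P{product:05d}", t))
    for _ in range(100 * n_proteins):
        product += 1
        corpus.records.append((f"P{product:05d}", root))
    ic = compute_ic(dag, corpus)

    records = []
    for i in range(n_proteins):
        mult_class = 1 + (i % 2)           # alternate: balanced factor {1,2}
        ss_class = 3 + ((i // 2) % 2)      # balanced factor {3,4}
        terms = [base]
        terms += [marker] * (1 if mult_class == 1 else 3)
        leaf = (leaves3 if ss_class == 3 else leaves4)[i]
        terms.append(leaf)
        records.append(ProteinRecord(f"CMP{i + 1:04d}", terms,
                                     frozenset({mult_class, ss_class})))
    # shuffle protein order so fold structure carries no block pattern
    order = rng.permutation(n_proteins)
    records = [records[k] for k in order]
    return dag, ic, records, 4


# ---------------------------------------------------------------------------
# fixture writers (OBO / GAF / BLAST outfmt-6 / dataset TSV)

def write_obo(dag: GoDag, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic term {t}\n")
            ns = {"CC": "cellular_component", "BP": "biological_process",
                  "MF": "molecular_function"}.get(dag.taxonomy.get(t, "CC"),
                                                  "cellular_component")
            fh.write(f"namespace: {ns}\n")
            for parent in sorted(dag.isa.successors(t)):
                fh.write(f"is_a: {parent} ! synthetic term {parent}\n")


def write_gaf(corpus: AnnotationCorpus, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for product, term in corpus.records:
            cols = ["SYNTH", product, product, "", term, "SYNTH:0000001",
                    "IEA", "", "C", "", "", "protein", "taxon:0000", "20240101",
                    "SYNTH", "", ""]
            fh.write("\t".join(cols) + "\n")


def write_blast_tab(records: list[ProteinRecord], path: Path,
                    seed: int = 0) -> None:
    """Fake outfmt-6 hits: each protein's homologs are its dataset neighbours."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            hits = [records[(i + k) % len(records)] for k in range(1, 4)]
            ev = np.sort(rng.uniform(1e-50, 1e-5, size=len(hits)))
            for h, e in zip(hits, ev):
                fh.write(f"{r.accession}\t{h.accession}\t95.0\t100\t5\t0\t1\t100"
                         f"\t1\t100\t{e:.2e}\t200.0\n")


def write_fixture_dir(cfg: SynthConfig, outdir: Path) -> dict[str, Path]:
    """Emit a complete fixture set (OBO, GAF, BLAST, dataset TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag, corpus = make_dag(cfg)
    records = make_dataset(cfg, dag)
    paths = {
        "obo": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
        "blast": outdir / "homologs.blast6",
        "dataset": outdir / "dataset.tsv",
    }
    write_obo(dag, paths["obo"])
    write_gaf(corpus, paths["gaf"])
    write_blast_tab(records, paths["blast"], seed=cfg.seed)
    with open(paths["dataset"], "w") as fh:
        write_dataset_tsv(records, fh)
    return paths
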