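# Methods

## Model overview

A protein is represented by the multiset of GO terms retrieved for it (its
own GOA entries, or those of its closest annotated BLAST homolog), and is
assigned a non-empty set of subcellular locations out of M candidates.
Three feature families feed an one-vs-rest bank of linear SVMs:

* term-frequency coordinates over the training term space W;
* gene-product semantic-similarity coordinates, one per training protein;
* their concatenation (the hybrid vector) — the package's default.

The two families are complementary by construction: frequency coordinates
are independent per term and carry multiplicity information, while the SS
coordinates are built from inter-term ('is-a') relationships and compare
whole term groups, so related-but-distinct annotations still register.

## Information content

The annotation probability of term *c* is the number of distinct gene
products annotated to *c or any descendant* (true-path propagation) divided
by the number of distinct annotated products in *c*'s taxonomy;
`ic(c) = −ln p(c)`. Propagation is what makes `p` monotone along 'is-a'
edges (`p(child) ≤ p(parent)`, `p(root) = 1`) and hence self-similarity
Lin(x, x) = 1; without it neither property holds. The natural logarithm is
a convention: the base cancels in Lin's ratio and only scales Resnik and
the Jiang-Conrath distance. Terms that no annotation reaches have
*undefined* probability and are rejected by the similarity layer rather
than smoothed — the retrieval cascade only ever yields annotated terms, so
in practice no smoothing rule is needed. All evidence codes are counted by
default; `parse_gaf(exclude_evidence={"IEA"})` restricts the corpus to
curated annotations.

## Similarity

Term-level measures (SS1 Lin, SS2 Jiang-Conrath, SS3 relevance) all reduce
to the most informative common ancestor, with ancestor sets taken
self-inclusive and only 'is-a' edges traversed. Choices in corner cases:

* **Jiang transform.** Jiang-Conrath is natively the distance
  `d = ic(x) + ic(y) − 2·ic(MICA)`; the similarity transform is
  `1/(1+d)` (maps d = 0 to 1, stays in (0, 1]), selectable via
  `TermSimConfig.jiang_transform`.
* **Both terms roots.** `ic(x) + ic(y) = 0` would make Lin 0/0; the
  similarity is defined as 0 (no shared information content).
* **Cross-taxonomy pairs.** The three GO taxonomies are orthogonal DAGs
  with no shared 'is-a' ancestor, so similarity is 0.
* **MICA ties.** Equal-IC common ancestors break lexicographically, making
  runs reproducible (the similarity value is unaffected).

Gene-product similarity is the best-match average: for each term of one
protein take its best match in the other protein's set, average per
direction, and combine the two directions by an arithmetic mean. Duplicated
terms are removed before this step — multiplicity information lives in the
frequency block, keeping the two families non-redundant.

## Features and classification

W is the lexicographically sorted union of the distinct training terms
(order fixed so serialized models reproduce). Test-protein terms outside W
are dropped with a log message, never an error — novel proteins routinely
carry unseen terms. Frequency counts are raw and the hybrid blocks are not
rescaled against each other (the SS block is naturally in [0, 1]); an
optional per-block L2 normalization exists, default off.

Each of the M classes gets an independent binary SVM with a linear kernel
(regularization C = 1.0 by default; high-dimensional GO vectors with few
training proteins are the regime where linear SVMs behave well). Scores are
raw decision values — no calibration, since the adaptive rule's absolute
cap of 1 is meant for uncalibrated SVM outputs. Decision schemes:

* **fixed**: predict `{m : s_m > 0}`, falling back to the argmax when
  empty (ties to the smallest class index);
* **adaptive**: when `max(s) > 0`, predict `{m : s_m ≥ min(1, θ·max(s))}`
  (the `≥` guarantees the top class is always included; the unit cap keeps
  the threshold meaningful when scores exceed 1); otherwise the argmax
  singleton. θ ∈ [0, 1] is chosen on a grid by k-fold cross-validation
  maximizing exact-match accuracy, with seeded fold assignment, skipping
  folds that lose all positives of some class, and breaking ties toward
  the smaller θ.

In leave-one-out cross-validation the term space and SS basis are rebuilt
from the N−1 training proteins of each fold by default. A
`global_term_space` flag instead builds W once from the full dataset — the
historical benchmark protocol; it exposes the test protein's vocabulary
(not its label) to training and is off by default. Degenerate folds whose
training half loses every positive of a class are still scored: that
class's scorer degrades to a constant −1.

## Synthetic data

The generator emulates the inputs of a real study: an OBO ontology (rooted
random 'is-a' tree per branch plus redundant shortcut edges, acyclic by
construction), a GAF annotation corpus giving every term at least one
product, a BLAST outfmt-6 homolog table, and a dataset TSV. Each location
class owns one signature subtree under the root; a protein in locations S
keeps each signature term of each class in S with probability
`signature_strength` and adds `noise_terms_per_protein` uniform draws from
the non-signature branches. Label-set sizes follow a 1/2/3-location profile
with `multi_label_fraction = 0.20` of proteins multi-located and the
2-vs-3-location split 39:3 — the multi-location prevalence and tail shape
typical of curated localization benchmarks. Identical configs (including
the seed) reproduce byte-identical files.

What the generator does *not* emulate: realistic GO DAG depth and fan-out,
annotation-bias across species, BLAST E-value distributions, or correlated
label structure beyond the signature model. Passing the end-to-end tests
therefore demonstrates that the pipeline recovers planted class structure
through every stage, not that benchmark-level accuracy transfers to real
proteomes — reproducing historical benchmark numbers would require the
original Swiss-Prot-era datasets and GOA snapshots.

A dedicated *complementarity scenario* encodes one label factor purely in
term multiplicity (invisible to set-based similarity) and another purely in
protein-private leaf terms under per-class subtrees (invisible to frequency
coordinates, whose training basis never contains the left-out protein's
leaf). A large root-level annotation background keeps subtree-head IC
comparable to leaf IC so sibling leaves score high under any measure. On
this scenario the hybrid features resolve both factors while each family
alone resolves at most one — the package's central design claim, tested at
a fixed seed.

## Problem sizes and numerics

Default test and acceptance runs use 12-term DAGs for exhaustive oracle
comparisons (every term pair, tolerance 1e−12), 48–60 proteins and 3–4
classes for LOOCV, and 10,000 random score vectors for decision-rule
properties — sizes at which exact brute-force oracles are feasible and the
full suite runs in seconds. Retrieval, similarity and metric computations
are deterministic; the only randomness (synthetic data, fold assignment)
is seeded.

## Known limitations

* Only 'is-a' edges contribute to similarity; `part_of` and regulatory
  relations are parsed but ignored.
* Resnik's measure is implemented as the base of the other measures and
  for inspection, not wired into the feature pipeline (it ignores the
  term-to-ancestor distance that the ratio measures capture).
* BLAST is not executed in-package; homology input is its tabular output.
* No probability calibration, kernels beyond linear, or feature selection.
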