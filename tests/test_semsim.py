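"""Term-level and gene-product-level semantic similarity.

Frozen expected values for the T1 fixture were computed by hand from the
propagated probabilities (p(a)=0.7, p(b)=p(c)=0.3, p(d)=0.2) and the
measure formulas; exhaustive comparisons use the independent brute-force
oracle from conftest.
"""

import math
from itertools import combinations_with_replacement

import pytest

from hybridgo.ontology import AnnotationCorpus, compute_ic
from hybridgo.semsim import (GoTermSet, TermSimConfig, directional_set_sim,
                             mica, protein_sim, sim_jiang, sim_lin,
                             sim_resnik, sim_rs, term_similarity)
from hybridgo.synth import SynthConfig, make_dag

from conftest import brute_set_sim, brute_term_sim, build_dag

IC_A = 0.35667494393873245       # -ln 0.7
LIN_CD = 0.25355341245695145     # 2 ic(a) / (ic(c) + ic(d))
JIANG_CD = 0.322574315537045     # 1 / (1 + ic(c) + ic(d) - 2 ic(a))
RS_CD = 0.07606602373708544      # LIN_CD * (1 - 0.7)


class TestMica:
    def test_self_mica_is_self(self, t1_dag, t1_ic):
        assert mica(t1_dag, t1_ic, "c", "c") == ("c", t1_ic.ic["c"])

    def test_t1_cd_maximizer(self, t1_dag, t1_ic):
        term, value = mica(t1_dag, t1_ic, "c", "d")
        assert term == "a"
        assert value == pytest.approx(IC_A)

    def test_root_only_common_ancestor(self, t1_dag, t1_ic):
        assert mica(t1_dag, t1_ic, "a", "b") == ("r", 0.0)

    def test_unknown_term_raises(self, t1_dag, t1_ic):
        with pytest.raises(KeyError):
            mica(t1_dag, t1_ic, "c", "zz")

    def test_zero_count_term_rejected(self, t1_dag):
        ic = compute_ic(t1_dag, AnnotationCorpus(records=[("g1", "c")]))
        with pytest.raises(ValueError, match="annotation mass"):
            mica(t1_dag, ic, "c", "b")

    def test_cross_taxonomy_no_ancestor(self):
        dag = build_dag(["r1", "x"], [("x", "r1")], taxonomy="CC")
        dag2 = build_dag(["r2", "y"], [("y", "r2")], taxonomy="BP")
        dag.terms |= dag2.terms
        dag.isa.add_edges_from(dag2.isa.edges)
        dag.taxonomy.update(dag2.taxonomy)
        corpus = AnnotationCorpus(records=[("g1", "x"), ("g2", "r1"),
                                           ("h1", "y"), ("h2", "r2")])
        ic = compute_ic(dag, corpus)
        assert mica(dag, ic, "x", "y") == (None, 0.0)
        assert sim_lin(dag, ic, "x", "y") == 0.0
        assert sim_jiang(dag, ic, "x", "y") == 0.0
        assert sim_rs(dag, ic, "x", "y") == 0.0


class TestTermMeasures:
    def test_resnik_t1(self, t1_dag, t1_ic):
        assert sim_resnik(t1_dag, t1_ic, "c", "c") == t1_ic.ic["c"]
        assert sim_resnik(t1_dag, t1_ic, "a", "b") == 0.0
        assert sim_resnik(t1_dag, t1_ic, "c", "d") == pytest.approx(IC_A)

    def test_lin_t1(self, t1_dag, t1_ic):
        assert sim_lin(t1_dag, t1_ic, "c", "c") == pytest.approx(1.0)
        assert sim_lin(t1_dag, t1_ic, "c", "d") == pytest.approx(LIN_CD)
        assert sim_lin(t1_dag, t1_ic, "r", "c") == 0.0

    def test_lin_both_roots_defined_zero(self, t1_dag, t1_ic):
        assert sim_lin(t1_dag, t1_ic, "r", "r") == 0.0

    def test_jiang_t1(self, t1_dag, t1_ic):
        assert sim_jiang(t1_dag, t1_ic, "c", "c") == pytest.approx(1.0)
        assert sim_jiang(t1_dag, t1_ic, "c", "d") == pytest.approx(JIANG_CD)

    def test_jiang_custom_transform(self, t1_dag, t1_ic):
        cfg = TermSimConfig("SS2", jiang_transform=lambda d: math.exp(-d))
        expected = math.exp(-(t1_ic.ic["c"] + t1_ic.ic["d"] - 2 * IC_A))
        assert sim_jiang(t1_dag, t1_ic, "c", "d", cfg) == pytest.approx(expected)

    def test_rs_t1(self, t1_dag, t1_ic):
        assert sim_rs(t1_dag, t1_ic, "c", "c") == pytest.approx(1 - 0.3)
        assert sim_rs(t1_dag, t1_ic, "c", "d") == pytest.approx(RS_CD)

    def test_rs_never_exceeds_lin(self, t1_dag, t1_ic):
        for x in t1_dag.terms:
            for y in t1_dag.terms:
                assert (sim_rs(t1_dag, t1_ic, x, y)
                        <= sim_lin(t1_dag, t1_ic, x, y) + 1e-15)


@pytest.mark.parametrize("seed", range(3))
@pytest.mark.parametrize("measure", ["resnik", "SS1", "SS2", "SS3"])
def test_exhaustive_oracle_equivalence(seed, measure):
    """Every term pair on fixture DAGs matches brute force to 1e-12."""
    dag, corpus = make_dag(SynthConfig(n_terms=12, n_classes=2, seed=seed))
    ic = compute_ic(dag, corpus)
    terms = sorted(dag.terms)
    edges = list(dag.isa.edges)
    fns = {"resnik": sim_resnik, "SS1": sim_lin, "SS2": sim_jiang,
           "SS3": sim_rs}
    for x, y in combinations_with_replacement(terms, 2):
        expected = brute_term_sim(terms, edges, ic.p, ic.ic, x, y, measure)
        got = fns[measure](dag, ic, x, y)
        assert got == pytest.approx(expected, abs=1e-12)
        assert fns[measure](dag, ic, y, x) == pytest.approx(got, abs=1e-12)


@pytest.mark.parametrize("measure", ["SS1", "SS2", "SS3"])
def test_range_bounds(measure, t1_dag, t1_ic):
    for x in t1_dag.terms:
        for y in t1_dag.terms:
            v = term_similarity(t1_dag, t1_ic, x, y, TermSimConfig(measure))
            assert 0.0 <= v <= 1.0


def test_deepening_mica_never_decreases_lin():
    """Moving the shared ancestor down a chain raises Lin similarity."""
    chain = ["r", "m1", "m2", "m3"]
    edges = [("m1", "r"), ("m2", "m1"), ("m3", "m2"),
             ("x1", "m1"), ("x2", "m2"), ("x3", "m3"),
             ("y1", "m1"), ("y2", "m2"), ("y3", "m3")]
    terms = chain + ["x1", "x2", "x3", "y1", "y2", "y3"]
    dag = build_dag(terms, edges)
    # one product per leaf pair level, plus filler to spread probabilities
    records = []
    for i, t in enumerate(["x1", "x2", "x3", "y1", "y2", "y3"]):
        records.append((f"g{i}", t))
    records += [(f"f{i}", "r") for i in range(6)]
    ic = compute_ic(dag, AnnotationCorpus(records=records))
    sims = [sim_lin(dag, ic, f"x{k}", f"y{k}") for k in (1, 2, 3)]
    assert sims == sorted(sims)
    assert sims[0] < sims[2]


class TestSetSimilarity:
    def test_self_similarity_is_one(self, t1_dag, t1_ic):
        g = GoTermSet({"c", "d"})
        for m in ("SS1", "SS2"):
            cfg = TermSimConfig(m)
            assert directional_set_sim(t1_dag, t1_ic, g, g, cfg) == pytest.approx(1.0)
            assert protein_sim(t1_dag, t1_ic, g, g, cfg) == pytest.approx(1.0)

    def test_exact_match_dominates(self, t1_dag, t1_ic):
        cfg = TermSimConfig("SS1")
        got = directional_set_sim(t1_dag, t1_ic, GoTermSet({"c"}),
                                  GoTermSet({"c", "d"}), cfg)
        assert got == pytest.approx(1.0)

    def test_two_term_directional_value(self, t1_dag, t1_ic):
        cfg = TermSimConfig("SS1")
        got = directional_set_sim(t1_dag, t1_ic, GoTermSet({"c", "d"}),
                                  GoTermSet({"c"}), cfg)
        assert got == pytest.approx(0.6267767062284757)  # (1 + lin(c,d)) / 2

    def test_singleton_pair_reduces_to_term_sim(self, t1_dag, t1_ic):
        cfg = TermSimConfig("SS1")
        got = protein_sim(t1_dag, t1_ic, GoTermSet({"c"}), GoTermSet({"d"}), cfg)
        assert got == pytest.approx(LIN_CD)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GoTermSet([])

    @pytest.mark.parametrize("measure", ["SS1", "SS2", "SS3"])
    def test_symmetry_and_oracle_on_random_sets(self, measure):
        import random
        rng = random.Random(7)
        dag, corpus = make_dag(SynthConfig(n_terms=12, n_classes=2, seed=1))
        ic = compute_ic(dag, corpus)
        terms = sorted(dag.terms)
        edges = list(dag.isa.edges)
        cfg = TermSimConfig(measure)
        for _ in range(20):
            gi = GoTermSet(rng.sample(terms, rng.randint(1, 4)))
            gj = GoTermSet(rng.sample(terms, rng.randint(1, 4)))
            ours = protein_sim(dag, ic, gi, gj, cfg)
            assert ours == pytest.approx(
                protein_sim(dag, ic, gj, gi, cfg), abs=1e-12)
            expected = 0.5 * (
                brute_set_sim(terms, edges, ic.p, ic.ic, gi, gj, measure)
                + brute_set_sim(terms, edges, ic.p, ic.ic, gj, gi, measure))
            assert ours == pytest.approx(expected, abs=1e-12)
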