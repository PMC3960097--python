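"""Multi-label metrics, their invariants, and LOOCV orchestration."""

import pytest

from hybridgo.classify import DecisionConfig
from hybridgo.datasets import ProteinRecord
from hybridgo.evaluate import (EvalPair, locative_count, loocv,
                               multilabel_metrics)
from hybridgo.ontology import compute_ic
from hybridgo.semsim import TermSimConfig
from hybridgo.synth import SynthConfig, make_dag, make_dataset

from conftest import all_label_sets, label_set_pairs


def metrics_oracle(pairs, n_classes):
    """Literal re-evaluation of every metric formula, independent of the
    package implementation."""
    n = len(pairs)
    acc = sum(len(t & p) / len(t | p) for t, p in pairs) / n
    prec = sum(len(t & p) / len(p) for t, p in pairs) / n
    rec = sum(len(t & p) / len(t) for t, p in pairs) / n
    f1 = sum(2 * len(t & p) / (len(t) + len(p)) for t, p in pairs) / n
    hl = sum(len(t ^ p) / n_classes for t, p in pairs) / n
    oaa = sum(t == p for t, p in pairs) / n
    ola = sum(len(t & p) for t, p in pairs) / sum(len(t) for t, p in pairs)
    return acc, prec, rec, f1, hl, oaa, ola


class TestMultilabelMetrics:
    def test_perfect_prediction(self):
        pairs = [EvalPair(frozenset({1, 2}), frozenset({1, 2})),
                 EvalPair(frozenset({3}), frozenset({3}))]
        r = multilabel_metrics(pairs, 4)
        assert (r.accuracy, r.precision, r.recall, r.f1, r.ola, r.oaa) == \
            (1, 1, 1, 1, 1, 1)
        assert r.hamming_loss == 0

    def test_single_pair_hand_values(self):
        # L = {1, 2}, predicted {1}, M = 6
        r = multilabel_metrics([EvalPair(frozenset({1, 2}), frozenset({1}))], 6)
        assert r.accuracy == pytest.approx(1 / 2)
        assert r.precision == pytest.approx(1.0)
        assert r.recall == pytest.approx(1 / 2)
        assert r.f1 == pytest.approx(2 / 3)
        assert r.hamming_loss == pytest.approx(1 / 6)
        assert r.oaa == 0.0
        assert r.ola == pytest.approx(1 / 2)

    def test_overprediction_extreme_case(self):
        """Predicting every location for every protein: OLA 1, OAA 0."""
        full = frozenset(range(1, 7))
        trues = [frozenset({1}), frozenset({2, 3}), frozenset({4, 5, 6}),
                 frozenset({1, 6})]
        pairs = [EvalPair(t, full) for t in trues]
        r = multilabel_metrics(pairs, 6)
        assert r.ola == 1.0
        assert r.oaa == 0.0

    def test_complete_misprediction(self):
        pairs = [EvalPair(frozenset({1, 2, 3}), frozenset({4, 5, 6}))]
        r = multilabel_metrics(pairs, 6)
        assert r.hamming_loss == 1.0
        assert r.accuracy == r.precision == r.recall == r.f1 == 0.0

    def test_label_outside_range_rejected(self):
        with pytest.raises(ValueError):
            multilabel_metrics([EvalPair(frozenset({7}), frozenset({1}))], 6)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            multilabel_metrics([], 4)

    @pytest.mark.parametrize("n_classes", [2, 3, 4])
    def test_enumeration_oracle_all_pairs(self, n_classes):
        """Every (true, predicted) pair with M <= 4 matches direct formulas."""
        for t, p in label_set_pairs(n_classes):
            r = multilabel_metrics([EvalPair(t, p)], n_classes)
            acc, prec, rec, f1, hl, oaa, ola = metrics_oracle([(t, p)],
                                                              n_classes)
            assert r.accuracy == pytest.approx(acc, abs=1e-12)
            assert r.precision == pytest.approx(prec, abs=1e-12)
            assert r.recall == pytest.approx(rec, abs=1e-12)
            assert r.f1 == pytest.approx(f1, abs=1e-12)
            assert r.hamming_loss == pytest.approx(hl, abs=1e-12)
            assert r.oaa == oaa
            assert r.ola == pytest.approx(ola, abs=1e-12)

    def test_ordering_chain_over_all_pairs(self):
        """OAA <= Accuracy <= F1 <= (Precision + Recall) / 2, any pair list."""
        import itertools
        for combo in itertools.islice(
                itertools.combinations(label_set_pairs(3), 2), 500):
            pairs = [EvalPair(t, p) for t, p in combo]
            r = multilabel_metrics(pairs, 3)
            assert r.oaa <= r.accuracy + 1e-12
            assert r.accuracy <= r.f1 + 1e-12
            assert r.f1 <= (r.precision + r.recall) / 2 + 1e-12

    def test_hl_zero_iff_exact(self):
        for t, p in label_set_pairs(3):
            r = multilabel_metrics([EvalPair(t, p)], 3)
            assert (r.hamming_loss == 0) == (r.oaa == 1)

    def test_locative_count(self):
        sets = [frozenset({1}), frozenset({2, 3}), frozenset({1, 2, 4})]
        assert locative_count(sets) == 6

    def test_ola_denominator_is_locative_count(self):
        pairs = [EvalPair(frozenset({1, 2}), frozenset({1})),
                 EvalPair(frozenset({3}), frozenset({3}))]
        r = multilabel_metrics(pairs, 4)
        assert r.n_locative == locative_count([p.true for p in pairs]) == 3


class TestLoocv:
    def test_two_protein_dataset_runs_two_folds(self, t1_dag, t1_ic):
        records = [ProteinRecord("p1", ["c", "c"], frozenset({1})),
                   ProteinRecord("p2", ["d"], frozenset({2}))]
        report, preds = loocv(records, t1_dag, t1_ic, 2, feature="freq",
                              decision=DecisionConfig("fixed"))
        assert len(preds) == 2
        assert report.n_actual == 2

    def test_separable_synthetic_recovers_labels(self):
        cfg = SynthConfig(n_terms=40, n_classes=3, n_proteins=24,
                          signature_strength=1.0, noise_terms_per_protein=0,
                          seed=5)
        dag, corpus = make_dag(cfg)
        ic = compute_ic(dag, corpus)
        records = make_dataset(cfg, dag)
        report, _ = loocv(records, dag, ic, 3, feature="freq",
                          decision=DecisionConfig("fixed"))
        assert report.oaa >= 0.9

    def test_global_term_space_flag_changes_only_w(self):
        """The benchmark-protocol flag must not alter fold membership or
        predictions on a dataset whose term space is fold-invariant."""
        cfg = SynthConfig(n_terms=40, n_classes=3, n_proteins=18,
                          signature_strength=1.0, seed=2)
        dag, corpus = make_dag(cfg)
        ic = compute_ic(dag, corpus)
        records = make_dataset(cfg, dag)
        r1, p1 = loocv(records, dag, ic, 3, feature="freq",
                       decision=DecisionConfig("fixed"))
        r2, p2 = loocv(records, dag, ic, 3, feature="freq",
                       decision=DecisionConfig("fixed"),
                       global_term_space=True)
        assert [acc for acc, _, _ in p1] == [acc for acc, _, _ in p2]
        # strength-1 signatures: every fold already sees all terms, so the
        # two protocols coincide
        assert r1.oaa == r2.oaa

    def test_single_protein_rejected(self, t1_dag, t1_ic):
        with pytest.raises(ValueError):
            loocv([ProteinRecord("p1", ["c"], frozenset({1}))],
                  t1_dag, t1_ic, 2)
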