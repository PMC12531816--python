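"""Rank metrics against hand-derived confusions and a brute-force HA oracle."""

import numpy as np
import pytest

from hftc.metrics import (
    REPORT_RANKS,
    confusion_table,
    evaluate,
    hierarchical_accuracy,
    mcc,
    prf,
    rank_accuracy,
)
from hftc.taxonomy import RANKS, Lineage


def _lin(*names):
    attrs = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")
    return Lineage(**dict(zip(attrs, names)))


def _random_pairs(n, rng, n_phyla=3, fanout=3, flip=0.3):
    """Random truth lineages plus predictions perturbed independently per rank
    (hierarchically inconsistent on purpose)."""
    truths, preds = [], []
    for _ in range(n):
        t = ["Fungi"]
        for depth in range(6):
            t.append(f"T{depth}_{rng.integers(n_phyla if depth == 0 else fanout)}")
        p = list(t)
        for depth in range(1, 7):
            if rng.random() < flip:
                p[depth] = f"T{depth - 1}_{rng.integers(fanout)}"
        truths.append(_lin(*t))
        preds.append(_lin(*p))
    return preds, truths


def _ha_oracle(preds, truths, rank):
    """Brute force: join the path prefix into one string and compare."""
    upto = RANKS.index(rank)
    n_ok = 0
    for p, t in zip(preds, truths):
        p_path = ";".join(str(p.name_at(r)) for r in RANKS[1 : upto + 1])
        t_path = ";".join(str(t.name_at(r)) for r in RANKS[1 : upto + 1])
        if p_path == t_path and "None" not in p_path:
            n_ok += 1
    return n_ok / len(preds)


class TestRankAccuracy:
    def test_all_correct(self):
        lins = [_lin("Fungi", "P1", "C1", "O1", "F1", "G1", "S1")] * 3
        assert rank_accuracy(lins, lins, "species") == 1.0

    def test_absent_predicted_rank_counts_incorrect(self):
        truths = [_lin("Fungi", "P1", "C1", "O1", "F1", "G1", "S1")] * 2
        preds = [_lin("Fungi", "P1")] * 2
        assert rank_accuracy(preds, truths, "class") == 0.0
        assert rank_accuracy(preds, truths, "phylum") == 1.0

    def test_three_of_four(self):
        truths = [_lin("Fungi", "P1")] * 4
        preds = [_lin("Fungi", "P1")] * 3 + [_lin("Fungi", "P2")]
        assert rank_accuracy(preds, truths, "phylum") == 0.75

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_accuracy([], [], "phylum")


class TestHierarchicalAccuracy:
    def test_spec_hand_case(self):
        # wrong phylum but right class (s2) and vice versa (s3): single-rank
        # accuracy hides the inconsistency, HA does not
        truths = [
            _lin("Fungi", "P1", "C1"), _lin("Fungi", "P1", "C1"),
            _lin("Fungi", "P1", "C1"), _lin("Fungi", "P2", "C3"),
        ]
        preds = [
            _lin("Fungi", "P1", "C1"), _lin("Fungi", "P2", "C1"),
            _lin("Fungi", "P1", "C2"), _lin("Fungi", "P2", "C3"),
        ]
        assert rank_accuracy(preds, truths, "class") == 0.75
        assert hierarchical_accuracy(preds, truths, "class") == 0.50
        assert rank_accuracy(preds, truths, "phylum") == 0.75
        assert hierarchical_accuracy(preds, truths, "phylum") == 0.75

    def test_identical_gives_one_everywhere(self):
        lins = [_lin("Fungi", "P1", "C1", "O1", "F1", "G1", "S1")] * 5
        for rank in REPORT_RANKS:
            assert hierarchical_accuracy(lins, lins, rank) == 1.0

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        preds, truths = _random_pairs(10_000, rng)
        for rank in ("phylum", "class", "order", "family", "genus", "species"):
            assert hierarchical_accuracy(preds, truths, rank) == pytest.approx(
                _ha_oracle(preds, truths, rank)
            )

    def test_ha_bounded_by_acc_and_non_increasing(self):
        rng = np.random.default_rng(7)
        preds, truths = _random_pairs(2_000, rng)
        has = []
        for rank in ("phylum", "class", "order", "family", "genus", "species"):
            ha = hierarchical_accuracy(preds, truths, rank)
            assert ha <= rank_accuracy(preds, truths, rank) + 1e-12
            has.append(ha)
        assert all(a >= b for a, b in zip(has, has[1:]))

    def test_phylum_ha_equals_phylum_acc(self):
        rng = np.random.default_rng(3)
        preds, truths = _random_pairs(500, rng)
        assert hierarchical_accuracy(preds, truths, "phylum") == rank_accuracy(
            preds, truths, "phylum"
        )


# binary confusion TP=2, FP=1, FN=0, TN=1 at the phylum rank
_BIN_TRUTH = [_lin("F", "P")] * 2 + [_lin("F", "N")] * 2
_BIN_PRED = [_lin("F", "P")] * 3 + [_lin("F", "N")]


class TestPRF:
    def test_perfect_any_averaging(self):
        lins = [_lin("F", "P1"), _lin("F", "P2"), _lin("F", "P1")]
        for avg in ("macro", "weighted", "micro"):
            assert prf(lins, lins, "phylum", avg) == (1.0, 1.0, 1.0)

    def test_binary_confusion_hand_values(self):
        # positive label: precision 2/3, recall 1, F1 0.8; negative label:
        # precision 1, recall 1/2, F1 2/3 — macro averages the two
        p, r, f1 = prf(_BIN_PRED, _BIN_TRUTH, "phylum", "macro")
        assert p == pytest.approx((2 / 3 + 1) / 2)
        assert r == pytest.approx((1 + 0.5) / 2)
        assert f1 == pytest.approx((0.8 + 2 / 3) / 2)

    def test_micro_equals_accuracy(self):
        rng = np.random.default_rng(11)
        preds, truths = _random_pairs(300, rng)
        for rank in ("phylum", "species"):
            p, r, _ = prf(preds, truths, rank, "micro")
            acc = rank_accuracy(preds, truths, rank)
            assert p == pytest.approx(acc) and r == pytest.approx(acc)

    def test_unknown_averaging_rejected(self):
        with pytest.raises(ValueError):
            prf(_BIN_PRED, _BIN_TRUTH, "phylum", "median")


class TestMCC:
    def test_perfect_is_one(self):
        lins = [_lin("F", "P1"), _lin("F", "P2")] * 3
        assert mcc(lins, lins, "phylum") == pytest.approx(1.0)

    def test_symmetric_confusion_is_zero(self):
        truths = [_lin("F", "P")] * 2 + [_lin("F", "N")] * 2
        preds = [_lin("F", "P"), _lin("F", "N"), _lin("F", "P"), _lin("F", "N")]
        assert mcc(preds, truths, "phylum") == pytest.approx(0.0)

    def test_binary_hand_value(self):
        # (2·1 − 1·0) / sqrt(3·2·2·1) = 0.57735
        assert mcc(_BIN_PRED, _BIN_TRUTH, "phylum") == pytest.approx(0.57735, abs=1e-4)

    def test_single_truth_label_warns_and_returns_zero(self):
        lins = [_lin("F", "P1")] * 3
        with pytest.warns(UserWarning):
            assert mcc(lins, lins, "phylum") == 0.0

    def test_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(9)
        preds, truths = _random_pairs(400, rng)
        before = mcc(preds, truths, "class")

        def relabel(lin):
            return lin.replace(**{"class": "X" + lin.name_at("class")})

        after = mcc([relabel(p) for p in preds], [relabel(t) for t in truths], "class")
        assert after == pytest.approx(before)


class TestEvaluate:
    def test_perfect_report_all_ones(self):
        lins = [
            _lin("F", "P1", "C1", "O1", "F1", "G1", "S1"),
            _lin("F", "P2", "C2", "O2", "F2", "G2", "S2"),
        ] * 3
        rep = evaluate(lins, lins)
        assert (rep.table.values == 1.0).all()

    def test_genus_row_equals_species_row(self):
        rng = np.random.default_rng(21)
        preds, truths = _random_pairs(500, rng)
        rep = evaluate(preds, truths)
        assert rep.row("genus") == rep.row("species")

    def test_report_invariants_on_random_sets(self):
        rng = np.random.default_rng(33)
        preds, truths = _random_pairs(1_000, rng)
        rep = evaluate(preds, truths)
        tab = rep.table
        assert ((tab["ha"] <= tab["acc"] + 1e-12)).all()
        assert (tab.drop(columns="mcc") >= 0).all().all()
        assert (tab.drop(columns="mcc") <= 1).all().all()
        ha = tab["ha"].to_numpy()
        assert all(a >= b for a, b in zip(ha, ha[1:]))

    def test_tsv_output(self, tmp_path):
        lins = [
            _lin("F", "P1", "C1", "O1", "F1", "G1", "S1"),
            _lin("F", "P2", "C2", "O2", "F2", "G2", "S2"),
        ]
        rep = evaluate(lins, lins)
        rep.to_tsv(tmp_path / "m.tsv")
        lines = (tmp_path / "m.tsv").read_text().splitlines()
        assert lines[0].split("\t") == [
            "level", "acc", "ha", "recall", "precision", "f1", "mcc",
        ]
        assert len(lines) == 7


class TestConfusionTable:
    def test_total_and_support(self):
        ct = confusion_table(_BIN_PRED, _BIN_TRUTH, "phylum")
        assert ct.total == 4
        assert ct.support() == {"N": 2, "P": 2}
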