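"""Training/prediction behaviour: consistency by construction, determinism,
degenerate configurations, k selection, persistence, and the estimator API."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from hftc.classify import (
    FeatureConfig,
    ForestConfig,
    HFTCClassifier,
    load_model,
    predict_batch,
    predict_one,
    save_model,
    select_k,
    train_hftc,
)
from hftc.hierarchy import HierarchyConfig, build_hierarchy
from hftc.metrics import evaluate
from hftc.seqio import Dataset
from hftc.taxonomy import RANKS, format_lineage

SMALL_FC = dict(n_dims=8, epochs=2, seed=5)


def test_toy_model_trains_all_nonDegenerate_forests(toy_model):
    for node in toy_model.root.walk():
        if node.needs_forest:
            forest = toy_model.forests[node.name]
            assert sorted(forest.classes_) == sorted(node.class_labels)
        else:
            assert node.name not in toy_model.forests


def test_training_replay_recovers_own_species(toy_model, toy_dataset):
    sample = toy_dataset.records[::17]
    preds = predict_batch(toy_model, Dataset(sample))
    assert all(
        p.lineage.species == r.lineage.species for p, r in zip(preds, sample)
    )


def test_predicted_lineage_is_reference_path(toy_model, toy_holdout):
    preds = predict_batch(toy_model, toy_holdout)
    for p in preds:
        assert p.error is None
        assert p.lineage.path_equal(toy_model.species_lineage[p.lineage.species])
        assert set(p.confidences) == set(RANKS[1:])
        assert all(0 <= c <= 1 for c in p.confidences.values())


def test_node_path_starts_at_root_ends_at_leaf(toy_model, toy_holdout):
    p = predict_one(toy_model, toy_holdout.records[0].sequence)
    nodes = {n.name: n for n in toy_model.root.walk()}
    assert p.node_path[0] == toy_model.root.name
    assert nodes[p.node_path[-1]].is_leaf


def test_min_confidence_above_one_stops_at_root(toy_model, toy_holdout):
    p = predict_one(toy_model, toy_holdout.records[0].sequence, min_confidence=1.01)
    assert p.lineage.kingdom is not None
    assert p.lineage.phylum is None
    assert p.confidences == {}


def test_batch_matches_recordwise_and_preserves_order(toy_model, toy_holdout):
    subset = toy_holdout.records[:6]
    batch = predict_batch(toy_model, Dataset(subset))
    assert [p.id for p in batch] == [r.id for r in subset]
    for rec, bp in zip(subset, batch):
        single = predict_one(toy_model, rec.sequence, query_id=rec.id)
        assert single.lineage == bp.lineage
        assert single.confidences == bp.confidences


def test_batch_records_per_record_failures(toy_model):
    batch = predict_batch(toy_model, ["ACGTN" + "ACGT" * 50, "ACGT" * 50])
    assert batch[0].error is not None and batch[0].lineage.kingdom is None
    assert batch[1].error is None
    with pytest.raises(ValueError, match="non-ACGT"):
        predict_one(toy_model, "ACGTN" + "ACGT" * 50)


def test_short_query_rejected(toy_model):
    with pytest.raises(ValueError, match="length"):
        predict_one(toy_model, "ACGTACG")  # shorter than k_upper=10


def test_empty_batch(toy_model):
    assert predict_batch(toy_model, []) == []


class TestDeterminismAndPersistence:
    def test_identical_seeds_identical_manifest(self, micro_dataset, tmp_path):
        dirs = []
        for tag in ("a", "b"):
            model = train_hftc(
                micro_dataset,
                HierarchyConfig(group_threshold=2),
                FeatureConfig(**SMALL_FC),
                ForestConfig(seed=5),
            )
            out = tmp_path / tag
            save_model(model, out)
            dirs.append(out)
        assert (dirs[0] / "manifest.json").read_bytes() == (
            dirs[1] / "manifest.json"
        ).read_bytes()
        for rel in ("embeddings/k7.w2v.txt", "species_lineage.tsv"):
            assert (dirs[0] / rel).read_bytes() == (dirs[1] / rel).read_bytes()

    def test_save_load_round_trip_predictions(self, micro_dataset, tmp_path):
        model = train_hftc(
            micro_dataset,
            HierarchyConfig(group_threshold=2),
            FeatureConfig(**SMALL_FC),
            ForestConfig(seed=5),
        )
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        seqs = [r.sequence for r in micro_dataset.records[:5]]
        a = predict_batch(model, seqs)
        b = predict_batch(loaded, seqs)
        assert [p.lineage for p in a] == [p.lineage for p in b]
        assert [p.confidences for p in a] == [p.confidences for p in b]

    def test_version_mismatch_requires_retrain(self, micro_dataset, tmp_path):
        model = train_hftc(
            micro_dataset, HierarchyConfig(group_threshold=2),
            FeatureConfig(**SMALL_FC), ForestConfig(seed=5),
        )
        save_model(model, tmp_path / "m")
        manifest = (tmp_path / "m" / "manifest.json").read_text()
        (tmp_path / "m" / "manifest.json").write_text(
            manifest.replace('"format_version": "1"', '"format_version": "99"')
        )
        with pytest.raises(ValueError, match="retrain required"):
            load_model(tmp_path / "m")


class TestFlatVsHierarchical:
    def test_flat_and_deep_configs_both_fit_training_set(self, micro_dataset):
        reports = {}
        for name, threshold in (("flat", math.inf), ("deep", 1)):
            model = train_hftc(
                micro_dataset,
                HierarchyConfig(group_threshold=threshold),
                FeatureConfig(**SMALL_FC),
                ForestConfig(seed=5),
            )
            preds = predict_batch(model, micro_dataset)
            rep = evaluate(preds, [r.lineage for r in micro_dataset])
            reports[name] = rep.row("species")["acc"]
        assert reports["flat"] == 1.0
        assert reports["deep"] == 1.0

    def test_flat_model_has_single_species_leaf(self, micro_dataset):
        model = train_hftc(
            micro_dataset, HierarchyConfig(group_threshold=math.inf),
            FeatureConfig(**SMALL_FC), ForestConfig(seed=5),
        )
        assert len(model.forests) == 1
        assert model.root.is_leaf


class TestSelectK:
    def test_single_candidate_returned(self, micro_dataset):
        root = build_hierarchy(micro_dataset, HierarchyConfig(group_threshold=2))
        best, scores = select_k(
            micro_dataset, root, [7], folds=3,
            feature_config=FeatureConfig(**SMALL_FC),
            forest_config=ForestConfig(seed=5, n_trees=20),
        )
        assert best == 7 and set(scores) == {7}

    def test_tie_breaks_to_smaller_k(self, micro_dataset):
        # phylum routing on well-separated data: both k reach accuracy 1.0
        root = build_hierarchy(micro_dataset, HierarchyConfig(group_threshold=2))
        best, scores = select_k(
            micro_dataset, root, [8, 7], folds=3,
            feature_config=FeatureConfig(**SMALL_FC),
            forest_config=ForestConfig(seed=5, n_trees=20),
        )
        assert scores[7] == scores[8] == 1.0  # precondition for the tie rule
        assert best == 7

    def test_hybrid_candidate_supported(self, micro_dataset):
        root = build_hierarchy(micro_dataset, HierarchyConfig(group_threshold=2))
        best, scores = select_k(
            micro_dataset, root, [(7, 8)], folds=3,
            feature_config=FeatureConfig(**SMALL_FC),
            forest_config=ForestConfig(seed=5, n_trees=20),
        )
        assert best == (7, 8)

    def test_empty_candidates_rejected(self, micro_dataset):
        root = build_hierarchy(micro_dataset, HierarchyConfig(group_threshold=2))
        with pytest.raises(ValueError):
            select_k(micro_dataset, root, [])


class TestEstimatorAPI:
    def _xy(self, dataset):
        X = [r.sequence for r in dataset]
        y = [format_lineage(r.lineage) for r in dataset]
        return X, y

    def test_fit_predict_score(self, micro_dataset):
        X, y = self._xy(micro_dataset)
        clf = HFTCClassifier(group_threshold=2, n_dims=8, epochs=2, seed=5)
        clf.fit(X, y)
        assert clf.score(X, y) == 1.0
        preds = clf.predict(X[:3])
        assert list(preds) == y[:3]
        assert len(clf.classes_) == 4

    def test_get_set_params_and_clone(self):
        clf = HFTCClassifier(k_species=6, n_trees=50)
        params = clf.get_params()
        assert params["k_species"] == 6
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            HFTCClassifier().predict(["ACGT" * 10])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="len"):
            HFTCClassifier().fit(["ACGT"], [])


def test_hybrid_node_k_override_trains_wider_forest(micro_dataset):
    fc = FeatureConfig(n_dims=8, epochs=2, seed=5, node_k={"Fungi2p": [7, 8]})
    model = train_hftc(
        micro_dataset, HierarchyConfig(group_threshold=2), fc, ForestConfig(seed=5)
    )
    assert model.forests["Fungi2p"].n_features_in_ == 2 * 2 * 8
    preds = predict_batch(model, micro_dataset.records[:3])
    assert all(p.error is None for p in preds)
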