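"""Training and prediction for the hierarchical classifier.

One random forest per hierarchy node, fit on skip-gram sequence vectors with
a level-appropriate k-mer length: long k-mers (default k=10) for routing
nodes, where deep clades separate on broad compositional differences, and
short k-mers (default k=7) for species-level leaves, where discrimination
rests on local microvariation.  One embedding per distinct k is trained on
the full training corpus and shared by every node using that k.

Prediction descends root-to-leaf taking the argmax-probability class at each
node (no confidence-based early stopping by default; a ``min_confidence``
threshold may optionally truncate the path).  The final lineage is resolved
from the species → lineage map, so every full prediction is hierarchically
consistent by construction.
"""

from __future__ import annotations

import json
import re
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import EmbeddingModel, build_corpus, embed_sequence, tokenize_bikmer, train_embedding
from .hierarchy import HierarchyConfig, HierarchyNode, build_hierarchy, node_label
from .seqio import Dataset, SeqRecord
from .taxonomy import RANKS, Lineage, format_lineage, parse_lineage

FORMAT_VERSION = "1"

_ACGT = frozenset("ACGT")


@dataclass
class FeatureConfig:
    """Embedding/tokenization knobs.  ``node_k`` overrides the per-node k-mer
    length (an int, or a list of distinct ints for hybrid-k concatenation)."""

    k_upper: int = 10
    k_species: int = 7
    stride: int = 1
    n_dims: int = 100
    window: int = 5
    epochs: int = 5
    negative: int = 5
    min_count: int = 1
    reverse_mode: str = "revcomp"
    seed: int = 0
    node_k: Dict[str, Union[int, List[int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in self.all_ks():
            if not 1 <= k <= 15:
                raise ValueError(f"k={k} outside 1..15")

    def ks_for(self, node: HierarchyNode) -> Tuple[int, ...]:
        """Ascending tuple of k values a node's features use."""
        if node.name in self.node_k:
            v = self.node_k[node.name]
            ks = (v,) if isinstance(v, int) else tuple(sorted(v))
            if len(set(ks)) != len(ks):
                raise ValueError(f"duplicate k in node_k[{node.name!r}]: {v}")
            return ks
        return (self.k_species,) if node.is_leaf else (self.k_upper,)

    def all_ks(self) -> set:
        ks = {self.k_upper, self.k_species}
        for v in self.node_k.values():
            ks.update((v,) if isinstance(v, int) else v)
        return ks


@dataclass
class ForestConfig:
    """Random-forest knobs; library defaults (100 trees, sqrt features) serve
    most sub-classifiers well.  ``node_overrides`` maps node name → kwargs."""

    n_trees: int = 100
    max_features: Union[int, str] = "sqrt"
    seed: int = 0
    n_jobs: int = 1
    node_overrides: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be ≥ 1")


@dataclass
class Prediction:
    """A predicted lineage with per-rank confidences and the visited nodes."""

    id: str
    lineage: Lineage
    confidences: Dict[str, float] = field(default_factory=dict)
    node_path: List[str] = field(default_factory=list)
    error: Optional[str] = None


@dataclass
class HFTCModel:
    """The trained artifact: hierarchy + forests + embeddings + species map."""

    root: HierarchyNode
    forests: Dict[str, RandomForestClassifier]
    embeddings: Dict[int, EmbeddingModel]
    species_lineage: Dict[str, Lineage]
    hierarchy_config: HierarchyConfig
    feature_config: FeatureConfig
    forest_config: ForestConfig
    format_version: str = FORMAT_VERSION

    def nodes(self) -> List[HierarchyNode]:
        return list(self.root.walk())

    @property
    def max_k(self) -> int:
        return max(m.k for m in self.embeddings.values())


def _node_seed(base: int, name: str) -> int:
    return (int(base) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


def _make_forest(config: ForestConfig, node_name: str) -> RandomForestClassifier:
    kwargs = dict(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        random_state=_node_seed(config.seed, node_name),
        n_jobs=config.n_jobs,
    )
    kwargs.update(config.node_overrides.get(node_name, {}))
    return RandomForestClassifier(**kwargs)


def _species_map(dataset: Dataset) -> Dict[str, Lineage]:
    out: Dict[str, Lineage] = {}
    for r in dataset:
        sp = r.lineage.species
        if sp in out and not out[sp].path_equal(r.lineage):
            raise ValueError(
                f"species name {sp!r} maps to two different lineages; "
                "species names must be unique across the reference"
            )
        out[sp] = r.lineage
    return out


def _node_records(dataset: Dataset, node: HierarchyNode) -> List[SeqRecord]:
    recs = [r for r in dataset if r.lineage.startswith(node.taxon_path)]
    if node.is_leaf:
        recs = [r for r in recs if r.lineage.species in node.species_set]
    return recs


def _embed_matrix(
    dataset: Dataset, models: Sequence[EmbeddingModel], fc: FeatureConfig
) -> np.ndarray:
    """(n_records, 2N × len(models)) matrix, models in ascending-k order."""
    parts = []
    for m in sorted(models, key=lambda m: m.k):
        block = np.empty((len(dataset.records), 2 * m.dim), dtype=np.float32)
        for i, r in enumerate(dataset.records):
            tok = tokenize_bikmer(r.sequence, m.k, fc.stride, fc.reverse_mode, r.id)
            block[i] = embed_sequence(tok, m).values
        parts.append(block)
    return np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]


def train_embeddings_for(
    dataset: Dataset, ks: Sequence[int], fc: FeatureConfig
) -> Dict[int, EmbeddingModel]:
    """One skip-gram model per distinct k, each trained on the full corpus."""
    models = {}
    for k in sorted(set(ks)):
        corpus = build_corpus(dataset, k, fc.stride, fc.reverse_mode)
        models[k] = train_embedding(
            corpus, k=k, dim=fc.n_dims, window=fc.window, epochs=fc.epochs,
            negative=fc.negative, min_count=fc.min_count,
            seed=_node_seed(fc.seed, f"k{k}"),
        )
    return models


def train_hftc(
    dataset: Dataset,
    hierarchy_config: Optional[HierarchyConfig] = None,
    feature_config: Optional[FeatureConfig] = None,
    forest_config: Optional[ForestConfig] = None,
    allow_degenerate: bool = True,
) -> HFTCModel:
    """Build the hierarchy, train embeddings and per-node forests.

    Deterministic given the configs' seeds (single-worker embedding SGD,
    per-node forest seeds derived from the forest seed and node name).
    """
    if not dataset.records:
        raise ValueError("empty dataset")
    hc = hierarchy_config or HierarchyConfig()
    fc = feature_config or FeatureConfig()
    fo = forest_config or ForestConfig()

    species_map = _species_map(dataset)
    root = build_hierarchy(dataset, hc)

    needed_ks = sorted({k for n in root.walk() if n.needs_forest for k in fc.ks_for(n)})
    embeddings = train_embeddings_for(dataset, needed_ks, fc)

    # All records embedded once per k; nodes select their rows.
    matrices = {
        k: _embed_matrix(dataset, [embeddings[k]], fc) for k in needed_ks
    }
    row_of = {r.id: i for i, r in enumerate(dataset.records)}

    forests: Dict[str, RandomForestClassifier] = {}
    for node in root.walk():
        if not node.needs_forest:
            if not allow_degenerate:
                raise ValueError(
                    f"node {node.name!r} has fewer than 2 labels and "
                    "degenerate routing is disabled"
                )
            continue
        recs = _node_records(dataset, node)
        y = [node_label(r, node) for r in recs]
        rows = [row_of[r.id] for r in recs]
        ks = fc.ks_for(node)
        X = np.concatenate([matrices[k][rows] for k in ks], axis=1)
        forest = _make_forest(fo, node.name)
        forests[node.name] = forest.fit(X, y)

    return HFTCModel(
        root=root,
        forests=forests,
        embeddings=embeddings,
        species_lineage=species_map,
        hierarchy_config=hc,
        feature_config=fc,
        forest_config=fo,
    )


def _query_vector(
    sequence: str, ks: Tuple[int, ...], model: HFTCModel, cache: Dict[int, np.ndarray]
) -> np.ndarray:
    parts = []
    for k in ks:
        if k not in cache:
            emb = model.embeddings[k]
            tok = tokenize_bikmer(
                sequence, k, model.feature_config.stride,
                model.feature_config.reverse_mode,
            )
            cache[k] = embed_sequence(tok, emb).values
        parts.append(cache[k])
    return np.concatenate(parts) if len(parts) > 1 else parts[0]


def predict_one(
    model: HFTCModel,
    sequence: str,
    min_confidence: Optional[float] = None,
    query_id: str = "?",
) -> Prediction:
    """Classify one sequence by root-to-leaf traversal.

    Ties at a node break to the lexicographically smallest class label.  With
    ``min_confidence`` set, traversal stops at the first node whose top
    probability falls below it and ranks below the last confident decision
    stay absent.
    """
    sequence = sequence.upper()
    if not set(sequence) <= _ACGT:
        bad = sorted(set(sequence) - _ACGT)
        raise ValueError(f"query {query_id!r}: non-ACGT character(s) {bad}")
    if len(sequence) < model.max_k:
        raise ValueError(
            f"query {query_id!r}: length {len(sequence)} < largest k-mer "
            f"length {model.max_k}"
        )

    cache: Dict[int, np.ndarray] = {}
    confidences: Dict[str, float] = {}
    node_path: List[str] = []
    node = model.root
    while True:
        node_path.append(node.name)
        if node.needs_forest:
            forest = model.forests[node.name]
            vec = _query_vector(sequence, model.feature_config.ks_for(node), model, cache)
            proba = forest.predict_proba(vec.reshape(1, -1))[0]
            best = int(np.argmax(proba))  # classes_ sorted: first max is smallest label
            label = str(forest.classes_[best])
            conf = float(proba[best])
        else:
            label = node.class_labels[0]
            conf = 1.0

        if min_confidence is not None and conf < min_confidence:
            partial = _partial_lineage(node.taxon_path)
            return Prediction(query_id, partial, confidences, node_path)

        if node.is_leaf:
            confidences["species"] = conf
            lineage = model.species_lineage[label]
            for rank in RANKS[1:]:  # inherited ranks carry the species confidence
                confidences.setdefault(rank, conf)
            return Prediction(query_id, lineage, confidences, node_path)

        if label in node.children and label not in node.other_species_labels.values():
            confidences[node.target_rank] = conf  # an actual taxon was decided
        node = node.children[label]


def _partial_lineage(taxon_path: Tuple[str, ...]) -> Lineage:
    names = dict(zip(("kingdom", "phylum", "class_", "order", "family"), taxon_path))
    return Lineage(**names)


def predict_batch(
    model: HFTCModel,
    queries: Union[Dataset, Sequence[str]],
    min_confidence: Optional[float] = None,
) -> List[Prediction]:
    """Map :func:`predict_one` over queries in order; per-record failures are
    recorded on the Prediction (``error`` set, empty lineage), never fatal."""
    preds = []
    for i, q in enumerate(queries):
        seq = q if isinstance(q, str) else q.sequence
        qid = f"q{i}" if isinstance(q, str) else q.id
        try:
            preds.append(predict_one(model, seq, min_confidence, query_id=qid))
        except ValueError as exc:
            preds.append(Prediction(qid, Lineage(), error=str(exc)))
    return preds


# ---------------------------------------------------------------------------
# per-level k selection


def _normalize_candidate(c) -> Tuple[int, ...]:
    return (c,) if isinstance(c, int) else tuple(sorted(c))


def select_k(
    dataset: Dataset,
    node: HierarchyNode,
    k_candidates: Sequence[Union[int, Sequence[int]]],
    folds: int = 5,
    seed: int = 0,
    feature_config: Optional[FeatureConfig] = None,
    forest_config: Optional[ForestConfig] = None,
) -> Tuple[Union[int, Tuple[int, ...]], Dict[Union[int, Tuple[int, ...]], float]]:
    """Pick the k (or hybrid-k combination) maximising stratified k-fold CV
    accuracy of ``node``'s forest; ties break to the smaller k.

    Classes with fewer than ``folds`` records are excluded from the CV with a
    warning.  Embeddings are trained on the full dataset corpus, one per
    distinct k, and shared across candidates.
    """
    if not k_candidates:
        raise ValueError("empty candidate set")
    fc = feature_config or FeatureConfig(seed=seed)
    fo = forest_config or ForestConfig(seed=seed)

    recs = _node_records(dataset, node)
    labels = np.array([node_label(r, node) for r in recs])
    keep = np.zeros(len(recs), dtype=bool)
    uniq, counts = np.unique(labels, return_counts=True)
    small = {u for u, c in zip(uniq, counts) if c < folds}
    if small:
        warnings.warn(
            f"{len(small)} class(es) at node {node.name!r} have fewer than "
            f"{folds} records and are excluded from the CV"
        )
    for i, lab in enumerate(labels):
        keep[i] = lab not in small
    recs = [r for r, k in zip(recs, keep) if k]
    labels = labels[keep]
    if len(set(labels)) < 2:
        raise ValueError(f"node {node.name!r}: fewer than 2 usable classes for CV")

    candidates = [_normalize_candidate(c) for c in k_candidates]
    all_ks = sorted({k for c in candidates for k in c})
    embeddings = train_embeddings_for(dataset, all_ks, fc)
    sub = Dataset(list(recs))
    blocks = {k: _embed_matrix(sub, [embeddings[k]], fc) for k in all_ks}

    scores: Dict[Tuple[int, ...], float] = {}
    for cand in candidates:
        X = np.concatenate([blocks[k] for k in cand], axis=1)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31 - 1))
        accs = []
        for train_idx, test_idx in cv.split(X, labels):
            forest = _make_forest(fo, node.name)
            forest.fit(X[train_idx], labels[train_idx])
            accs.append(float(np.mean(forest.predict(X[test_idx]) == labels[test_idx])))
        scores[cand] = float(np.mean(accs))

    ordered = sorted(scores)  # ascending k; ties resolve to the smaller
    best = max(ordered, key=lambda c: scores[c])
    for c in ordered:  # first candidate achieving the max
        if scores[c] == scores[best]:
            best = c
            break
    unpack = lambda c: c[0] if len(c) == 1 else c
    return unpack(best), {unpack(c): s for c, s in scores.items()}


# ---------------------------------------------------------------------------
# persistence


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", name)


def save_model(model: HFTCModel, model_dir: Union[str, Path]) -> None:
    """Write the model directory: manifest.json, word2vec-text embeddings,
    joblib forests, species_lineage.tsv.  No timestamps: identical training
    runs produce byte-identical manifests."""
    model_dir = Path(model_dir)
    (model_dir / "embeddings").mkdir(parents=True, exist_ok=True)
    (model_dir / "forests").mkdir(exist_ok=True)

    emb_files = {}
    for k, emb in sorted(model.embeddings.items()):
        rel = f"embeddings/k{k}.w2v.txt"
        emb.save(model_dir / rel)
        emb_files[str(k)] = {"path": rel, "train_params": emb.train_params}
    forest_files = {}
    for name, forest in sorted(model.forests.items()):
        rel = f"forests/{_safe_name(name)}.bin"
        joblib.dump(forest, model_dir / rel)
        forest_files[name] = rel
    with open(model_dir / "species_lineage.tsv", "w", encoding="utf-8") as fh:
        for sp, lin in sorted(model.species_lineage.items()):
            fh.write(f"{sp}\t{format_lineage(lin)}\n")

    manifest = {
        "format_version": model.format_version,
        "hierarchy_config": asdict(model.hierarchy_config),
        "feature_config": asdict(model.feature_config),
        "forest_config": asdict(model.forest_config),
        "hierarchy": model.root.to_dict(),
        "embeddings": emb_files,
        "forests": forest_files,
        "species_lineage": "species_lineage.tsv",
    }
    with open(model_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(model_dir: Union[str, Path]) -> HFTCModel:
    model_dir = Path(model_dir)
    with open(model_dir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"model format_version {manifest.get('format_version')!r} != "
            f"{FORMAT_VERSION!r}: retrain required"
        )
    root = HierarchyNode.from_dict(manifest["hierarchy"])
    embeddings = {}
    for k_str, entry in manifest["embeddings"].items():
        embeddings[int(k_str)] = EmbeddingModel.load(
            model_dir / entry["path"], k=int(k_str), train_params=entry["train_params"]
        )
    forests = {
        name: joblib.load(model_dir / rel)
        for name, rel in manifest["forests"].items()
    }
    species_lineage = {}
    with open(model_dir / manifest["species_lineage"], encoding="utf-8") as fh:
        for line in fh:
            sp, tax = line.rstrip("\n").split("\t")
            species_lineage[sp] = parse_lineage(tax)
    return HFTCModel(
        root=root,
        forests=forests,
        embeddings=embeddings,
        species_lineage=species_lineage,
        hierarchy_config=HierarchyConfig(**manifest["hierarchy_config"]),
        feature_config=FeatureConfig(**manifest["feature_config"]),
        forest_config=ForestConfig(**manifest["forest_config"]),
        format_version=manifest["format_version"],
    )


# ---------------------------------------------------------------------------
# sklearn estimator facade


class HFTCClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchical taxonomic classifier with the sklearn estimator API.

    ``fit(X, y)`` takes raw ACGT sequences and taxonomy strings (or
    :class:`Lineage` objects); ``predict(X)`` returns canonical full-lineage
    strings, so ``score`` is species-level accuracy (full-path equality).
    Use :meth:`predict_records` for per-rank confidences.

    >>> clf = HFTCClassifier(n_dims=16, epochs=2)        # doctest: +SKIP
    >>> clf.fit(train_seqs, train_tax).predict(query_seqs)
    """

    def __init__(self, group_threshold=1000, threshold_unit="species",
                 max_leaf_classes=None, k_upper=10, k_species=7, stride=1,
                 n_dims=100, window=5, epochs=5, negative=5, min_count=1,
                 reverse_mode="revcomp", n_trees=100, max_features="sqrt",
                 n_jobs=1, seed=0):
        self.group_threshold = group_threshold
        self.threshold_unit = threshold_unit
        self.max_leaf_classes = max_leaf_classes
        self.k_upper = k_upper
        self.k_species = k_species
        self.stride = stride
        self.n_dims = n_dims
        self.window = window
        self.epochs = epochs
        self.negative = negative
        self.min_count = min_count
        self.reverse_mode = reverse_mode
        self.n_trees = n_trees
        self.max_features = max_features
        self.n_jobs = n_jobs
        self.seed = seed

    def _dataset(self, X, y=None, sh_ids=None) -> Dataset:
        records = []
        for i, seq in enumerate(X):
            lin = y[i] if y is not None else Lineage()
            if not isinstance(lin, Lineage):
                lin = parse_lineage(lin)
            sh = sh_ids[i] if sh_ids is not None else None
            records.append(SeqRecord(f"x{i}", str(seq).upper(), lin, sh))
        return Dataset(records)

    def fit(self, X, y, sh_ids=None):
        if len(X) != len(y):
            raise ValueError(f"len(X)={len(X)} != len(y)={len(y)}")
        if len(X) == 0:
            raise ValueError("empty training set")
        dataset = self._dataset(X, y, sh_ids)
        self.model_ = train_hftc(
            dataset,
            HierarchyConfig(
                group_threshold=self.group_threshold,
                threshold_unit=self.threshold_unit,
                max_leaf_classes=self.max_leaf_classes,
            ),
            FeatureConfig(
                k_upper=self.k_upper, k_species=self.k_species,
                stride=self.stride, n_dims=self.n_dims, window=self.window,
                epochs=self.epochs, negative=self.negative,
                min_count=self.min_count, reverse_mode=self.reverse_mode,
                seed=self.seed,
            ),
            ForestConfig(
                n_trees=self.n_trees, max_features=self.max_features,
                seed=self.seed, n_jobs=self.n_jobs,
            ),
        )
        self.classes_ = np.array(sorted(
            format_lineage(lin) for lin in self.model_.species_lineage.values()
        ))
        return self

    def predict_records(self, X, min_confidence=None) -> List[Prediction]:
        if not hasattr(self, "model_"):
            raise AttributeError("HFTCClassifier is not fitted")
        return predict_batch(self.model_, list(X), min_confidence)

    def predict(self, X) -> np.ndarray:
        preds = self.predict_records(X)
        return np.array([format_lineage(p.lineage) for p in preds])

    def score(self, X, y, sample_weight=None) -> float:
        """Species-level accuracy (full-path string equality)."""
        canon = [
            format_lineage(t if isinstance(t, Lineage) else parse_lineage(t))
            for t in y
        ]
        return float(np.mean(self.predict(X) == np.array(canon)))
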