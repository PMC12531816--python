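# Methods

## Problem and model

Fungal ITS barcode classification maps a query sequence to a 7-rank lineage
(kingdom, phylum, class, order, family, genus, species).  Reference sets of
UNITE type cluster sequences into species hypotheses (SHs, species proxies at
a fixed similarity threshold) and are heavily imbalanced: a few clades hold
most species, and most taxa are too small to support a dedicated classifier.

The package combines three components:

1. **Bi-kmer skip-gram embeddings.**  A sequence is two k-mer "sentences"
   (forward and reverse-complement orientation, sliding window k, stride L).
   A skip-gram model with negative sampling is trained on all sentences of
   the training set; a sequence embeds as the concatenation of its two
   orientation-wise mean k-mer vectors (2N dimensions).  Averaging discards
   position — a known limitation — but collapses the 4^k KFV space to 200
   dimensions while preserving compositional context.
2. **A recursive tree of random-forest sub-classifiers.**  Phyla with ≥ T
   species are expanded rank by rank (class, order, family); taxa below T
   merge into an "Other" class classified directly to species.  Family is the
   deepest routing rank: genus is bypassed and recovered from the species →
   lineage map, which enforces hierarchical consistency by construction.
   When *every* child of a node falls below T, the node collapses to a single
   direct species-level leaf (`<taxon>_c2s`-style nodes); a node left with a
   single class routes deterministically and trains no forest.
3. **Path-aware evaluation.**  Alongside per-rank accuracy, precision,
   recall, F1 and multi-class MCC, hierarchical accuracy (HA) counts a record
   only if every rank from phylum down to the evaluated rank is correct.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `k_upper` | 10 | k-mer length for routing nodes; longer k-mers give sparser, more clade-distinctive motifs |
| `k_species` | 7 | k-mer length for species leaves; shorter k-mers resolve point mutations and short indels |
| stride `L` | 1 | window stride; 1 keeps every overlapping k-mer (no canonical value exists, configurable) |
| `n_dims` (N) | 100 | per-direction embedding dimension → 2N = 200 per sequence |
| `window`, `negative`, `epochs`, `min_count` | 5, 5, 5, 1 | skip-gram training; standard word2vec-style values, fixed seed, single worker |
| `group_threshold` (T) | 1000 | minimum species count for a taxon to earn its own sub-classifier; counted in **species** (configurable to sequences) |
| `min_sh_size`, `per_sh_sample` | 10, 10 | curation: drop SHs with < 10 records, then subsample every SH to exactly 10 |
| `n_trees`, `max_features` | 100, "sqrt" | random-forest defaults; per-node overrides exposed |

Argmax ties at a node break to the lexicographically smallest label.  A
direction whose tokens are all out-of-vocabulary contributes a zero
half-vector (counted and logged).  Queries shorter than the largest k in use,
or containing non-ACGT characters, are rejected per record (a batch
continues).  No confidence threshold is applied by default; `min_confidence`
optionally truncates the path at the last confident decision.

## Numerical and design choices

* **Skip-gram trainer.**  Implemented in vectorized numpy: dynamic context
  windows (radius ~ U{1..window}), unigram^0.75 noise distribution, linearly
  decaying learning rate (0.025 → 1e-4), mini-batch SGD (batch 4096) where
  gradients of rows colliding within a batch are summed via a sparse one-hot
  product.  Deterministic for a fixed seed; training twice yields identical
  vector tables.
* **"Reverse direction"** is reverse *complement* (biological convention);
  plain string reversal is available behind `reverse_mode="reverse"`.
* **One embedding per k**, trained on the full training corpus and shared by
  all nodes using that k (per-node retraining would multiply cost with no
  separability gain at this scale); both orientations train one model as
  separate sentences, since pooling only needs the token lists kept apart.
* **Subsampling determinism.**  Per-SH draws sort record ids and key the RNG
  on (seed, SH id), so curation output is independent of file order.
* **Threshold unit.**  T counts species (SHs), not sequences; with 10
  sequences per SH the two differ only by a factor, and species is the unit
  the grouping rule is stated in.
* **Ambiguity matching** is case-insensitive substring matching on every rank
  name (tokens: "unidentified", "incertae sedis", "incertae_sedis";
  configurable).
* **Metric aggregation.**  Precision/recall/F1 default to weighted
  one-vs-rest averaging (macro and micro are selectable); MCC uses the
  multi-class confusion-matrix generalization and is defined as 0 when a
  marginal is degenerate.  Records the model declined to classify at a rank
  count as incorrect there, keeping denominators fixed.
* **Genus row.**  `evaluate` reports the species-level decision as the genus
  row: genus is never independently predicted, so its metrics restate the
  species decision and the two rows are identical by construction.  The
  standalone `rank_accuracy`/`prf`/`mcc` operations compare genus names
  genuinely when called with `rank="genus"`.
* **Model persistence** writes a timestamp-free JSON manifest, word2vec-text
  embeddings, joblib forests and a species→lineage TSV; identical seeds give
  byte-identical manifests and embedding files.  A manifest format-version
  mismatch demands retraining rather than guessing.

## The synthetic data generator

`simulate` evolves sequences down a balanced taxonomy: a random kingdom
ancestor, per-rank ancestor mutation with substitution rates decreasing
toward the tips (phylum 0.30, class 0.15, order 0.10, family 0.06, genus
0.04, species 0.02), and per-record within-species noise (0.005 substitution,
0.001 single-base indel rate).  Defaults give 2×2×1×2×2×2 = 32 species,
600 bp sequences and 12 records per species, so curation's subsample-to-10
step is exercised; optional noise records (2% ambiguous-labeled, 2% with an
injected `N`) exercise the filters, and an optional homonym mode reuses a
rank name across parents to stress path-aware metrics.  Held-out records are
drawn from an RNG stream disjoint from the training draw.

This emulates the *divergence structure* real ITS data only approximates: it
has no length heterogeneity, chimeras, secondary-structure constraints,
taxonomic imbalance or annotation error.  Tests passing on it show that the
pipeline recovers taxonomy when the signal is present at the assumed
rank-wise scales — not that real-data accuracies transfer.

## Problem sizes used in tests and the acceptance script

The end-to-end recovery runs the default 32-species simulation (320 curated
records) with the default embedding/forest settings and `group_threshold=4` —
the scaled analog of T = 1000 at reference scale (both thresholds sit between
typical small-taxon and large-taxon species counts), chosen so the toy tree
contains routing nodes, an Other leaf and species leaves rather than
collapsing flat.  Curation arithmetic is checked at full reference scale
(25,163 SHs × 10 records) with minimal 11-bp sequences.  The
hierarchical-accuracy oracle comparison uses 10⁴ randomized lineage pairs
over a deliberately homonym-rich name space.

## Known limitations

* Average pooling loses positional signal; closely related species separated
  by motif order rather than composition may not be resolved.
* The fixed 7-rank fungal scheme is assumed; rank-flexible taxonomies and
  sub-species resolution are out of scope.
* Species names must be unique across the reference (they key the
  species → lineage map); SH ids are the intended safeguard.
* Embedding training is CPU-bound and single-worker by design (determinism
  over speed); reference-scale corpora would need a parallel trainer.
* Probabilities from the forests are not calibrated; `min_confidence` is a
  filter, not a calibrated abstention rule.
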