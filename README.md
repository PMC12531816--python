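# hftc — hierarchical fungal ITS taxonomic classification

`hftc` assigns full taxonomic lineages (kingdom → species) to fungal ITS
(internal transcribed spacer) amplicon sequences.  It is aimed at
metagenomics and mycology workflows that classify reads or OTU/SH
representatives against a UNITE-style reference and care about two things
flat classifiers neglect: **feature dimensionality** and **hierarchical
consistency** (a read assigned to one phylum should not receive a genus from
another).

## Method

**Features.**  Each sequence is tokenized into *Bi-kmers*: k-mers taken with
a sliding window of length *k* and stride *L* from both the given orientation
and its reverse complement.  Each orientation is a "sentence" whose words are
k-mers; a skip-gram word-embedding model with negative sampling maps every
k-mer to an *N*-dimensional vector (N = 100).  A sequence is pooled to the
concatenation of its forward-token mean and reverse-token mean — a dense
2N = 200-dimensional vector, versus 4^k (16,384 at k = 7) for the classical
k-mer frequency vector (KFV), which is also provided as a baseline
transformer.

**Classifier.**  Training lineages are compiled into a tree of random-forest
sub-classifiers.  The root assigns phyla; any taxon with at least *T* species
(default T = 1,000) gets its own sub-classifier one rank deeper, down to
family at the deepest; taxa below *T* are merged into an "Other" class that
is classified **directly to species**.  Genus is never routed — the genus of
a prediction falls out of the species → lineage map, so every prediction is
a root-to-species path of the reference taxonomy by construction.  Routing
nodes embed with k = 10, species-level leaves with k = 7 (long k-mers
separate deep clades, short k-mers resolve species-level point variation);
per-node k can be re-selected by cross-validation (`select_k`).

**Evaluation.**  Per rank: accuracy, precision/recall/F1 (macro / weighted /
micro), multi-class MCC, and *hierarchical accuracy* (HA) — the fraction of
records predicted correctly at **every** rank from phylum down to the
evaluated rank, which penalises the inconsistent predictions that single-rank
accuracy hides.

## Worked example

```python
from hftc import (SimConfig, generate_dataset, generate_holdout, curate,
                  CurationConfig, HFTCClassifier, evaluate)
from hftc.taxonomy import format_lineage

sim = SimConfig(seed=42)                       # 32 species, 12 seqs/species
train = curate(generate_dataset(sim), CurationConfig(seed=1))
X = [r.sequence for r in train]
y = [format_lineage(r.lineage) for r in train]

clf = HFTCClassifier(group_threshold=4, n_dims=16, epochs=2, seed=5)
clf.fit(X, y)

hold = generate_holdout(sim, 3)                # 96 fresh records
preds = clf.predict_records([r.sequence for r in hold])
print(evaluate(preds, [r.lineage for r in hold]).table)
```

prints (this run):

```
              acc        ha    recall  precision        f1       mcc
phylum   1.000000  1.000000  1.000000   1.000000  1.000000  1.000000
class    1.000000  1.000000  1.000000   1.000000  1.000000  1.000000
order    1.000000  1.000000  1.000000   1.000000  1.000000  1.000000
family   0.989583  0.989583  0.989583   0.990385  0.989565  0.988218
genus    0.958333  0.958333  0.958333   0.968750  0.957143  0.957418
species  0.958333  0.958333  0.958333   0.968750  0.957143  0.957418
```

Reading the table: held-out records are routed perfectly down to order;
~1% are confused between sister families and ~4% between congeneric species
(the simulation separates species by only 2% substitution plus 0.5%
within-species noise).  `ha == acc` at every rank and the genus row equals
the species row because predictions are hierarchically consistent by
construction and genus is derived from the species decision.  With the
default embedding size (`n_dims=100, epochs=5`) the same experiment reaches
species accuracy 1.0.

The same pipeline is available from the shell:

```bash
hftc simulate --out-dir sim --seed 11
hftc curate sim/simulated.fasta sim/simulated.tsv --out-dir cur --seed 3
hftc train cur/curated.fasta cur/curated.tsv --model-dir model --seed 5
hftc predict model queries.fasta --out predictions.tsv
hftc evaluate predictions.tsv truth.tsv --out metrics.tsv
```

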