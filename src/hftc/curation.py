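"""Reference-set curation: the four-step preprocessing pipeline.

Mirrors the curation applied to UNITE-style ITS reference data before
training:

1. drop records with ambiguous/unidentified labels or no species annotation;
2. drop sequences containing non-ACGT characters (or shorter than the largest
   k-mer in use);
3. drop species hypotheses (SHs) with fewer than ``min_sh_size`` records;
4. subsample every SH down to exactly ``per_sh_sample`` records, uniformly at
   random without replacement.

Every step appends a provenance count, so removed+retained telescopes from the
raw input to the curated output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import Dataset, SeqRecord

_STANDARD_BASES = frozenset("ACGT")

DEFAULT_AMBIGUOUS_TOKENS = ("unidentified", "incertae sedis", "incertae_sedis")


@dataclass
class CurationConfig:
    """Knobs of the curation pipeline.

    ``min_sh_size``/``per_sh_sample`` default to 10, the reference protocol for
    balancing species-hypothesis representation; ``min_length`` should be at
    least the largest k-mer length used downstream (11 covers k ∈ 7..11).
    """

    ambiguous_tokens: Sequence[str] = DEFAULT_AMBIGUOUS_TOKENS
    min_sh_size: int = 10
    per_sh_sample: int = 10
    seed: int = 0
    min_length: int = 11

    def __post_init__(self) -> None:
        if self.min_sh_size < 1 or self.per_sh_sample < 1 or self.min_length < 1:
            raise ValueError("min_sh_size, per_sh_sample and min_length must be ≥ 1")


def _is_ambiguous(record: SeqRecord, tokens: Sequence[str]) -> bool:
    if record.lineage.species is None:
        return True
    lowered = [t.lower() for t in tokens]
    for _rank, name in record.lineage.iter_names():
        low = name.lower()
        if any(tok in low for tok in lowered):
            return True
    return False


def drop_ambiguous(dataset: Dataset, config: CurationConfig) -> Dataset:
    """Remove records lacking a species rank or matching an ambiguous token
    (case-insensitive substring match on every rank name)."""
    kept = [r for r in dataset if not _is_ambiguous(r, config.ambiguous_tokens)]
    return dataset.with_records(kept, "drop_ambiguous")


def drop_nonstandard(dataset: Dataset, config: CurationConfig) -> Dataset:
    """Remove sequences with non-ACGT characters or length < ``min_length``."""
    kept = [
        r
        for r in dataset
        if len(r.sequence) >= config.min_length and set(r.sequence) <= _STANDARD_BASES
    ]
    return dataset.with_records(kept, "drop_nonstandard")


def _group_by_sh(dataset: Dataset) -> dict:
    groups: dict = {}
    for r in dataset:
        sh = r.sh
        if sh is None:
            raise ValueError(f"record {r.id!r} has neither sh_id nor species name")
        groups.setdefault(sh, []).append(r)
    return groups


def drop_small_sh(dataset: Dataset, config: CurationConfig) -> Dataset:
    """Remove every record of an SH represented by < ``min_sh_size`` records."""
    groups = _group_by_sh(dataset)
    big = {sh for sh, recs in groups.items() if len(recs) >= config.min_sh_size}
    kept = [r for r in dataset if r.sh in big]
    return dataset.with_records(kept, "drop_small_sh")


def subsample_per_sh(dataset: Dataset, config: CurationConfig) -> Dataset:
    """Retain exactly ``per_sh_sample`` records per SH, drawn uniformly without
    replacement.

    Records are sorted by id within each SH before drawing and the per-SH RNG
    is keyed on (seed, SH id), so the retained id set is a function of the
    dataset *content* and seed only, not of file order.
    """
    groups = _group_by_sh(dataset)
    keep_ids = set()
    for sh in sorted(groups):
        recs = sorted(groups[sh], key=lambda r: r.id)
        if len(recs) < config.per_sh_sample:
            raise ValueError(
                f"SH {sh!r} has {len(recs)} records, fewer than "
                f"per_sh_sample={config.per_sh_sample}; run drop_small_sh first"
            )
        if len(recs) == config.per_sh_sample:
            keep_ids.update(r.id for r in recs)
            continue
        rng = np.random.default_rng([config.seed, zlib.crc32(sh.encode("utf-8"))])
        chosen = rng.choice(len(recs), size=config.per_sh_sample, replace=False)
        keep_ids.update(recs[i].id for i in chosen)
    kept = [r for r in dataset if r.id in keep_ids]
    return dataset.with_records(kept, "subsample_per_sh")


def curate(dataset: Dataset, config: CurationConfig = None) -> Dataset:
    """Run the full pipeline; the result has exactly ``per_sh_sample`` records
    per surviving SH and all sequences over ``[ACGT]+`` with length ≥
    ``min_length``."""
    config = config or CurationConfig()
    if not dataset.provenance:
        from .seqio import ProvenanceStep

        dataset = Dataset(
            list(dataset.records),
            [ProvenanceStep("input", 0, len(dataset.records))],
        )
    out = drop_ambiguous(dataset, config)
    out = drop_nonstandard(out, config)
    out = drop_small_sh(out, config)
    out = subsample_per_sh(out, config)
    return out
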