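"""Synthetic ITS-like datasets with taxonomy-shaped divergence.

Sequences are evolved down a balanced taxonomy: a kingdom ancestor is drawn
uniformly over ACGT, each child taxon's ancestor is a mutated copy of its
parent's, and per-rank substitution rates *decrease* toward the tips — phyla
differ by broad divergence while congeneric species differ only by point
mutations and rare short indels.  That mirrors the structure of real ITS
reference data this kind of classifier exploits (long k-mers separate deep
clades; short k-mers resolve species-level microvariation).

Record sampling is stream-separated from taxonomy generation, so held-out
query records for the same taxonomy can be drawn without disturbing the
training draw.  Output is byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqio import Dataset, ProvenanceStep, SeqRecord
from .taxonomy import Lineage

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Rank order used for descent (kingdom ancestor is drawn, not mutated).
_DESCENT = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Default taxon counts give 2×2×1×2×2×2 = 32 species; 12 sequences per
    species exercise the subsample-to-10 curation step.  Substitution rates
    are the fraction of positions mutated when descending one rank and
    decrease strictly with depth; ``within_species_rate`` scatters records
    around their species ancestor.  ``seq_length`` is ITS-scale (≈600 bp).
    """

    n_phyla: int = 2
    classes_per_phylum: int = 2
    orders_per_class: int = 1
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    seq_length: int = 600
    sub_rates: Dict[str, float] = field(
        default_factory=lambda: {
            "phylum": 0.30,
            "class": 0.15,
            "order": 0.10,
            "family": 0.06,
            "genus": 0.04,
            "species": 0.02,
        }
    )
    within_species_rate: float = 0.005
    indel_rate: float = 0.001
    seqs_per_species: int = 12
    ambiguous_fraction: float = 0.02
    nonacgt_fraction: float = 0.02
    homonym_rank: Optional[str] = None
    kingdom: str = "Fungi"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_phyla, self.classes_per_phylum, self.orders_per_class,
            self.families_per_order, self.genera_per_family, self.species_per_genus,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all per-rank counts must be ≥ 1")
        rates = [self.sub_rates[r] for r in _DESCENT]
        if any(not (0 <= x < 1) for x in rates + [self.within_species_rate, self.indel_rate]):
            raise ValueError("all rates must lie in [0, 1)")
        if self.seq_length < 1 or self.seqs_per_species < 1:
            raise ValueError("seq_length and seqs_per_species must be ≥ 1")

    @property
    def n_species(self) -> int:
        return (
            self.n_phyla * self.classes_per_phylum * self.orders_per_class
            * self.families_per_order * self.genera_per_family * self.species_per_genus
        )


def mutate(
    sequence: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Point-substitute each position with probability ``sub_rate`` (to a
    uniformly chosen *different* base) and apply single-base indels per
    position with probability ``indel_rate`` (deletion or insertion, equally
    likely).  ``sub_rate=1`` forces a substitution at every position."""
    if not (0 <= sub_rate <= 1 and 0 <= indel_rate < 1):
        raise ValueError("sub_rate must lie in [0, 1], indel_rate in [0, 1)")
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    idx = np.searchsorted(_BASES, codes)  # ACGT are sorted ascii
    n = len(idx)
    sub_mask = rng.random(n) < sub_rate
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        idx[sub_mask] = (idx[sub_mask] + shift) % 4
    if indel_rate > 0:
        u = rng.random(n)
        pieces: List[np.ndarray] = []
        last = 0
        for pos in np.flatnonzero(u < indel_rate):
            pieces.append(idx[last:pos])
            if u[pos] < indel_rate / 2:  # deletion
                pass
            else:  # insertion of a random base before this position
                pieces.append(np.array([rng.integers(0, 4)], dtype=idx.dtype))
                pieces.append(idx[pos : pos + 1])
            last = pos + 1
        pieces.append(idx[last:])
        idx = np.concatenate(pieces) if len(pieces) > 1 else idx
    return _BASES[idx].tobytes().decode("ascii")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _ancestors(config: SimConfig) -> List[Tuple[Lineage, str]]:
    """(full lineage, species ancestor sequence) per species; deterministic
    function of the config (uses its own RNG stream)."""
    rng = np.random.default_rng([config.seed, 0])
    out: List[Tuple[Lineage, str]] = []
    king_seq = _random_seq(config.seq_length, rng)

    def descend(rank_i: int, names: Tuple[str, ...], seq: str) -> None:
        rank = _DESCENT[rank_i]
        count = (
            config.n_phyla, config.classes_per_phylum, config.orders_per_class,
            config.families_per_order, config.genera_per_family,
            config.species_per_genus,
        )[rank_i]
        letter = rank[0].upper()  # P, C, O, F, G, S
        for j in range(1, count + 1):
            if config.homonym_rank == rank:
                name = f"{letter}{j}"  # deliberately reused across parents
            else:
                name = f"{names[-1]}_{letter}{j}" if len(names) > 1 else f"{letter}{j}"
            child_seq = mutate(seq, config.sub_rates[rank], 0.0, rng)
            child_names = names + (name,)
            if rank == "species":
                lin = Lineage(*child_names)
                out.append((lin, child_seq))
            else:
                descend(rank_i + 1, child_names, child_seq)

    descend(0, (config.kingdom,), king_seq)
    return out


def _draw_records(
    ancestors: Sequence[Tuple[Lineage, str]],
    n_per_species: int,
    config: SimConfig,
    rng: np.random.Generator,
    id_suffix: str = "",
) -> List[SeqRecord]:
    records = []
    for lin, anc in ancestors:
        for i in range(1, n_per_species + 1):
            seq = mutate(anc, config.within_species_rate, config.indel_rate, rng)
            rid = f"{lin.species}{id_suffix}_r{i}"
            records.append(SeqRecord(rid, seq, lin, sh_id=lin.species))
    return records


def generate_dataset(config: SimConfig = None) -> Dataset:
    """Generate the labeled training pool (core records plus noise records).

    Noise records are *extra*: ``ambiguous_fraction`` of the core count get an
    unidentified genus and no species rank; ``nonacgt_fraction`` get one ``N``
    injected.  Curation therefore removes exactly the noise plus the per-SH
    oversampling.
    """
    config = config or SimConfig()
    ancestors = _ancestors(config)
    rng = np.random.default_rng([config.seed, 1])
    records = _draw_records(ancestors, config.seqs_per_species, config, rng)
    n_core = len(records)

    n_amb = round(config.ambiguous_fraction * n_core)
    for i in range(1, n_amb + 1):
        lin, anc = ancestors[int(rng.integers(0, len(ancestors)))]
        seq = mutate(anc, config.within_species_rate, config.indel_rate, rng)
        noisy = Lineage(
            lin.kingdom, lin.phylum, lin.class_, lin.order, lin.family,
            "Incertae_sedis", None,
        )
        records.append(SeqRecord(f"amb_r{i}", seq, noisy, sh_id=f"amb{i}"))

    n_bad = round(config.nonacgt_fraction * n_core)
    for i in range(1, n_bad + 1):
        lin, anc = ancestors[int(rng.integers(0, len(ancestors)))]
        seq = list(mutate(anc, config.within_species_rate, config.indel_rate, rng))
        seq[int(rng.integers(0, len(seq)))] = "N"
        records.append(SeqRecord(f"badbase_r{i}", "".join(seq), lin, sh_id=lin.species))

    return Dataset(records, [ProvenanceStep("input", 0, len(records))])


def generate_holdout(config: SimConfig, n_per_species: int, subseed: int = 0) -> Dataset:
    """Fresh records from the same taxonomy (disjoint RNG stream from the
    training draw), for held-out evaluation."""
    ancestors = _ancestors(config)
    rng = np.random.default_rng([config.seed, 2, subseed])
    records = _draw_records(ancestors, n_per_species, config, rng, id_suffix="_h")
    return Dataset(records, [ProvenanceStep("input", 0, len(records))])
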