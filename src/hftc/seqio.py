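"""File I/O: FASTA + taxonomy sources, prediction tables, embedding vectors.

Fixed dialects (all files UTF-8, TSVs use literal tabs, no quoting):

* FASTA headers are either plain ids, ``>id|taxonomy`` or ``>id|sh_id|taxonomy``
  (the UNITE-release style); the record id is the first ``|``/whitespace-
  delimited token.
* A taxonomy TSV maps ``id<TAB>taxonomy_string[<TAB>sh_id]``.
* Predictions are written as a TSV with one row per query, a full lineage and
  per-rank confidences to four decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .taxonomy import RANKS, Lineage, format_lineage, parse_lineage

PREDICTION_COLUMNS = (
    "id", "kingdom", "phylum", "class", "order", "family", "genus", "species",
    "conf_phylum", "conf_class", "conf_order", "conf_family", "conf_species",
)


@dataclass
class SeqRecord:
    """An identified ITS sequence with its lineage and species-hypothesis id.

    ``sh_id`` defaults to the species name when the source carries no explicit
    species hypothesis (SHs act as species proxies).
    """

    id: str
    sequence: str
    lineage: Lineage
    sh_id: Optional[str] = None

    @property
    def sh(self) -> Optional[str]:
        return self.sh_id if self.sh_id is not None else self.lineage.species


@dataclass
class ProvenanceStep:
    step: str
    removed: int
    retained: int


@dataclass
class Dataset:
    """An ordered collection of records plus curation provenance counts."""

    records: List[SeqRecord]
    provenance: List[ProvenanceStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def with_records(self, records: Sequence[SeqRecord], step: str) -> "Dataset":
        """New dataset retaining ``records``, appending a provenance step."""
        removed = len(self.records) - len(records)
        if removed < 0:
            raise ValueError("a curation step cannot add records")
        prov = list(self.provenance) + [ProvenanceStep(step, removed, len(records))]
        return Dataset(list(records), prov)

    def ids(self) -> List[str]:
        return [r.id for r in self.records]


def _parse_header(description: str) -> Tuple[str, Optional[str], Optional[str]]:
    """Split a FASTA description into (id, sh_id, taxonomy string)."""
    head = description.strip()
    fields = head.split("|")
    rec_id = re.split(r"[\s|]", head, maxsplit=1)[0]
    if len(fields) == 1:
        return rec_id, None, None
    if len(fields) == 2:
        return rec_id, None, fields[1].strip()
    if len(fields) == 3:
        return rec_id, fields[1].strip() or None, fields[2].strip()
    raise ValueError(f"malformed FASTA header (more than 3 '|' fields): {head!r}")


def read_taxonomy_tsv(path: Union[str, Path]) -> dict:
    """Read an ``id → (taxonomy string, sh_id)`` map from a 2/3-column TSV."""
    table = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected ≥2 tab-separated columns")
            rec_id, tax = cols[0], cols[1]
            sh = cols[2] if len(cols) > 2 and cols[2] else None
            if rec_id in table:
                raise ValueError(f"{path}: duplicate id {rec_id!r}")
            table[rec_id] = (tax, sh)
    return table


def read_dataset(
    fasta_path: Union[str, Path],
    tax_source: Union[str, Path] = "header",
    convert_u: bool = False,
) -> Dataset:
    """Read a FASTA plus taxonomy into a :class:`Dataset`.

    ``tax_source`` is the literal string ``"header"`` (taxonomy embedded in the
    FASTA headers) or the path of a taxonomy TSV.  Sequences are uppercased;
    ``U`` is converted to ``T`` only when ``convert_u`` is set.
    """
    tax_map = None
    if tax_source != "header":
        tax_map = read_taxonomy_tsv(tax_source)

    records: List[SeqRecord] = []
    seen = set()
    missing = []
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        rec_id, sh, tax = _parse_header(entry.description)
        if tax_map is not None:
            if rec_id not in tax_map:
                missing.append(rec_id)
                continue
            tax, sh = tax_map[rec_id]
        if tax is None:
            raise ValueError(
                f"record {rec_id!r}: no taxonomy in header and no TSV supplied"
            )
        if rec_id in seen:
            raise ValueError(f"duplicate record id {rec_id!r} in {fasta_path}")
        seen.add(rec_id)
        seq = str(entry.seq).upper()
        if convert_u:
            seq = seq.replace("U", "T")
        records.append(SeqRecord(rec_id, seq, parse_lineage(tax), sh))
    if missing:
        raise ValueError(
            f"{len(missing)} FASTA ids missing from taxonomy TSV: "
            + ", ".join(missing[:10])
            + ("…" if len(missing) > 10 else "")
        )
    return Dataset(records, [ProvenanceStep("input", 0, len(records))])


def write_dataset(
    dataset: Dataset,
    fasta_path: Union[str, Path],
    tax_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write records as FASTA (plain-id headers) plus a taxonomy TSV."""
    entries = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in dataset
    ]
    SeqIO.write(entries, str(fasta_path), "fasta")
    if tax_path is not None:
        with open(tax_path, "w", encoding="utf-8") as fh:
            for r in dataset:
                sh = r.sh or ""
                fh.write(f"{r.id}\t{format_lineage(r.lineage)}\t{sh}\n")


def write_provenance(dataset: Dataset, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("step\tremoved\tretained\n")
        for step in dataset.provenance:
            fh.write(f"{step.step}\t{step.removed}\t{step.retained}\n")


# ---------------------------------------------------------------------------
# predictions


def write_predictions(predictions: Iterable, path: Union[str, Path]) -> None:
    """Write predictions as a fixed-column TSV (input order preserved)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for p in predictions:
            lin = p.lineage
            names = [lin.name_at(rank) or "" for rank in RANKS]
            confs = [
                _fmt_conf(p.confidences.get(rank))
                for rank in ("phylum", "class", "order", "family", "species")
            ]
            fh.write("\t".join([p.id, *names, *confs]) + "\n")


def _fmt_conf(value) -> str:
    return "" if value is None else f"{value:.4f}"


def read_predictions(path: Union[str, Path]) -> list:
    """Round-trip reader for :func:`write_predictions` output."""
    from .classify import Prediction  # local import: avoid a cycle

    preds = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PREDICTION_COLUMNS:
            raise ValueError(f"{path}: unexpected prediction header {header}")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            row = dict(zip(PREDICTION_COLUMNS, cols))
            lineage = Lineage(
                **{
                    ("class_" if rank == "class" else rank): (row[rank] or None)
                    for rank in RANKS
                }
            )
            confs = {}
            for rank in ("phylum", "class", "order", "family", "species"):
                raw = row[f"conf_{rank}"]
                if raw:
                    confs[rank] = float(raw)
            preds.append(Prediction(id=row["id"], lineage=lineage, confidences=confs))
    return preds


# ---------------------------------------------------------------------------
# word2vec text format


def save_word2vec(path: Union[str, Path], tokens: Sequence[str], vectors: np.ndarray) -> None:
    """Write vectors in the word2vec text format (``vocab dim`` header line)."""
    vectors = np.asarray(vectors)
    if vectors.ndim != 2 or vectors.shape[0] != len(tokens):
        raise ValueError("vectors must be (len(tokens), dim)")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(tokens)} {vectors.shape[1]}\n")
        for token, row in zip(tokens, vectors):
            fh.write(token + " " + " ".join(repr(float(x)) for x in row) + "\n")


def load_word2vec(path: Union[str, Path]) -> Tuple[List[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        n, dim = (int(x) for x in fh.readline().split())
        tokens, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    vectors = np.asarray(rows, dtype=np.float32)
    if len(tokens) != n or vectors.shape != (n, dim):
        raise ValueError(f"{path}: inconsistent word2vec text file")
    return tokens, vectors
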