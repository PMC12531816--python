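"""Per-rank evaluation: ACC, precision/recall/F1, MCC and hierarchical
accuracy (HA).

ACC at a rank is the fraction of records whose predicted name equals the true
name; HA counts a record only when *every* rank from phylum down to the
evaluated rank is correct, so it penalises hierarchically inconsistent
predictions that single-rank accuracy hides.  Precision/recall/F1 are
one-vs-rest per label combined by macro/weighted/micro averaging (weighted by
default: the aggregation behind reference benchmarks of this kind is not
uniquely determined, so it is configurable).  MCC is the multi-class
confusion-matrix generalization.

``evaluate`` produces the six-rank report (phylum…species).  Because the
classifier bypasses genus — the genus of a prediction is read off the
species → lineage map, never decided independently — the genus row restates
the species-level decision and is therefore identical to the species row by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    matthews_corrcoef,
    precision_recall_fscore_support,
)

from .taxonomy import RANKS, Lineage

#: Ranks reported in a MetricsReport (kingdom is trivially single-class).
REPORT_RANKS = ("phylum", "class", "order", "family", "genus", "species")

_ABSENT = ""  # sentinel for an absent predicted rank; never a valid name

AVERAGING_MODES = ("macro", "weighted", "micro")


def _lineage_of(obj) -> Lineage:
    return obj if isinstance(obj, Lineage) else obj.lineage


def _names(items: Sequence, rank: str) -> List[str]:
    return [(_lineage_of(x).name_at(rank) or _ABSENT) for x in items]


def _check_pair(preds: Sequence, truths: Sequence) -> None:
    if len(preds) != len(truths):
        raise ValueError(f"length mismatch: {len(preds)} preds, {len(truths)} truths")
    if len(preds) == 0:
        raise ValueError("empty prediction set")


def rank_accuracy(preds: Sequence, truths: Sequence, rank: str) -> float:
    """Fraction of records correct at ``rank``; an absent predicted rank
    counts as incorrect."""
    _check_pair(preds, truths)
    p = _names(preds, rank)
    t = _names(truths, rank)
    return sum(a == b and b != _ABSENT for a, b in zip(p, t)) / len(t)


def hierarchical_accuracy(preds: Sequence, truths: Sequence, rank: str) -> float:
    """Fraction of records correct at *every* rank from phylum down to
    ``rank`` inclusive."""
    _check_pair(preds, truths)
    upto = RANKS.index(rank)
    path_ranks = RANKS[RANKS.index("phylum") : upto + 1]
    n_ok = 0
    for p, t in zip(preds, truths):
        lp, lt = _lineage_of(p), _lineage_of(t)
        if all(
            lp.name_at(r) is not None and lp.name_at(r) == lt.name_at(r)
            for r in path_ranks
        ):
            n_ok += 1
    return n_ok / len(preds)


def prf(
    preds: Sequence, truths: Sequence, rank: str, averaging: str = "weighted"
) -> Tuple[float, float, float]:
    """(precision, recall, F1) with one-vs-rest per-label aggregation.

    Labels are the names present in the truths; labels with zero predicted
    instances contribute precision 0.
    """
    if averaging not in AVERAGING_MODES:
        raise ValueError(f"averaging must be one of {AVERAGING_MODES}")
    _check_pair(preds, truths)
    y_true = _names(truths, rank)
    y_pred = _names(preds, rank)
    labels = sorted(set(y_true))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average=averaging, zero_division=0
        )
    return float(p), float(r), float(f1)


def mcc(preds: Sequence, truths: Sequence, rank: str) -> float:
    """Multi-class Matthews correlation coefficient at ``rank``; 0 when any
    marginal is degenerate (including a single truth label, with a warning)."""
    _check_pair(preds, truths)
    y_true = _names(truths, rank)
    y_pred = _names(preds, rank)
    if len(set(y_true)) < 2:
        warnings.warn(f"single truth label at rank {rank!r}; MCC defined as 0")
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(y_true, y_pred))


@dataclass
class ConfusionTable:
    rank: str
    labels: List[str]
    matrix: np.ndarray  # true x predicted

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def support(self) -> Dict[str, int]:
        return {lab: int(n) for lab, n in zip(self.labels, self.matrix.sum(axis=1))}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def confusion_table(preds: Sequence, truths: Sequence, rank: str) -> ConfusionTable:
    _check_pair(preds, truths)
    y_true = _names(truths, rank)
    y_pred = _names(preds, rank)
    labels = sorted(set(y_true) | set(y_pred))
    mat = confusion_matrix(y_true, y_pred, labels=labels)
    return ConfusionTable(rank=rank, labels=labels, matrix=mat)


@dataclass
class MetricsReport:
    """Six metrics at each of the six reported ranks."""

    table: pd.DataFrame  # index: rank; columns: acc ha recall precision f1 mcc
    averaging: str
    n_records: int

    def row(self, rank: str) -> Dict[str, float]:
        return self.table.loc[rank].to_dict()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "level", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda x: f"{x:.4f}")


def evaluate(
    preds: Sequence, truths: Sequence, averaging: str = "weighted"
) -> MetricsReport:
    """Full per-rank report.  The genus row restates the species row (genus is
    derived from the species decision, never predicted independently)."""
    _check_pair(preds, truths)
    rows = {}
    for rank in REPORT_RANKS:
        if rank == "genus":
            continue
        p, r, f1 = prf(preds, truths, rank, averaging)
        rows[rank] = {
            "acc": rank_accuracy(preds, truths, rank),
            "ha": hierarchical_accuracy(preds, truths, rank),
            "recall": r,
            "precision": p,
            "f1": f1,
            "mcc": mcc(preds, truths, rank),
        }
    rows["genus"] = dict(rows["species"])
    table = pd.DataFrame([rows[r] for r in REPORT_RANKS], index=list(REPORT_RANKS))
    return MetricsReport(table=table, averaging=averaging, n_records=len(preds))
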