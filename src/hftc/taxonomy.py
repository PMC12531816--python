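"""Seven-rank fungal taxonomic lineages and the rank-prefixed string dialect.

A lineage is the ordered kingdom→species path of a record.  On disk it is a
semicolon-separated, optionally rank-prefixed string in the UNITE/SINTAX
convention, e.g.::

    k__Fungi;p__Ascomycota;c__Sordariomycetes;o__Hypocreales;f__Nectriaceae;g__Fusarium;s__Fusarium_oxysporum

Ranks are filled top-down: a rank may be absent only if every rank below it is
also absent.  Name tokens carry no semicolons and no rank prefixes; underscores
inside names are allowed (``Fusarium_oxysporum``).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterator, Optional

#: Canonical rank order, top-down.  ``class`` is a Python keyword, hence the
#: attribute is spelled ``class_``; every public API accepts the plain rank
#: name "class".
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_ATTRS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")
_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_TO_IDX = {p: i for i, p in enumerate(_PREFIXES)}

#: Single-letter rank codes used in sub-classifier names (``Fungi2p``,
#: ``Cortinariaceae_f2s``).
RANK_LETTERS = {r: p[0] for r, p in zip(RANKS, _PREFIXES)}


class LineageParseError(ValueError):
    """Raised when a taxonomy string violates the dialect."""


def _attr(rank: str) -> str:
    if rank == "class":
        return "class_"
    if rank not in RANKS:
        raise KeyError(f"unknown rank: {rank!r}")
    return rank


@dataclass(frozen=True)
class Lineage:
    """An ordered 7-rank taxonomic path; trailing ranks may be absent (None)."""

    kingdom: Optional[str] = None
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        seen_absent = False
        for attr in _ATTRS:
            name = getattr(self, attr)
            if name is None:
                seen_absent = True
                continue
            if seen_absent:
                raise LineageParseError(
                    f"rank {attr.rstrip('_')!r} is filled below an absent rank"
                )
            if ";" in name:
                raise LineageParseError(f"name token contains a semicolon: {name!r}")
            if name[:3] in _PREFIX_TO_IDX:
                raise LineageParseError(f"name token carries a rank prefix: {name!r}")

    def name_at(self, rank: str) -> Optional[str]:
        """Name at ``rank`` ("kingdom" … "species"), or None if absent."""
        return getattr(self, _attr(rank))

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, a) for a in _ATTRS)

    @property
    def depth(self) -> int:
        """Number of filled ranks (0–7)."""
        return sum(1 for a in _ATTRS if getattr(self, a) is not None)

    @property
    def is_full(self) -> bool:
        return self.depth == len(RANKS)

    def prefix(self, rank: str) -> tuple:
        """Names from kingdom down to ``rank`` inclusive."""
        i = RANKS.index(rank)
        return self.as_tuple()[: i + 1]

    def startswith(self, path: tuple) -> bool:
        return self.as_tuple()[: len(path)] == tuple(path)

    def path_equal(self, other: "Lineage") -> bool:
        """Equal at every rank present in either lineage."""
        return self.as_tuple() == other.as_tuple()

    def replace(self, **kwargs) -> "Lineage":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update({_attr(k) if k in RANKS else k: v for k, v in kwargs.items()})
        return Lineage(**d)

    def iter_names(self) -> Iterator[tuple]:
        for rank, attr in zip(RANKS, _ATTRS):
            name = getattr(self, attr)
            if name is not None:
                yield rank, name


def parse_lineage(tax_string: str) -> Lineage:
    """Parse a rank-prefixed taxonomy string into a :class:`Lineage`.

    Tokens are semicolon-separated; each may carry one of the prefixes
    ``k__ p__ c__ o__ f__ g__ s__``.  Prefixes, when present, must occur in
    rank order and at most once.  Unprefixed tokens are assigned to the next
    rank by position.  An empty token after a prefix marks an absent rank.
    """
    tokens = [t.strip() for t in tax_string.strip().split(";")]
    # A trailing semicolon is tolerated (common in exported taxonomy strings).
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) > len(RANKS):
        raise LineageParseError(
            f"more than {len(RANKS)} tokens in taxonomy string: {tax_string!r}"
        )
    names: list = [None] * len(RANKS)
    next_idx = 0
    for token in tokens:
        prefix = token[:3]
        if prefix in _PREFIX_TO_IDX:
            idx = _PREFIX_TO_IDX[prefix]
            if idx < next_idx:
                raise LineageParseError(
                    f"out-of-order or duplicate rank prefix at token {token!r}"
                )
            name = token[3:].strip()
        else:
            if next_idx >= len(RANKS):
                raise LineageParseError(f"too many tokens at {token!r}")
            idx = next_idx
            name = token
        names[idx] = name if name else None
        next_idx = idx + 1
    try:
        return Lineage(**dict(zip(_ATTRS, names)))
    except LineageParseError as exc:
        raise LineageParseError(f"{exc} (in {tax_string!r})") from exc


def format_lineage(lineage: Lineage, prefixes: bool = True, full: bool = False) -> str:
    """Inverse of :func:`parse_lineage` on any valid lineage.

    With ``full=True`` absent trailing ranks are emitted as bare prefixes
    (``s__``) so the string always has seven tokens.
    """
    parts = []
    for rank, prefix, name in zip(RANKS, _PREFIXES, lineage.as_tuple()):
        if name is None and not full:
            break
        token = name or ""
        parts.append(f"{prefix}{token}" if prefixes else token)
    return ";".join(parts)
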