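"""Substrate association: mapping observation keys to plant cell wall targets.

Each observation key is assigned the plant cell wall polymer(s) its enzyme is
expected to act on — cellulose, xylan, pectin or lignin — via a declarative
map of (EC pattern, family pattern) rules.  When a key is associated with two
substrates the enzyme counts as half for both, so every mapped key carries a
total weight of exactly one; this conservation is what makes a genome's Total
score equal the sum of its four substrate scores.

The map shipped with the package (``data/substrate_map.tsv``) is an
illustrative set of canonical assignments assembled for testing and
demonstration; production analyses should supply their own curated map via
``--substrate-map``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from .observation import ObservationKey

__all__ = [
    "SUBSTRATES",
    "WILDCARD",
    "SubstrateMapEntry",
    "SubstrateMap",
    "MapAmbiguityError",
    "substrates_for",
    "default_substrate_map",
]

logger = logging.getLogger(__name__)

#: The four plant cell wall substrates, in reporting order.
SUBSTRATES: tuple[str, ...] = ("cellulose", "pectin", "xylan", "lignin")

WILDCARD = "*"


class MapAmbiguityError(ValueError):
    """Two equally specific map entries match one observation key."""


@dataclass(frozen=True, slots=True)
class SubstrateMapEntry:
    """One association rule: an EC pattern and family pattern (each either a
    literal label or the wildcard ``"*"``) mapped to a nonempty substrate set."""

    ec_pattern: str
    family_pattern: str
    substrates: frozenset[str]

    def __post_init__(self) -> None:
        if not self.substrates:
            raise ValueError("substrate set must be nonempty")
        bad = self.substrates - set(SUBSTRATES)
        if bad:
            raise ValueError(
                f"unknown substrate token(s) {sorted(bad)} in entry "
                f"({self.ec_pattern}, {self.family_pattern})"
            )

    @property
    def specificity(self) -> int:
        """Resolution tier: exact EC+family (3) > exact EC (2) > exact
        family (1) > catch-all (0)."""
        ec_exact = self.ec_pattern != WILDCARD
        fam_exact = self.family_pattern != WILDCARD
        if ec_exact and fam_exact:
            return 3
        if ec_exact:
            return 2
        if fam_exact:
            return 1
        return 0

    def matches(self, key: ObservationKey) -> bool:
        if self.ec_pattern != WILDCARD and self.ec_pattern != str(key.ec):
            return False
        if self.family_pattern != WILDCARD and self.family_pattern != key.family:
            return False
        return True


class SubstrateMap:
    """A validated collection of association rules with specificity-resolved
    lookup.

    Lookup returns the single most-specific matching entry; two distinct
    equally specific matches raise :class:`MapAmbiguityError`.  Duplicate
    (ec_pattern, family_pattern) pairs are rejected at construction.
    """

    def __init__(self, entries: Iterable[SubstrateMapEntry]):
        self._entries: list[SubstrateMapEntry] = []
        seen: dict[tuple[str, str], SubstrateMapEntry] = {}
        for e in entries:
            pair = (e.ec_pattern, e.family_pattern)
            if pair in seen:
                raise ValueError(
                    f"duplicate substrate-map entry for pattern pair {pair}"
                )
            seen[pair] = e
            self._entries.append(e)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def lookup(self, key: ObservationKey) -> SubstrateMapEntry | None:
        matches = [e for e in self._entries if e.matches(key)]
        if not matches:
            return None
        top = max(e.specificity for e in matches)
        winners = [e for e in matches if e.specificity == top]
        if len(winners) > 1:
            a, b = winners[0], winners[1]
            raise MapAmbiguityError(
                f"key {key} matched by equally specific entries "
                f"({a.ec_pattern}, {a.family_pattern}) and "
                f"({b.ec_pattern}, {b.family_pattern})"
            )
        return winners[0]


def substrates_for(key: ObservationKey, smap: SubstrateMap) -> dict[str, float]:
    """Resolve a key to its weighted substrate set.

    An entry with *k* substrates contributes weight 1/k to each (the
    half-count rule for k = 2, generalized so that weights always sum to one
    for a mapped key).  An unmapped key yields an empty mapping.
    """
    entry = smap.lookup(key)
    if entry is None:
        logger.debug("substrates_for: no map entry for key %s", key)
        return {}
    k = len(entry.substrates)
    return {s: 1.0 / k for s in sorted(entry.substrates)}


def default_substrate_map() -> SubstrateMap:
    """Load the illustrative substrate map bundled with the package."""
    from .io import parse_substrate_map_text

    text = (
        resources.files("cazhotspot").joinpath("data/substrate_map.tsv").read_text()
    )
    return parse_substrate_map_text(text)
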