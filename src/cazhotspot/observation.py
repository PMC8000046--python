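"""Integrated "Function;Family" observation keys.

The unit of analysis throughout the package is the *observation*: a predicted
EC function paired with the CAZy family of the protein carrying it, written
canonically as ``"3.2.1.4;GH5"``.  The same EC number found in two different
families counts as two different observations, because family membership
carries mechanistic and substrate information the bare EC does not.

Two counting modes derive from observations:

* *redundant* — every protein-level occurrence counts, measuring degradation
  capacity (gene-copy redundancy boosts the score);
* *unique* — each distinct key counts once per genome, measuring the breadth
  of enzyme function specificity.

Glycosyl transferases (GT families) are excluded because they build rather
than degrade glycans, and lytic polysaccharide monooxygenases (the AA LPMO
families) are excluded because their molecular function cannot currently be
predicted reliably from sequence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ECLabel",
    "ObservationKey",
    "ObservationInstance",
    "DEFAULT_LPMO_FAMILIES",
    "normalize_ec",
    "make_observation_key",
    "parent_family",
    "default_excluded",
    "extract_observations",
]

logger = logging.getLogger(__name__)

#: CAZy LPMO families excluded by default (configurable).
DEFAULT_LPMO_FAMILIES: frozenset[str] = frozenset(
    {"AA9", "AA10", "AA11", "AA13", "AA14", "AA15", "AA16", "AA17"}
)

_EC_RE = re.compile(r"^(\d+)\.(\d+)\.(\d+)\.(\d+|\*|-)$")

#: A CAZy family, optionally with a subfamily (``GH5_7``) or CUPP group
#: (``GH7:2.1``) suffix.
FAMILY_RE = re.compile(r"^(?P<parent>(GH|GT|PL|CE|AA|CBM)\d+)(_\d+|:[\d.]+)?$")


@dataclass(frozen=True, slots=True)
class ECLabel:
    """A four-field Enzyme Commission label; the fourth field may be ``"*"``
    when only the sub-subclass of the function is predicted."""

    c1: int
    c2: int
    c3: int
    c4: str  # digits or "*"

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0 or self.c3 <= 0:
            raise ValueError(f"EC fields must be positive: {self}")
        if self.c4 != "*" and not self.c4.isdigit():
            raise ValueError(f"EC fourth field must be digits or '*': {self.c4!r}")

    def __str__(self) -> str:
        return f"{self.c1}.{self.c2}.{self.c3}.{self.c4}"

    @property
    def is_partial(self) -> bool:
        return self.c4 == "*"


def normalize_ec(raw: str) -> ECLabel:
    """Parse an EC string, rewriting a ``-`` fourth field to ``*``.

    Annotators disagree on the placeholder for an incomplete fourth field;
    ``3.2.1.-`` and ``3.2.1.*`` denote the same partial assignment and are
    normalized to the ``*`` form.

    Raises
    ------
    ValueError
        If *raw* does not have four dot-separated fields with numeric leading
        fields.
    """
    m = _EC_RE.match(raw.strip())
    if m is None:
        raise ValueError(f"not a valid EC label: {raw!r}")
    c4 = m.group(4)
    if c4 == "-":
        c4 = "*"
    return ECLabel(int(m.group(1)), int(m.group(2)), int(m.group(3)), c4)


@dataclass(frozen=True, slots=True)
class ObservationKey:
    """An integrated Function;Family key, e.g. ``"3.2.1.4;GH5"``.

    Equality is on the (EC, family) pair only; subfamily labels never
    participate (they are collapsed before key construction).
    """

    ec: ECLabel
    family: str

    def __str__(self) -> str:
        return f"{self.ec};{self.family}"

    @classmethod
    def from_string(cls, s: str) -> "ObservationKey":
        ec_part, sep, family = s.partition(";")
        if not sep or not family:
            raise ValueError(f"not a valid observation key: {s!r}")
        return cls(normalize_ec(ec_part), family)


def make_observation_key(ec: ECLabel, family: str) -> ObservationKey:
    """Combine a predicted EC function with its CAZy family into a key."""
    if FAMILY_RE.match(family) is None:
        raise ValueError(f"not a valid CAZy family label: {family!r}")
    return ObservationKey(ec, parent_family(family))


def parent_family(family: str) -> str:
    """Collapse a subfamily/CUPP-group label to its parent family.

    ``GH5_7`` and ``GH7:2.1`` both carry annotation resolution below the
    family level; observation keys are defined on the family, so the suffix
    is dropped (``GH5_7`` → ``GH5``).
    """
    m = FAMILY_RE.match(family)
    if m is None:
        raise ValueError(f"not a valid CAZy family label: {family!r}")
    return m.group("parent")


@dataclass(frozen=True, slots=True)
class ObservationInstance:
    """A protein-level occurrence of an observation key.

    The (protein_id, key) pair is the unit of redundant counting; identical
    duplicates (re-annotation artifacts) are collapsed upstream.
    """

    genome_id: str
    protein_id: str
    key: ObservationKey


def default_excluded(lpmo_families: Iterable[str] = DEFAULT_LPMO_FAMILIES) -> frozenset[str]:
    """The default exclusion set: the LPMO AA families.  GT families are
    excluded wholesale by prefix and need not be enumerated here."""
    return frozenset(lpmo_families)


def _is_excluded(family: str, excluded: frozenset[str]) -> bool:
    return family.startswith("GT") or family in excluded


def extract_observations(
    records: Sequence,
    excluded_families: Iterable[str] | None = None,
) -> list[ObservationInstance]:
    """Turn annotation records into observation instances.

    One instance is produced per distinct (protein, EC, family) triple:
    a protein carrying two EC predictions in one family yields two instances
    with distinct keys, and duplicate identical annotation rows collapse to
    one.  Records with no EC prediction (e.g. CBM-only annotations) yield
    nothing, as do records in excluded families (all GT families plus the
    LPMO list).

    Parameters
    ----------
    records
        :class:`~cazhotspot.io.AnnotationRecord` sequence (validated).
    excluded_families
        Family labels to drop in addition to the GT prefix rule; defaults to
        :data:`DEFAULT_LPMO_FAMILIES`.

    Returns
    -------
    list of ObservationInstance in first-seen order.
    """
    excluded = (
        frozenset(excluded_families)
        if excluded_families is not None
        else default_excluded()
    )
    seen: set[tuple[str, str, ObservationKey]] = set()
    out: list[ObservationInstance] = []
    n_excluded = 0
    n_no_ec = 0
    for rec in records:
        family = parent_family(rec.family)
        if _is_excluded(family, excluded):
            n_excluded += 1
            continue
        if not rec.ec_labels:
            n_no_ec += 1
            continue
        for raw_ec in rec.ec_labels:
            key = ObservationKey(normalize_ec(raw_ec), family)
            triple = (rec.genome_id, rec.protein_id, key)
            if triple in seen:
                continue
            seen.add(triple)
            out.append(ObservationInstance(rec.genome_id, rec.protein_id, key))
    if n_excluded or n_no_ec:
        logger.debug(
            "extract_observations: dropped %d records in excluded families, "
            "%d records without EC prediction",
            n_excluded,
            n_no_ec,
        )
    return out
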