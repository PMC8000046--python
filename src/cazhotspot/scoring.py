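"""Per-genome capacity and diversity scoring, and the Redundancy
Multiplication Score.

For each genome and substrate *s* two weighted counts are accumulated over
the genome's observation instances:

* redundant score ``R_s`` — every instance contributes its substrate weight
  (degradation capacity; gene copies of the same Function;Family all count);
* unique score ``U_s`` — every *distinct* observation key contributes once
  (enzyme function specificity diversity).

Totals sum the four substrate scores.  The Redundancy Multiplication Score
(RMS) is the ratio redundant/unique for any chosen grouping; a high RMS
(> 8) marks genomes that boost capacity through gene-copy redundancy, a low
RMS (< 3) marks genomes whose capacity comes almost entirely from distinct
specificities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

from .observation import ObservationInstance, ObservationKey
from .substrate import SUBSTRATES, SubstrateMap, substrates_for

__all__ = [
    "GenomeProfile",
    "RMSValue",
    "RMS_HIGH_THRESHOLD",
    "RMS_LOW_THRESHOLD",
    "score_genome",
    "total_capacity",
    "association_sum",
    "rms",
    "round_half_up",
]

#: Table-caption thresholds on the unrounded ratio.
RMS_HIGH_THRESHOLD = 8.0
RMS_LOW_THRESHOLD = 3.0

Mode = Literal["redundant", "unique"]


def _zero_scores() -> dict[str, float]:
    return {s: 0.0 for s in SUBSTRATES}


@dataclass(slots=True)
class GenomeProfile:
    """Per-genome weighted observation scores.

    ``redundant`` and ``unique`` map each of the four substrates to its
    weighted count; unmapped instances contribute to neither.  The invariant
    ``U_s <= R_s`` holds per substrate because the distinct keys behind
    ``U_s`` are a subset of the instances behind ``R_s`` with identical
    weights.
    """

    genome_id: str
    redundant: dict[str, float] = field(default_factory=_zero_scores)
    unique: dict[str, float] = field(default_factory=_zero_scores)

    @property
    def total_redundant(self) -> float:
        return sum(self.redundant[s] for s in SUBSTRATES)

    @property
    def total_unique(self) -> float:
        return sum(self.unique[s] for s in SUBSTRATES)

    def score(self, metric: str | Iterable[str], mode: Mode = "redundant") -> float:
        """A single number for ranking: one substrate, ``"total"``, or an
        association combination (iterable of substrates)."""
        table = self.redundant if mode == "redundant" else self.unique
        if isinstance(metric, str):
            if metric == "total":
                return sum(table[s] for s in SUBSTRATES)
            if metric not in SUBSTRATES:
                raise ValueError(f"unknown metric {metric!r}")
            return table[metric]
        return association_sum(self, set(metric), mode)


def score_genome(
    instances: Sequence[ObservationInstance], smap: SubstrateMap
) -> GenomeProfile:
    """Accumulate one genome's observation instances into a profile.

    Raises
    ------
    ValueError
        If instances carry more than one genome_id (profiles are strictly
        per-genome; mixing would silently merge species).
    """
    genomes = {i.genome_id for i in instances}
    if len(genomes) > 1:
        raise ValueError(f"instances span multiple genomes: {sorted(genomes)}")
    genome_id = next(iter(genomes)) if genomes else ""
    profile = GenomeProfile(genome_id=genome_id)
    weight_cache: dict[ObservationKey, dict[str, float]] = {}
    seen_keys: set[ObservationKey] = set()
    for inst in instances:
        if inst.key not in weight_cache:
            weight_cache[inst.key] = substrates_for(inst.key, smap)
        weights = weight_cache[inst.key]
        for s, w in weights.items():
            profile.redundant[s] += w
        if inst.key not in seen_keys:
            seen_keys.add(inst.key)
            for s, w in weights.items():
                profile.unique[s] += w
    return profile


def total_capacity(profile: GenomeProfile) -> float:
    """The genome's Total degradation capacity: sum of the four substrate
    redundant scores."""
    return profile.total_redundant


def association_sum(
    profile: GenomeProfile, combo: Iterable[str], mode: Mode = "redundant"
) -> float:
    """Sum of one mode's scores over a substrate combination, e.g.
    pectin + lignin."""
    combo = set(combo)
    bad = combo - set(SUBSTRATES)
    if bad:
        raise ValueError(f"unknown substrate token(s): {sorted(bad)}")
    table = profile.redundant if mode == "redundant" else profile.unique
    return sum(table[s] for s in combo)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (so 4.25 → 4.3), used for all reported scores."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, slots=True)
class RMSValue:
    """A Redundancy Multiplication Score: redundant/unique ratio with the
    flag thresholds of the reporting convention.

    ``ratio`` is the unrounded value (``None`` when undefined, i.e. the
    unique score is zero); ``rounded`` is ratio rounded half-up to one
    decimal for reporting.  ``flag`` is ``"high"`` for ratio > 8, ``"low"``
    for ratio < 3, else ``"none"``; flags are decided on the unrounded ratio.
    """

    numerator: float
    denominator: float
    ratio: float | None
    flag: Literal["high", "low", "none", "undefined"]

    @property
    def rounded(self) -> float | None:
        return None if self.ratio is None else round_half_up(self.ratio, 1)

    @property
    def flag_char(self) -> str:
        return {"high": "*", "low": "¤", "none": "", "undefined": ""}[self.flag]

    def __str__(self) -> str:
        if self.ratio is None:
            return "NA"
        s = f"{self.rounded:.1f}"
        return f"{s} {self.flag_char}".rstrip()


def rms(redundant_score: float, unique_score: float) -> RMSValue:
    """Redundancy Multiplication Score for a (redundant, unique) score pair.

    A zero unique score leaves the ratio undefined (reported ``"NA"``), never
    zero or infinity — an undefined RMS must not order against real ones.
    """
    if redundant_score < 0 or unique_score < 0:
        raise ValueError("scores must be non-negative")
    if unique_score == 0:
        return RMSValue(redundant_score, unique_score, None, "undefined")
    ratio = redundant_score / unique_score
    if ratio > RMS_HIGH_THRESHOLD:
        flag = "high"
    elif ratio < RMS_LOW_THRESHOLD:
        flag = "low"
    else:
        flag = "none"
    return RMSValue(redundant_score, unique_score, ratio, flag)
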