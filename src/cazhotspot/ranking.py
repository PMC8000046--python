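"""Genome ranking, rank-window phylum censuses, and intra-genus variation.

Rankings use competition ("1224") semantics: genomes with equal scores share
the minimum rank and are flagged as tied, and the next distinct score resumes
at the ordinal position.  Ties are deliberately not broken by score — the
reporting convention marks them rather than inventing an order — but output
order is made deterministic by a secondary sort on species name.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

from .scoring import GenomeProfile, Mode

__all__ = [
    "RankingEntry",
    "RankWindow",
    "GenusSummary",
    "DEFAULT_WINDOWS",
    "rank_genomes",
    "phylum_distribution",
    "genus_variation",
]


@dataclass(frozen=True, slots=True)
class RankingEntry:
    rank: int
    genome_id: str
    species: str
    genus: str
    class_: str
    phylum: str
    score: float
    tied: bool


@dataclass(frozen=True, slots=True)
class RankWindow:
    """An inclusive 1-based rank interval with its per-phylum species counts."""

    start: int
    end: int
    phylum_counts: Mapping[str, int]


@dataclass(frozen=True, slots=True)
class GenusSummary:
    genus: str
    n_genomes: int
    best_rank: int
    worst_rank: int
    median_rank: float

    @property
    def spread(self) -> int:
        return self.worst_rank - self.best_rank


def rank_genomes(
    profiles: Sequence[GenomeProfile],
    metadata: Mapping[str, "object"],
    metric: str | Iterable[str] = "total",
    mode: Mode = "redundant",
) -> list[RankingEntry]:
    """Rank genomes descending by a chosen score.

    Parameters
    ----------
    profiles
        One :class:`GenomeProfile` per genome.
    metadata
        genome_id → metadata object with ``species``, ``genus``, ``class_``
        and ``phylum`` attributes (see :class:`cazhotspot.io.GenomeMeta`).
    metric
        A substrate name, ``"total"``, or an iterable of substrates
        (association combination).
    mode
        ``"redundant"`` (capacity) or ``"unique"`` (diversity).

    Raises
    ------
    KeyError
        If a profile's genome_id is missing from *metadata*.
    """
    if not profiles:
        raise ValueError("cannot rank an empty profile list")
    metric_key = metric if isinstance(metric, str) else tuple(metric)
    rows = []
    for p in profiles:
        if p.genome_id not in metadata:
            raise KeyError(f"no metadata for genome {p.genome_id!r}")
        meta = metadata[p.genome_id]
        rows.append((p.score(metric_key, mode), meta, p))
    # Deterministic order: score desc, then species name.
    rows.sort(key=lambda r: (-r[0], r[1].species, r[2].genome_id))

    score_multiplicity: dict[float, int] = {}
    for score, _, _ in rows:
        score_multiplicity[score] = score_multiplicity.get(score, 0) + 1

    entries: list[RankingEntry] = []
    rank = 0
    prev_score: float | None = None
    for pos, (score, meta, p) in enumerate(rows, start=1):
        if prev_score is None or score != prev_score:
            rank = pos
            prev_score = score
        entries.append(
            RankingEntry(
                rank=rank,
                genome_id=p.genome_id,
                species=meta.species,
                genus=meta.genus,
                class_=meta.class_,
                phylum=meta.phylum,
                score=score,
                tied=score_multiplicity[score] > 1,
            )
        )
    return entries


#: Default rank windows for the phylum census (inclusive, 1-based); the last
#: window is truncated to the ranking length.
DEFAULT_WINDOWS: tuple[tuple[int, int], ...] = ((1, 500), (501, 1000), (1001, 10**9))


def phylum_distribution(
    ranking: Sequence[RankingEntry],
    windows: Iterable[tuple[int, int]] = DEFAULT_WINDOWS,
) -> list[RankWindow]:
    """Count species per phylum inside each rank window.

    Window counts are over ranked *positions* (1-based, inclusive), so that
    each window of width w accounts for exactly w genomes regardless of ties.
    Windows must be disjoint and non-empty within the ranking length; the
    final window may extend past the end and is truncated.
    """
    n = len(ranking)
    resolved: list[tuple[int, int]] = []
    for start, end in windows:
        if start < 1 or end < start:
            raise ValueError(f"invalid rank window ({start}, {end})")
        end = min(end, n)
        if start > n:
            raise ValueError(
                f"window ({start}, ...) lies beyond the ranking length {n}"
            )
        resolved.append((start, end))
    for (s1, e1) in resolved:
        for (s2, e2) in resolved:
            if (s1, e1) < (s2, e2) and e1 >= s2:
                raise ValueError(
                    f"overlapping rank windows ({s1}, {e1}) and ({s2}, {e2})"
                )
    out = []
    for start, end in resolved:
        counts: dict[str, int] = {}
        for entry in ranking[start - 1 : end]:
            counts[entry.phylum] = counts.get(entry.phylum, 0) + 1
        out.append(RankWindow(start=start, end=end, phylum_counts=counts))
    return out


def genus_variation(
    ranking: Sequence[RankingEntry], min_genomes: int = 2
) -> list[GenusSummary]:
    """Summarize rank variation within each genus having at least
    *min_genomes* ranked genomes (best, worst and median rank; spread =
    worst − best)."""
    if min_genomes < 2:
        raise ValueError("min_genomes must be at least 2")
    by_genus: dict[str, list[int]] = {}
    for entry in ranking:
        by_genus.setdefault(entry.genus, []).append(entry.rank)
    out = []
    for genus in sorted(by_genus):
        ranks = by_genus[genus]
        if len(ranks) < min_genomes:
            continue
        out.append(
            GenusSummary(
                genus=genus,
                n_genomes=len(ranks),
                best_rank=min(ranks),
                worst_rank=max(ranks),
                median_rank=float(median(ranks)),
            )
        )
    return out
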