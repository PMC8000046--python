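"""Representative-assembly selection by sequencing coverage × contig N50.

When several assemblies exist for one species (one NCBI taxid), the analysis
keeps the single assembly maximizing coverage × N50 — deep sequencing and
long contigs both argue for a more complete gene catalogue, and their product
is a simple joint criterion.  N50 is the standard contiguity statistic: the
largest contig length L such that contigs of length ≥ L together cover at
least half the assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

__all__ = ["AssemblyMetadata", "SelectionScore", "n50", "select_representative"]

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class AssemblyMetadata:
    """One candidate assembly: coverage plus either raw contig lengths or a
    precomputed N50 (at least one must be present)."""

    species_taxid: str
    accession: str
    coverage: float
    contig_lengths: list[int] | None = None
    n50: int | None = None

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError(
                f"negative coverage for assembly {self.accession}: {self.coverage}"
            )
        if self.contig_lengths is None and self.n50 is None:
            raise ValueError(
                f"assembly {self.accession}: neither contig lengths nor N50 available"
            )

    def resolve_n50(self) -> int:
        if self.n50 is not None:
            return self.n50
        return n50(self.contig_lengths)


@dataclass(frozen=True, slots=True)
class SelectionScore:
    species_taxid: str
    accession: str
    coverage: float
    n50: int
    selected: bool = False

    @property
    def score(self) -> float:
        return self.coverage * self.n50


def n50(contig_lengths: Sequence[int]) -> int:
    """Contig N50: the largest length L with cumulative length of contigs of
    length ≥ L reaching at least half the total assembly length."""
    if not contig_lengths:
        raise ValueError("cannot compute N50 of an empty contig list")
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(contig_lengths) / 2
    acc = 0
    for length in sorted(contig_lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def select_representative(
    assemblies: Sequence[AssemblyMetadata],
) -> tuple[dict[str, str], list[SelectionScore]]:
    """Pick one representative accession per species taxid.

    The winner maximizes coverage × N50; exact product ties go to the higher
    coverage, then to the lexicographically smaller accession (a fixed chain
    so reruns are reproducible).  Returns the per-species selection and the
    full score table for audit.
    """
    scores: list[SelectionScore] = []
    by_species: dict[str, list[SelectionScore]] = {}
    for a in assemblies:
        s = SelectionScore(
            species_taxid=a.species_taxid,
            accession=a.accession,
            coverage=a.coverage,
            n50=a.resolve_n50(),
        )
        if s.coverage == 0:
            logger.warning(
                "assembly %s has zero coverage; it will only be selected if "
                "no alternative exists",
                s.accession,
            )
        by_species.setdefault(a.species_taxid, []).append(s)

    selection: dict[str, str] = {}
    table: list[SelectionScore] = []
    for taxid in sorted(by_species):
        candidates = sorted(
            by_species[taxid],
            key=lambda s: (-s.score, -s.coverage, s.accession),
        )
        winner = candidates[0]
        selection[taxid] = winner.accession
        for c in candidates:
            table.append(
                SelectionScore(
                    species_taxid=c.species_taxid,
                    accession=c.accession,
                    coverage=c.coverage,
                    n50=c.n50,
                    selected=c.accession == winner.accession,
                )
            )
    return selection, table
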