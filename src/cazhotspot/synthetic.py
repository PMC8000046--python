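"""Synthetic annotation cohorts with known ground truth.

The generator emulates the shape of a CAZyme annotation pipeline's output —
per-protein annotation rows, genome metadata, a substrate-association map and
candidate assembly sets — with every downstream score known by construction,
so each pipeline stage can be tested without any sequence data or downloads.

Model
-----
For each genome and substrate *s* the spec fixes the target unique score
``u_s`` and a redundancy multiplier ``m_s``.  Distinct observation keys are
drawn from a fictitious key pool (EC class 9, which no real enzyme uses, so
synthetic keys can never collide with entries of a real substrate map), and
each key receives ``1 + Poisson(m_s − 1)`` protein copies — at least one gene
per key present, with mean copy number ``m_s``, so the scored per-substrate
RMS converges to ``m_s`` as ``u_s`` grows.

A configurable fraction of keys is dual-substrate: such keys are created for
substrate *pairs* along a fixed cycle and weigh ½ on each side, and the
per-substrate dual counts are kept even so that the weighted unique score
still equals ``u_s`` exactly for every genome, substrate and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .assembly import AssemblyMetadata
from .io import AnnotationRecord, GenomeMeta
from .scoring import GenomeProfile
from .substrate import SUBSTRATES, SubstrateMap, SubstrateMapEntry

__all__ = ["GenomeSpec", "CohortBundle", "generate_genome", "generate_cohort", "write_bundle"]

#: Substrate pairs eligible for dual-substrate keys (a fixed cycle over the
#: four substrates).
DUAL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (SUBSTRATES[i], SUBSTRATES[(i + 1) % len(SUBSTRATES)])
    for i in range(len(SUBSTRATES))
)

#: Distinct keys available per substrate (and per dual pair) in the pool.
POOL_SIZE = 5000


@dataclass(frozen=True, slots=True)
class GenomeSpec:
    """Ground-truth parameters for one synthetic genome.

    ``u`` maps each substrate to its target unique score (distinct keys),
    ``m`` to its redundancy multiplier (mean protein copies per key, ≥ 1).
    ``dual_fraction`` is the approximate fraction of each substrate's unique
    score carried by dual-substrate keys.
    """

    genome_id: str
    u: Mapping[str, int]
    m: Mapping[str, float] = field(default_factory=dict)
    dual_fraction: float = 0.0
    seed: int | None = None
    species: str = ""
    genus: str = "Synthogenus"
    class_: str = "Synthomycetes"
    phylum: str = "Ascomycota"

    def __post_init__(self) -> None:
        for s, v in self.u.items():
            if s not in SUBSTRATES:
                raise ValueError(f"unknown substrate {s!r} in spec")
            if v < 0 or v != int(v):
                raise ValueError(f"u[{s}] must be a non-negative integer")
        for s, v in self.m.items():
            if v < 1:
                raise ValueError(f"m[{s}] must be >= 1")
        if not 0.0 <= self.dual_fraction <= 1.0:
            raise ValueError("dual_fraction must lie in [0, 1]")

    def u_of(self, s: str) -> int:
        return int(self.u.get(s, 0))

    def m_of(self, s: str) -> float:
        return float(self.m.get(s, 1.0))

    @property
    def display_species(self) -> str:
        return self.species or self.genome_id


def _single_key(substrate_index: int, j: int) -> tuple[str, str]:
    """The j-th single-substrate pool key: fictitious EC (class 9, second
    field 1–4 = substrate) and a fictitious high-numbered GH family."""
    ec = f"9.{substrate_index + 1}.{j // 500 + 1}.{j % 500 + 1}"
    family = f"GH9{substrate_index + 1}{j % 7 + 1}"
    return ec, family


def _dual_key(pair_index: int, j: int) -> tuple[str, str]:
    """The j-th dual pool key for pair *pair_index* (EC second field 5–8)."""
    ec = f"9.{pair_index + 5}.{j // 500 + 1}.{j % 500 + 1}"
    family = f"GH98{pair_index + 1}"
    return ec, family


def _dual_counts(spec: GenomeSpec) -> list[int]:
    """Dual keys per pair: an even count bounded by the smaller budget of the
    two substrates.  Evenness keeps every substrate's incident dual count
    even (so the integer single-key budget works out exactly), and the
    minimum bound keeps each substrate's total dual weight at most
    ``dual_fraction * u_s``, so single counts never go negative."""
    counts = []
    for s, t in DUAL_PAIRS:
        budget = min(spec.u_of(s), spec.u_of(t))
        counts.append(2 * math.floor(spec.dual_fraction * budget / 2))
    return counts


def generate_genome(
    spec: GenomeSpec, pool_size: int = POOL_SIZE
) -> tuple[list[AnnotationRecord], list[SubstrateMapEntry], GenomeProfile]:
    """Generate one genome's annotation rows, matching map entries, and the
    exact ground-truth profile.

    Fully reproducible from ``spec.seed``; the scored profile of the output
    equals the returned ground truth (``U_s = u_s`` exactly; ``R_s`` equals
    the realized copy sums).
    """
    if spec.seed is None:
        raise ValueError(f"genome {spec.genome_id}: spec.seed must be set")
    rng = np.random.default_rng(spec.seed)

    k = _dual_counts(spec)
    incident = {
        s: k[i] + k[(i - 1) % len(DUAL_PAIRS)] for i, s in enumerate(SUBSTRATES)
    }
    singles = {}
    for s in SUBSTRATES:
        n_single = spec.u_of(s) - incident[s] // 2
        if n_single < 0:
            raise ValueError(
                f"genome {spec.genome_id}: dual_fraction too high for u[{s}]"
            )
        singles[s] = n_single

    # (key, family, substrates, mean multiplier) per drawn key
    drawn: list[tuple[str, str, tuple[str, ...], float]] = []
    for si, s in enumerate(SUBSTRATES):
        if singles[s] > pool_size:
            raise ValueError(
                f"genome {spec.genome_id}: {singles[s]} distinct {s} keys "
                f"requested but the pool holds {pool_size}"
            )
        idx = np.sort(rng.choice(pool_size, size=singles[s], replace=False))
        for j in idx:
            ec, family = _single_key(si, int(j))
            drawn.append((ec, family, (s,), spec.m_of(s)))
    for pi, (s, t) in enumerate(DUAL_PAIRS):
        if k[pi] > pool_size:
            raise ValueError(
                f"genome {spec.genome_id}: {k[pi]} dual keys requested for "
                f"({s}, {t}) but the pool holds {pool_size}"
            )
        idx = np.sort(rng.choice(pool_size, size=k[pi], replace=False))
        for j in idx:
            ec, family = _dual_key(pi, int(j))
            drawn.append((ec, family, (s, t), spec.m_of(s)))

    records: list[AnnotationRecord] = []
    profile = GenomeProfile(genome_id=spec.genome_id)
    entries: list[SubstrateMapEntry] = []
    protein_counter = 0
    for ec, family, subs, mult in drawn:
        copies = 1 + int(rng.poisson(mult - 1.0))
        w = 1.0 / len(subs)
        for s in subs:
            profile.unique[s] += w
            profile.redundant[s] += w * copies
        entries.append(
            SubstrateMapEntry(
                ec_pattern=ec, family_pattern="*", substrates=frozenset(subs)
            )
        )
        for _ in range(copies):
            protein_counter += 1
            records.append(
                AnnotationRecord(
                    genome_id=spec.genome_id,
                    protein_id=f"{spec.genome_id}_p{protein_counter:06d}",
                    family=family,
                    ec_labels=(ec,),
                )
            )
    return records, entries, profile


@dataclass(slots=True)
class CohortBundle:
    """A full synthetic input bundle plus its ground truth."""

    records: list[AnnotationRecord]
    substrate_map: SubstrateMap
    metadata: dict[str, GenomeMeta]
    assemblies: list[AssemblyMetadata]
    true_profiles: dict[str, GenomeProfile]
    expected_representatives: dict[str, str]


def generate_cohort(specs: Sequence[GenomeSpec], seed: int = 0) -> CohortBundle:
    """Generate a multi-genome cohort: merged annotations, consistent
    metadata, a deduplicated substrate map, and candidate assembly sets whose
    intended representative is known by construction.

    Genomes without an explicit per-spec seed get one derived from *seed*.
    """
    ids = [s.genome_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in cohort specs")

    rng = np.random.default_rng(seed)
    records: list[AnnotationRecord] = []
    entry_by_pair: dict[tuple[str, str], SubstrateMapEntry] = {}
    metadata: dict[str, GenomeMeta] = {}
    assemblies: list[AssemblyMetadata] = []
    true_profiles: dict[str, GenomeProfile] = {}
    expected_representatives: dict[str, str] = {}

    for i, spec in enumerate(specs):
        if spec.seed is None:
            spec = GenomeSpec(
                genome_id=spec.genome_id,
                u=spec.u,
                m=spec.m,
                dual_fraction=spec.dual_fraction,
                seed=int((seed * 1_000_003 + i) % 2**31),
                species=spec.species,
                genus=spec.genus,
                class_=spec.class_,
                phylum=spec.phylum,
            )
        recs, entries, profile = generate_genome(spec)
        records.extend(recs)
        true_profiles[spec.genome_id] = profile
        for e in entries:
            pair = (e.ec_pattern, e.family_pattern)
            prev = entry_by_pair.get(pair)
            if prev is not None and prev.substrates != e.substrates:
                raise AssertionError(
                    f"pool inconsistency for map entry {pair}"
                )  # pragma: no cover
            entry_by_pair[pair] = e
        metadata[spec.genome_id] = GenomeMeta(
            genome_id=spec.genome_id,
            species=spec.display_species,
            genus=spec.genus,
            class_=spec.class_,
            phylum=spec.phylum,
            accession=f"SYN_{spec.genome_id}.1",
        )

        # Three candidate assemblies; the first dominates on coverage x N50.
        taxid = f"tax_{spec.genome_id}"
        winner = f"SYN_{spec.genome_id}.1"
        expected_representatives[taxid] = winner
        assemblies.append(
            AssemblyMetadata(
                species_taxid=taxid,
                accession=winner,
                coverage=float(rng.integers(80, 121)),
                contig_lengths=[500_000, 300_000, 200_000],
            )
        )
        assemblies.append(
            AssemblyMetadata(
                species_taxid=taxid,
                accession=f"SYN_{spec.genome_id}.2",
                coverage=float(rng.integers(20, 51)),
                contig_lengths=[120_000, 90_000, 60_000, 30_000],
            )
        )
        assemblies.append(
            AssemblyMetadata(
                species_taxid=taxid,
                accession=f"SYN_{spec.genome_id}.3",
                coverage=float(rng.integers(5, 16)),
                contig_lengths=[50_000] * 10,
            )
        )

    return CohortBundle(
        records=records,
        substrate_map=SubstrateMap(entry_by_pair.values()),
        metadata=metadata,
        assemblies=assemblies,
        true_profiles=true_profiles,
        expected_representatives=expected_representatives,
    )


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort bundle as the four input TSVs the pipeline reads.

    Returns the path of each written table, keyed by role.
    """
    import csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "metadata": outdir / "metadata.tsv",
        "substrate_map": outdir / "substrate_map.tsv",
        "assemblies": outdir / "assemblies.tsv",
    }

    with open(paths["annotations"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "protein_id", "family", "subfamily", "ec"])
        for r in bundle.records:
            w.writerow(
                [r.genome_id, r.protein_id, r.family, r.subfamily or "", ";".join(r.ec_labels)]
            )

    with open(paths["metadata"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "species", "genus", "class", "phylum", "accession"])
        for m in bundle.metadata.values():
            w.writerow([m.genome_id, m.species, m.genus, m.class_, m.phylum, m.accession])

    with open(paths["substrate_map"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ec_pattern", "family_pattern", "substrates"])
        for e in sorted(
            bundle.substrate_map, key=lambda e: (e.ec_pattern, e.family_pattern)
        ):
            w.writerow([e.ec_pattern, e.family_pattern, ",".join(sorted(e.substrates))])

    with open(paths["assemblies"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species_taxid", "accession", "coverage", "n50", "contig_lengths"])
        for a in bundle.assemblies:
            w.writerow(
                [
                    a.species_taxid,
                    a.accession,
                    f"{a.coverage:g}",
                    a.n50 if a.n50 is not None else "",
                    ",".join(str(l) for l in a.contig_lengths or []),
                ]
            )
    return paths
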