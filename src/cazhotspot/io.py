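"""Tab-separated input/output for annotation tables, metadata and reports.

All tables are UTF-8 TSV with a header row; lines starting with ``#`` are
treated as comments.  Column names and the multi-EC delimiter are declared in
a :class:`Dialect` because annotator output formats differ; unknown extra
columns are ignored so heterogeneous upstream output can be ingested as-is.

Scores are serialized with at most one decimal place (trailing ``.0``
dropped), the precision at which they are reported; writing a profile table
and re-reading it reproduces the serialized values bit-exactly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .assembly import AssemblyMetadata, SelectionScore
from .observation import FAMILY_RE, ObservationInstance
from .ranking import GenusSummary, RankingEntry, RankWindow
from .scoring import GenomeProfile, RMSValue, round_half_up
from .substrate import SUBSTRATES, SubstrateMap, SubstrateMapEntry

__all__ = [
    "FormatError",
    "Dialect",
    "AnnotationRecord",
    "GenomeMeta",
    "DEFAULT_PHYLA",
    "read_annotations",
    "read_genome_metadata",
    "read_substrate_map",
    "parse_substrate_map_text",
    "read_assembly_metadata",
    "format_score",
    "write_profiles",
    "read_profiles",
    "write_ranking",
    "write_rms_table",
    "write_phylum_distribution",
    "write_genus_variation",
    "write_selection",
    "write_observations",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A table violates its format contract (missing column, bad value)."""


@dataclass(frozen=True, slots=True)
class Dialect:
    """Column names and separators of the annotation table dialect.

    Defaults model public CUPP-style output: tab-separated, one row per
    protein annotation, multiple EC predictions joined with ``";"``.
    """

    genome_col: str = "genome_id"
    protein_col: str = "protein_id"
    family_col: str = "family"
    subfamily_col: str = "subfamily"
    ec_col: str = "ec"
    ec_delimiter: str = ";"
    #: Tokens in the EC cell meaning "no prediction".
    na_tokens: frozenset[str] = frozenset({"", "-", "NA"})


@dataclass(frozen=True, slots=True)
class AnnotationRecord:
    """One per-protein annotation row: the raw input unit."""

    genome_id: str
    protein_id: str
    family: str
    ec_labels: tuple[str, ...]
    subfamily: str | None = None


#: Controlled list of fungal phyla accepted in genome metadata (extensible
#: via the ``extra_phyla`` argument of :func:`read_genome_metadata`).
DEFAULT_PHYLA: frozenset[str] = frozenset(
    {
        "Ascomycota",
        "Basidiomycota",
        "Chytridiomycota",
        "Blastocladiomycota",
        "Mucoromycota",
        "Zoopagomycota",
        "Glomeromycota",
        "Cryptomycota",
        "Microsporidia",
        "Olpidiomycota",
    }
)


@dataclass(frozen=True, slots=True)
class GenomeMeta:
    genome_id: str
    species: str
    genus: str
    class_: str
    phylum: str
    accession: str = ""


def _read_table(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    """Read a commented TSV into row dicts, checking required columns."""
    path = Path(path)
    rows: list[dict[str, str]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        logger.warning("table %s is empty", path)
        return rows
    reader = csv.DictReader(lines, delimiter="\t")
    missing = [c for c in required if c not in (reader.fieldnames or [])]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for row in reader:
        rows.append({k: (v or "").strip() for k, v in row.items() if k is not None})
    if not rows:
        logger.warning("table %s has a header but no data rows", path)
    return rows


def read_annotations(
    path: str | Path, dialect: Dialect = Dialect(), strict: bool = True
) -> list[AnnotationRecord]:
    """Read a per-protein annotation table.

    Rows whose family does not parse as a CAZy family label are rejected with
    row-numbered diagnostics (1-based over data rows): with ``strict=True``
    (default) any rejected row raises :class:`FormatError`; otherwise they
    are skipped with a warning.  Multi-EC cells are split on the dialect
    delimiter and preserved as lists.
    """
    d = dialect
    rows = _read_table(path, [d.genome_col, d.protein_col, d.family_col, d.ec_col])
    records: list[AnnotationRecord] = []
    problems: list[str] = []
    for i, row in enumerate(rows, start=1):
        genome_id = row[d.genome_col]
        protein_id = row[d.protein_col]
        family = row[d.family_col]
        if not genome_id or not protein_id:
            problems.append(f"row {i}: empty genome_id or protein_id")
            continue
        if FAMILY_RE.match(family) is None:
            problems.append(f"row {i}: unparseable family {family!r}")
            continue
        ec_cell = row[d.ec_col]
        ec_labels = tuple(
            tok.strip()
            for tok in ec_cell.split(d.ec_delimiter)
            if tok.strip() not in d.na_tokens
        )
        subfamily = row.get(d.subfamily_col) or None
        records.append(
            AnnotationRecord(genome_id, protein_id, family, ec_labels, subfamily)
        )
    if problems:
        msg = f"{path}: {len(problems)} rejected row(s): " + "; ".join(problems[:20])
        if strict:
            raise FormatError(msg)
        logger.warning(msg)
    return records


def read_genome_metadata(
    path: str | Path, extra_phyla: Iterable[str] = ()
) -> dict[str, GenomeMeta]:
    """Read the genome metadata table into a genome_id → GenomeMeta map.

    genome_ids must be unique and phyla must come from the controlled list
    (:data:`DEFAULT_PHYLA` plus *extra_phyla*).
    """
    allowed = DEFAULT_PHYLA | set(extra_phyla)
    rows = _read_table(path, ["genome_id", "species", "genus", "class", "phylum"])
    out: dict[str, GenomeMeta] = {}
    for i, row in enumerate(rows, start=1):
        gid = row["genome_id"]
        if gid in out:
            raise FormatError(f"{path}: row {i}: duplicate genome_id {gid!r}")
        if row["phylum"] not in allowed:
            raise FormatError(
                f"{path}: row {i}: phylum {row['phylum']!r} not in the "
                f"controlled list (pass extra_phyla to extend it)"
            )
        out[gid] = GenomeMeta(
            genome_id=gid,
            species=row["species"],
            genus=row["genus"],
            class_=row["class"],
            phylum=row["phylum"],
            accession=row.get("accession", ""),
        )
    return out


def parse_substrate_map_text(text: str) -> SubstrateMap:
    """Parse substrate-map TSV content (columns ec_pattern, family_pattern,
    substrates with comma-separated tokens)."""
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    required = ["ec_pattern", "family_pattern", "substrates"]
    missing = [c for c in required if c not in (reader.fieldnames or [])]
    if missing:
        raise FormatError(f"substrate map: missing required column(s) {missing}")
    entries = []
    for i, row in enumerate(reader, start=1):
        tokens = [t.strip() for t in row["substrates"].split(",") if t.strip()]
        bad = [t for t in tokens if t not in SUBSTRATES]
        if bad:
            raise FormatError(
                f"substrate map row {i}: unknown substrate token(s) {bad}"
            )
        if not tokens:
            raise FormatError(f"substrate map row {i}: empty substrate set")
        entries.append(
            SubstrateMapEntry(
                ec_pattern=row["ec_pattern"].strip(),
                family_pattern=row["family_pattern"].strip(),
                substrates=frozenset(tokens),
            )
        )
    try:
        return SubstrateMap(entries)
    except ValueError as exc:
        raise FormatError(f"substrate map: {exc}") from exc


def read_substrate_map(path: str | Path) -> SubstrateMap:
    """Read and validate a substrate-association map."""
    return parse_substrate_map_text(Path(path).read_text(encoding="utf-8"))


_FASTA_SUFFIXES = (".fasta", ".fa", ".fna")


def read_assembly_metadata(
    path: str | Path, fasta_dir: str | Path | None = None
) -> list[AssemblyMetadata]:
    """Read candidate-assembly metadata.

    Each row needs a resolvable source of contig lengths: an ``n50`` value, a
    comma-separated ``contig_lengths`` cell, or a contig FASTA named by
    accession under *fasta_dir*.  Missing coverage is treated as zero with a
    warning rather than aborting the run (public assembly metadata is often
    incomplete; a zero effectively deprioritizes the assembly).
    """
    rows = _read_table(path, ["species_taxid", "accession", "coverage"])
    out: list[AssemblyMetadata] = []
    for i, row in enumerate(rows, start=1):
        accession = row["accession"]
        cov_cell = row["coverage"]
        if cov_cell == "":
            logger.warning(
                "%s row %d: assembly %s has no coverage; treating as 0",
                path,
                i,
                accession,
            )
            coverage = 0.0
        else:
            coverage = float(cov_cell)
        n50_val = int(row["n50"]) if row.get("n50") else None
        lengths = None
        if row.get("contig_lengths"):
            lengths = [int(t) for t in row["contig_lengths"].split(",") if t.strip()]
        if n50_val is None and lengths is None:
            lengths = _contig_lengths_from_fasta(accession, fasta_dir)
            if lengths is None:
                raise FormatError(
                    f"{path} row {i}: assembly {accession}: no n50, no "
                    f"contig_lengths and no contig FASTA found"
                )
        out.append(
            AssemblyMetadata(
                species_taxid=row["species_taxid"],
                accession=accession,
                coverage=coverage,
                contig_lengths=lengths,
                n50=n50_val,
            )
        )
    return out


def _contig_lengths_from_fasta(
    accession: str, fasta_dir: str | Path | None
) -> list[int] | None:
    if fasta_dir is None:
        return None
    for suffix in _FASTA_SUFFIXES:
        fasta = Path(fasta_dir) / f"{accession}{suffix}"
        if fasta.exists():
            return [len(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")]
    return None


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def format_score(x: float) -> str:
    """Render a score with at most one decimal, dropping a trailing ``.0``."""
    r = round_half_up(x, 1)
    if r == int(r):
        return str(int(r))
    return f"{r:.1f}"


_PROFILE_COLUMNS = (
    ["genome_id"]
    + [f"R_{s}" for s in SUBSTRATES]
    + ["T_R"]
    + [f"U_{s}" for s in SUBSTRATES]
    + ["T_U"]
)


def write_profiles(profiles: Sequence[GenomeProfile], path: str | Path) -> None:
    """Write a per-genome profile table (redundant and unique scores per
    substrate plus totals)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PROFILE_COLUMNS)
        for p in profiles:
            w.writerow(
                [p.genome_id]
                + [format_score(p.redundant[s]) for s in SUBSTRATES]
                + [format_score(p.total_redundant)]
                + [format_score(p.unique[s]) for s in SUBSTRATES]
                + [format_score(p.total_unique)]
            )


def read_profiles(path: str | Path) -> list[GenomeProfile]:
    """Read a profile table written by :func:`write_profiles` back into
    :class:`GenomeProfile` objects (totals are recomputed, not trusted)."""
    rows = _read_table(path, [c for c in _PROFILE_COLUMNS if not c.startswith("T_")])
    out = []
    for row in rows:
        out.append(
            GenomeProfile(
                genome_id=row["genome_id"],
                redundant={s: float(row[f"R_{s}"]) for s in SUBSTRATES},
                unique={s: float(row[f"U_{s}"]) for s in SUBSTRATES},
            )
        )
    return out


def write_ranking(ranking: Sequence[RankingEntry], path: str | Path) -> None:
    """Write a ranking table.

    Both the tie-aware competition rank and the ordinal output position are
    emitted; ``tie`` carries ``*`` for scores shared by several genomes.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["rank", "position", "tie", "genome_id", "species", "class", "phylum", "score"]
        )
        for pos, e in enumerate(ranking, start=1):
            w.writerow(
                [
                    e.rank,
                    pos,
                    "*" if e.tied else "",
                    e.genome_id,
                    e.species,
                    e.class_,
                    e.phylum,
                    format_score(e.score),
                ]
            )


def write_rms_table(
    rows: Sequence[tuple[str, str, RMSValue]], path: str | Path
) -> None:
    """Write an RMS table; *rows* are (genome_id, grouping, RMSValue).

    Flags follow the reporting convention: ``*`` marks ratios above 8,
    ``¤`` marks ratios below 3; an undefined ratio prints ``NA``.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "grouping", "redundant", "unique", "rms", "flag"])
        for genome_id, grouping, v in rows:
            w.writerow(
                [
                    genome_id,
                    grouping,
                    format_score(v.numerator),
                    format_score(v.denominator),
                    "NA" if v.ratio is None else f"{v.rounded:.1f}",
                    v.flag_char,
                ]
            )


def write_phylum_distribution(
    windows: Sequence[RankWindow], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["window_start", "window_end", "phylum", "n_species"])
        for win in windows:
            for phylum in sorted(win.phylum_counts):
                w.writerow([win.start, win.end, phylum, win.phylum_counts[phylum]])


def write_genus_variation(
    summaries: Sequence[GenusSummary], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["genus", "n_genomes", "best_rank", "worst_rank", "median_rank", "spread"]
        )
        for s in summaries:
            w.writerow(
                [
                    s.genus,
                    s.n_genomes,
                    s.best_rank,
                    s.worst_rank,
                    format_score(s.median_rank),
                    s.spread,
                ]
            )


def write_selection(
    selection: Mapping[str, str], table: Sequence[SelectionScore], path: str | Path
) -> None:
    """Write the representative-assembly audit table (one row per candidate,
    selected winners marked)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["species_taxid", "accession", "coverage", "n50", "score", "selected"]
        )
        for s in table:
            w.writerow(
                [
                    s.species_taxid,
                    s.accession,
                    format_score(s.coverage),
                    s.n50,
                    format_score(s.score),
                    "yes" if s.selected else "",
                ]
            )


def write_observations(
    instances: Sequence[ObservationInstance], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "protein_id", "key"])
        for inst in instances:
            w.writerow([inst.genome_id, inst.protein_id, str(inst.key)])
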