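"""Domain types and readers/writers for FASTA bins, quality tables and ANI edge lists.

The on-disk dialects are deliberately boring: plain (or gzipped) FASTA for
bins, a CheckM2-style ``quality_report.tsv`` for quality values, and a
skani-``dist``-style TSV for precomputed ANI edges.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

FASTA_SUFFIXES = (".fa", ".fasta", ".fna")

# uppercase then map anything outside {A,C,G,T,N} to N
_NORMALIZE = bytes(b if b in b"ACGTN" else ord("N") for b in range(256))


def normalize_sequence(seq: str) -> str:
    """Uppercase a DNA string and collapse non-ACGTN symbols to N."""
    return seq.encode("ascii", errors="replace").upper().translate(_NORMALIZE).decode("ascii")


@dataclass(frozen=True)
class Contig:
    """A single named sequence inside a bin."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceBin:
    """A named set of contigs from one sample; the unit being dereplicated."""

    bin_id: str
    sample_id: str
    contigs: tuple[Contig, ...]

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class QualityRecord:
    """Completeness/contamination for one bin plus derived scores.

    ``quality_score`` is completeness − 5 × contamination, the standard MAG
    ranking statistic; ``purity`` is the complement of contamination capped
    at 0.
    """

    bin_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise InputError(
                f"completeness for {self.bin_id!r} must be in [0, 100], got {self.completeness}"
            )
        if self.contamination < 0.0:
            raise InputError(
                f"contamination for {self.bin_id!r} must be >= 0, got {self.contamination}"
            )

    @property
    def purity(self) -> float:
        return 100.0 - min(self.contamination, 100.0)

    @property
    def quality_score(self) -> float:
        return self.completeness - 5.0 * self.contamination


@dataclass(frozen=True)
class AniEdge:
    """An undirected ANI estimate between two distinct bins.

    Endpoints are stored in canonical (lexicographic) order.
    """

    bin_a: str
    bin_b: str
    ani: float
    aligned_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_a == self.bin_b:
            raise InputError(f"self-edge for bin {self.bin_a!r}")
        if self.bin_a > self.bin_b:
            a, b = self.bin_b, self.bin_a
            object.__setattr__(self, "bin_a", a)
            object.__setattr__(self, "bin_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.bin_a, self.bin_b)


def _strip_fasta_suffix(name: str) -> str:
    if name.endswith(".gz"):
        name = name[:-3]
    for suf in FASTA_SUFFIXES:
        if name.endswith(suf):
            return name[: -len(suf)]
    return name


def _open_maybe_gzip(path: Path):
    if path.name.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_fasta_path(path: Path) -> bool:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    return path.is_file() and name.endswith(FASTA_SUFFIXES)


def read_fasta(path: Path | str) -> list[Contig]:
    """Read one FASTA file into normalized contigs."""
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        first = handle.read(1)
        if first not in (">", ""):
            raise InputError(f"unparsable FASTA record in {path}: file does not start with '>'")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            seq = normalize_sequence(str(record.seq))
            if not seq:
                raise InputError(f"unparsable FASTA record in {path}: empty sequence for {record.id!r}")
            if record.id in seen:
                raise InputError(f"duplicate contig id {record.id!r} in {path}")
            seen.add(record.id)
            contigs.append(Contig(record.id, seq))
    return contigs


def read_bins(directory_path: Path | str, sample_delimiter: str = "__") -> list[SequenceBin]:
    """Load every FASTA file in a directory as one :class:`SequenceBin`.

    The bin id is the file stem; the sample id is the text before the first
    ``sample_delimiter`` in the stem, or the whole stem when the delimiter is
    absent.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise InputError(f"bin directory not found: {directory}")
    paths = sorted(p for p in directory.iterdir() if _is_fasta_path(p))
    if not paths:
        raise InputError(f"no FASTA files (*.fa/*.fasta/*.fna[.gz]) in {directory}")
    bins: list[SequenceBin] = []
    seen: set[str] = set()
    for path in paths:
        bin_id = _strip_fasta_suffix(path.name)
        if bin_id in seen:
            raise InputError(f"duplicate bin id {bin_id!r} (from {path})")
        seen.add(bin_id)
        if sample_delimiter and sample_delimiter in bin_id:
            sample_id = bin_id.split(sample_delimiter, 1)[0]
        else:
            sample_id = bin_id
        contigs = read_fasta(path)
        bins.append(SequenceBin(bin_id=bin_id, sample_id=sample_id, contigs=tuple(contigs)))
    return bins


_NAME_ALIASES = ("name", "bin_id")
_COMPLETENESS_ALIASES = ("completeness",)
_CONTAMINATION_ALIASES = ("contamination",)


def _find_column(columns: Sequence[str], aliases: Sequence[str], what: str) -> str:
    lowered = {c.lower(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    raise FormatError(f"quality table is missing a {what} column (looked for {aliases})")


def read_quality_table(path: Path | str) -> dict[str, QualityRecord]:
    """Parse a CheckM2-style quality TSV into a bin_id → record mapping.

    Requires (case-insensitive) Name, Completeness and Contamination
    columns; extra columns are ignored.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"quality table {path} is empty") from exc
    name_col = _find_column(table.columns, _NAME_ALIASES, "Name")
    comp_col = _find_column(table.columns, _COMPLETENESS_ALIASES, "Completeness")
    cont_col = _find_column(table.columns, _CONTAMINATION_ALIASES, "Contamination")

    records: dict[str, QualityRecord] = {}
    for _, row in table.iterrows():
        name = str(row[name_col])
        if name in records:
            raise FormatError(f"duplicate Name {name!r} in quality table {path}")
        try:
            completeness = float(row[comp_col])
            contamination = float(row[cont_col])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric quality values for {name!r} in {path}") from exc
        try:
            records[name] = QualityRecord(name, completeness, contamination)
        except InputError as exc:
            raise FormatError(str(exc)) from exc
    return records


_SKANI_COLUMNS = {
    "ref": "Ref_file",
    "query": "Query_file",
    "ani": "ANI",
    "af_ref": "Align_fraction_ref",
    "af_query": "Align_fraction_query",
}


def read_ani_edges(path: Path | str, known_bins: Iterable[str]) -> list[AniEdge]:
    """Parse a skani-``dist`` TSV into canonical ANI edges.

    Genome paths are mapped to bin ids by file stem. Rows naming unknown
    bins are skipped with a warning; if every row is skipped the file is
    considered unusable. When both orientations of a pair are present the
    one with the higher ANI wins; the aligned fraction of an edge is the
    minimum of the two reported fractions on the winning row.
    """
    known = set(known_bins)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"ANI edge list {path} is empty") from exc
    missing = [c for c in _SKANI_COLUMNS.values() if c not in table.columns]
    if missing:
        raise FormatError(f"ANI edge list {path} is missing columns: {missing}")

    best: dict[tuple[str, str], AniEdge] = {}
    skipped = 0
    total = 0
    for _, row in table.iterrows():
        total += 1
        a = _strip_fasta_suffix(Path(str(row[_SKANI_COLUMNS["ref"]])).name)
        b = _strip_fasta_suffix(Path(str(row[_SKANI_COLUMNS["query"]])).name)
        if a not in known or b not in known:
            logger.warning("skipping ANI row with unknown bin(s): %r / %r", a, b)
            skipped += 1
            continue
        if a == b:
            logger.debug("skipping self-comparison row for %r", a)
            continue
        ani = float(row[_SKANI_COLUMNS["ani"]])
        af = min(float(row[_SKANI_COLUMNS["af_ref"]]), float(row[_SKANI_COLUMNS["af_query"]]))
        if af > 1.0:  # skani reports percentages; normalize to a fraction
            af /= 100.0
        edge = AniEdge(a, b, ani, af)
        prior = best.get(edge.pair)
        if prior is None or edge.ani > prior.ani:
            best[edge.pair] = edge
    if total > 0 and skipped == total:
        raise InputError(f"every row of {path} named unknown bins; nothing usable")
    return [best[pair] for pair in sorted(best)]


@dataclass(frozen=True)
class RetainedBin:
    """One bin in the final output plus its provenance."""

    bin: SequenceBin
    quality: QualityRecord
    source: str  # "input" | "merged"
    cluster_id: str
    members: tuple[str, ...]


@dataclass
class DereplicationResult:
    """The final non-redundant bin set with full provenance."""

    retained: list[RetainedBin] = field(default_factory=list)
    decisions: list = field(default_factory=list)  # list[ClusterDecision]
    dropped_redundant: list[tuple[str, str, float]] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)


REPORT_COLUMNS = (
    "bin_id",
    "source",
    "cluster_id",
    "completeness",
    "contamination",
    "quality_score",
    "member_bins",
)


def write_fasta(contigs: Iterable[Contig], path: Path | str, width: int = 80) -> None:
    with open(path, "w") as out:
        for contig in contigs:
            out.write(f">{contig.id}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_output(result: DereplicationResult, directory_path: Path | str) -> list[Path]:
    """Write one FASTA per retained bin plus the dereplication report TSV.

    Returns the manifest of files written, report first.
    """
    directory = Path(directory_path)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {directory}: {exc}") from exc

    manifest: list[Path] = []
    report_path = directory / "derep_report.tsv"
    retained = sorted(result.retained, key=lambda r: r.bin.bin_id)
    with open(report_path, "w") as report:
        report.write("\t".join(REPORT_COLUMNS) + "\n")
        for entry in retained:
            q = entry.quality
            report.write(
                "\t".join(
                    [
                        entry.bin.bin_id,
                        entry.source,
                        entry.cluster_id,
                        repr(q.completeness),
                        repr(q.contamination),
                        repr(q.quality_score),
                        ",".join(entry.members),
                    ]
                )
                + "\n"
            )
    manifest.append(report_path)
    for entry in retained:
        fasta_path = directory / f"{entry.bin.bin_id}.fa"
        write_fasta(entry.bin.contigs, fasta_path)
        manifest.append(fasta_path)
    return manifest


def write_run_summary(result: DereplicationResult, path: Path | str) -> None:
    """Flat ``key: value`` run summary (stage counts, decisions, drops)."""
    with open(path, "w") as out:
        for key, value in result.stage_counts.items():
            out.write(f"{key}: {value}\n")
        out.write(f"retained: {len(result.retained)}\n")
        out.write(f"dropped_redundant: {len(result.dropped_redundant)}\n")


def canonical_edge_set(edges: Iterable[AniEdge]) -> dict[tuple[str, str], AniEdge]:
    """Deduplicate edges on unordered pairs, keeping the higher ANI."""
    best: dict[tuple[str, str], AniEdge] = {}
    for edge in edges:
        prior = best.get(edge.pair)
        if prior is None or edge.ani > prior.ani:
            best[edge.pair] = edge
    return best
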