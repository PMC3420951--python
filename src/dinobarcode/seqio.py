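"""Readers and writers for the formats the barcoding pipeline touches.

The analysis path consumes a *pre-aligned* multi-FASTA (alignment is an
upstream step, e.g. MAFFT); unaligned input is rejected with a message
directing the user to align first.  Strain metadata arrive as TSV/CSV
tables keyed on ``strain_id``; Newick is emitted for tree output.

Normalisation at load: sequences are case-folded to upper case and 'U'
is mapped to 'T', because all downstream distances are DNA-alphabet
p-distances.
"""

from __future__ import annotations

import ast
import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .njtree import Tree

__all__ = [
    "ParseError",
    "AlignmentError",
    "SequenceRecord",
    "Alignment",
    "StrainRow",
    "StrainTable",
    "CloneGroupTable",
    "STATUSES",
    "read_fasta",
    "write_fasta",
    "read_strain_table",
    "write_strain_table",
    "read_clone_groups",
    "write_newick",
]

IUPAC_CHARS = frozenset("ACGTUNRYSWKMBDHV-")
UNAMBIGUOUS = frozenset("ACGT")

#: Sequencing-outcome categories for a culture-collection strain.
STATUSES = ("barcoded", "amplification_failed", "sequencing_failed", "low_quality")
FAILURE_STATUSES = tuple(s for s in STATUSES if s != "barcoded")


class ParseError(ValueError):
    """Malformed or empty input file."""


class AlignmentError(ValueError):
    """Structurally valid file whose records do not form an alignment."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode sequence.

    ``id`` is whatever identifier the dataset keys on (culture-collection
    strain id, BOLD process id, clone accession); ``taxon_label`` is the
    given species name, possibly empty.
    """

    id: str
    sequence: str
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        if not self.sequence:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - IUPAC_CHARS
        if bad:
            raise ParseError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length sequence records."""

    records: tuple[SequenceRecord, ...]
    n_columns: int

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "Alignment":
        records = tuple(records)
        if not records:
            raise ParseError("alignment has no records")
        n = len(records[0].sequence)
        for i, rec in enumerate(records):
            if len(rec.sequence) != n:
                raise AlignmentError(
                    f"record {i + 1} ({rec.id!r}) has length {len(rec.sequence)}, "
                    f"expected {n}; input must be a pre-aligned FASTA "
                    "(align upstream, e.g. with MAFFT, before running the pipeline)"
                )
        ids = [r.id for r in records]
        dupes = {x for x in ids if ids.count(x) > 1}
        if dupes:
            raise ParseError(f"duplicate sequence ids: {sorted(dupes)}")
        return cls(records=records, n_columns=n)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> Alignment:
    """Read a pre-aligned multi-FASTA file.

    Raises :class:`ParseError` for malformed/empty FASTA and
    :class:`AlignmentError` (naming the offending record) for unequal
    lengths — two distinct failure modes.
    """
    path = Path(path)
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not raw:
        raise ParseError(f"no FASTA records found in {path}")
    records = []
    for rec in raw:
        label = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, sequence=_normalise(str(rec.seq)), taxon_label=label)
        )
    return Alignment.from_records(records)


def write_fasta(alignment: Alignment, path: str | Path, width: int = 70) -> None:
    """Write an alignment back to multi-FASTA, preserving record order."""
    with open(path, "w") as fh:
        for rec in alignment:
            header = f">{rec.id}" + (f" {rec.taxon_label}" if rec.taxon_label else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Strain metadata tables


@dataclass(frozen=True)
class StrainRow:
    strain_id: str
    given_species: str = ""
    genus: str = ""
    collection: str = ""
    source: str = "this_study"
    synonyms: tuple[str, ...] = ()
    status: str = "barcoded"
    complex_name: str = ""
    cross_refs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ParseError(
                f"strain {self.strain_id!r}: unknown status {self.status!r}; "
                f"allowed values: {', '.join(STATUSES)}"
            )


class StrainTable:
    """Strain metadata keyed on strain id, with a symmetric synonym relation."""

    def __init__(self, rows: Iterable[StrainRow]):
        self._rows: dict[str, StrainRow] = {}
        for row in rows:
            if row.strain_id in self._rows:
                raise ParseError(f"duplicate strain_id {row.strain_id!r}")
            self._rows[row.strain_id] = row
        self._symmetrize()

    def _symmetrize(self) -> None:
        extra: dict[str, set[str]] = {sid: set(r.synonyms) for sid, r in self._rows.items()}
        for sid, row in self._rows.items():
            for syn in row.synonyms:
                if syn in extra:
                    extra[syn].add(sid)
        for sid, syns in extra.items():
            syns.discard(sid)
            row = self._rows[sid]
            if set(row.synonyms) != syns:
                self._rows[sid] = replace(row, synonyms=tuple(sorted(syns)))

    def __contains__(self, strain_id: str) -> bool:
        return strain_id in self._rows

    def __getitem__(self, strain_id: str) -> StrainRow:
        return self._rows[strain_id]

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self) -> Iterator[StrainRow]:
        return iter(self._rows.values())

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._rows)

    def get(self, strain_id: str, default: StrainRow | None = None) -> StrainRow | None:
        return self._rows.get(strain_id, default)

    def genus_of(self, strain_id: str) -> str:
        """Genus column if present, else the first token of the given name."""
        row = self._rows[strain_id]
        if row.genus:
            return row.genus
        return row.given_species.split()[0] if row.given_species else ""

    def synonym_pairs(self) -> list[tuple[str, str]]:
        """Unordered declared-synonym pairs, each reported once, input order."""
        seen: set[frozenset[str]] = set()
        pairs: list[tuple[str, str]] = []
        for sid, row in self._rows.items():
            for syn in row.synonyms:
                key = frozenset((sid, syn))
                if len(key) == 2 and key not in seen:
                    seen.add(key)
                    pairs.append((sid, syn))
        return pairs


_STRAIN_COLUMNS = (
    "strain_id", "given_species", "genus", "collection", "source",
    "synonyms", "status", "complex_name", "cross_refs",
)


def _parse_cross_refs(text: str) -> dict[str, str]:
    text = text.strip()
    if not text:
        return {}
    if text.startswith("{"):
        return {str(k): str(v) for k, v in ast.literal_eval(text).items()}
    out = {}
    for item in text.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_strain_table(path: str | Path, dialect: str = "tsv") -> StrainTable:
    """Read a TSV (default) or CSV strain metadata table.

    The only mandatory column is ``strain_id``; missing optional columns
    are filled with defaults.  Synonym lists use ';' as the in-cell
    separator and are symmetrized after load.  Delimiter guessing is
    deliberately off: pass ``dialect`` explicitly.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    delim = "\t" if dialect == "tsv" else ","
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "strain_id" not in reader.fieldnames:
            raise ParseError(f"{path}: header must contain a 'strain_id' column")
        rows = []
        for raw in reader:
            get = lambda k, d="": (raw.get(k) or d).strip()
            synonyms = tuple(s.strip() for s in get("synonyms").split(";") if s.strip())
            rows.append(
                StrainRow(
                    strain_id=get("strain_id"),
                    given_species=get("given_species"),
                    genus=get("genus"),
                    collection=get("collection"),
                    source=get("source", "this_study") or "this_study",
                    synonyms=synonyms,
                    status=get("status", "barcoded") or "barcoded",
                    complex_name=get("complex_name"),
                    cross_refs=_parse_cross_refs(get("cross_refs")),
                )
            )
    return StrainTable(rows)


def write_strain_table(table: StrainTable, path: str | Path, dialect: str = "tsv") -> None:
    delim = "\t" if dialect == "tsv" else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(_STRAIN_COLUMNS)
        for row in table:
            writer.writerow([
                row.strain_id, row.given_species, row.genus, row.collection,
                row.source, ";".join(row.synonyms), row.status, row.complex_name,
                ";".join(f"{k}={v}" for k, v in row.cross_refs.items()),
            ])


# ---------------------------------------------------------------------------
# Clone groups (rDNA paralogue libraries)


class CloneGroupTable:
    """Maps a parent strain to the clone accessions sequenced from it."""

    def __init__(self, groups: Mapping[str, Iterable[str]]):
        self.groups: dict[str, tuple[str, ...]] = {}
        seen: dict[str, str] = {}
        for parent, clones in groups.items():
            clones = tuple(clones)
            for c in clones:
                if c in seen:
                    raise ParseError(
                        f"clone {c!r} appears in groups {seen[c]!r} and {parent!r}"
                    )
                seen[c] = parent
            self.groups[parent] = clones

    def __len__(self) -> int:
        return len(self.groups)

    def items(self):
        return self.groups.items()


def read_clone_groups(path: str | Path, dialect: str = "tsv") -> CloneGroupTable:
    """Read a long-format clone table with columns parent_strain, clone_id."""
    delim = "\t" if dialect == "tsv" else ","
    groups: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        need = {"parent_strain", "clone_id"}
        if reader.fieldnames is None or not need.issubset(reader.fieldnames):
            raise ParseError(f"{path}: header must contain columns {sorted(need)}")
        for raw in reader:
            parent = (raw["parent_strain"] or "").strip()
            clone = (raw["clone_id"] or "").strip()
            if parent and clone:
                groups.setdefault(parent, []).append(clone)
    return CloneGroupTable(groups)


def write_clone_groups(table: CloneGroupTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["parent_strain", "clone_id"])
        for parent, clones in table.items():
            for clone in clones:
                writer.writerow([parent, clone])


# ---------------------------------------------------------------------------
# Newick

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _quote_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: "Tree", precision: int = 6) -> str:
    """Serialise a tree to Newick with branch lengths at fixed precision."""

    def fmt(node) -> str:
        if node.is_leaf:
            body = _quote_label(node.name)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.length is not None:
            body += f":{node.length:.{precision}f}"
        return body

    root = tree.root
    return "(" + ",".join(fmt(c) for c in root.children) + ");"


def write_newick(tree: "Tree", path: str | Path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree, precision=precision) + "\n")
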