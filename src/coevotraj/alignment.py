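"""Core containers for paired histidine-kinase / response-regulator alignments.

A *cognate pair* is a sensor histidine kinase (HK) and a response regulator
(RR) encoded by adjacent genes.  The analysis operates on a concatenated
alignment whose rows are ``hk.aligned_seq + rr.aligned_seq`` for each cognate
pair, with per-column provenance recording which protein and which source
column every concatenated column came from.

Column indices are 1-based everywhere in the public API, matching the
field's "position 8 / position 270" convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import AlignIO, SeqIO

#: Canonical residue alphabet: 20 amino acids plus the gap character.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
GAP_CODE = ALPHABET.index(GAP)
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}

HK = "HK"
RR = "RR"


class AlignmentFormatError(ValueError):
    """Raised for malformed records or inconsistent alignment geometry."""


class NoReferenceMapping(LookupError):
    """Raised when a column falls on a gap in the designated reference row."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned domain sequence with its genome-ordinal gene identifier.

    ``gene_index`` is the integer identifier used for operon-adjacency
    pairing: an HK and an RR whose indices differ by one are treated as a
    cognate pair.
    """

    record_id: str
    gene_index: int
    protein_class: str  # HK or RR
    aligned_seq: str

    def __post_init__(self) -> None:
        if self.gene_index < 0:
            raise AlignmentFormatError(
                f"gene_index must be >= 0, got {self.gene_index} ({self.record_id})"
            )
        if self.protein_class not in (HK, RR):
            raise AlignmentFormatError(
                f"protein_class must be HK or RR, got {self.protein_class!r}"
            )
        bad = set(self.aligned_seq) - set(ALPHABET)
        if bad:
            raise AlignmentFormatError(
                f"record {self.record_id}: unknown symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class ColumnOrigin:
    """Provenance of one concatenated column: source protein and 1-based source column."""

    source_protein: str
    source_col: int


@dataclass(frozen=True)
class PairedRow:
    hk_record_id: str
    rr_record_id: str
    seq: str


@dataclass
class PairedAlignment:
    """Concatenated cognate-pair alignment (HK columns precede RR columns)."""

    rows: list[PairedRow]
    column_meta: list[ColumnOrigin]

    def __post_init__(self) -> None:
        n = self.n_cols
        for row in self.rows:
            if len(row.seq) != n:
                raise AlignmentFormatError(
                    f"row {row.hk_record_id}+{row.rr_record_id} has length "
                    f"{len(row.seq)}, expected {n}"
                )
            bad = set(row.seq) - set(ALPHABET)
            if bad:
                raise AlignmentFormatError(
                    f"row {row.hk_record_id}+{row.rr_record_id}: "
                    f"unknown symbols {sorted(bad)}"
                )

    @property
    def n_cols(self) -> int:
        return len(self.column_meta)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[PairedRow]:
        return iter(self.rows)

    def column(self, col: int) -> str:
        """Return column ``col`` (1-based) as a string over rows."""
        self._check_col(col)
        return "".join(row.seq[col - 1] for row in self.rows)

    def _check_col(self, col: int) -> None:
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range 1..{self.n_cols}")

    def to_codes(self) -> np.ndarray:
        """Encode as an (n_rows, n_cols) uint8 matrix over the 21-symbol alphabet."""
        if not self.rows:
            return np.empty((0, self.n_cols), dtype=np.uint8)
        flat = np.frombuffer(
            "".join(r.seq for r in self.rows).encode("ascii"), dtype=np.uint8
        )
        lut = np.zeros(128, dtype=np.uint8)
        for ch, code in _CODE.items():
            lut[ord(ch)] = code
        return lut[flat].reshape(self.n_rows, self.n_cols)

    def row_by_reference(self, reference_row_id: str) -> PairedRow:
        """Find the row whose HK id, RR id, or ``hk|rr`` joint id matches."""
        for row in self.rows:
            if reference_row_id in (
                row.hk_record_id,
                row.rr_record_id,
                f"{row.hk_record_id}|{row.rr_record_id}",
            ):
                return row
        raise KeyError(f"reference row {reference_row_id!r} not found")

    def subset_columns(self, keep: list[int]) -> "PairedAlignment":
        """New alignment restricted to 1-based columns ``keep`` (in order)."""
        for c in keep:
            self._check_col(c)
        idx = [c - 1 for c in keep]
        rows = [
            PairedRow(r.hk_record_id, r.rr_record_id, "".join(r.seq[i] for i in idx))
            for r in self.rows
        ]
        meta = [self.column_meta[i] for i in idx]
        return PairedAlignment(rows, meta)


@dataclass(frozen=True)
class ColumnMapEntry:
    filtered_col: int  # 1-based in the filtered alignment
    source_protein: str
    source_col: int  # 1-based within the source protein's alignment
    original_col: int  # 1-based in the unfiltered concatenated alignment
    reference_residue: Optional[int]  # 1-based ungapped reference position, or None


@dataclass
class ColumnMap:
    """Mapping from filtered concatenated columns back to their origins.

    When built with a designated reference row (e.g. the EnvZ/OmpR pair),
    each entry also carries the 1-based residue number in the ungapped
    reference sequence of the source protein, giving the familiar
    "EnvZ T250"-style numbering.
    """

    entries: list[ColumnMapEntry]
    reference_row_id: Optional[str] = None

    def __post_init__(self) -> None:
        refs = [
            (e.source_protein, e.reference_residue)
            for e in self.entries
            if e.reference_residue is not None
        ]
        if len(refs) != len(set(refs)):
            raise AlignmentFormatError("reference numbering is not injective")

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, filtered_col: int) -> ColumnMapEntry:
        if not 1 <= filtered_col <= len(self.entries):
            raise IndexError(f"filtered column {filtered_col} out of range")
        return self.entries[filtered_col - 1]

    def source_protein(self, filtered_col: int) -> str:
        return self.entry(filtered_col).source_protein

    @classmethod
    def identity(cls, column_meta: list[ColumnOrigin]) -> "ColumnMap":
        return cls(
            [
                ColumnMapEntry(i + 1, m.source_protein, m.source_col, i + 1, None)
                for i, m in enumerate(column_meta)
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "filtered_col\tsource_protein\tsource_col\toriginal_col\treference_residue\n"
            )
            for e in self.entries:
                ref = "" if e.reference_residue is None else str(e.reference_residue)
                fh.write(
                    f"{e.filtered_col}\t{e.source_protein}\t{e.source_col}\t"
                    f"{e.original_col}\t{ref}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, reference_row_id: Optional[str] = None) -> "ColumnMap":
        entries = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("filtered_col"):
                raise AlignmentFormatError(f"unrecognized column-map header in {path}")
            for line in fh:
                fc, sp, sc, oc, ref = line.rstrip("\n").split("\t")
                entries.append(
                    ColumnMapEntry(int(fc), sp, int(sc), int(oc), int(ref) if ref else None)
                )
        return cls(entries, reference_row_id=reference_row_id)


def map_column_to_reference(
    col: int, reference_row_id: str, colmap: ColumnMap
) -> tuple[str, int]:
    """Translate a filtered column to (protein, 1-based reference residue number).

    Raises :class:`NoReferenceMapping` if the reference row has a gap at the
    column, and ``ValueError`` if the map was built for a different reference.
    """
    if colmap.reference_row_id != reference_row_id:
        raise ValueError(
            f"column map was built for reference {colmap.reference_row_id!r}, "
            f"not {reference_row_id!r}"
        )
    e = colmap.entry(col)
    if e.reference_residue is None:
        raise NoReferenceMapping(
            f"reference row {reference_row_id!r} has a gap at filtered column {col}"
        )
    return e.source_protein, e.reference_residue


# ---------------------------------------------------------------------------
# I/O: domain record sets and paired alignments
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, int, str]:
    parts = header.split("|")
    if len(parts) != 3:
        raise AlignmentFormatError(
            f"header {header!r} does not match 'record_id|gene_index|HK_or_RR'"
        )
    rid, idx, cls_ = parts
    try:
        gene_index = int(idx)
    except ValueError as exc:
        raise AlignmentFormatError(f"non-integer gene index in {header!r}") from exc
    return rid, gene_index, cls_


def read_domain_records(path: str | Path, fmt: str = "fasta") -> list[SequenceRecord]:
    """Read aligned domain sequences with ``>record_id|gene_index|HK`` headers.

    ``fmt`` is ``"fasta"`` or ``"stockholm"``.
    """
    if fmt == "fasta":
        raw: Iterable = SeqIO.parse(str(path), "fasta")
    elif fmt == "stockholm":
        raw = AlignIO.read(str(path), "stockholm")
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    records = []
    for rec in raw:
        rid, gene_index, cls_ = _parse_header(rec.id)
        records.append(SequenceRecord(rid, gene_index, cls_, str(rec.seq).upper()))
    return records


def write_domain_records(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.record_id}|{r.gene_index}|{r.protein_class}\n{r.aligned_seq}\n")


def _meta_sidecar(path: str | Path) -> Path:
    return Path(str(path) + ".columns.tsv")


def write_paired_alignment(
    aln: PairedAlignment, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write rows as FASTA (``>hk_id|rr_id``) plus a column-provenance TSV sidecar."""
    with open(path, "w") as fh:
        for row in aln.rows:
            fh.write(f">{row.hk_record_id}|{row.rr_record_id}\n{row.seq}\n")
    meta_path = _meta_sidecar(path) if meta_path is None else meta_path
    with open(meta_path, "w") as fh:
        fh.write("col\tsource_protein\tsource_col\n")
        for i, m in enumerate(aln.column_meta, start=1):
            fh.write(f"{i}\t{m.source_protein}\t{m.source_col}\n")


def read_paired_alignment(
    path: str | Path, meta_path: str | Path | None = None
) -> PairedAlignment:
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 2:
            raise AlignmentFormatError(f"header {rec.id!r} does not match 'hk_id|rr_id'")
        rows.append(PairedRow(parts[0], parts[1], str(rec.seq).upper()))
    meta_path = _meta_sidecar(path) if meta_path is None else meta_path
    meta = []
    with open(meta_path) as fh:
        fh.readline()
        for line in fh:
            _, sp, sc = line.rstrip("\n").split("\t")
            meta.append(ColumnOrigin(sp, int(sc)))
    return PairedAlignment(rows, meta)
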