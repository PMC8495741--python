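"""Two-subfamily protein alignments.

A :class:`SubfamilyAlignment` is a gapped amino-acid alignment whose rows
are partitioned into two labelled paralog subfamilies — group ``A``
(Mlh3-like) and group ``B`` (Pms1-like).  Columns are 1-based everywhere
a column index is reported; per-sequence residue coordinates are 1-based
ungapped indices, matching the convention used for domain boundaries.

The gap character is ``-``.  Ambiguous residues (B, Z, X and anything
else outside the 20-letter alphabet) are treated as gaps for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

_STANDARD = frozenset(AMINO_ACIDS)


@dataclass
class SubfamilyAlignment:
    """Aligned sequences with one group label ('A' or 'B') per row."""

    sequence_ids: list[str]
    group_labels: list[str]
    matrix: np.ndarray = field(repr=False)  # (n_seqs, length), dtype '<U1'

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise FormatError("alignment matrix must be 2-D")
        n = self.matrix.shape[0]
        if not (len(self.sequence_ids) == len(self.group_labels) == n):
            raise ValidationError("ids, labels and rows must have equal counts")
        if len(set(self.sequence_ids)) != n:
            raise ValidationError("duplicate sequence ids")
        bad = set(self.group_labels) - {"A", "B"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if "A" not in self.group_labels or "B" not in self.group_labels:
            raise ValidationError("both groups must be non-empty")
        # Uppercase once so scoring is case-insensitive.
        self.matrix = np.char.upper(self.matrix)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    def group_rows(self, label: str) -> np.ndarray:
        """Row indices belonging to group ``label``."""
        return np.flatnonzero(np.asarray(self.group_labels) == np.str_(label))

    def group_matrix(self, label: str) -> np.ndarray:
        return self.matrix[self.group_rows(label)]

    def row(self, sequence_id: str) -> np.ndarray:
        try:
            i = self.sequence_ids.index(sequence_id)
        except ValueError:
            raise KeyError(f"unknown sequence id: {sequence_id}") from None
        return self.matrix[i]

    def is_gap_matrix(self) -> np.ndarray:
        """Boolean mask marking gaps and non-standard residues."""
        return ~np.isin(self.matrix, list(_STANDARD))


def read_fasta_alignment(path, group_map: Mapping[str, str]) -> SubfamilyAlignment:
    """Read an aligned FASTA file and attach subfamily labels.

    ``group_map`` maps every record id to 'A' or 'B'.  Records of unequal
    length raise :class:`FormatError`; a record id missing from
    ``group_map`` raises :class:`ValidationError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    ids, labels = [], []
    for r in records:
        if r.id not in group_map:
            raise ValidationError(f"sequence {r.id!r} has no group label")
        ids.append(r.id)
        labels.append(group_map[r.id])
    matrix = np.array([list(str(r.seq)) for r in records], dtype="<U1")
    return SubfamilyAlignment(ids, labels, matrix)


def write_fasta_alignment(aln: SubfamilyAlignment, path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=sid, description="")
        for sid, row in zip(aln.sequence_ids, aln.matrix)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_group_map(aln: SubfamilyAlignment, path) -> None:
    """Write the id -> group assignment as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tgroup\n")
        for sid, lab in zip(aln.sequence_ids, aln.group_labels):
            fh.write(f"{sid}\t{lab}\n")


def read_group_map(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence_id"):
            raise FormatError(f"{path}: expected header 'sequence_id\\tgroup'")
        for line in fh:
            if not line.strip():
                continue
            sid, lab = line.rstrip("\n").split("\t")
            out[sid] = lab
    return out


def ungapped_index(row: Sequence[str], column: int) -> int | None:
    """1-based ungapped residue number of 1-based ``column`` in ``row``.

    Returns ``None`` when the sequence is gapped at that column.
    """
    if not 1 <= column <= len(row):
        raise IndexError(f"column {column} outside alignment of length {len(row)}")
    if row[column - 1] not in _STANDARD:
        return None
    return int(sum(1 for c in row[:column] if c in _STANDARD))
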