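"""Protein sequence records and plain-text I/O.

Sequences are amino-acid strings over the 20 canonical one-letter codes
plus a single unknown symbol ``X``; any non-standard letter (B, Z, J, U,
O, ...) is mapped to ``X`` on input.  Per-residue interfacial-binding-site
(IBS) labels are binary vectors aligned with the sequence: 1 marks a
membrane-interacting residue, 0 everything else.  Positions are 0-based
half-open internally and 1-based inclusive in every file format.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_AA = "X"
ALPHABET = CANONICAL_AA + UNKNOWN_AA


def sanitize_sequence(raw: str) -> str:
    """Uppercase and map every non-canonical letter to the unknown symbol."""
    up = raw.upper()
    return "".join(c if c in CANONICAL_AA else UNKNOWN_AA for c in up)


@dataclass
class ProteinRecord:
    """One protein: id, sequence, optional IBS labels and superfamily tag."""

    id: str
    sequence: str
    labels: np.ndarray | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.sequence),):
                raise ValueError(
                    f"protein {self.id!r}: labels length {self.labels.shape} "
                    f"!= sequence length {len(self.sequence)}"
                )
            bad = set(np.unique(self.labels)) - {0, 1}
            if bad:
                raise ValueError(f"protein {self.id!r}: non-binary labels {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_positive(self) -> int:
        return 0 if self.labels is None else int(self.labels.sum())


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into records.

    Sequences are uppercased and non-standard residues become ``X``.
    Raises on an empty file and on duplicate ids (naming the id).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id: {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, sanitize_sequence(str(entry.seq))))
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord]) -> None:
    entries = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(entries, str(Path(path)), "fasta")


def read_labels(
    path: str | Path,
    sequences: Mapping[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Read a per-residue label TSV into dense binary vectors.

    The file has a header and columns ``protein_id``, ``position``
    (1-based), ``label`` (0/1).  Positions without a row default to 0.
    When ``sequences`` is given, vectors are returned for every supplied
    protein (all-zero if unmentioned) and out-of-bounds positions raise.
    Without it, vector length is the maximum position seen per protein.
    """
    rows: dict[str, dict[int, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"protein_id", "position", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"label TSV must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for line in reader:
            pid = line["protein_id"]
            pos = int(line["position"])
            lab = int(line["label"])
            if lab not in (0, 1):
                raise ValueError(f"non-binary label {lab} for {pid!r} position {pos}")
            if pos < 1:
                raise ValueError(f"position must be 1-based positive, got {pos}")
            prev = rows.setdefault(pid, {})
            if pos in prev and prev[pos] != lab:
                raise ValueError(
                    f"conflicting labels for {pid!r} position {pos}: "
                    f"{prev[pos]} vs {lab}"
                )
            prev[pos] = lab

    out: dict[str, np.ndarray] = {}
    if sequences is not None:
        for pid, seq in sequences.items():
            vec = np.zeros(len(seq), dtype=np.int8)
            for pos, lab in rows.get(pid, {}).items():
                if pos > len(seq):
                    raise ValueError(
                        f"position {pos} out of bounds for {pid!r} "
                        f"(length {len(seq)})"
                    )
                vec[pos - 1] = lab
            out[pid] = vec
        unknown = set(rows) - set(sequences)
        if unknown:
            raise ValueError(f"labels for unknown proteins: {sorted(unknown)}")
    else:
        for pid, posmap in rows.items():
            vec = np.zeros(max(posmap), dtype=np.int8)
            for pos, lab in posmap.items():
                vec[pos - 1] = lab
            out[pid] = vec
    return out


def write_labels(path: str | Path, labels: Mapping[str, np.ndarray]) -> None:
    """Write dense label vectors as the sparse 1-based TSV (positive rows only)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for pid in sorted(labels):
            vec = np.asarray(labels[pid])
            for pos in np.flatnonzero(vec):
                fh.write(f"{pid}\t{int(pos) + 1}\t1\n")


def attach_labels(
    records: Sequence[ProteinRecord], labels: Mapping[str, np.ndarray]
) -> list[ProteinRecord]:
    """Return new records carrying the given label vectors (missing → zeros)."""
    out = []
    for r in records:
        vec = labels.get(r.id)
        if vec is None:
            vec = np.zeros(len(r.sequence), dtype=np.int8)
        out.append(ProteinRecord(r.id, r.sequence, labels=vec, family=r.family))
    return out
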