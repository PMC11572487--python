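"""Protein-level train/validation/test splitting.

Splitting is always by whole protein — residues of one protein never
straddle two splits, which would leak near-duplicate feature rows across
the evaluation boundary.  Counts per split are the largest-remainder
rounding of ``fractions × n_proteins`` and the assignment is a seeded
permutation, reproducible bit-for-bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import ProteinRecord

SPLIT_NAMES = ("train", "validation", "test")

__all__ = ["SplitAssignment", "split_by_protein", "read_split", "write_split"]


@dataclass(frozen=True)
class SplitAssignment:
    assignment: dict[str, str]
    fractions: tuple[float, float, float]

    def __post_init__(self) -> None:
        bad = {s for s in self.assignment.values() if s not in SPLIT_NAMES}
        if bad:
            raise ValueError(f"unknown split names: {bad}")

    def __getitem__(self, protein_id: str) -> str:
        return self.assignment[protein_id]

    def ids(self, split: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == split)

    def counts(self) -> dict[str, int]:
        return {s: len(self.ids(s)) for s in SPLIT_NAMES}


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [f * n for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    # distribute the remainder to the largest fractional parts, stable order
    order = sorted(range(len(fractions)), key=lambda i: -(exact[i] - base[i]))
    for i in order[:short]:
        base[i] += 1
    return base


def split_by_protein(
    records: Sequence[ProteinRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly assign whole proteins to train/validation/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    n_splits = sum(1 for f in fractions if f > 0)
    if len(records) < n_splits:
        raise ValueError(
            f"{len(records)} proteins cannot fill {n_splits} nonempty splits"
        )
    counts = _largest_remainder_counts(len(records), fractions)
    rng = np.random.default_rng(seed)
    ids = sorted(r.id for r in records)
    perm = rng.permutation(len(ids))
    assignment: dict[str, str] = {}
    cursor = 0
    for name, cnt in zip(SPLIT_NAMES, counts):
        for k in perm[cursor : cursor + cnt]:
            assignment[ids[k]] = name
        cursor += cnt
    return SplitAssignment(assignment, tuple(fractions))


def split_by_family(
    records: Sequence[ProteinRecord],
    held_out_families: Sequence[str],
) -> SplitAssignment:
    """Assign every protein of the named families to test, the rest to train.

    Used to probe generalization to unseen superfamilies: a model trained
    on some families is evaluated on proteins whose family it never saw.
    """
    held = set(held_out_families)
    assignment = {
        r.id: ("test" if r.family in held else "train") for r in records
    }
    n_test = sum(1 for s in assignment.values() if s == "test")
    frac = n_test / len(records)
    return SplitAssignment(assignment, (1.0 - frac, 0.0, frac))


def write_split(path: str | Path, split: SplitAssignment) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "split"])
        for pid in sorted(split.assignment):
            writer.writerow([pid, split.assignment[pid]])


def read_split(path: str | Path) -> SplitAssignment:
    assignment: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            assignment[row["protein_id"]] = row["split"]
    if not assignment:
        raise ValueError(f"empty split file: {path}")
    n = len(assignment)
    fracs = tuple(
        sum(1 for s in assignment.values() if s == name) / n for name in SPLIT_NAMES
    )
    return SplitAssignment(assignment, fracs)  # type: ignore[arg-type]
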