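"""Pairwise global alignment, identity, and cross-sequence label transfer.

Database (e.g. UniProt) sequences and structure-resolved (PDB) sequences
of the same protein differ by terminal truncation, internal unresolved
stretches, and occasional engineered point mutations.  A global alignment
with free end gaps recovers the position mapping between the two, which
is then used to carry per-residue IBS annotation from one numbering to
the other.

Scoring defaults: BLOSUM62, gap open 10, gap extend 0.5, end gaps free —
configurable through :func:`make_aligner`.  Identity uses the CD-HIT
convention: identical aligned columns divided by the shorter sequence
length.  The unknown symbol ``X`` never counts as an identity match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import UNKNOWN_AA, ProteinRecord

__all__ = [
    "AlignmentMap",
    "make_aligner",
    "align_sequences",
    "pairwise_identity",
    "transfer_labels",
    "select_chain",
]


@dataclass(frozen=True)
class AlignmentMap:
    """Non-gap column pairing between two sequences.

    ``column_pairs`` holds 0-based ``(source_position, target_position)``
    pairs, strictly increasing in both coordinates.  ``identity`` is the
    fraction of paired columns whose residues are identical (``X`` never
    matches), over the shorter sequence length.
    """

    source_id: str
    target_id: str
    column_pairs: tuple[tuple[int, int], ...]
    identity: float

    def __post_init__(self) -> None:
        prev = (-1, -1)
        for p in self.column_pairs:
            if not (p[0] > prev[0] and p[1] > prev[1]):
                raise ValueError(f"column pairs not strictly increasing at {p}")
            prev = p


def make_aligner(
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> Align.PairwiseAligner:
    """Global affine-gap aligner with free end gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    new_names = (
        "open_end_insertion_score",
        "extend_end_insertion_score",
        "open_end_deletion_score",
        "extend_end_deletion_score",
    )
    old_names = (
        "target_end_open_gap_score",
        "target_end_extend_gap_score",
        "query_end_open_gap_score",
        "query_end_extend_gap_score",
    )
    names = new_names if hasattr(aligner, new_names[0]) else old_names
    for name in names:
        setattr(aligner, name, 0.0)
    return aligner


def _aligned_pairs(a: str, b: str, aligner: Align.PairwiseAligner | None):
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    pairs: list[tuple[int, int]] = []
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for k in range(ea - sa):
            pairs.append((sa + k, sb + k))
    return pairs


def _identity_from_pairs(a: str, b: str, pairs) -> float:
    matches = sum(
        1
        for i, j in pairs
        if a[i] == b[j] and a[i] != UNKNOWN_AA
    )
    return matches / min(len(a), len(b))


def pairwise_identity(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Global-alignment sequence identity in [0, 1].

    Denominator is the shorter sequence length (CD-HIT convention), so a
    perfect substring scores 1.0.
    """
    pairs = _aligned_pairs(a, b, aligner)
    return _identity_from_pairs(a, b, pairs)


def align_sequences(
    source: ProteinRecord,
    target: ProteinRecord,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentMap:
    """Globally align two records and return the non-gap column mapping."""
    pairs = _aligned_pairs(source.sequence, target.sequence, aligner)
    ident = _identity_from_pairs(source.sequence, target.sequence, pairs)
    return AlignmentMap(source.id, target.id, tuple(pairs), ident)


def transfer_labels(
    source: ProteinRecord, target: ProteinRecord, mapping: AlignmentMap
) -> np.ndarray:
    """Carry per-residue labels from source to target through an alignment.

    Each paired target position receives the source label at its partner
    column (mismatched residues included: structures may carry point
    mutations); unpaired target positions get 0.  Positives can only be
    lost, never created.
    """
    if mapping.source_id != source.id or mapping.target_id != target.id:
        raise ValueError(
            f"alignment map joins {mapping.source_id!r}->{mapping.target_id!r}, "
            f"not {source.id!r}->{target.id!r}"
        )
    if source.labels is None:
        raise ValueError(f"source record {source.id!r} has no labels")
    out = np.zeros(len(target.sequence), dtype=np.int8)
    for i, j in mapping.column_pairs:
        out[j] = source.labels[i]
    return out


def select_chain(
    chains: dict[str, str],
    reference: str,
    aligner: Align.PairwiseAligner | None = None,
) -> str:
    """Pick the chain most identical to a reference sequence.

    Used for multimeric structures where only the chain matching the
    database sequence is kept.  Ties break to the lexicographically
    smallest chain id.
    """
    if not chains:
        raise ValueError("empty chain map")
    best_id, best_score = None, -1.0
    for cid in sorted(chains):
        score = pairwise_identity(chains[cid], reference, aligner)
        if score > best_score:
            best_id, best_score = cid, score
    assert best_id is not None
    return best_id
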