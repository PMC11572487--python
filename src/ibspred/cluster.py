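"""Greedy incremental sequence-identity clustering and representative selection.

Re-creates the CD-HIT contract used to de-bias superfamily-heavy protein
collections: sequences are sorted by descending length (ties break to the
lexicographically smaller id), then each sequence joins the first existing
cluster whose representative it matches at or above the identity cutoff,
otherwise it founds a new cluster.  The founding (longest) member is the
cluster representative; downstream curation keeps representatives only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align

from .align import pairwise_identity
from .records import ProteinRecord

__all__ = ["Cluster", "cluster_sequences", "representatives", "write_clusters"]


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]
    identity_cutoff: float

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member of its cluster")

    def __len__(self) -> int:
        return len(self.member_ids)


def cluster_sequences(
    records: Sequence[ProteinRecord],
    cutoff: float = 0.40,
    aligner: Align.PairwiseAligner | None = None,
) -> list[Cluster]:
    """Greedy incremental clustering at the given identity cutoff.

    Every record lands in exactly one cluster (the result is a partition).
    Identity is measured against cluster representatives only, in cluster
    creation order, and uses the shorter-sequence denominator so that a
    fragment of a representative clusters with it.
    """
    if not records:
        raise ValueError("need at least one record to cluster")
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"identity cutoff must be in (0, 1], got {cutoff}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")

    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in order:
        for k, rep in enumerate(reps):
            if pairwise_identity(rep.sequence, rec.sequence, aligner) >= cutoff:
                members[k].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    return [
        Cluster(rep.id, tuple(mem), cutoff) for rep, mem in zip(reps, members)
    ]


def representatives(
    clusters: Sequence[Cluster], records: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """Return the representative record of each cluster, in cluster order."""
    by_id = {r.id: r for r in records}
    return [by_id[c.representative_id] for c in clusters]


def write_clusters(path: str | Path, clusters: Sequence[Cluster]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cluster_index", "representative_id", "member_id"])
        for k, c in enumerate(clusters):
            for mid in c.member_ids:
                writer.writerow([k, c.representative_id, mid])
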