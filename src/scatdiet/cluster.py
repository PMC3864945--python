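"""Greedy centroid clustering of per-scat reads at 90% identity.

Reads are dereplicated, unique sequences are processed in decreasing
abundance (ties: decreasing length, then lexicographic) and each is joined
to the FIRST existing centroid, in centroid creation order, whose seed it
matches at or above the identity threshold; otherwise it founds a new
cluster whose seed it becomes.  This mirrors the greedy semantics of the
usual centroid-based OTU tools without their word-indexing accelerations,
which are unnecessary at the scale of per-scat amplicon sets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import pairwise_identity

__all__ = ["SequenceCluster", "greedy_cluster", "write_cluster_fasta"]


@dataclass
class SequenceCluster:
    """A centroid ("seed") sequence with its member reads."""

    seed: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def greedy_cluster(
    sequences: Sequence[tuple[str, str]], threshold: float = 0.90
) -> list[SequenceCluster]:
    """Cluster ``(read_id, sequence)`` pairs at the given identity threshold.

    Returns clusters in creation order; cluster sizes sum to the number of
    input reads.  The result depends only on the input multiset, not its
    order.  ``threshold = 1.0`` degenerates to exact dereplication.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    by_seq: dict[str, list[str]] = defaultdict(list)
    for read_id, seq in sequences:
        if not seq:
            raise ValueError(f"read {read_id}: empty sequence")
        by_seq[seq].append(read_id)
    # deterministic greedy order: abundance desc, length desc, lexicographic
    order = sorted(by_seq, key=lambda s: (-len(by_seq[s]), -len(s), s))
    clusters: list[SequenceCluster] = []
    for seq in order:
        ids = sorted(by_seq[seq])
        for cluster in clusters:
            if pairwise_identity(seq, cluster.seed) >= threshold:
                cluster.member_ids.extend(ids)
                break
        else:
            clusters.append(SequenceCluster(seed=seq, member_ids=list(ids)))
    return clusters


def write_cluster_fasta(
    clusters: Iterable[SequenceCluster], scat_id: str, path
) -> None:
    """Write seeds as FASTA (header: scat, cluster index, size)."""
    with open(path, "w") as fh:
        for idx, c in enumerate(clusters):
            fh.write(f">{scat_id};cluster={idx};size={c.size}\n{c.seed}\n")
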