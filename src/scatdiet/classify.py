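"""Taxonomic assignment of cluster seeds and aggregation to diet categories.

Each cluster seed is matched exhaustively against the lineage-named
reference collection (the desk-scale stand-in for a BLAST search); the best
hit's lineage is scanned most-specific-first against the aggregation list
— the curated table mapping higher taxa (Euphausiidae, Scyphozoa, ...) to
the categories food / parasite / contaminant / unicell.  Seeds with no
qualifying alignment are discarded (this is what removes most PCR
chimaeras); hits at or below the identity threshold are kept separate as
``below_identity``; hits whose lineage contains no listed taxon surface in
the training report so a curator can grow the list ("training" phase).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .align import semi_global_align
from .cluster import SequenceCluster
from .reference import ReferenceRecord, TaxonLineage

__all__ = [
    "Category",
    "AggregationRule",
    "HitResult",
    "Outcome",
    "ClusterClassification",
    "best_hit",
    "classify_cluster",
    "classify_clusters",
    "run_training_phase",
    "load_aggregation_list",
    "default_aggregation_list",
    "write_training_report",
]


class Category(str, enum.Enum):
    FOOD = "food"
    PARASITE = "parasite"
    CONTAMINANT = "contaminant"
    UNICELL = "unicell"


@dataclass(frozen=True)
class AggregationRule:
    """One row of the aggregation list: taxon -> category."""

    taxon: str
    category: Category
    common_name: str = ""


@dataclass(frozen=True)
class HitResult:
    """Best reference match for a seed."""

    record_id: str
    identity: float
    lineage: TaxonLineage

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


class Outcome(str, enum.Enum):
    ASSIGNED = "assigned"
    TRAINING_REPORT = "training_report"
    DISCARDED_NO_MATCH = "discarded_no_match"
    BELOW_IDENTITY = "below_identity"


@dataclass
class ClusterClassification:
    """The single outcome attached to one cluster."""

    cluster: SequenceCluster
    outcome: Outcome
    taxon: str | None = None          # aggregation taxon when assigned
    category: Category | None = None  # its category when assigned
    lineage: TaxonLineage | None = None  # closest-match lineage when any hit
    identity: float | None = None

    @property
    def n_reads(self) -> int:
        return self.cluster.size


def best_hit(
    seed: str,
    reference: Sequence[ReferenceRecord],
    min_coverage: float = 0.7,
) -> HitResult | None:
    """Exhaustive best match of a seed against the reference collection.

    A record qualifies when the optimal alignment accounts for at least
    ``min_coverage`` of the seed, measured as normalized alignment score
    (score / seed length; 1.0 for a perfect full-length match).  Unrelated
    random sequences score ~0.1-0.2 against any record and chimaeric
    splices ~0.5, so both fall to the "no match" outcome at the default
    0.7 floor, while even a hit at exactly 90% identity (normalized score
    ~0.8) still qualifies and is reported as below the assignment
    threshold.  Among qualifying records the highest identity wins, ties
    broken by database order; ``None`` when no record qualifies.
    """
    if not seed:
        raise ValueError("empty seed sequence")
    if not reference:
        raise ValueError("empty reference collection")
    best: HitResult | None = None
    for rec in reference:
        stats = semi_global_align(seed, rec.sequence)
        if stats.score < min_coverage * len(seed):
            continue
        if best is None or stats.identity > best.identity:
            best = HitResult(rec.record_id, stats.identity, rec.lineage)
    return best


def classify_cluster(
    cluster: SequenceCluster,
    hit: HitResult | None,
    rules: Mapping[str, AggregationRule],
    assignment_threshold: float = 0.90,
) -> ClusterClassification:
    """Turn a best hit into a cluster outcome.

    Assignment requires identity strictly greater than the threshold (a 90%
    hit does *not* qualify, unlike the >=90% clustering rule).  The hit
    lineage is scanned from species up; the most specific listed rank wins.
    """
    if not rules:
        raise ValueError("aggregation rule list is empty")
    if hit is None:
        return ClusterClassification(cluster, Outcome.DISCARDED_NO_MATCH)
    if hit.identity <= assignment_threshold:
        return ClusterClassification(
            cluster, Outcome.BELOW_IDENTITY, lineage=hit.lineage, identity=hit.identity
        )
    for rank in reversed(hit.lineage.ranks):
        rule = rules.get(rank)
        if rule is not None:
            return ClusterClassification(
                cluster,
                Outcome.ASSIGNED,
                taxon=rule.taxon,
                category=rule.category,
                lineage=hit.lineage,
                identity=hit.identity,
            )
    return ClusterClassification(
        cluster, Outcome.TRAINING_REPORT, lineage=hit.lineage, identity=hit.identity
    )


def classify_clusters(
    clusters: Iterable[SequenceCluster],
    reference: Sequence[ReferenceRecord],
    rules: Mapping[str, AggregationRule],
    assignment_threshold: float = 0.90,
    min_coverage: float = 0.7,
) -> list[ClusterClassification]:
    """Classify every cluster (best hit + aggregation) in one pass."""
    out = []
    for cluster in clusters:
        hit = best_hit(cluster.seed, reference, min_coverage=min_coverage)
        out.append(classify_cluster(cluster, hit, rules, assignment_threshold))
    return out


def run_training_phase(
    classifications: Iterable[ClusterClassification],
) -> list[tuple[str, int, int]]:
    """Aggregate training-report outcomes by closest species lineage.

    Returns ``(lineage text, n_clusters, n_reads)`` rows sorted by read
    count descending, the report a curator turns into new aggregation
    rules.  Re-running classification with the grown list removes the
    corresponding rows.
    """
    counts: dict[str, list[int]] = {}
    for c in classifications:
        if c.outcome is Outcome.TRAINING_REPORT:
            key = c.lineage.render()
            entry = counts.setdefault(key, [0, 0])
            entry[0] += 1
            entry[1] += c.n_reads
    return sorted(
        ((lin, n_cl, n_rd) for lin, (n_cl, n_rd) in counts.items()),
        key=lambda row: (-row[2], row[0]),
    )


def write_training_report(rows: Sequence[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("closest_lineage\tn_clusters\tn_reads\n")
        for lin, n_cl, n_rd in rows:
            fh.write(f"{lin}\t{n_cl}\t{n_rd}\n")


def load_aggregation_list(path: str | Path) -> dict[str, AggregationRule]:
    """Parse an aggregation list TSV (taxon, category[, common_name]).

    Duplicate taxa and unknown category labels are errors.
    """
    rules: dict[str, AggregationRule] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if lineno == 1 and fields[0].lower() == "taxon":
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected taxon<TAB>category")
            taxon, category_label = fields[0], fields[1]
            common = fields[2] if len(fields) > 2 else ""
            try:
                category = Category(category_label)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unknown category {category_label!r}"
                ) from exc
            if taxon in rules:
                raise ValueError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
            rules[taxon] = AggregationRule(taxon, category, common)
    return rules


@lru_cache(maxsize=1)
def default_aggregation_list() -> dict[str, AggregationRule]:
    """The packaged aggregation table for the Adelie penguin scat assay."""
    path = resources.files("scatdiet.data").joinpath("aggregation_taxa.tsv")
    with resources.as_file(path) as p:
        return load_aggregation_list(p)
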