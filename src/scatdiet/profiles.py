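"""Per-scat diet accounting and population-level summaries.

Each read inherits its cluster's classification, giving per-scat read
counts per (category, taxon).  Scats returning fewer than 50 food
sequences are removed before any summary.  Population summaries are means
of *per-scat* proportions (not pooled counts), with standard errors,
percent frequency of occurrence (FOC), pairwise co-occurrence and the
percentage of scats containing a single food taxon; proportions are always
computed within a category (food among food reads, parasites among
parasite reads, ...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Category, ClusterClassification, Outcome

logger = logging.getLogger(__name__)

__all__ = [
    "ScatProfile",
    "PopulationDietSummary",
    "tally_scats",
    "apply_food_floor",
    "scat_proportions",
    "summarize_population",
    "write_summary_tsv",
    "write_cooccurrence_tsv",
    "write_profiles_tsv",
]


@dataclass
class ScatProfile:
    """Read counts per (category, taxon) for one scat, plus its metadata."""

    scat_id: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)
    # read-level bookkeeping for non-assigned outcomes
    other_counts: dict[str, int] = field(default_factory=dict)

    def category_total(self, category: str | Category = Category.FOOD) -> int:
        category = Category(category).value
        return sum(n for (cat, _), n in self.counts.items() if cat == category)

    @property
    def food_total(self) -> int:
        return self.category_total(Category.FOOD)


def tally_scats(
    classifications: Mapping[str, Sequence[ClusterClassification]],
    metadata: Mapping[str, Mapping[str, str]],
) -> list[ScatProfile]:
    """One profile per scat from its cluster classifications.

    ``classifications`` maps scat_id to that scat's classified clusters;
    every read inherits its cluster's outcome.  Scats lacking metadata are
    an error (listed in the message).
    """
    missing = sorted(set(classifications) - set(metadata))
    if missing:
        raise ValueError(f"scats without sample-sheet metadata: {missing}")
    profiles = []
    for scat_id in classifications:
        profile = ScatProfile(scat_id=scat_id, metadata=dict(metadata[scat_id]))
        for c in classifications[scat_id]:
            if c.outcome is Outcome.ASSIGNED:
                key = (c.category.value, c.taxon)
                profile.counts[key] = profile.counts.get(key, 0) + c.n_reads
            else:
                profile.other_counts[c.outcome.value] = (
                    profile.other_counts.get(c.outcome.value, 0) + c.n_reads
                )
        profiles.append(profile)
    return profiles


def apply_food_floor(
    profiles: Sequence[ScatProfile], min_food_reads: int = 50
) -> tuple[list[ScatProfile], list[ScatProfile]]:
    """Split profiles into (retained, dropped) by total food read count."""
    retained = [p for p in profiles if p.food_total >= min_food_reads]
    dropped = [p for p in profiles if p.food_total < min_food_reads]
    return retained, dropped


def scat_proportions(
    profile: ScatProfile, category: str | Category = Category.FOOD
) -> dict[str, float]:
    """Within-category proportions for one scat; category total must be >= 1."""
    category = Category(category).value
    total = profile.category_total(category)
    if total < 1:
        raise ValueError(
            f"scat {profile.scat_id}: no {category} reads; filter before "
            "computing proportions"
        )
    return {
        taxon: n / total
        for (cat, taxon), n in sorted(profile.counts.items())
        if cat == category
    }


@dataclass
class PopulationDietSummary:
    """Mean-of-proportions diet summary for one population (one category)."""

    population_id: str
    category: str
    n_scats_retained: int
    taxa: list[str]
    mean_proportion: dict[str, float]
    se_proportion: dict[str, float]
    foc_percent: dict[str, float]
    single_item_percent: float
    cooccurrence: pd.DataFrame  # percent of scats containing both taxa

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.taxa,
                "mean_proportion": [self.mean_proportion[t] for t in self.taxa],
                "se_proportion": [self.se_proportion[t] for t in self.taxa],
                "foc_percent": [self.foc_percent[t] for t in self.taxa],
            }
        )


def summarize_population(
    profiles: Sequence[ScatProfile],
    category: str | Category = Category.FOOD,
    population_id: str = "",
    stratify_by: str | None = None,
) -> PopulationDietSummary | dict[str, PopulationDietSummary]:
    """Population summary over retained scats, optionally per stratum.

    Means/SEs average per-scat within-category proportions over the scats
    that contain at least one read of the category (for food this is every
    retained scat, by the 50-read floor).  FOC, co-occurrence and
    single-item percentages use all retained scats as denominator.  The
    n = 1 standard-error convention is 0, with a logged warning.
    """
    if stratify_by is not None:
        strata: dict[str, list[ScatProfile]] = {}
        for p in profiles:
            strata.setdefault(p.metadata.get(stratify_by, ""), []).append(p)
        out = {}
        for label in sorted(strata):
            if not strata[label]:
                raise ValueError(f"empty stratum {label!r}")
            out[label] = summarize_population(
                strata[label], category, population_id=f"{population_id}/{label}"
            )
        return out

    if not profiles:
        raise ValueError(f"no retained scats for population {population_id!r}")
    category = Category(category).value
    n = len(profiles)

    with_reads = [p for p in profiles if p.category_total(category) >= 1]
    taxa = sorted(
        {taxon for p in with_reads for (cat, taxon) in p.counts if cat == category}
    )
    props = np.zeros((len(with_reads), len(taxa)))
    for i, p in enumerate(with_reads):
        for taxon, frac in scat_proportions(p, category).items():
            props[i, taxa.index(taxon)] = frac

    mean = dict(zip(taxa, props.mean(axis=0))) if with_reads else {}
    if len(with_reads) > 1:
        se = dict(zip(taxa, props.std(axis=0, ddof=1) / math.sqrt(len(with_reads))))
    else:
        if with_reads:
            logger.warning(
                "population %r: single scat with %s reads; SE reported as 0",
                population_id, category,
            )
        se = {t: 0.0 for t in taxa}

    presence = np.zeros((n, len(taxa)), dtype=bool)
    for i, p in enumerate(profiles):
        for j, taxon in enumerate(taxa):
            presence[i, j] = p.counts.get((category, taxon), 0) >= 1
    foc = {t: 100.0 * presence[:, j].mean() for j, t in enumerate(taxa)}
    co = pd.DataFrame(
        100.0 * (presence[:, :, None] & presence[:, None, :]).mean(axis=0),
        index=taxa,
        columns=taxa,
    )
    single = 100.0 * float(np.mean(presence.sum(axis=1) == 1)) if taxa else 0.0

    return PopulationDietSummary(
        population_id=population_id,
        category=category,
        n_scats_retained=n,
        taxa=taxa,
        mean_proportion={t: float(v) for t, v in mean.items()},
        se_proportion={t: float(v) for t, v in se.items()},
        foc_percent=foc,
        single_item_percent=single,
        cooccurrence=co,
    )


def write_summary_tsv(summary: PopulationDietSummary, path: str | Path) -> None:
    df = summary.as_frame()
    df.insert(0, "population_id", summary.population_id)
    df.insert(1, "category", summary.category)
    df.insert(2, "n_scats_retained", summary.n_scats_retained)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_cooccurrence_tsv(summary: PopulationDietSummary, path: str | Path) -> None:
    summary.cooccurrence.to_csv(path, sep="\t", float_format="%.6g")


def write_profiles_tsv(profiles: Iterable[ScatProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for (category, taxon), count in sorted(p.counts.items()):
            rows.append(
                {"scat_id": p.scat_id, "category": category, "taxon": taxon, "n_reads": count}
            )
        for outcome, count in sorted(p.other_counts.items()):
            rows.append(
                {"scat_id": p.scat_id, "category": outcome, "taxon": "", "n_reads": count}
            )
    pd.DataFrame(rows, columns=["scat_id", "category", "taxon", "n_reads"]).to_csv(
        path, sep="\t", index=False
    )
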