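"""End-to-end orchestration: FASTQ runs -> population diet summaries.

``run_pipeline`` composes the stages in the assay's processing order
(quality filter -> length filter -> demultiplex -> per-scat clustering ->
classification -> per-scat tallies -> 50-food-read floor -> population
summaries), writes every intermediate as TSV for provenance, and is
byte-reproducible for identical inputs, configuration and seed.
``accounting_report`` reproduces the survey-style bookkeeping (collected /
amplified / sexed counts and success percentages).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classify import AggregationRule, ClusterClassification, classify_clusters
from .cluster import greedy_cluster
from .profiles import (
    ScatProfile,
    apply_food_floor,
    summarize_population,
    tally_scats,
    write_profiles_tsv,
    write_summary_tsv,
)
from .qc import demultiplex, length_filter, mean_quality_filter, read_fastq
from .reference import ReferenceRecord
from .samples import SampleSheetRow
from .tags import TagScheme, default_tag_scheme

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RunAccounting",
    "run_pipeline",
    "accounting_report",
    "load_sample_set_table",
    "round_half_away",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric threshold of the analysis, with the assay defaults."""

    mean_q_threshold: float = 30.0
    min_length_bp: int = 120
    cluster_identity: float = 0.90     # >= joins a cluster
    assignment_identity: float = 0.90  # strictly > assigns
    min_food_reads: int = 50
    proportion_floor: float = 0.001
    n_permutations: int = 9999
    rev_tag_mismatches: int = 0
    min_hit_coverage: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cluster_identity <= 1 or not 0 < self.assignment_identity <= 1:
            raise ValueError("identity thresholds must lie in (0, 1]")
        if self.min_length_bp < 0 or self.min_food_reads < 0:
            raise ValueError("length/read floors must be >= 0")
        if not 0 <= self.proportion_floor <= 1 or not 0 <= self.min_hit_coverage <= 1:
            raise ValueError("floors must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    config: PipelineConfig
    n_input_reads: int
    n_low_quality: int
    n_too_short: int
    demux_rejects: dict[str, str]
    assignments: dict[str, str]
    classifications: dict[str, list[ClusterClassification]]
    profiles: list[ScatProfile]
    retained: list[ScatProfile]
    dropped: list[ScatProfile]
    summaries: dict[str, object]


def run_pipeline(
    config: PipelineConfig,
    fastq_paths: Sequence[str | Path],
    sample_sheet: Sequence[SampleSheetRow],
    reference: Sequence[ReferenceRecord],
    rules: Mapping[str, AggregationRule],
    scheme: TagScheme | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis over one or more sequencing runs.

    Summaries are computed per ``population_id`` found in the sample
    sheet; populations with no retained scats are skipped with a warning
    (an empty input yields empty summaries rather than an error).
    """
    scheme = scheme or default_tag_scheme()
    sheet_by_run: dict[str, list[SampleSheetRow]] = {}
    for row in sample_sheet:
        sheet_by_run.setdefault(row.run_id, []).append(row)
    metadata = {
        row.scat_id: {
            "population_id": row.population_id, "location": row.location,
            "year": row.year, "phase": row.phase, "sex": row.sex,
        }
        for row in sample_sheet
    }

    n_input = n_low_q = n_short = 0
    all_rejects: dict[str, str] = {}
    assignments: dict[str, str] = {}
    trimmed_by_scat: dict[str, list] = {}
    run_ids = sorted(sheet_by_run)
    if len(fastq_paths) != len(run_ids):
        raise ValueError(
            f"{len(fastq_paths)} FASTQ files for {len(run_ids)} runs in sheet"
        )
    for fastq_path, run_id in zip(fastq_paths, run_ids):
        reads = read_fastq(fastq_path)
        n_input += len(reads)
        kept, low_q = mean_quality_filter(reads, config.mean_q_threshold)
        n_low_q += len(low_q)
        all_rejects.update((rid, "low_quality") for rid in low_q)
        kept, short = length_filter(kept, config.min_length_bp)
        n_short += len(short)
        all_rejects.update((rid, "too_short") for rid in short)
        demux = demultiplex(
            kept, scheme, sheet_by_run[run_id],
            rev_tag_mismatches_allowed=config.rev_tag_mismatches,
        )
        logger.info(
            "run %s: %d reads, %d low-quality, %d short, %d assigned, %d demux rejects",
            run_id, len(reads), len(low_q), len(short),
            demux.n_assigned, len(demux.rejects),
        )
        all_rejects.update(demux.rejects)
        assignments.update(demux.assignments)
        for scat_id, trimmed in demux.trimmed_reads.items():
            trimmed_by_scat.setdefault(scat_id, []).extend(trimmed)

    classifications: dict[str, list[ClusterClassification]] = {}
    for scat_id in sorted(trimmed_by_scat):
        seqs = [(r.read_id, r.bases) for r in trimmed_by_scat[scat_id]]
        clusters = greedy_cluster(seqs, threshold=config.cluster_identity)
        classifications[scat_id] = classify_clusters(
            clusters, reference, rules,
            assignment_threshold=config.assignment_identity,
            min_coverage=config.min_hit_coverage,
        )

    profiles = tally_scats(classifications, metadata)
    retained, dropped = apply_food_floor(profiles, config.min_food_reads)
    logger.info(
        "%d scats profiled, %d retained after the %d-food-read floor",
        len(profiles), len(retained), config.min_food_reads,
    )

    by_population: dict[str, list[ScatProfile]] = {}
    for p in retained:
        by_population.setdefault(p.metadata.get("population_id", ""), []).append(p)
    summaries = {
        pop: summarize_population(pops, "food", population_id=pop)
        for pop, pops in sorted(by_population.items())
    }

    result = PipelineResult(
        config=config,
        n_input_reads=n_input,
        n_low_quality=n_low_q,
        n_too_short=n_short,
        demux_rejects=all_rejects,
        assignments=assignments,
        classifications=classifications,
        profiles=profiles,
        retained=retained,
        dropped=dropped,
        summaries=summaries,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(result.config.to_json() + "\n")
    with open(outdir / "demux_report.tsv", "w") as fh:
        fh.write("read_id\tdisposition\tscat_id\n")
        for rid, scat in sorted(result.assignments.items()):
            fh.write(f"{rid}\tassigned\t{scat}\n")
        for rid, reason in sorted(result.demux_rejects.items()):
            fh.write(f"{rid}\t{reason}\t\n")
    with open(outdir / "classifications.tsv", "w") as fh:
        fh.write("scat_id\tcluster\toutcome\ttaxon\tcategory\tidentity\tn_reads\n")
        for scat_id in sorted(result.classifications):
            for idx, c in enumerate(result.classifications[scat_id]):
                ident = "" if c.identity is None else f"{c.identity:.4f}"
                fh.write(
                    f"{scat_id}\t{idx}\t{c.outcome.value}\t{c.taxon or ''}\t"
                    f"{c.category.value if c.category else ''}\t{ident}\t{c.n_reads}\n"
                )
    write_profiles_tsv(result.profiles, outdir / "scat_profiles.tsv")
    for pop, summary in result.summaries.items():
        safe = pop.replace("/", "_") or "all"
        write_summary_tsv(summary, outdir / f"summary_{safe}.tsv")


def round_half_away(x: float) -> int:
    """Round half away from zero (the reporting convention for percents)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


@dataclass(frozen=True)
class RunAccounting:
    """Collected / amplified / sexed bookkeeping over sample sets."""

    per_set: pd.DataFrame
    n_collected: int
    n_amplified: int
    n_sexed: int

    @property
    def amplification_success_percent(self) -> int:
        return round_half_away(100.0 * self.n_amplified / self.n_collected)

    @property
    def sexing_success_percent(self) -> int:
        return round_half_away(100.0 * self.n_sexed / self.n_amplified)


def accounting_report(table: pd.DataFrame) -> RunAccounting:
    """Totals and success percentages from a per-sample-set table.

    The table needs columns n_collected, n_amplified, n_sexed (one row per
    location/year/phase sample set); the invariant
    sexed <= amplified <= collected is enforced per row.
    """
    for col in ("n_collected", "n_amplified", "n_sexed"):
        if col not in table.columns:
            raise ValueError(f"accounting table missing column {col!r}")
    bad = table[
        (table.n_sexed > table.n_amplified) | (table.n_amplified > table.n_collected)
    ]
    if len(bad):
        raise ValueError(f"rows violate sexed <= amplified <= collected:\n{bad}")
    return RunAccounting(
        per_set=table.copy(),
        n_collected=int(table.n_collected.sum()),
        n_amplified=int(table.n_amplified.sum()),
        n_sexed=int(table.n_sexed.sum()),
    )


def load_sample_set_table() -> pd.DataFrame:
    """The packaged 12-row sample-set table of the Adelie scat survey."""
    path = resources.files("scatdiet.data").joinpath("sample_sets.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
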