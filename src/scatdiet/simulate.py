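"""Simulated tagged amplicon sequencing runs with ground truth.

This module generates everything the pipeline consumes — a mock
lineage-named reference, its aggregation list, sample sheets, and tagged
FASTQ reads with a per-read truth table — so the whole analysis can run
and be validated without any external download.

The error model emulates the salient feature of the single-direction
semiconductor chemistry the assay was run on: a per-base substitution
probability that is flat over the 5' portion of the read and then ramps up
linearly towards the 3' end.  Phred scores are derived from the same
per-position probabilities (Q = -10 log10 p, clipped to [2, 40]), so the
mean-quality filter interacts realistically with the ramp, and a steep
ramp corrupts the 3' reverse tag and makes reads unassignable — the
read-loss phenomenon the strict dual-tag demultiplexer reproduces.  PCR
chimaeras are single-breakpoint splices of two templates from the same
scat.  Reads can also be drawn from taxa deliberately absent from the
reference ("unassignable" pool).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import pairwise_identity
from .classify import AggregationRule, Category, default_aggregation_list
from .qc import SequencingRead, write_fastq
from .reference import ReferenceRecord, TaxonLineage
from .samples import SampleSheetRow
from .tags import TagScheme, default_tag_scheme, revcomp

__all__ = [
    "ErrorModel",
    "MockCommunity",
    "GenerationError",
    "build_mock_reference",
    "simulate_scat_reads",
    "simulate_run",
    "make_population",
    "write_truth_table",
    "write_aggregation_list",
    "DEFAULT_COMPOSITION",
    "DEFAULT_NUISANCE_FRACTIONS",
    "NOISE_FREE",
    "DEFAULT_ERROR_MODEL",
]

_BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """Raised when requested synthetic data cannot be generated."""


@dataclass(frozen=True)
class ErrorModel:
    """Per-read corruption parameters.

    substitution probability at position i is
    ``min(base + ramp_rate * max(0, i - ramp_start), max_substitution)``;
    it is non-decreasing beyond ``ramp_start`` by construction.  Because
    Phred scores are derived deterministically from these probabilities,
    the defaults are calibrated so a typical ~220 bp tagged read keeps a
    mean Q just above 30 (flat region ~Q37, ramped 3' tail much lower)
    while the ramp corrupts a substantial fraction of 10 nt reverse tags —
    reads survive the quality filter but many become unassignable, the
    qualitative read-loss behaviour of the original chemistry.
    """

    base_substitution_rate: float = 0.0002
    ramp_start: int = 170
    ramp_rate: float = 0.002
    indel_rate: float = 0.0005
    chimera_rate: float = 0.01
    max_substitution: float = 0.75

    def __post_init__(self) -> None:
        for name in ("base_substitution_rate", "ramp_rate", "indel_rate",
                     "chimera_rate", "max_substitution"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ramp_start < 0:
            raise ValueError("ramp_start must be >= 0")

    def substitution_probs(self, length: int) -> np.ndarray:
        pos = np.arange(length)
        p = self.base_substitution_rate + self.ramp_rate * np.maximum(0, pos - self.ramp_start)
        return np.minimum(p, self.max_substitution)


NOISE_FREE = ErrorModel(base_substitution_rate=0.0, ramp_rate=0.0,
                        indel_rate=0.0, chimera_rate=0.0)
DEFAULT_ERROR_MODEL = ErrorModel()


@dataclass(frozen=True)
class MockCommunity:
    """Ground-truth composition behind one simulated scat.

    ``composition`` gives the mixture over food taxa (sums to 1);
    ``nuisance_fractions`` gives the fractions of *total* reads drawn from
    the parasite, contaminant and unicell reference pools and from taxa
    absent from the reference; food reads take the remainder.
    """

    scat_id: str
    composition: Mapping[str, float]
    nuisance_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NUISANCE_FRACTIONS)
    )
    sex: str = "unknown"

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"food proportions sum to {total}, not 1")
        bad = set(self.nuisance_fractions) - {"parasite", "contaminant", "unicell", "absent"}
        if bad:
            raise ValueError(f"unknown nuisance pools {sorted(bad)}")
        s = sum(self.nuisance_fractions.values())
        if any(not 0 <= v <= 1 for v in self.nuisance_fractions.values()) or s >= 1:
            raise ValueError("nuisance fractions must lie in [0,1] and sum to < 1")


# Mirrors the category-level composition of sequences recovered in the
# original survey (~51% food, with krill dominating the food fraction).
DEFAULT_COMPOSITION: dict[str, float] = {
    "Euphausiidae": 0.45,
    "Actinopterygii": 0.20,
    "Calanoida": 0.15,
    "Amphipoda": 0.10,
    "Scyphozoa": 0.07,
    "Ctenophora": 0.03,
}
DEFAULT_NUISANCE_FRACTIONS: dict[str, float] = {
    "parasite": 0.107,
    "contaminant": 0.149,
    "unicell": 0.130,
    "absent": 0.105,
}

# name pools for generated taxa, keyed by category
_TAXON_POOLS: dict[Category, list[str]] = {}


def _taxon_pools() -> dict[Category, list[str]]:
    if not _TAXON_POOLS:
        pools: dict[Category, list[str]] = {c: [] for c in Category}
        for rule in default_aggregation_list().values():
            pools[rule.category].append(rule.taxon)
        _TAXON_POOLS.update(pools)
    return _TAXON_POOLS

_LINEAGE_PARENTS: dict[Category, tuple[str, ...]] = {
    Category.FOOD: ("Eukaryota", "Metazoa"),
    Category.PARASITE: ("Eukaryota", "Metazoa"),
    Category.CONTAMINANT: ("Eukaryota", "Opisthokonta"),
    Category.UNICELL: ("Eukaryota", "Protista"),
}


def _random_template(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(_BASES, size=length))


def build_mock_reference(
    n_food: int,
    n_parasite: int = 2,
    n_contaminant: int = 2,
    n_unicell: int = 2,
    amplicon_length_range: tuple[int, int] = (140, 170),
    seed: int = 0,
    scheme: TagScheme | None = None,
    food_taxa: Sequence[str] | None = None,
    max_identity: float = 0.90,
) -> tuple[list[ReferenceRecord], dict[str, AggregationRule]]:
    """Generate a lineage-named reference and its aggregation list.

    Taxon labels come from the packaged aggregation table (or
    ``food_taxa`` for the food category); templates are mutually below
    ``max_identity`` so the 90% clustering and >90% assignment thresholds
    separate them; every record carries the scheme's primer-binding flanks.
    """
    if min(n_food, n_parasite, n_contaminant, n_unicell) < 1:
        raise ValueError("all taxon counts must be >= 1")
    lo, hi = amplicon_length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"bad amplicon length range {amplicon_length_range}")
    scheme = scheme or default_tag_scheme()
    rng = np.random.default_rng(seed)
    pools = _taxon_pools()

    requested: list[tuple[str, Category]] = []
    for category, count in [
        (Category.FOOD, n_food),
        (Category.PARASITE, n_parasite),
        (Category.CONTAMINANT, n_contaminant),
        (Category.UNICELL, n_unicell),
    ]:
        if category is Category.FOOD:
            # default order puts the dominant survey prey groups first so a
            # small n_food matches the default community composition
            names = list(food_taxa) if food_taxa else (
                list(DEFAULT_COMPOSITION)
                + [t for t in pools[category] if t not in DEFAULT_COMPOSITION]
            )
        else:
            names = pools[category]
        if count > len(names):
            raise GenerationError(
                f"{count} {category.value} taxa requested but only "
                f"{len(names)} names available"
            )
        requested.extend((name, category) for name in names[:count])

    templates: list[str] = []
    records: list[ReferenceRecord] = []
    rules: dict[str, AggregationRule] = {}
    for idx, (taxon, category) in enumerate(requested):
        for _attempt in range(60):
            template = _random_template(rng, amplicon_length_range)
            if all(pairwise_identity(template, t) < max_identity for t in templates):
                break
        else:
            raise GenerationError(
                f"could not generate a template for {taxon} mutually "
                f"<{max_identity:.0%} identical to the others; requested "
                "taxon set too large for the amplicon length range"
            )
        templates.append(template)
        lineage = TaxonLineage(
            _LINEAGE_PARENTS[category]
            + (taxon, f"{taxon}_genus", f"{taxon}_{'sp'}{idx}")
        )
        sequence = scheme.forward_primer + template + revcomp(scheme.reverse_primer)
        records.append(ReferenceRecord(f"MOCK{idx:04d}", lineage, sequence))
        rules[taxon] = AggregationRule(taxon, category)
    return records, rules


def _record_template(record: ReferenceRecord, scheme: TagScheme) -> str:
    """Strip the primer-binding flanks if present; else use the sequence."""
    seq = record.sequence
    fp, rp = scheme.forward_primer, revcomp(scheme.reverse_primer)
    if seq.startswith(fp) and seq.endswith(rp) and len(seq) > len(fp) + len(rp):
        return seq[len(fp) : len(seq) - len(rp)]
    return seq


def _record_category(record: ReferenceRecord,
                     rules: Mapping[str, AggregationRule]) -> tuple[str, Category] | None:
    for rank in reversed(record.lineage.ranks):
        rule = rules.get(rank)
        if rule is not None:
            return rule.taxon, rule.category
    return None


def _phred_from_probs(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        q = np.where(p > 0, -10.0 * np.log10(np.maximum(p, 1e-12)), 40.0)
    return np.clip(np.rint(q), 2, 40).astype(int)


def _corrupt(clean: str, model: ErrorModel, rng: np.random.Generator) -> SequencingRead:
    bases = np.frombuffer(clean.encode(), dtype="S1").astype("U1")
    if model.indel_rate > 0:
        keep = rng.random(bases.size) >= model.indel_rate / 2
        bases = bases[keep]
        n_ins = rng.binomial(bases.size, model.indel_rate / 2)
        if n_ins:
            at = rng.integers(0, bases.size + 1, size=n_ins)
            bases = np.insert(bases, at, rng.choice(_BASES, size=n_ins))
    p = model.substitution_probs(bases.size)
    hit = rng.random(bases.size) < p
    if hit.any():
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx = np.searchsorted(_BASES, bases[hit])
        bases[hit] = _BASES[(idx + shift) % 4]
    quals = _phred_from_probs(p)
    return SequencingRead("", "".join(bases), tuple(int(q) for q in quals))


def simulate_scat_reads(
    community: MockCommunity,
    n_reads: int,
    tag_pair: tuple[str, str],
    scheme: TagScheme,
    model: ErrorModel,
    reference: Sequence[ReferenceRecord],
    seed: int,
    rules: Mapping[str, AggregationRule] | None = None,
    read_id_prefix: str | None = None,
    n_absent_taxa: int = 2,
) -> tuple[list[SequencingRead], list[tuple[str, str, str, str]]]:
    """Simulate one scat's tagged reads plus truth rows.

    Truth rows are ``(read_id, scat_id, category, taxon)`` with category
    "chimera" for spliced reads and "absent" for reads from taxa missing
    from the reference.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if not reference:
        raise ValueError("empty reference collection")
    fwd_name, rev_name = tag_pair
    if fwd_name not in scheme.forward_tags or rev_name not in scheme.reverse_tags:
        raise ValueError(f"tag pair {tag_pair!r} not in scheme")
    rules = rules if rules is not None else default_aggregation_list()
    rng = np.random.default_rng(seed)

    # organise reference templates by (taxon, category)
    by_taxon: dict[str, list[str]] = {}
    by_category: dict[Category, list[str]] = {c: [] for c in Category}
    for rec in reference:
        tc = _record_category(rec, rules)
        if tc is None:
            continue
        taxon, category = tc
        by_taxon.setdefault(taxon, []).append(_record_template(rec, scheme))
        if taxon not in by_category[category]:
            by_category[category].append(taxon)
    missing = [t for t in community.composition if t not in by_taxon]
    if missing:
        raise GenerationError(f"composition taxa missing from reference: {missing}")
    for pool in ("parasite", "contaminant", "unicell"):
        if community.nuisance_fractions.get(pool, 0) > 0 and not by_category[Category(pool)]:
            raise GenerationError(f"nuisance pool {pool!r} empty in reference")

    mean_len = int(np.mean([len(_record_template(r, scheme)) for r in reference]))
    absent_templates = [
        _random_template(rng, (mean_len, mean_len)) for _ in range(n_absent_taxa)
    ]

    food_taxa = list(community.composition)
    nuis = community.nuisance_fractions
    food_total = 1.0 - sum(nuis.values())
    source_labels = (
        [("food", t) for t in food_taxa]
        + [("parasite", None), ("contaminant", None), ("unicell", None), ("absent", None)]
    )
    probs = np.array(
        [food_total * community.composition[t] for t in food_taxa]
        + [nuis.get("parasite", 0.0), nuis.get("contaminant", 0.0),
           nuis.get("unicell", 0.0), nuis.get("absent", 0.0)]
    )
    probs = probs / probs.sum()

    prefix = read_id_prefix or community.scat_id
    fwd = scheme.forward_tags[fwd_name] + scheme.forward_primer
    rev = revcomp(scheme.reverse_primer) + revcomp(scheme.reverse_tags[rev_name])

    choices = rng.choice(len(source_labels), size=n_reads, p=probs)
    is_chimera = rng.random(n_reads) < model.chimera_rate

    def _pick_template(source_idx: int) -> tuple[str, str, str]:
        kind, taxon = source_labels[source_idx]
        if kind == "food":
            pool = by_taxon[taxon]
            return pool[int(rng.integers(len(pool)))], kind, taxon
        if kind == "absent":
            return absent_templates[int(rng.integers(len(absent_templates)))], kind, "absent"
        taxon = by_category[Category(kind)][
            int(rng.integers(len(by_category[Category(kind)])))
        ]
        pool = by_taxon[taxon]
        return pool[int(rng.integers(len(pool)))], kind, taxon

    reads: list[SequencingRead] = []
    truth: list[tuple[str, str, str, str]] = []
    for k in range(n_reads):
        read_id = f"{prefix}_r{k:06d}"
        if is_chimera[k]:
            t1, _, _ = _pick_template(int(choices[k]))
            t2, _, _ = _pick_template(int(rng.choice(len(source_labels), p=probs)))
            cut = int(rng.integers(1, min(len(t1), len(t2))))
            template = t1[:cut] + t2[cut:]
            category, taxon = "chimera", "chimera"
        else:
            template, category, taxon = _pick_template(int(choices[k]))
        clean = fwd + template + rev
        read = _corrupt(clean, model, rng)
        reads.append(replace(read, read_id=read_id))
        truth.append((read_id, community.scat_id, category, taxon))
    return reads, truth


def simulate_run(
    sample_sheet: Sequence[SampleSheetRow],
    communities: Mapping[str, MockCommunity],
    scheme: TagScheme,
    model: ErrorModel,
    reference: Sequence[ReferenceRecord],
    seed: int,
    n_reads: int | Mapping[str, int] = 500,
    rules: Mapping[str, AggregationRule] | None = None,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[SequencingRead], list[tuple[str, str, str, str]]]:
    """Simulate a pooled run: all scats' reads, deterministically shuffled.

    Every sheet row's tag pair must be unique within the run (a collision
    would make demultiplexing ill-posed).
    """
    pairs = [(row.fwd_tag, row.rev_tag) for row in sample_sheet]
    dupes = {p for p in pairs if pairs.count(p) > 1}
    if dupes:
        raise ValueError(f"duplicate tag pair(s) in run: {sorted(dupes)}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sample_sheet) + 1)
    all_reads: list[SequencingRead] = []
    truth: list[tuple[str, str, str, str]] = []
    for row, child in zip(sample_sheet, children[:-1]):
        community = communities[row.scat_id]
        count = n_reads if isinstance(n_reads, int) else n_reads[row.scat_id]
        reads, rows = simulate_scat_reads(
            community, count, (row.fwd_tag, row.rev_tag), scheme, model,
            reference, seed=int(child.generate_state(1)[0] % (2**31)), rules=rules,
        )
        all_reads.extend(reads)
        truth.extend(rows)
    shuffle_rng = np.random.default_rng(children[-1])
    order = shuffle_rng.permutation(len(all_reads))
    all_reads = [all_reads[i] for i in order]
    if fastq_path is not None:
        write_fastq(all_reads, fastq_path)
    if truth_path is not None:
        write_truth_table(truth, truth_path)
    return all_reads, truth


def make_population(
    scat_ids: Sequence[str],
    composition: Mapping[str, float] | None = None,
    nuisance_fractions: Mapping[str, float] | None = None,
    dirichlet_concentration: float | None = None,
    seed: int = 0,
    sexes: Sequence[str] | None = None,
) -> dict[str, MockCommunity]:
    """Communities for a population of scats sharing a base composition.

    With ``dirichlet_concentration`` set, each scat's food composition is a
    Dirichlet draw centred on the base composition (between-scat diet
    heterogeneity); otherwise every scat uses the base composition exactly.
    """
    composition = dict(composition or DEFAULT_COMPOSITION)
    nuisance = dict(
        nuisance_fractions if nuisance_fractions is not None else DEFAULT_NUISANCE_FRACTIONS
    )
    rng = np.random.default_rng(seed)
    taxa = list(composition)
    base = np.array([composition[t] for t in taxa])
    out: dict[str, MockCommunity] = {}
    for i, scat_id in enumerate(scat_ids):
        if dirichlet_concentration is not None:
            p = rng.dirichlet(base * dirichlet_concentration)
            p = p / p.sum()
        else:
            p = base
        out[scat_id] = MockCommunity(
            scat_id=scat_id,
            composition={t: float(v) for t, v in zip(taxa, p)},
            nuisance_fractions=nuisance,
            sex=sexes[i] if sexes else "unknown",
        )
    return out


def write_truth_table(
    rows: Iterable[tuple[str, str, str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tscat_id\tcategory\ttaxon\n")
        for read_id, scat_id, category, taxon in rows:
            fh.write(f"{read_id}\t{scat_id}\t{category}\t{taxon}\n")


def write_aggregation_list(
    rules: Mapping[str, AggregationRule], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tcategory\tcommon_name\n")
        for rule in rules.values():
            fh.write(f"{rule.taxon}\t{rule.category.value}\t{rule.common_name}\n")
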