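"""Best-hit search, aggregation rules and the two-phase training workflow."""

import numpy as np
import pytest

from scatdiet.classify import (
    AggregationRule,
    Category,
    HitResult,
    Outcome,
    best_hit,
    classify_cluster,
    classify_clusters,
    default_aggregation_list,
    load_aggregation_list,
    run_training_phase,
)
from scatdiet.cluster import SequenceCluster, greedy_cluster
from scatdiet.reference import TaxonLineage
from scatdiet.tags import default_tag_scheme


def template_of(record):
    """Strip the primer-binding flanks of a mock reference record."""
    scheme = default_tag_scheme()
    return record.sequence[len(scheme.forward_primer): -len(scheme.reverse_primer)]


def substitute(seq, positions):
    out = list(seq)
    for pos in positions:
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


class TestBestHit:
    def test_exact_sequence_identity_one(self, mock_reference):
        records, _ = mock_reference
        hit = best_hit(template_of(records[0]), records)
        assert hit.record_id == records[0].record_id
        assert hit.identity == 1.0

    def test_single_substitution(self, mock_reference):
        records, _ = mock_reference
        seed = substitute(template_of(records[2]), [40])
        hit = best_hit(seed, records)
        assert hit.record_id == records[2].record_id
        n = len(seed)
        assert hit.identity == pytest.approx((n - 1) / n)

    def test_random_seed_no_match(self, mock_reference):
        records, _ = mock_reference
        rng = np.random.default_rng(123)
        for _ in range(5):
            seed = "".join(rng.choice(list("ACGT"), size=150))
            assert best_hit(seed, records) is None

    def test_chimera_no_match(self, mock_reference):
        records, _ = mock_reference
        t1, t2 = template_of(records[0]), template_of(records[1])
        chimera = t1[: len(t1) // 2] + t2[len(t2) // 2:]
        assert best_hit(chimera, records) is None

    def test_errors(self, mock_reference):
        records, _ = mock_reference
        with pytest.raises(ValueError):
            best_hit("", records)
        with pytest.raises(ValueError):
            best_hit("ACGT", [])


class TestClassifyCluster:
    RULES = {
        "Scyphozoa": AggregationRule("Scyphozoa", Category.FOOD),
        "Primates": AggregationRule("Primates", Category.CONTAMINANT),
        "Calanoida": AggregationRule("Calanoida", Category.FOOD),
        "Metazoa": AggregationRule("Metazoa", Category.FOOD),
    }
    LINEAGE = TaxonLineage.parse(
        "Metazoa;Cnidaria;Scyphozoa;Coronatae;Nausithoidae;Nausithoe;Nausithoe_rubra"
    )
    CLUSTER = SequenceCluster("ACGT" * 30, ["r1", "r2"])

    def test_listed_rank_assigned(self):
        hit = HitResult("db1", 0.97, self.LINEAGE)
        c = classify_cluster(self.CLUSTER, hit, self.RULES)
        assert c.outcome is Outcome.ASSIGNED
        assert (c.taxon, c.category) == ("Scyphozoa", Category.FOOD)

    def test_most_specific_listed_rank_wins(self):
        # both Metazoa and Scyphozoa are listed; the more specific wins
        hit = HitResult("db1", 0.97, self.LINEAGE)
        c = classify_cluster(self.CLUSTER, hit, self.RULES)
        assert c.taxon == "Scyphozoa"

    def test_identity_exactly_090_below_threshold(self):
        hit = HitResult("db1", 0.90, self.LINEAGE)
        c = classify_cluster(self.CLUSTER, hit, self.RULES)
        assert c.outcome is Outcome.BELOW_IDENTITY

    def test_no_hit_discarded(self):
        c = classify_cluster(self.CLUSTER, None, self.RULES)
        assert c.outcome is Outcome.DISCARDED_NO_MATCH

    def test_contaminant_lineage(self):
        lineage = TaxonLineage.parse("Metazoa;Chordata;Mammalia;Primates;Homo_sapiens")
        hit = HitResult("db2", 0.99, lineage)
        c = classify_cluster(self.CLUSTER, hit, {k: v for k, v in self.RULES.items() if k != "Metazoa"})
        assert (c.taxon, c.category) == ("Primates", Category.CONTAMINANT)

    def test_unlisted_lineage_goes_to_training(self):
        hit = HitResult("db1", 0.97, TaxonLineage.parse("Fungi;Ascomycota;Unknown_sp"))
        c = classify_cluster(self.CLUSTER, hit, self.RULES)
        assert c.outcome is Outcome.TRAINING_REPORT
        assert c.lineage.species == "Unknown_sp"


class TestTrainingPhase:
    def test_all_covered_empty_report(self):
        hit = HitResult("db1", 0.97, TestClassifyCluster.LINEAGE)
        c = classify_cluster(TestClassifyCluster.CLUSTER, hit, TestClassifyCluster.RULES)
        assert run_training_phase([c]) == []

    def test_two_pass_workflow_grows_the_list(self, mock_reference):
        """Unlisted lineages surface once, then assign after list growth."""
        records, rules = mock_reference
        partial = {k: v for k, v in rules.items() if k != "Scyphozoa"}
        seeds = [template_of(r) for r in records]
        clusters = [SequenceCluster(s, [f"r{i}"]) for i, s in enumerate(seeds)]

        first = classify_clusters(clusters, records, partial)
        report = run_training_phase(first)
        assert len(report) == 1
        lineage_text, n_clusters, n_reads = report[0]
        assert "Scyphozoa" in lineage_text and n_clusters == 1 and n_reads == 1

        grown = dict(partial)
        grown["Scyphozoa"] = AggregationRule("Scyphozoa", Category.FOOD)
        second = classify_clusters(clusters, records, grown)
        assert run_training_phase(second) == []
        # previously assigned clusters keep their outcome (monotone growth)
        for before, after in zip(first, second):
            if before.outcome is Outcome.ASSIGNED:
                assert (after.taxon, after.category) == (before.taxon, before.category)
        assert all(c.outcome is Outcome.ASSIGNED for c in second)


class TestAggregationList:
    def test_packaged_table(self):
        rules = default_aggregation_list()
        assert rules["Euphausiidae"].category is Category.FOOD
        assert rules["Cestoda"].category is Category.PARASITE
        assert rules["Primates"].category is Category.CONTAMINANT
        assert rules["Saccharomycotina"].category is Category.UNICELL
        assert len(rules) == 60

    def test_load_and_errors(self, tmp_path):
        path = tmp_path / "agg.tsv"
        path.write_text("taxon\tcategory\tcommon_name\nEuphausiidae\tfood\tKrill\nCestoda\tparasite\tTapeworms\n")
        rules = load_aggregation_list(path)
        assert rules["Euphausiidae"].common_name == "Krill"

        dup = tmp_path / "dup.tsv"
        dup.write_text("Scyphozoa\tfood\nScyphozoa\tfood\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_aggregation_list(dup)

        bad = tmp_path / "bad.tsv"
        bad.write_text("Scyphozoa\tjellyfishes\n")
        with pytest.raises(ValueError, match="unknown category"):
            load_aggregation_list(bad)


class TestReadLevelAccounting:
    def test_outcome_partition_conserves_reads(self, small_run, scheme):
        from scatdiet.qc import demultiplex

        reference, rules = small_run["reference"], small_run["rules"]
        demux = demultiplex(small_run["reads"], scheme, small_run["rows"])
        total = 0
        for scat_id, trimmed in demux.trimmed_reads.items():
            clusters = greedy_cluster([(r.read_id, r.bases) for r in trimmed])
            classifications = classify_clusters(clusters, reference, rules)
            total += sum(c.n_reads for c in classifications)
        assert total == len(demux.assignments)
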