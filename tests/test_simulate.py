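"""Synthetic data generator: determinism, truth accounting, error model."""

import numpy as np
import pytest

import scatdiet as sd
from scatdiet.align import pairwise_identity
from scatdiet.classify import Category
from scatdiet.simulate import (
    NOISE_FREE,
    ErrorModel,
    GenerationError,
    MockCommunity,
    build_mock_reference,
    simulate_run,
    simulate_scat_reads,
)
from scatdiet.tags import revcomp


class TestTagScheme:
    def test_six_by_eight_unique_tags(self, scheme):
        assert len(scheme.forward_tags) == 6
        assert len(scheme.reverse_tags) == 8
        assert len(set(scheme.forward_tags.values())) == 6
        assert len(set(scheme.reverse_tags.values())) == 8

    def test_duplicate_tags_rejected(self):
        with pytest.raises(ValueError):
            sd.TagScheme({"a": "ACGT", "b": "ACGT"}, {"r": "GGGG"}, "AC", "GT")


class TestMockReference:
    def test_all_pairs_below_threshold(self, mock_reference):
        records, _ = mock_reference
        scheme = sd.default_tag_scheme()
        fp, rp = scheme.forward_primer, revcomp(scheme.reverse_primer)
        templates = [r.sequence[len(fp): -len(rp)] for r in records]
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                assert pairwise_identity(templates[i], templates[j]) < 0.90

    def test_conserved_primer_flanks(self, mock_reference, scheme):
        records, _ = mock_reference
        for r in records:
            assert r.sequence.startswith(scheme.forward_primer)
            assert r.sequence.endswith(revcomp(scheme.reverse_primer))

    def test_aggregation_list_categories(self):
        _, rules = build_mock_reference(
            n_food=2, seed=0, food_taxa=["Euphausiidae", "Actinopterygii"]
        )
        assert rules["Euphausiidae"].category is Category.FOOD
        assert rules["Actinopterygii"].category is Category.FOOD
        assert sum(r.category is Category.PARASITE for r in rules.values()) == 2

    def test_seeded_determinism(self):
        r1, _ = build_mock_reference(n_food=3, seed=42)
        r2, _ = build_mock_reference(n_food=3, seed=42)
        assert r1 == r2

    def test_infeasible_separation_errors(self):
        with pytest.raises(GenerationError):
            build_mock_reference(n_food=6, amplicon_length_range=(1, 1), seed=0)


class TestMockCommunity:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MockCommunity("S1", {"Euphausiidae": 0.6, "Calanoida": 0.3})

    def test_nuisance_fraction_bounds(self):
        with pytest.raises(ValueError):
            MockCommunity(
                "S1", {"Euphausiidae": 1.0},
                nuisance_fractions={"parasite": 0.6, "contaminant": 0.5},
            )
        with pytest.raises(ValueError):
            MockCommunity("S1", {"Euphausiidae": 1.0}, nuisance_fractions={"bogus": 0.1})


class TestSimulateScatReads:
    def test_noise_free_reads_are_exact_tagged_templates(self, scheme, mock_reference):
        records, rules = mock_reference
        community = MockCommunity(
            "S1", {"Euphausiidae": 1.0},
            nuisance_fractions={"parasite": 0, "contaminant": 0, "unicell": 0, "absent": 0},
        )
        reads, truth = simulate_scat_reads(
            community, 30, ("F_1", "R_A"), scheme, NOISE_FREE, records,
            seed=1, rules=rules,
        )
        prefix = scheme.read_prefix("F_1")
        suffix = scheme.read_suffix("R_A")
        for read in reads:
            assert read.bases.startswith(prefix)
            assert read.bases.endswith(suffix)
            assert len(set(read.qualities)) == 1  # constant quality at zero error
        assert all(taxon == "Euphausiidae" for _, _, _, taxon in truth)

    def test_truth_rows_match_reads(self, scheme, mock_reference):
        records, rules = mock_reference
        community = MockCommunity("S1", dict(sd.DEFAULT_COMPOSITION))
        reads, truth = simulate_scat_reads(
            community, 50, ("F_1", "R_A"), scheme, NOISE_FREE, records,
            seed=2, rules=rules,
        )
        assert [r.read_id for r in reads] == [row[0] for row in truth]
        categories = {row[2] for row in truth}
        assert categories <= {"food", "parasite", "contaminant", "unicell", "absent", "chimera"}

    def test_terminal_tag_corruption_matches_closed_form(self, scheme, mock_reference):
        """Substitution ramp vs the Bernoulli-product corruption probability."""
        records, rules = mock_reference
        # fixed-length templates so every read has the same length
        ref, rules2 = build_mock_reference(
            n_food=2, n_parasite=1, n_contaminant=1, n_unicell=1,
            amplicon_length_range=(150, 150), seed=3,
        )
        model = ErrorModel(
            base_substitution_rate=0.0, ramp_start=205, ramp_rate=0.05,
            indel_rate=0.0, chimera_rate=0.0,
        )
        community = MockCommunity(
            "S1", {"Euphausiidae": 1.0},
            nuisance_fractions={"parasite": 0, "contaminant": 0, "unicell": 0, "absent": 0},
        )
        n = 10_000
        reads, _ = simulate_scat_reads(
            community, n, ("F_1", "R_A"), scheme, model, ref, seed=4, rules=rules2,
        )
        read_len = len(reads[0])
        assert read_len == 10 + 21 + 150 + 26 + 10
        probs = model.substitution_probs(read_len)
        tag_probs = probs[-10:]
        assert float(np.mean(probs[-12:])) == pytest.approx(0.3, abs=0.12)
        expected = 1.0 - np.prod(1.0 - tag_probs)
        suffix = scheme.read_suffix("R_A")[-10:]
        observed = np.mean([r.bases[-10:] != suffix for r in reads])
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se

    def test_quality_drops_beyond_ramp(self, scheme, mock_reference):
        records, rules = mock_reference
        model = ErrorModel(base_substitution_rate=0.002, ramp_start=120, ramp_rate=0.02)
        community = MockCommunity("S1", {"Euphausiidae": 1.0})
        reads, _ = simulate_scat_reads(
            community, 10, ("F_1", "R_A"), scheme, model, records, seed=5, rules=rules,
        )
        for r in reads:
            head = np.mean(r.qualities[:100])
            tail = np.mean(r.qualities[-20:])
            assert tail < head

    def test_error_model_validation(self):
        with pytest.raises(ValueError):
            ErrorModel(base_substitution_rate=1.5)
        with pytest.raises(ValueError):
            ErrorModel(ramp_start=-1)
        probs = ErrorModel(ramp_start=50, ramp_rate=0.01).substitution_probs(200)
        assert (np.diff(probs[50:]) >= 0).all()  # non-decreasing beyond ramp


class TestSimulateRun:
    def test_count_conservation(self, scheme, mock_reference):
        records, rules = mock_reference
        rows = [
            sd.SampleSheetRow("run1", "S1", "F_1", "R_A"),
            sd.SampleSheetRow("run1", "S2", "F_2", "R_B"),
        ]
        communities = sd.make_population(["S1", "S2"], seed=0)
        reads, truth = simulate_run(
            rows, communities, scheme, NOISE_FREE, records, seed=1,
            n_reads=100, rules=rules,
        )
        assert len(reads) == 200 and len(truth) == 200
        per_scat = {}
        for _, scat, _, _ in truth:
            per_scat[scat] = per_scat.get(scat, 0) + 1
        assert per_scat == {"S1": 100, "S2": 100}
        assert len({row[0] for row in truth}) == 200  # read ids unique

    def test_same_seed_identical_fastq_bytes(self, tmp_path, scheme, mock_reference):
        records, rules = mock_reference
        rows = [sd.SampleSheetRow("run1", "S1", "F_1", "R_A")]
        communities = sd.make_population(["S1"], seed=0)
        blobs = []
        for name in ("a.fastq", "b.fastq"):
            simulate_run(
                rows, communities, scheme, sd.DEFAULT_ERROR_MODEL, records,
                seed=9, n_reads=50, rules=rules, fastq_path=tmp_path / name,
            )
            blobs.append((tmp_path / name).read_bytes())
        assert blobs[0] == blobs[1]

    def test_different_seeds_differ(self, scheme, mock_reference):
        records, rules = mock_reference
        rows = [sd.SampleSheetRow("run1", "S1", "F_1", "R_A")]
        communities = sd.make_population(["S1"], seed=0)
        reads_a, _ = simulate_run(rows, communities, scheme, NOISE_FREE, records,
                                  seed=1, n_reads=50, rules=rules)
        reads_b, _ = simulate_run(rows, communities, scheme, NOISE_FREE, records,
                                  seed=2, n_reads=50, rules=rules)
        assert [r.bases for r in reads_a] != [r.bases for r in reads_b]

    def test_duplicate_tag_pair_rejected(self, scheme, mock_reference):
        records, rules = mock_reference
        rows = [
            sd.SampleSheetRow("run1", "S1", "F_1", "R_A"),
            sd.SampleSheetRow("run1", "S2", "F_1", "R_A"),
        ]
        communities = sd.make_population(["S1", "S2"], seed=0)
        with pytest.raises(ValueError, match="duplicate tag pair"):
            simulate_run(rows, communities, scheme, NOISE_FREE, records,
                         seed=1, n_reads=10, rules=rules)
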