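import numpy as np
import pytest

from oracles import bfs_view
from hco.frames import extract_view, make_config
from hco.model import fma
from hco.queries import resolve_expression, competency_query
from hco.synthetic import (
    CohortConfig,
    MASK1_PARCEL_IDS,
    generate_cohort,
    generate_mini_fma,
    tract_class_names,
    subcortical_region_terms,
)
from hco.workflow import competency_answers, parcel_ids, saturate_bundle


class TestMiniFma:
    def test_manifest_counts_match_graph(self, mini_fma):
        g = mini_fma.graph
        assert mini_fma.manifest["n_entities"] == len(g.entities)
        assert mini_fma.manifest["n_triples"] == len(g.triples)
        assert mini_fma.manifest["n_metaclasses"] == 1
        assert len(g.metaclass_flags) == 1

    def test_generation_is_deterministic(self, mini_fma):
        again = generate_mini_fma()
        assert again.graph.triples == mini_fma.graph.triples
        assert again.manifest == mini_fma.manifest

    def test_gyrus_reaches_root_through_part_of_edges(self, mini_fma):
        config = make_config([fma("Right_precentral_gyrus")])
        view = bfs_view(mini_fma.graph, config)
        assert fma("Neuraxis") in view.entities
        assert extract_view(mini_fma.graph, config).entities == view.entities

    def test_twenty_tract_classes(self):
        names = tract_class_names()
        assert len(names) == 20
        assert len(set(names)) == 20
        assert "Right_corticospinal_tract_of_brain" in names
        assert "Right_superior_longitudinal_fasciculus" in names

    def test_fifteen_subcortical_regions(self):
        terms = subcortical_region_terms()
        assert len(terms) == 15
        assert fma("Brainstem") in terms

    def test_query_vocabulary_closure(self, reference_tbox):
        for n in (1, 2, 3, 4):
            resolve_expression(competency_query(n), reference_tbox)


class TestCohortShapes:
    def test_default_configuration_matches_study_design(self):
        config = CohortConfig()
        assert config.n_subjects == 5
        assert config.n_parcels == 1000
        assert config.mask1_parcel_count == 11
        assert len(config.seed_masks) == 22
        assert sum(1 for m in config.seed_masks if m is None) == 2
        assert config.n_columns == 1000 - 11 + 15 == 1004

    def test_small_cohort_matrix_shapes(self, small_cohort,
                                        small_cohort_config):
        cfg = small_cohort_config
        for bundle in small_cohort:
            assert len(bundle.matrices) == 22
            for m in bundle.matrices:
                assert m.values.shape == (cfg.mask1_parcel_count,
                                          cfg.n_columns)

    def test_mask_parcels_use_published_identifiers(self, small_cohort):
        mask_rows = small_cohort[0].matrices[0].row_labels
        assert tuple(int(r) for r in mask_rows) == MASK1_PARCEL_IDS

    def test_same_seed_reproduces_bitwise(self, small_cohort_config):
        a = generate_cohort(small_cohort_config)
        b = generate_cohort(small_cohort_config)
        for ba, bb in zip(a, b):
            assert ba.adjacency.edges == bb.adjacency.edges
            assert ba.truth == bb.truth
            for ma, mb in zip(ba.matrices, bb.matrices):
                assert ma.values.tobytes() == mb.values.tobytes()

    def test_different_seeds_differ(self, small_cohort_config):
        import dataclasses

        other = dataclasses.replace(small_cohort_config, rng_seed=8,
                                    noise_rate=0.01)
        base = dataclasses.replace(small_cohort_config, noise_rate=0.01)
        a = generate_cohort(base)
        b = generate_cohort(other)
        assert any(ma.values.tobytes() != mb.values.tobytes()
                   for ma, mb in zip(a[0].matrices, b[0].matrices))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_parcels=5, mask1_parcel_count=11)
        with pytest.raises(ValueError):
            CohortConfig(noise_rate=1.5)


class TestPlantedRecovery:
    def test_noise_free_answers_equal_planted_truth(self, small_cohort,
                                                    reference_tbox):
        for bundle in small_cohort:
            s = saturate_bundle(bundle, reference_tbox)
            answers = competency_answers(s)
            truth = bundle.truth
            assert parcel_ids(answers[1]) == truth["sma_parcels"]
            assert parcel_ids(answers[2]) == truth["pre_sma_parcels"]
            assert parcel_ids(answers[3]) == truth["motor_extended_parcels"]
            assert truth["bundle_individual"] \
                in [str(a) for a in answers[4].answers]

    def test_low_noise_only_adds_answers(self, small_cohort_config,
                                         reference_tbox):
        import dataclasses

        noisy_cfg = dataclasses.replace(small_cohort_config,
                                        noise_rate=0.01, n_subjects=1)
        bundle = generate_cohort(noisy_cfg)[0]
        s = saturate_bundle(bundle, reference_tbox)
        answers = competency_answers(s)
        assert set(bundle.truth["sma_parcels"]) \
            <= set(parcel_ids(answers[1]))
        assert set(bundle.truth["pre_sma_parcels"]) \
            <= set(parcel_ids(answers[2]))
        assert bundle.truth["bundle_individual"] \
            in [str(a) for a in answers[4].answers]

    def test_planted_values_survive_binarization_noise_does_not(
            self, small_cohort):
        from hco.annotate import binarize_matrix
        from hco.synthetic import PLANTED_VALUE

        bundle = small_cohort[0]
        planted_found = 0
        for matrix in bundle.matrices:
            binary = binarize_matrix(matrix)
            planted = matrix.values == PLANTED_VALUE
            assert np.all(binary.values[planted] == 1.0)
            planted_found += int(planted.sum())
        assert planted_found == 6  # 2 SMA + 2 pre-SMA + neighbor + bundle
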