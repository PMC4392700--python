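import math
import random

import numpy as np
import pytest

from hco.annotate import (
    Adjacency,
    AnnotationConfig,
    AnnotationError,
    BinaryMatrix,
    ParcelInfo,
    Parcellation,
    RegionMatrix,
    aggregate_voxelwise,
    annotate_subject,
    binarize_matrix,
    route_count,
)
from hco.model import (
    CONTINUOUS_WITH,
    MR_CONNECTION,
    MR_ROUTE,
    REGIONAL_PART_OF,
    TRACTO_CONNECTS,
    fma,
    hco,
)


class TestAggregateVoxelwise:
    def test_one_voxel_per_region_is_identity(self):
        m = RegionMatrix(("v1", "v2"), ("w1",), np.array([[1.0], [2.0]]))
        out = aggregate_voxelwise(m, {"v1": "r1", "v2": "r2", "w1": "c1"})
        assert out.values.shape == (2, 1)
        assert sorted(out.row_labels) == ["r1", "r2"]
        assert np.allclose(np.sort(out.values, axis=0), [[1.0], [2.0]])

    def test_mean_over_voxel_pairs(self):
        m = RegionMatrix(("v1", "v2"), ("w1",), np.array([[0.2], [0.4]]))
        out = aggregate_voxelwise(m, {"v1": "R", "v2": "R", "w1": "C"})
        assert out.values[0, 0] == pytest.approx(0.3)

    def test_all_zero_matrix_stays_zero(self):
        m = RegionMatrix(("v1", "v2"), ("w1", "w2"), np.zeros((2, 2)))
        out = aggregate_voxelwise(m, {"v1": "R", "v2": "R",
                                      "w1": "C", "w2": "C"})
        assert np.all(out.values == 0)

    def test_constant_matrix_aggregates_to_same_constant(self):
        m = RegionMatrix(tuple("abcd"), tuple("wxyz"),
                         np.full((4, 4), 2.5))
        out = aggregate_voxelwise(m, {v: f"r{i % 2}" for i, v in
                                      enumerate("abcd")} |
                                  {v: f"c{i % 2}" for i, v in
                                   enumerate("wxyz")})
        assert np.allclose(out.values, 2.5)

    def test_unmapped_voxel_is_an_error_naming_it(self):
        m = RegionMatrix(("v1",), ("w1",), np.array([[1.0]]))
        with pytest.raises(AnnotationError, match="w1"):
            aggregate_voxelwise(m, {"v1": "R"})


class TestBinarizeMatrix:
    def test_ln_ratio_hand_example(self):
        # ln(1+9)=ln 10, ln(1+99)=ln 100; the ratio is exactly 0.5
        m = RegionMatrix(("r",), ("a", "b", "c"),
                         np.array([[9.0, 99.0, 0.0]]))
        out = binarize_matrix(m, AnnotationConfig(threshold=0.7))
        assert out.values.tolist() == [[0.0, 1.0, 0.0]]

    def test_zero_row_stays_zero(self):
        m = RegionMatrix(("r",), ("a", "b", "c"), np.zeros((1, 3)))
        out = binarize_matrix(m)
        assert out.values.tolist() == [[0.0, 0.0, 0.0]]

    @pytest.mark.parametrize("trial", range(20))
    def test_row_maximum_always_survives(self, trial):
        rng = np.random.default_rng(trial)
        values = rng.uniform(0, 50, size=(4, 6))
        out = binarize_matrix(RegionMatrix(
            tuple("rstu"), tuple("abcdef"), values))
        for i in range(4):
            assert out.values[i, np.argmax(np.log1p(values[i]))] == 1.0

    def test_not_scale_invariant_but_max_preserved(self):
        row = np.array([[3.0, 20.0, 0.0]])
        m1 = binarize_matrix(RegionMatrix(("r",), ("a", "b", "c"), row))
        m2 = binarize_matrix(RegionMatrix(("r",), ("a", "b", "c"),
                                          row * 1000))
        # scaling changes ln-ratios: cell 'a' crosses the 0.7 threshold
        assert m1.values.tolist() == [[0.0, 1.0, 0.0]]
        assert m2.values.tolist() == [[1.0, 1.0, 0.0]]

    def test_threshold_is_inclusive(self):
        x = math.e - 1  # ln(1+x) = 1
        y = math.exp(0.7) - 1  # normalized value exactly 0.7
        m = RegionMatrix(("r",), ("a", "b"), np.array([[x, y]]))
        out = binarize_matrix(m, AnnotationConfig(threshold=0.7))
        assert out.values.tolist() == [[1.0, 1.0]]

    def test_negative_values_rejected(self):
        with pytest.raises(AnnotationError):
            RegionMatrix(("r",), ("a",), np.array([[-1.0]]))


def _tiny_setup(tbox):
    parcels = (
        ParcelInfo(17, fma("Right_superior_frontal_gyrus"), "right"),
        ParcelInfo(20, fma("Right_superior_frontal_gyrus"), "right"),
        ParcelInfo(39, fma("Left_superior_frontal_gyrus"), "left"),
    )
    hints = {
        fma("Right_superior_frontal_gyrus"):
            ((REGIONAL_PART_OF, fma("Right_frontal_lobe")),),
    }
    parc = Parcellation("s1", parcels, (("brainstem", fma("Brainstem")),),
                        hints)
    adjacency = Adjacency()
    adjacency.add("17", "20")
    return parc, adjacency


class TestAnnotateSubject:
    def test_interhemispheric_route_through_named_bundle(self,
                                                         reference_tbox):
        parc, adjacency = _tiny_setup(reference_tbox)
        forceps = fma("Anterior_forceps_of_corpus_callosum")
        matrix = BinaryMatrix(("17",), ("39", "brainstem"),
                              np.array([[1.0, 0.0]]), seed_label=forceps)
        abox = annotate_subject(parc, adjacency, [matrix], reference_tbox)
        route = hco("s1_mr_route_1")
        n17 = hco("s1_gray_matter_of_right_superior_frontal_gyrus_17")
        n39 = hco("s1_gray_matter_of_left_superior_frontal_gyrus_39")
        assert (route, MR_ROUTE) in abox.type_assertions
        assert (TRACTO_CONNECTS, route, n17) in abox.role_assertions
        assert (TRACTO_CONNECTS, route, n39) in abox.role_assertions
        assert (REGIONAL_PART_OF, route,
                hco("s1_anterior_forceps_of_corpus_callosum")) \
            in abox.role_assertions
        assert (MR_CONNECTION, n17, n39) in abox.role_assertions

    def test_all_zero_matrices_give_no_routes(self, reference_tbox):
        parc, adjacency = _tiny_setup(reference_tbox)
        matrix = BinaryMatrix(("17",), ("39", "brainstem"),
                              np.zeros((1, 2)))
        abox = annotate_subject(parc, adjacency, [matrix], reference_tbox)
        assert route_count(abox) == 0
        assert not any(p == MR_CONNECTION for p, _, _ in
                       abox.role_assertions)
        # parcels are typed Gray_matter_part only (realization is deferred)
        n17 = hco("s1_gray_matter_of_right_superior_frontal_gyrus_17")
        assert {c for i, c in abox.type_assertions if i == n17} \
            == {hco("Gray_matter_part")}

    def test_partonomy_chain_and_adjacency_assertions(self, reference_tbox):
        parc, adjacency = _tiny_setup(reference_tbox)
        abox = annotate_subject(parc, adjacency, [], reference_tbox)
        n17 = hco("s1_gray_matter_of_right_superior_frontal_gyrus_17")
        gm = hco("s1_gray_matter_of_right_superior_frontal_gyrus")
        region = hco("s1_right_superior_frontal_gyrus")
        assert (REGIONAL_PART_OF, n17, gm) in abox.role_assertions
        assert (fma("constitutional_part_of"), gm, region) \
            in abox.role_assertions
        assert (REGIONAL_PART_OF, region, hco("s1_right_frontal_lobe")) \
            in abox.role_assertions
        # one continuous_with direction per neighbor pair
        cw = [r for r in abox.role_assertions if r[0] == CONTINUOUS_WITH]
        assert len(cw) == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_route_count_identity_on_random_binary_matrices(
            self, reference_tbox, trial):
        rng = random.Random(trial)
        parc, adjacency = _tiny_setup(reference_tbox)
        matrices = []
        k_total = 0
        distinct_cells = set()
        for _ in range(rng.randint(1, 4)):
            values = np.array(
                [[1.0 if rng.random() < 0.4 else 0.0 for _ in range(2)]])
            k_total += int(values.sum())
            distinct_cells |= {("17", c) for j, c in
                               enumerate(("39", "brainstem"))
                               if values[0, j] == 1.0}
            matrices.append(BinaryMatrix(("17",), ("39", "brainstem"),
                                         values))
        abox = annotate_subject(parc, adjacency, matrices, reference_tbox)
        assert route_count(abox) == k_total
        tc = [r for r in abox.role_assertions if r[0] == TRACTO_CONNECTS]
        assert len(tc) == 2 * k_total
        mrc = {r for r in abox.role_assertions if r[0] == MR_CONNECTION}
        assert len(mrc) == len(distinct_cells)
        # no self-connections are ever asserted
        assert all(s != o for p, s, o in abox.role_assertions
                   if p == MR_CONNECTION)

    def test_duplicate_parcel_ids_rejected(self, reference_tbox):
        parc = Parcellation("s1", (
            ParcelInfo(1, fma("Right_superior_frontal_gyrus"), "right"),
            ParcelInfo(1, fma("Right_superior_frontal_gyrus"), "right")))
        with pytest.raises(AnnotationError, match="duplicate"):
            annotate_subject(parc, Adjacency(), [], reference_tbox)

    def test_unknown_matrix_label_rejected(self, reference_tbox):
        parc, adjacency = _tiny_setup(reference_tbox)
        matrix = BinaryMatrix(("17",), ("nope",), np.array([[1.0]]))
        with pytest.raises(AnnotationError, match="nope"):
            annotate_subject(parc, adjacency, [matrix], reference_tbox)

    def test_route_names_number_across_matrices_row_major(self,
                                                          reference_tbox):
        parc, adjacency = _tiny_setup(reference_tbox)
        m1 = BinaryMatrix(("17", "20"), ("39", "brainstem"),
                          np.array([[0.0, 1.0], [1.0, 0.0]]))
        m2 = BinaryMatrix(("17",), ("39", "brainstem"),
                          np.array([[1.0, 0.0]]))
        abox = annotate_subject(parc, adjacency, [m1, m2], reference_tbox)
        routes = sorted(i.name for i, c in abox.type_assertions
                        if c == MR_ROUTE)
        assert routes == ["s1_mr_route_1", "s1_mr_route_2", "s1_mr_route_3"]
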