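import numpy as np
import pytest
from scipy import ndimage
from shapely.geometry import LineString

from carniplan import occupancy
from carniplan.occupancy import AJO, APJO, EMPTY

from conftest import make_class_map, records_frame


def square_map(n=10, code=2, cell_km=1.0):
    return make_class_map(np.full((n, n), code), cell_km)


class TestExtractFragments:
    def test_single_block(self):
        frags = occupancy.extract_fragments(square_map())
        assert len(frags) == 1
        assert frags[0].area_km2 == pytest.approx(100.0)
        assert frags[0].good_area_km2 == pytest.approx(100.0)

    def test_vertical_road_splits(self):
        cm = square_map()
        road = LineString([(5.5, -1), (5.5, 11)])
        frags = occupancy.extract_fragments(cm, [road])
        assert len(frags) == 2
        total = sum(f.area_km2 for f in frags)
        assert total == pytest.approx(100.0 - 10.0)  # one cell column removed

    def test_l_shape_diagonal_arms_split_under_4conn(self):
        # two arms touching only at a corner
        codes = np.zeros((4, 4), dtype=int)
        codes[0:2, 0:2] = 2
        codes[2:4, 2:4] = 2
        frags = occupancy.extract_fragments(make_class_map(codes))
        # oracle: scipy 4-connectivity labelling of the same mask
        _, n4 = ndimage.label(codes > 0, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        assert n4 == 2
        assert len(frags) == 2

    def test_empty_mask_empty_list(self):
        frags = occupancy.extract_fragments(square_map(code=0))
        assert frags == []

    def test_good_area_counts_medium_high_only(self):
        codes = np.array([[1, 2], [3, 1]])
        frags = occupancy.extract_fragments(make_class_map(codes))
        assert len(frags) == 1
        assert frags[0].area_km2 == pytest.approx(4.0)
        assert frags[0].good_area_km2 == pytest.approx(2.0)

    def test_size_class(self):
        frags = occupancy.extract_fragments(square_map(n=5))  # 25 km2
        assert frags[0].size_class == "<100"


class TestMedianOutsideDistance:
    def setup_method(self):
        self.frags = occupancy.extract_fragments(square_map(n=10))  # [0,10]^2

    def test_median_of_three(self):
        recs = records_frame([(11.0, 5.0), (11.7, 5.0), (13.0, 5.0)])
        assert occupancy.median_outside_distance(recs, self.frags) == pytest.approx(1.7)

    def test_single_outside_record(self):
        recs = records_frame([(12.4, 5.0)])
        assert occupancy.median_outside_distance(recs, self.frags) == pytest.approx(2.4)

    def test_inside_records_ignored(self):
        recs = records_frame([(5.0, 5.0), (2.0, 2.0), (13.0, 5.0)])
        assert occupancy.median_outside_distance(recs, self.frags) == pytest.approx(3.0)

    def test_no_outside_records_errors(self):
        recs = records_frame([(5.0, 5.0)])
        with pytest.raises(ValueError, match="radius"):
            occupancy.median_outside_distance(recs, self.frags)


def two_fragment_map(gap_cols):
    """Two 4x4 blocks separated by `gap_cols` empty columns."""
    codes = np.zeros((4, 8 + gap_cols), dtype=int)
    codes[:, :4] = 2
    codes[:, 4 + gap_cols:] = 2
    return make_class_map(codes)


class TestClassifyOccupancy:
    def test_interior_record_is_ajo(self):
        frags = occupancy.extract_fragments(square_map(5))
        labels = occupancy.classify_occupancy(frags, records_frame([(2.5, 2.5)]), 1.7)
        assert labels[0].label == AJO
        assert labels[0].supporting_record_ids == [0]

    def test_near_record_within_radius_is_ajo(self):
        frags = occupancy.extract_fragments(square_map(5))
        labels = occupancy.classify_occupancy(frags, records_frame([(6.0, 2.5)]), 1.7)
        assert labels[0].label == AJO

    def test_record_free_fragment_near_ajo_is_apjo(self):
        cm = two_fragment_map(gap_cols=1)  # 1 km gap
        frags = occupancy.extract_fragments(cm)
        recs = records_frame([(2.0, 2.0)])  # inside left block only
        labels = occupancy.classify_occupancy(frags, recs, 1.7)
        by_label = {l.fragment_id: l.label for l in labels}
        assert sorted(by_label.values()) == [AJO, APJO]

    def test_no_apjo_chaining(self):
        # three blocks in a row, 1 km gaps; record only in the leftmost.
        codes = np.zeros((4, 14), dtype=int)
        codes[:, 0:4] = 2
        codes[:, 5:9] = 2
        codes[:, 10:14] = 2
        frags = occupancy.extract_fragments(make_class_map(codes))
        recs = records_frame([(2.0, 2.0)])
        labels = occupancy.classify_occupancy(frags, recs, 1.7)
        # order fragments left to right
        ordered = [l for _, l in sorted(
            ((f.geometry.bounds[0], lab.label) for f, lab in zip(frags, labels))
        )]
        assert ordered == [AJO, APJO, EMPTY]

    def test_strict_inequality_at_radius(self):
        cm = two_fragment_map(gap_cols=2)  # 2 km gap
        frags = occupancy.extract_fragments(cm)
        recs = records_frame([(2.0, 2.0)])
        labels = occupancy.classify_occupancy(frags, recs, 2.0)
        by = {l.fragment_id: l.label for l in labels}
        assert sorted(by.values()) == [AJO, EMPTY]  # 2.0 < 2.0 is false

    def test_radius_zero_reduces_to_containment(self):
        cm = two_fragment_map(gap_cols=1)
        frags = occupancy.extract_fragments(cm)
        recs = records_frame([(2.0, 2.0), (4.2, 2.0)])  # one inside, one in the gap
        labels = occupancy.classify_occupancy(frags, recs, 0.0)
        by = {l.fragment_id: l.label for l in labels}
        assert sorted(by.values()) == [AJO, EMPTY]
        assert APJO not in by.values()

    def test_ajo_monotone_in_radius(self, rng):
        codes = (rng.random((20, 20)) < 0.35).astype(int) * 2
        frags = occupancy.extract_fragments(make_class_map(codes))
        recs = records_frame(list(zip(rng.uniform(0, 20, 8), rng.uniform(0, 20, 8))))
        prev = set()
        for radius in (0.0, 0.5, 1.5, 3.0, 8.0):
            labels = occupancy.classify_occupancy(frags, recs, radius)
            ajo = {l.fragment_id for l in labels if l.label == AJO}
            assert prev <= ajo
            prev = ajo

    def test_total_area_invariant_under_labeling(self, rng):
        codes = (rng.random((15, 15)) < 0.4).astype(int) * 2
        frags = occupancy.extract_fragments(make_class_map(codes))
        total = sum(f.area_km2 for f in frags)
        recs = records_frame([(7.0, 7.0)])
        for radius in (0.0, 2.0):
            labels = occupancy.classify_occupancy(frags, recs, radius)
            assert len(labels) == len(frags)
            assert sum(f.area_km2 for f in frags) == pytest.approx(total)


class TestOccupancySummary:
    def test_all_ajo_no_empty(self):
        frags = occupancy.extract_fragments(square_map(5))
        labels = occupancy.classify_occupancy(frags, records_frame([(2.0, 2.0)]), 1.0)
        table = occupancy.occupancy_summary(frags, labels)
        empties = table[table.label == EMPTY]
        assert (empties.n_fragments == 0).all()

    def test_counts_sum_to_fragment_count(self, rng):
        codes = (rng.random((20, 20)) < 0.3).astype(int) * 2
        frags = occupancy.extract_fragments(make_class_map(codes))
        recs = records_frame([(10.0, 10.0)])
        labels = occupancy.classify_occupancy(frags, recs, 2.0)
        table = occupancy.occupancy_summary(frags, labels)
        assert table.n_fragments.sum() == len(frags)
        assert table.area_km2.sum() == pytest.approx(sum(f.area_km2 for f in frags))

    def test_hand_enumerated_fixture(self):
        cm = two_fragment_map(gap_cols=1)  # two 16 km2 fragments
        frags = occupancy.extract_fragments(cm)
        labels = occupancy.classify_occupancy(frags, records_frame([(2.0, 2.0)]), 1.7)
        table = occupancy.occupancy_summary(frags, labels)
        small = table[table.size_class == "<100"].set_index("label")
        assert small.loc[AJO, "n_fragments"] == 1
        assert small.loc[APJO, "n_fragments"] == 1
        assert small.loc[AJO, "area_km2"] == pytest.approx(16.0)


class TestHabitatRatios:
    def test_simple_fractions(self):
        out = occupancy.habitat_ratios(
            {"marginal": 50.0, "medium": 30.0, "high": 20.0}, 25.0, 10.0
        )
        assert out["occupied_pct"] == 25.0
        assert out["potential_pct"] == 10.0
        assert out["empty_pct"] == 65.0

    def test_missing_class_errors(self):
        with pytest.raises(ValueError, match="missing"):
            occupancy.habitat_ratios({"marginal": 1.0}, 0.5, 0.1)


def test_rasterize_lines_marks_crossed_cells():
    cm = square_map(4)
    mask = occupancy.rasterize_lines(cm, [LineString([(0.5, 0.5), (3.5, 0.5)])])
    # bottom row (y in [0,1]) -> last array row
    assert mask[3, :].all()
    assert not mask[:3, :].any()
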