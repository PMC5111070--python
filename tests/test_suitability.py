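import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carniplan import suitability
from carniplan.raster import Raster

from conftest import make_raster, records_frame


class TestThinRecords:
    def test_one_per_cell(self):
        recs = records_frame([(1.0, 1.0), (2.0, 2.0)])  # same 12x12 cell
        out = suitability.thin_records(recs, 144.0, seed=0)
        assert len(out) == 1

    def test_distinct_cells_identity(self):
        recs = records_frame([(1.0, 1.0), (20.0, 1.0), (1.0, 20.0)])
        out = suitability.thin_records(recs, 144.0, seed=0)
        assert len(out) == 3

    def test_occupied_cell_count(self, rng):
        # 100 uniform records over a 24x24 extent -> 4 cells of side 12
        xs = rng.uniform(0, 24, 100)
        ys = rng.uniform(0, 24, 100)
        recs = records_frame(list(zip(xs, ys)))
        # oracle: number of occupied 12x12 cells
        occupied = len({(int(x // 12), int(y // 12)) for x, y in zip(xs, ys)})
        assert occupied == 4
        out = suitability.thin_records(recs, 144.0, seed=3)
        assert len(out) == 4

    def test_retained_record_is_member(self):
        recs = records_frame([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        out = suitability.thin_records(recs, 144.0, seed=5)
        assert out.iloc[0]["x_km"] in recs["x_km"].values

    def test_deterministic_per_seed(self, rng):
        recs = records_frame(list(zip(rng.uniform(0, 50, 40), rng.uniform(0, 50, 40))))
        a = suitability.thin_records(recs, 144.0, seed=9)
        b = suitability.thin_records(recs, 144.0, seed=9)
        assert a.equals(b)


class TestSplitTrainTest:
    def test_sizes(self, rng):
        recs = records_frame(list(zip(range(10), range(10))))
        splits = suitability.split_train_test(recs, 0.7, 1, rng)
        train, test = splits[0]
        assert len(train) == 7 and len(test) == 3

    def test_ten_replicates_each_partition(self, rng):
        recs = records_frame(list(zip(range(20), range(20))))
        splits = suitability.split_train_test(recs, 0.7, 10, rng)
        assert len(splits) == 10
        for train, test in splits:
            merged = sorted(list(train.x_km) + list(test.x_km))
            assert merged == sorted(recs.x_km)  # exact partition

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="at least 2"):
            suitability.split_train_test(records_frame([(0, 0)]), 0.7, 1, 0)

    def test_bootstrap_mode(self, rng):
        recs = records_frame(list(zip(range(30), range(30))))
        splits = suitability.split_train_test(recs, 0.7, 5, rng, mode="bootstrap")
        for train, test in splits:
            assert set(test.x_km).isdisjoint(set()) or True
            assert not set(test.x_km) & set(train.x_km)  # out-of-bag


class TestAuc:
    def test_perfect_separation(self):
        assert suitability.auc_presence_background([0.9, 0.8], [0.1, 0.6]) == 1.0

    def test_all_ties(self):
        assert suitability.auc_presence_background([0.5], [0.5]) == 0.5

    def test_enumerated_pairs(self):
        # pairs: .9>.5, .9>.1, .4<.5, .4>.1 -> 3/4
        assert suitability.auc_presence_background([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            suitability.auc_presence_background([], [0.5])

    @settings(max_examples=50, deadline=None)
    @given(
        pres=st.lists(st.floats(0.001, 0.999), min_size=1, max_size=20),
        back=st.lists(st.floats(0.001, 0.999), min_size=1, max_size=20),
    )
    def test_monotone_transform_invariance(self, pres, back):
        a1 = suitability.auc_presence_background(pres, back)
        f = lambda v: [x**3 + 2 * x for x in v]  # strictly increasing
        a2 = suitability.auc_presence_background(f(pres), f(back))
        assert a1 == pytest.approx(a2, abs=1e-12)


def brute_force_max_ss(pres, back):
    """Oracle: exhaustive scan over the same candidate set."""
    pres = np.asarray(pres)
    back = np.asarray(back)
    cands = suitability.candidate_thresholds(pres, back)
    best_t, best_v = None, -np.inf
    for t in cands:
        v = (pres >= t).mean() + (back < t).mean()
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t, best_v


class TestSelectThreshold:
    def test_clear_gap_returns_midpoint(self):
        t = suitability.select_threshold_max_ss([0.9, 0.8], [0.1, 0.2])
        assert t == 0.5  # midpoint of 0.2 and 0.8

    def test_degenerate_identical_sets(self):
        t = suitability.select_threshold_max_ss([0.5], [0.5])
        assert t == 0.0  # smallest candidate under a flat objective

    def test_seven_candidate_scan(self):
        pres, back = [0.9, 0.8, 0.4], [0.1, 0.2, 0.6]
        t = suitability.select_threshold_max_ss(pres, back)
        bt, bv = brute_force_max_ss(pres, back)
        assert t == bt
        v = (np.asarray(pres) >= t).mean() + (np.asarray(back) < t).mean()
        assert v == pytest.approx(bv)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_oracle_equivalence(self, data):
        pres = data.draw(st.lists(st.floats(0, 1), min_size=1, max_size=50))
        back = data.draw(st.lists(st.floats(0, 1), min_size=1, max_size=50))
        t = suitability.select_threshold_max_ss(pres, back)
        _, bv = brute_force_max_ss(pres, back)
        pres_a, back_a = np.asarray(pres), np.asarray(back)
        v = (pres_a >= t).mean() + (back_a < t).mean()
        # achieves the exhaustive-scan optimum ...
        assert v == pytest.approx(bv, abs=1e-9)
        # ... and no smaller candidate comes within the tie tolerance
        # (smallest-maximizer tie-break)
        for c in suitability.candidate_thresholds(pres_a, back_a):
            if c < t:
                vc = (pres_a >= c).mean() + (back_a < c).mean()
                assert vc < bv - 0.9e-9


class TestReclassify:
    def test_threshold_value_is_marginal(self):
        cm = suitability.reclassify(make_raster([[0.364]]), 0.364)
        assert cm.values[0, 0] == cm.MARGINAL

    def test_high_boundary(self):
        cm = suitability.reclassify(make_raster([[0.75, 1.0]]), 0.364)
        assert (cm.values == cm.HIGH).all()

    def test_uniform_medium_area(self, uniform_raster):
        cm = suitability.reclassify(uniform_raster, 0.364)
        areas = cm.class_areas_km2()
        assert areas["medium"] == pytest.approx(100.0)
        assert areas["unsuitable"] == areas["marginal"] == areas["high"] == 0.0

    def test_nodata_preserved(self):
        cm = suitability.reclassify(make_raster([[np.nan, 0.2]]), 0.364)
        assert cm.values[0, 0] == -1
        assert cm.values[0, 1] == cm.UNSUITABLE

    def test_area_conservation(self, rng):
        vals = rng.uniform(0, 1, (20, 20))
        vals[rng.random((20, 20)) < 0.2] = np.nan
        raster = make_raster(vals)
        cm = suitability.reclassify(raster, 0.364)
        total = sum(cm.class_areas_km2().values())
        assert total == pytest.approx(np.isfinite(vals).sum() * 1.0)

    def test_malformed_bounds(self):
        with pytest.raises(ValueError):
            suitability.reclassify(make_raster([[0.5]]), 0.6, bounds=(0.5, 0.75))


class TestEvaluate:
    def test_omission_zero_when_all_suitable(self, uniform_raster):
        recs = records_frame([(1.5, 1.5), (7.5, 2.5)])
        rep = suitability.evaluate(uniform_raster, recs, 0.5)
        assert rep.omission_rate == 0.0

    def test_binomial_closed_form(self):
        # 10 cells: half at 0.9, half at 0.1 -> suitable fraction 0.5 at t=0.5
        vals = np.array([[0.9] * 5 + [0.1] * 5])
        raster = Raster(vals, 1.0)
        # 9 records on suitable cells, 1 on an unsuitable cell
        recs = records_frame([(0.5, 0.5)] * 9 + [(7.5, 0.5)])
        rep = suitability.evaluate(raster, recs, 0.5)
        assert rep.omission_rate == pytest.approx(0.1)
        assert rep.binomial_p == pytest.approx(11 / 1024)

    def test_zero_threshold_zero_omission(self, uniform_raster, rng):
        recs = records_frame(list(zip(rng.uniform(0, 10, 20), rng.uniform(0, 10, 20))))
        rep = suitability.evaluate(uniform_raster, recs, 0.0)
        assert rep.omission_rate == 0.0

    def test_off_raster_records_error(self, uniform_raster):
        recs = records_frame([(1.0, 1.0), (99.0, 1.0)])
        with pytest.raises(ValueError, match="indices \\[1\\]"):
            suitability.evaluate(uniform_raster, recs, 0.5)

    def test_omission_monotone_in_threshold(self, rng):
        vals = rng.uniform(0, 1, (15, 15))
        raster = make_raster(vals)
        recs = records_frame(list(zip(rng.uniform(0, 15, 30), rng.uniform(0, 15, 30))))
        omis = [
            suitability.evaluate(raster, recs, t).omission_rate
            for t in np.linspace(0, 1, 11)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(omis, omis[1:]))


def test_cross_validate_keys(rng):
    vals = rng.uniform(0, 1, (30, 30))
    raster = make_raster(vals)
    recs = records_frame(list(zip(rng.uniform(0, 30, 60), rng.uniform(0, 30, 60))))
    out = suitability.cross_validate(raster, recs, n_replicates=4, n_background=500, seed=1)
    assert set(out) >= {"auc", "auc_sd", "threshold", "omission_rate", "binomial_p"}
    assert 0 <= out["auc"] <= 1
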