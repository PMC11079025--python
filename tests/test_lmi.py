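import itertools

import numpy as np
import pytest

from landmdi.criticality import CriticalMask
from landmdi.grid import MASK_NODATA, LandMask, ZonePartition
from landmdi.lmi import (
    LMIGrid,
    classify_lmi,
    compute_lmi,
    lmi_histogram,
    natural_breaks,
    zonal_stats,
)

from conftest import make_grid


def binary_masks(arrays):
    return [
        CriticalMask(make_grid(a.astype(np.uint8), nodata=MASK_NODATA), pid)
        for a, pid in zip(
            arrays,
            ["WaE", "WiE", "SOCL", "SS", "SA", "SC", "SNI", "SPP", "SPHM", "VD", "GD", "A"],
        )
    ]


def full_land(shape):
    codes = make_grid(np.full(shape, 211, dtype=np.int32))
    return LandMask(codes, agricultural_codes={211, 231}, arable_codes={211})


class TestComputeLMI:
    def test_simple_sum(self):
        masks = binary_masks([np.array([[1]]), np.array([[0]]), np.array([[1]]), np.array([[1]])])
        lmi = compute_lmi(masks, full_land((1, 1)))
        assert lmi.values[0, 0] == 3

    def test_all_zero(self):
        masks = binary_masks([np.zeros((3, 3))] * 12)
        lmi = compute_lmi(masks, full_land((3, 3)))
        assert (lmi.values == 0).all()

    def test_random_stack_equals_loop_oracle(self, rng):
        arrays = [rng.integers(0, 2, (32, 32)) for _ in range(12)]
        lmi = compute_lmi(binary_masks(arrays), full_land((32, 32)))
        for r in range(32):
            for c in range(32):
                assert lmi.values[r, c] == sum(a[r, c] for a in arrays)

    def test_outside_stratum_nodata(self):
        codes = make_grid(np.array([[211, 312]], dtype=np.int32))
        land = LandMask(codes, agricultural_codes={211}, arable_codes={211})
        masks = binary_masks([np.ones((1, 2))] * 3)
        lmi = compute_lmi(masks, land)
        assert lmi.values[0, 0] == 3
        assert lmi.values[0, 1] == MASK_NODATA

    def test_nodata_layer_reduces_availability(self):
        a = np.ones((1, 1), dtype=np.uint8)
        b = np.full((1, 1), MASK_NODATA, dtype=np.uint8)
        masks = binary_masks([a, b, a])
        lmi = compute_lmi(masks, full_land((1, 1)))
        assert lmi.values[0, 0] == 2
        assert lmi.n_available.values[0, 0] == 2

    def test_zero_masks_rejected(self):
        with pytest.raises(ValueError):
            compute_lmi([], full_land((2, 2)))

    def test_adding_zero_mask_is_identity(self, rng):
        arrays = [rng.integers(0, 2, (8, 8)) for _ in range(5)]
        base = compute_lmi(binary_masks(arrays), full_land((8, 8)))
        extended = compute_lmi(
            binary_masks(arrays + [np.zeros((8, 8))]), full_land((8, 8))
        )
        np.testing.assert_array_equal(base.values, extended.values)


class TestClassify:
    @pytest.mark.parametrize("count,expected", [(0, 0), (1, 1), (4, 4), (5, 5), (7, 5)])
    def test_binning(self, count, expected):
        lmi = LMIGrid(
            counts=make_grid(np.array([[count]], dtype=np.uint8), nodata=MASK_NODATA),
            n_available=make_grid(np.array([[12]], dtype=np.uint8), nodata=MASK_NODATA),
        )
        assert classify_lmi(lmi).values[0, 0] == expected

    def test_nodata_passthrough(self):
        lmi = LMIGrid(
            counts=make_grid(np.array([[MASK_NODATA]], dtype=np.uint8), nodata=MASK_NODATA),
            n_available=make_grid(np.array([[12]], dtype=np.uint8), nodata=MASK_NODATA),
        )
        assert classify_lmi(lmi).values[0, 0] == MASK_NODATA


class TestZonal:
    def make_zone_setup(self, class_values, zone_values):
        counts = make_grid(np.asarray(class_values, dtype=np.uint8), nodata=MASK_NODATA)
        lmi = LMIGrid(counts=counts, n_available=counts.with_values(
            np.full(counts.shape, 12, dtype=np.uint8)))
        classes = classify_lmi(lmi)
        zones = ZonePartition(
            zones=make_grid(np.asarray(zone_values, dtype=np.int32)),
            completeness={int(z): 12 for z in np.unique(zone_values)},
        )
        return classes, lmi, zones, full_land(counts.shape)

    def test_single_zone_uniform(self):
        classes, lmi, zones, land = self.make_zone_setup(
            np.full((10, 10), 2), np.ones((10, 10))
        )
        report = zonal_stats(classes, lmi, zones, land)
        row = report[(report.zone == 1) & (report.lmi_class == 2)].iloc[0]
        assert row.percent == pytest.approx(100.0)
        assert row.mean_processes == pytest.approx(2.0)

    def test_two_zone_weighted_mean(self):
        class_values = np.concatenate(
            [np.full((5, 10), 1), np.full((5, 10), 3)]
        )
        zone_values = np.concatenate([np.full((5, 10), 1), np.full((5, 10), 2)])
        classes, lmi, zones, land = self.make_zone_setup(class_values, zone_values)
        report = zonal_stats(classes, lmi, zones, land)
        agg = report[report.zone == "ALL"].iloc[0]
        assert agg.mean_processes == pytest.approx(2.0)

    def test_conservation(self, rng):
        class_values = rng.integers(0, 8, (20, 20))
        zone_values = rng.integers(1, 4, (20, 20))
        classes, lmi, zones, land = self.make_zone_setup(class_values, zone_values)
        report = zonal_stats(classes, lmi, zones, land)
        for zone in report.zone.unique():
            sub = report[report.zone == zone]
            assert sub.area_km2.sum() == pytest.approx(sub.stratum_area_km2.iloc[0])
            assert sub.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_zone_no_division_error(self):
        codes = make_grid(np.array([[211, 312], [211, 312]], dtype=np.int32))
        land = LandMask(codes, agricultural_codes={211}, arable_codes={211})
        counts = make_grid(np.array([[1, MASK_NODATA], [2, MASK_NODATA]], dtype=np.uint8),
                           nodata=MASK_NODATA)
        lmi = LMIGrid(counts=counts, n_available=counts.with_values(
            np.full((2, 2), 12, dtype=np.uint8)))
        zones = ZonePartition(
            zones=make_grid(np.array([[1, 2], [1, 2]], dtype=np.int32)),
            completeness={1: 12, 2: 12},
        )
        report = zonal_stats(classify_lmi(lmi), lmi, zones, land)
        z2 = report[report.zone == 2]
        assert (z2.area_km2 == 0).all()
        assert (z2.percent == 0).all()

    def test_incomplete_zone_excluded_from_complete_row(self):
        classes, lmi, zones, land = self.make_zone_setup(
            np.full((4, 4), 1), np.concatenate([np.full((2, 4), 1), np.full((2, 4), 2)])
        )
        zones.completeness[2] = 9
        report = zonal_stats(classes, lmi, zones, land)
        complete = report[report.zone == "COMPLETE"]
        assert complete.stratum_area_km2.iloc[0] == pytest.approx(8 * 0.25)
        assert not report[report.zone == 2].complete_data.any()


class TestHistogram:
    def test_single_spike(self):
        counts = make_grid(np.full((6, 6), 2, dtype=np.uint8), nodata=MASK_NODATA)
        lmi = LMIGrid(counts=counts, n_available=counts)
        hist = lmi_histogram(lmi)
        assert hist.pixels.sum() == 36
        assert hist.loc[hist.lmi_value == 2, "pixels"].iloc[0] == 36
        assert hist.share_nonzero_in_1_5.iloc[0] == 1.0

    def test_tally_oracle(self, rng):
        values = rng.integers(0, 9, (16, 16)).astype(np.uint8)
        counts = make_grid(values, nodata=MASK_NODATA)
        lmi = LMIGrid(counts=counts, n_available=counts)
        hist = lmi_histogram(lmi)
        for v in range(9):
            assert hist.loc[hist.lmi_value == v, "pixels"].iloc[0] == (values == v).sum()
        assert hist.pixels.sum() == 256


def jenks_oracle(values, k):
    """Exhaustive search over all contiguous partitions of the sorted sample."""
    x = sorted(values)
    n = len(x)
    best, best_breaks = None, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        sse = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = x[a:b]
            mu = sum(seg) / len(seg)
            sse += sum((v - mu) ** 2 for v in seg)
        if best is None or sse < best - 1e-12:
            best = sse
            best_breaks = [x[c - 1] for c in cuts]
    return best, best_breaks


def partition_sse(values, breaks):
    x = sorted(values)
    groups = []
    start = 0
    for b in breaks:
        end = max(i for i, v in enumerate(x) if v <= b) + 1
        groups.append(x[start:end])
        start = end
    groups.append(x[start:])
    sse = 0.0
    for seg in groups:
        mu = sum(seg) / len(seg)
        sse += sum((v - mu) ** 2 for v in seg)
    return sse


class TestNaturalBreaks:
    def test_separated_clusters(self):
        breaks = natural_breaks([1, 1, 1, 9, 9, 9], 2)
        assert breaks == [1]

    def test_k_equals_distinct_count(self):
        breaks = natural_breaks([1, 2, 5], 3)
        assert breaks == [1, 2]

    def test_matches_exhaustive_partition_minimum(self, rng):
        values = rng.uniform(0, 100, 12).tolist()
        breaks = natural_breaks(values, 3)
        best_sse, _ = jenks_oracle(values, 3)
        assert partition_sse(values, breaks) == pytest.approx(best_sse)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            natural_breaks([1, 1, 2], 3)
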