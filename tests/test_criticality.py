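import numpy as np
import pytest

from landmdi.criticality import (
    METAL_THRESHOLDS,
    PROCESS_ORDER,
    build_critical_stack,
    classify_class_membership,
    classify_heavy_metals,
    classify_nutrient_imbalance,
    classify_simple_threshold,
    classify_trend_process,
    compute_aridity,
    default_registry,
    registry_thresholds,
    risk_score_to_class,
)
from landmdi.grid import MASK_NODATA

from conftest import make_grid


@pytest.fixture
def registry():
    return default_registry()


class TestSimpleThreshold:
    def test_erosion_above_threshold(self, registry):
        g = make_grid(np.array([[3.5]]))
        assert classify_simple_threshold(g, registry["WaE"]).values[0, 0] == 1

    def test_ph_boundary_is_noncritical(self, registry):
        g = make_grid(np.array([[5.5]]))
        assert classify_simple_threshold(g, registry["SA"]).values[0, 0] == 0

    def test_random_grid_equals_loop_oracle(self, registry, rng):
        g = make_grid(rng.uniform(0, 5, (16, 16)))
        out = classify_simple_threshold(g, registry["WaE"]).values
        for r in range(16):
            for c in range(16):
                assert out[r, c] == (1 if g.values[r, c] > 2.0 else 0)

    def test_monotone_in_raw_value(self, registry, rng):
        # for a "greater" rule, increasing a value never flips 1 -> 0
        g = make_grid(rng.uniform(0, 5, (8, 8)))
        before = classify_simple_threshold(g, registry["WaE"]).values.copy()
        bumped = make_grid(g.values + rng.uniform(0, 3, (8, 8)))
        after = classify_simple_threshold(bumped, registry["WaE"]).values
        assert not ((before == 1) & (after == 0)).any()


class TestClassMembership:
    def test_very_high_critical(self):
        g = make_grid(np.array([[4]], dtype=np.uint8), nodata=255)
        assert classify_class_membership(g, {3, 4}).values[0, 0] == 1

    def test_moderate_noncritical(self):
        g = make_grid(np.array([[2]], dtype=np.uint8), nodata=255)
        assert classify_class_membership(g, {3, 4}).values[0, 0] == 0

    def test_unknown_code_rejected(self):
        g = make_grid(np.array([[9]], dtype=np.uint8), nodata=255)
        with pytest.raises(ValueError, match="unknown class code"):
            classify_class_membership(g, {3, 4})

    def test_risk_score_3_2_maps_to_high_and_critical(self):
        # high risk class is 3 < RS <= 4
        rs = make_grid(np.array([[3.2]]))
        codes = risk_score_to_class(rs)
        assert codes.values[0, 0] == 3
        assert classify_class_membership(codes, {3, 4}).values[0, 0] == 1

    def test_risk_score_exactly_3_not_high(self):
        codes = risk_score_to_class(make_grid(np.array([[3.0]])))
        assert codes.values[0, 0] == 2


class TestNutrients:
    def make(self, ns, nue, pa, pb):
        mk = lambda v: make_grid(np.array([[float(v)]]))
        return classify_nutrient_imbalance(mk(ns), mk(nue), mk(pa), mk(pb))

    def test_n_surplus(self):
        mask, sub = self.make(80, 0.5, 30, 5)
        assert mask.values[0, 0] == 1
        assert sub["n_surplus"].values[0, 0] == 1

    def test_n_deficit_via_nue(self):
        mask, sub = self.make(10, 0.95, 30, 5)
        assert mask.values[0, 0] == 1
        assert sub["n_deficit"].values[0, 0] == 1

    def test_all_fine(self):
        mask, _ = self.make(40, 0.8, 30, 5)
        assert mask.values[0, 0] == 0

    def test_p_surplus_needs_positive_budget(self):
        assert self.make(10, 0.5, 60, 5)[0].values[0, 0] == 1
        assert self.make(10, 0.5, 60, -5)[0].values[0, 0] == 0

    def test_p_deficit_needs_negative_budget(self):
        assert self.make(10, 0.5, 20, -5)[0].values[0, 0] == 1
        assert self.make(10, 0.5, 20, 5)[0].values[0, 0] == 0

    def test_union_of_subconditions(self, rng):
        mk = lambda a: make_grid(a)
        ns = rng.uniform(0, 100, (12, 12))
        nue = rng.uniform(0, 1.2, (12, 12))
        pa = rng.uniform(0, 100, (12, 12))
        pb = rng.uniform(-10, 10, (12, 12))
        mask, sub = classify_nutrient_imbalance(mk(ns), mk(nue), mk(pa), mk(pb))
        union = np.zeros((12, 12), dtype=bool)
        for m in sub.values():
            union |= m.values == 1
        np.testing.assert_array_equal(mask.values == 1, union)

    def test_negative_nue_rejected(self):
        with pytest.raises(ValueError, match="NUE"):
            self.make(10, -0.5, 30, 5)


class TestHeavyMetals:
    def constant_metals(self, overrides=None):
        overrides = overrides or {}
        return {
            m: make_grid(np.full((2, 2), overrides.get(m, t * 0.5)))
            for m, t in METAL_THRESHOLDS.items()
        }

    def test_all_below(self):
        mask = classify_heavy_metals(self.constant_metals())
        assert (mask.values == 0).all()

    def test_single_cd_exceedance(self):
        mask = classify_heavy_metals(self.constant_metals({"Cd": 1.5}))
        assert (mask.values == 1).all()

    def test_union_equals_per_pixel_or_oracle(self, rng):
        metals = {
            m: make_grid(rng.uniform(0, 2 * t, (16, 16)))
            for m, t in METAL_THRESHOLDS.items()
        }
        out = classify_heavy_metals(metals).values
        for r in range(16):
            for c in range(16):
                expected = any(
                    metals[m].values[r, c] > t for m, t in METAL_THRESHOLDS.items()
                )
                assert out[r, c] == int(expected)

    def test_missing_metal_rejected(self):
        metals = self.constant_metals()
        del metals["Hg"]
        with pytest.raises(ValueError, match="missing metal"):
            classify_heavy_metals(metals)
        classify_heavy_metals(metals, allow_subset=True)  # explicit opt-in

    def test_nodata_policy(self):
        # an exceedance certifies critical even with other metals missing;
        # all-below with gaps cannot certify non-critical
        metals = self.constant_metals({"Cd": 1.5})
        hg = np.full((2, 2), -1.0)
        metals["Hg"] = make_grid(hg, nodata=-1.0)
        assert (classify_heavy_metals(metals).values == 1).all()
        metals_low = self.constant_metals()
        metals_low["Hg"] = make_grid(hg, nodata=-1.0)
        assert (classify_heavy_metals(metals_low).values == MASK_NODATA).all()


class TestAridity:
    def run(self, p, pet):
        return compute_aridity(
            make_grid(np.array([[float(p)]])), make_grid(np.array([[float(pet)]]))
        )

    def test_semi_arid_critical(self):
        ai, cls, mask = self.run(300, 1000)
        assert ai.values[0, 0] == pytest.approx(0.3)
        assert cls.values[0, 0] == 2  # semi-arid
        assert mask.values[0, 0] == 1

    def test_boundary_065_noncritical(self):
        _, cls, mask = self.run(650, 1000)
        assert cls.values[0, 0] == 0  # humid
        assert mask.values[0, 0] == 0

    def test_hyper_arid_excluded(self):
        _, cls, mask = self.run(20, 1000)
        assert cls.values[0, 0] == 4  # hyper-arid
        assert mask.values[0, 0] == 0

    def test_nonpositive_pet_nodata(self):
        _, _, mask = self.run(300, 0)
        assert mask.values[0, 0] == MASK_NODATA

    @pytest.mark.parametrize(
        "ai,expected_class", [(0.7, 0), (0.6, 1), (0.3, 2), (0.1, 3), (0.02, 4)]
    )
    def test_class_bounds(self, ai, expected_class):
        _, cls, _ = self.run(ai * 1000, 1000)
        assert cls.values[0, 0] == expected_class


class TestTrendRule:
    def run(self, slope, p):
        return classify_trend_process(
            make_grid(np.array([[slope]])),
            make_grid(np.array([[p]])),
            slope_threshold=-0.001,
        )

    def test_significant_decline(self):
        assert self.run(-0.002, 0.04).values[0, 0] == 1

    def test_not_significant(self):
        assert self.run(-0.002, 0.2).values[0, 0] == 0

    def test_slope_above_threshold(self):
        assert self.run(-0.0005, 0.01).values[0, 0] == 0

    def test_p_boundary_non_strict(self):
        assert self.run(-0.002, 0.1).values[0, 0] == 1

    def test_positive_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_trend_process(
                make_grid(np.zeros((1, 1))), make_grid(np.ones((1, 1))), 0.001
            )


class TestStack:
    def test_full_scenario_recovers_ground_truth(self, classified_scenario):
        _, _, _, masks, _, truth = classified_scenario
        assert [m.process_id for m in masks] == list(PROCESS_ORDER)
        for m in masks:
            np.testing.assert_array_equal(
                m.mask.values, truth.masks[m.process_id].values
            )

    def test_withheld_layers_reported(self, small_scenario):
        from landmdi.pipeline import prepare_classification_inputs

        _, _, _, inputs, _ = small_scenario
        classify_inputs, _ = prepare_classification_inputs(inputs)
        for pid in ("WiE", "SS", "GD"):
            classify_inputs.pop(pid)
        masks, missing = build_critical_stack(classify_inputs)
        assert len(masks) == 9
        assert missing == ["WiE", "SS", "GD"]

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_critical_stack({})

    def test_registry_has_26_scalar_cutoffs(self):
        assert len(registry_thresholds()) == 26
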