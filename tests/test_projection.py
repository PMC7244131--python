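import math

import numpy as np
import pytest

from conftest import OPTIMAL_VALUES, make_stack
from cropsuit.errors import AlignmentError, InputError, UndefinedStatisticError
from cropsuit.projection import (
    AreaTable,
    BIN_LABELS,
    ScenarioEnsemble,
    bin_areas,
    change_map,
    crosstab_categorical,
    ensemble_suitability,
    mean_suitability,
    percent_change,
    round_scores,
)
from cropsuit.raster import (
    GEOGRAPHIC,
    GridLayer,
    GridTransform,
    NODATA,
    cell_areas,
    suitability_map,
)

# Printed current/RCP4.5/RCP8.5 per-bin areas (million km²) used as fixtures.
CURRENT_BINS = [2.59, 2.11, 1.97, 1.83, 2.03, 3.27, 1.64, 1.42, 1.63, 4.25, 12.50]
RCP45_BINS = [3.53, 4.68, 3.62, 2.90, 2.50, 3.74, 1.90, 1.96, 2.12, 5.25, 12.94]
RCP85_BINS = [9.35, 10.38, 6.20, 5.28, 4.62, 5.17, 3.16, 2.93, 4.17, 6.22, 13.59]


def suit_layer(values, cell=1000.0, crs_kind="projected"):
    values = np.asarray(values, dtype=float)
    t = GridTransform(0.0, values.shape[0] * cell, cell, cell)
    return GridLayer(values=values, transform=t, crs_kind=crs_kind, criterion="suitability")


def member_from(stack, dtemp=0.0, rain_mult=1.0):
    temp = stack["temperature"]
    rain = stack["rainfall"]
    return stack.with_layers(
        temperature=temp.grid_like(temp.values + dtemp),
        rainfall=rain.grid_like(rain.values * rain_mult),
    )


class TestEnsembleSuitability:
    def test_identical_members_equal_single_map(self, optimal_values, final_profile):
        stack = make_stack(optimal_values, shape=(4, 4))
        ens = ScenarioEnsemble("x", [member_from(stack)] * 3, stack)
        out = ensemble_suitability(ens, final_profile)
        single = suitability_map(stack, final_profile)
        np.testing.assert_array_equal(out.values, single.values)

    def test_two_members_average(self, optimal_values, final_profile):
        stack = make_stack(optimal_values, shape=(2, 2))
        # rainfall 1125 -> 50; optimal -> 100; mixed with a 30-score member
        m1 = member_from(stack)
        m1["rainfall"].values[:] = 1125.0  # score 40... compute: (1125-750)/750*100 = 50
        m2 = member_from(stack)
        ens = ScenarioEnsemble("x", [m1, m2], stack)
        out = ensemble_suitability(ens, final_profile)
        np.testing.assert_allclose(out.values, 75.0)

    def test_single_suitable_member_marginal_mean(self, optimal_values, final_profile):
        stack = make_stack(optimal_values, shape=(2, 2))
        members = [member_from(stack, dtemp=-20.0) for _ in range(16)]  # all score 0
        members.append(member_from(stack))  # the one suitable member
        ens = ScenarioEnsemble("x", members, stack)
        out = ensemble_suitability(ens, final_profile)
        assert np.all(out.values > 0.0)
        assert np.all(out.values <= 100.0 / 17.0 + 1e-12)

    def test_mean_within_member_envelope(self, final_profile):
        rng = np.random.default_rng(4)
        from conftest import random_env_arrays

        stack = make_stack(random_env_arrays(rng, (8, 8)), shape=(8, 8))
        members = [
            member_from(stack, dtemp=rng.normal(0, 3), rain_mult=rng.uniform(0.7, 1.3))
            for _ in range(5)
        ]
        ens = ScenarioEnsemble("x", members, stack)
        out = ensemble_suitability(ens, final_profile)
        per_member = np.stack(
            [
                suitability_map(
                    stack.with_layers(temperature=m["temperature"], rainfall=m["rainfall"]),
                    final_profile,
                ).values
                for m in members
            ]
        )
        assert np.all(out.values >= per_member.min(axis=0) - 1e-9)
        assert np.all(out.values <= per_member.max(axis=0) + 1e-9)

    def test_member_nodata_propagates(self, optimal_values, final_profile):
        stack = make_stack(optimal_values, shape=(2, 2))
        m1 = member_from(stack)
        m1["temperature"].values[0, 0] = math.nan
        ens = ScenarioEnsemble("x", [m1, member_from(stack)], stack)
        out = ensemble_suitability(ens, final_profile)
        assert out.mask[0, 0] and not out.mask[1, 1]

    def test_zero_members_rejected(self, optimal_stack):
        with pytest.raises(InputError):
            ScenarioEnsemble("x", [], optimal_stack)

    def test_member_missing_rainfall_rejected(self, optimal_values):
        stack = make_stack(optimal_values, shape=(2, 2))
        from cropsuit.raster import LayerStack

        with pytest.raises(InputError, match="rainfall"):
            ScenarioEnsemble("x", [LayerStack({"temperature": stack["temperature"]})], stack)


class TestChangeMap:
    def test_no_change(self):
        a = suit_layer(np.full((4, 4), 80.0))
        summary = change_map(a, a)
        assert summary.unchanged_fraction == 1.0
        assert summary.minimal_fraction == 0.0

    def test_uniform_small_shift(self):
        base = suit_layer(np.full((4, 4), 80.0))
        fut = suit_layer(np.full((4, 4), 85.0))
        summary = change_map(fut, base)
        assert summary.unchanged_fraction == 0.0
        assert summary.minimal_fraction == 1.0

    def test_single_changed_pixel_counts(self):
        base = suit_layer(np.full((5, 5), 50.0))
        vals = np.full((5, 5), 50.0)
        vals[0, 0] = 70.0
        summary = change_map(suit_layer(vals), base)
        assert summary.unchanged_fraction == pytest.approx(24 / 25)
        assert summary.minimal_fraction == 0.0

    def test_delta_values_and_nodata(self):
        base_vals = np.full((3, 3), 40.0)
        fut_vals = np.full((3, 3), 55.0)
        base_vals[1, 1] = NODATA
        summary = change_map(suit_layer(fut_vals), suit_layer(base_vals))
        assert summary.delta.values[0, 0] == 15.0
        assert summary.delta.mask[1, 1]
        # union denominator counts the one-sided pixel as changed
        assert summary.unchanged_fraction_union < summary.unchanged_fraction or (
            summary.unchanged_fraction == 0.0
        )
        assert summary.valid_area_km2 == pytest.approx(8.0)

    def test_union_vs_intersection_denominators(self):
        base_vals = np.full((2, 2), 50.0)
        fut_vals = np.full((2, 2), 50.0)
        base_vals[0, 0] = NODATA
        summary = change_map(suit_layer(fut_vals), suit_layer(base_vals))
        assert summary.unchanged_fraction == 1.0
        assert summary.unchanged_fraction_union == pytest.approx(3 / 4)

    def test_misaligned_rejected(self):
        a = suit_layer(np.full((4, 4), 80.0))
        b = suit_layer(np.full((4, 5), 80.0))
        with pytest.raises(AlignmentError):
            change_map(a, b)


class TestBinAreas:
    def test_uniform_95(self):
        layer = suit_layer(np.full((10, 10), 95.0))  # 1 km² cells
        table = bin_areas(layer)
        assert table.bins["91-100"] == pytest.approx(100 / 1e6)
        assert table.total == pytest.approx(100 / 1e6)

    def test_sub_one_excluded_from_total(self):
        layer = suit_layer(np.full((10, 10), 0.4))
        table = bin_areas(layer)
        assert table.bins["<1"] == pytest.approx(100 / 1e6)
        assert table.total == 0.0

    def test_rounding_to_bin_edges(self):
        # 0.5 rounds to 1 (1-10 bin); 10.4 rounds to 10 (1-10); 10.5 rounds to 11.
        layer = suit_layer(np.array([[0.4, 0.5], [10.4, 10.5]]))
        table = bin_areas(layer)
        assert table.bins["<1"] == pytest.approx(1 / 1e6)
        assert table.bins["1-10"] == pytest.approx(2 / 1e6)
        assert table.bins["11-20"] == pytest.approx(1 / 1e6)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bin_areas(suit_layer(np.array([[101.0]])))

    def test_groups_sum_their_bins(self):
        table = AreaTable.from_bin_values(CURRENT_BINS)
        g = table.groups
        assert g["<1 TO 30"] == pytest.approx(sum(CURRENT_BINS[:4]))
        assert g["31 TO 70"] == pytest.approx(sum(CURRENT_BINS[4:8]))
        assert g["71 TO 100"] == pytest.approx(sum(CURRENT_BINS[8:]))
        assert sum(g.values()) == pytest.approx(sum(CURRENT_BINS))
        assert table.total == pytest.approx(sum(CURRENT_BINS) - CURRENT_BINS[0])

    def test_conservation_partition_of_valid_area(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 100, (30, 30))
        vals[rng.random((30, 30)) < 0.1] = NODATA
        layer = suit_layer(vals)
        table = bin_areas(layer)
        valid_area = cell_areas(layer)[~layer.mask].sum() / 1e6
        assert sum(table.bins.values()) == pytest.approx(valid_area)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0, 100, (6, 6))
        t1 = bin_areas(suit_layer(vals))
        t2 = bin_areas(suit_layer(np.sort(vals.ravel()).reshape(6, 6)))
        for b in BIN_LABELS:
            assert t1.bins[b] == pytest.approx(t2.bins[b])

    def test_resolution_doubling_conserves_area(self):
        vals = np.full((4, 4), 55.0)
        coarse = bin_areas(suit_layer(vals, cell=1000.0))
        fine = bin_areas(suit_layer(np.full((8, 8), 55.0), cell=500.0))
        assert coarse.total == pytest.approx(fine.total)

    def test_round_scores_half_away_from_zero(self):
        np.testing.assert_array_equal(round_scores(np.array([0.5, 1.5, 2.5])), [1, 2, 3])


class TestPercentChange:
    def test_published_totals(self):
        cur = AreaTable.from_bin_values(CURRENT_BINS)
        r45 = AreaTable.from_bin_values(RCP45_BINS)
        r85 = AreaTable.from_bin_values(RCP85_BINS)
        assert percent_change(r45, cur)["total"]["rounded"] == 27
        assert percent_change(r85, cur)["total"]["rounded"] == 89

    def test_published_high_group(self):
        cur = AreaTable.from_bin_values(CURRENT_BINS)
        r85 = AreaTable.from_bin_values(RCP85_BINS)
        # 18.38 -> 23.97 is +30%
        assert percent_change(r85, cur)["high"]["rounded"] == 30

    def test_identical_tables_zero(self):
        cur = AreaTable.from_bin_values(CURRENT_BINS)
        out = percent_change(cur, cur)
        assert all(v["rounded"] == 0 for v in out.values())

    def test_zero_baseline_undefined(self):
        zero = AreaTable.from_bin_values([0.0] * 11)
        out = percent_change(AreaTable.from_bin_values(CURRENT_BINS), zero)
        assert out["total"]["rounded"] is None
        assert math.isnan(out["total"]["percent"])


class TestMeanSuitability:
    def test_uniform(self):
        assert mean_suitability(suit_layer(np.full((3, 3), 80.0))) == pytest.approx(80.0)

    def test_equal_area_halves(self):
        assert mean_suitability(suit_layer(np.array([[0.0, 100.0]]))) == pytest.approx(50.0)

    def test_geographic_area_weighting_matches_oracle(self):
        # Toy geographic grid: brute-force equal-area oracle via per-cell areas.
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 100, (18, 36))
        t = GridTransform(-180, 90, 10.0, 10.0)
        layer = GridLayer(vals, t, crs_kind=GEOGRAPHIC, criterion="suitability")
        areas = cell_areas(layer)
        oracle = (vals * areas).sum() / areas.sum()
        assert mean_suitability(layer) == pytest.approx(oracle)
        # And it differs from the naive unweighted mean (poles weigh less).
        assert abs(mean_suitability(layer) - vals.mean()) > 1e-9

    def test_no_valid_pixels_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            mean_suitability(suit_layer(np.full((2, 2), NODATA)))


class TestCrosstab:
    def test_all_best_high_scores(self):
        ref = suit_layer(np.full((4, 4), 2.0))
        suit = suit_layer(np.full((4, 4), 95.0))
        table = crosstab_categorical(ref, suit)
        row = table[table["class"] == 2].iloc[0]
        assert row["mean_suitability"] == pytest.approx(95.0)
        assert row["fraction_ge_90"] == pytest.approx(1.0)
        assert row["area_km2"] == pytest.approx(16.0)

    def test_classes_partition_area(self):
        rng = np.random.default_rng(6)
        ref = suit_layer(rng.integers(0, 3, (10, 10)).astype(float))
        suit = suit_layer(rng.uniform(0, 100, (10, 10)))
        table = crosstab_categorical(ref, suit)
        assert table["area_km2"].sum() == pytest.approx(100.0)

    def test_matches_pixel_count_oracle(self):
        rng = np.random.default_rng(13)
        ref_vals = rng.integers(0, 3, (12, 12)).astype(float)
        suit_vals = rng.uniform(0, 100, (12, 12))
        table = crosstab_categorical(suit_layer(ref_vals), suit_layer(suit_vals))
        for cls in (0, 1, 2):
            sel = ref_vals == cls
            row = table[table["class"] == cls].iloc[0]
            assert row["area_km2"] == pytest.approx(sel.sum() * 1.0)
            if sel.any():
                assert row["mean_suitability"] == pytest.approx(suit_vals[sel].mean())
                assert row["fraction_ge_90"] == pytest.approx(
                    (suit_vals[sel] >= 90).sum() / sel.sum()
                )

    def test_invalid_class_rejected(self):
        ref = suit_layer(np.array([[0.0, 3.0]]))
        suit = suit_layer(np.array([[50.0, 50.0]]))
        with pytest.raises(InputError):
            crosstab_categorical(ref, suit)
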