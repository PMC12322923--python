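"""Pattern classification, dominance ratios, ratings, sweeps, tabulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vdmap import (
    DominanceCategory,
    SupplyFractionRecord,
    ThresholdPair,
    build_sweep_grid,
    classify_pattern,
    dominance_ratios,
    frequency_table,
    interrater_correlation,
    rate_dominance,
    sweep_agreement,
)
from vdmap.patterns import VesselPattern, agreement_score


def record(**named):
    """Fraction record from vessel-name keyword arguments."""
    ids = {"peri": 1, "callo": 2, "pre": 3, "central": 4, "post": 5}
    fractions = {vid: 0.0 for vid in range(1, 6)}
    for name, value in named.items():
        fractions[ids[name]] = value
    return SupplyFractionRecord(
        key="h", fractions=fractions, roi_voxel_count=1000, roi_volume_mm3=91.125
    )


class TestClassifyPattern:
    def test_five_vessel_pattern(self):
        rec = record(peri=0.2, callo=0.2, pre=0.2, central=0.2, post=0.2)
        assert classify_pattern(rec).count == 5

    def test_three_vessel_composition(self):
        rec = record(peri=0.4, pre=0.35, central=0.25)
        pattern = classify_pattern(rec)
        assert pattern.count == 3
        assert pattern.composition == frozenset(
            {"pericallosa", "precentral", "central"}
        )
        assert pattern.key == "pericallosa+precentral+central"

    def test_sole_supplier(self):
        assert classify_pattern(record(peri=1.0)).count == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(record())

    def test_invariant_to_roi_size(self):
        a = record(peri=0.4, pre=0.6)
        b = SupplyFractionRecord("h", a.fractions, 10, 0.9)
        assert classify_pattern(a) == classify_pattern(b)


class TestDominanceRatios:
    def test_sole_aca_supplier_is_one(self):
        assert dominance_ratios(record(peri=0.4, pre=0.3, central=0.3)).peri_callosomarginalis == 1.0

    def test_equal_contribution_is_half(self):
        assert dominance_ratios(record(peri=0.2, callo=0.2, pre=0.6)).peri_callosomarginalis == 0.5

    def test_absent_vessel_is_zero(self):
        assert dominance_ratios(record(callo=0.4, pre=0.6)).peri_callosomarginalis == 0.0

    def test_all_four_ratios_against_direct_arithmetic(self):
        rec = record(peri=0.10, callo=0.30, pre=0.25, central=0.20, post=0.15)
        r = dominance_ratios(rec)
        assert r.aca_mca == pytest.approx(0.40)
        assert r.peri_callosomarginalis == pytest.approx(0.10 / 0.40)
        assert r.central_precentral == pytest.approx(0.20 / 0.45)
        assert r.postcentral_mca == pytest.approx(0.15 / 0.60)

    def test_zero_denominators_undefined_not_raised(self):
        r = dominance_ratios(record(pre=0.5, central=0.5))
        assert r.peri_callosomarginalis is None
        r = dominance_ratios(record(peri=1.0))
        assert r.central_precentral is None
        assert r.postcentral_mca is None

    @given(
        peri=st.floats(0.0, 0.5),
        callo=st.floats(0.0, 0.5),
    )
    def test_complementarity(self, peri, callo):
        """The pericallosa ratio and its callosomarginalis counterpart sum to 1."""
        if peri + callo == 0:
            return
        rec = record(peri=peri, callo=callo)
        r = dominance_ratios(rec).peri_callosomarginalis
        counterpart = callo / (peri + callo)
        assert r + counterpart == pytest.approx(1.0, abs=1e-12)


class TestRateDominance:
    EQUI = ThresholdPair(0.33, 0.66)

    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.5, DominanceCategory.EQUAL),
            (1.0, DominanceCategory.NUMERATOR_DOMINANT),
            (0.0, DominanceCategory.DENOMINATOR_DOMINANT),
            (0.33, DominanceCategory.EQUAL),  # closed boundary
            (0.66, DominanceCategory.EQUAL),
            (None, DominanceCategory.UNDEFINED),
        ],
    )
    def test_categories(self, ratio, expected):
        assert rate_dominance(ratio, self.EQUI).category is expected

    def test_monotone_in_ratio(self):
        order = {
            DominanceCategory.DENOMINATOR_DOMINANT: 0,
            DominanceCategory.EQUAL: 1,
            DominanceCategory.NUMERATOR_DOMINANT: 2,
        }
        cats = [
            order[rate_dominance(r, self.EQUI).category]
            for r in np.linspace(0, 1, 101)
        ]
        assert cats == sorted(cats)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rate_dominance(1.2, self.EQUI)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdPair(0.66, 0.33)


class TestSweep:
    def test_grid_defaults(self):
        grid = build_sweep_grid()
        assert len(grid) == 100
        assert grid[0] == ThresholdPair(0.05, 0.95)
        assert grid[-1].lower == pytest.approx(0.45)
        assert grid[-1].upper == pytest.approx(0.55)
        with pytest.raises(ValueError):
            build_sweep_grid(low=0.3, high=0.6)

    def test_self_agreement_is_one(self, rng):
        ratios = list(rng.random(38))
        grid = build_sweep_grid(n=10)
        pair = grid[4]
        cats = [rate_dominance(r, pair).category for r in ratios]
        reference = {
            c: cats.count(c) / len(cats)
            for c in (
                DominanceCategory.NUMERATOR_DOMINANT,
                DominanceCategory.EQUAL,
                DominanceCategory.DENOMINATOR_DOMINANT,
            )
        }
        result = sweep_agreement(ratios, grid, reference)
        assert result.agreement[4] == pytest.approx(1.0)

    def test_all_equal_ratios_agree_with_pure_equal_reference(self):
        result = sweep_agreement(
            [0.5] * 10, build_sweep_grid(n=5), {DominanceCategory.EQUAL: 1.0}
        )
        np.testing.assert_allclose(result.agreement, 1.0)

    def test_per_pair_tables_match_brute_force_rerating(self, rng):
        ratios = list(rng.random(38))
        grid = build_sweep_grid(n=25)
        result = sweep_agreement(
            ratios, grid, {DominanceCategory.EQUAL: 0.4,
                           DominanceCategory.NUMERATOR_DOMINANT: 0.3,
                           DominanceCategory.DENOMINATOR_DOMINANT: 0.3}
        )
        for i, pair in enumerate(grid):
            n_hi = sum(r > pair.upper for r in ratios)
            n_lo = sum(r < pair.lower for r in ratios)
            n_eq = len(ratios) - n_hi - n_lo
            row = result.frequencies.iloc[i]
            assert row["numerator_dominant"] == pytest.approx(n_hi / 38)
            assert row["equal"] == pytest.approx(n_eq / 38)
            assert row["denominator_dominant"] == pytest.approx(n_lo / 38)
            expected_score = 1 - 0.5 * (
                abs(row["numerator_dominant"] - 0.3)
                + abs(row["equal"] - 0.4)
                + abs(row["denominator_dominant"] - 0.3)
            )
            assert result.agreement[i] == pytest.approx(expected_score)

    def test_best_pair_tie_resolves_to_smallest_lower(self):
        # every pair yields identical frequencies -> all tie -> first pair wins
        result = sweep_agreement(
            [0.5, 0.5], build_sweep_grid(n=7), {DominanceCategory.EQUAL: 1.0}
        )
        assert result.best_pair == result.pairs[0]

    def test_reference_must_be_normalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sweep_agreement([0.5], build_sweep_grid(n=3), {DominanceCategory.EQUAL: 0.5})
        with pytest.raises(ValueError):
            sweep_agreement([], build_sweep_grid(n=3), {DominanceCategory.EQUAL: 1.0})

    def test_undefined_ratios_excluded_from_rating_denominator(self):
        result = sweep_agreement(
            [0.5, None, 0.5], build_sweep_grid(n=3), {DominanceCategory.EQUAL: 1.0}
        )
        assert result.frequencies["equal"].iloc[0] == pytest.approx(1.0)


class TestFrequencyTable:
    def patterns(self, counts):
        comps = {
            3: frozenset({"pericallosa", "precentral", "central"}),
            4: frozenset({"pericallosa", "callosomarginalis", "precentral", "central"}),
            5: frozenset(
                {"pericallosa", "callosomarginalis", "precentral", "central", "postcentral"}
            ),
        }
        items = []
        for size, n in counts.items():
            items.extend([VesselPattern(size, comps[size])] * n)
        return items

    def test_prevalence_percentages(self):
        table = frequency_table(self.patterns({3: 10, 4: 19, 5: 9}))
        assert table.loc["3-vessel", "count"] == 10
        assert list(table["percentage"]) == [26.3, 50.0, 23.7]

    def test_single_category_and_order_invariance(self, rng):
        items = self.patterns({4: 5})
        assert frequency_table(items)["percentage"].iloc[0] == 100.0
        mixed = self.patterns({3: 2, 5: 3})
        shuffled = [mixed[i] for i in rng.permutation(len(mixed))]
        assert frequency_table(mixed).equals(frequency_table(shuffled))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            frequency_table([])


class TestInterraterCorrelation:
    def test_identical_vectors(self):
        r, p = interrater_correlation([0.1, 0.4, 0.5], [0.1, 0.4, 0.5])
        assert r == pytest.approx(1.0)

    def test_anti_ordered_affine(self):
        r, _ = interrater_correlation([0.1, 0.2, 0.3], [0.9, 0.7, 0.5])
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.random(25)
        b = 0.5 * a + rng.normal(0, 0.1, 25)
        r, _ = interrater_correlation(a, b)
        expected = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_contracts(self):
        with pytest.raises(ValueError):
            interrater_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            interrater_correlation([0.1, 0.2], [0.1, 0.2])


def test_agreement_score_is_one_minus_half_l1():
    f = {DominanceCategory.EQUAL: 0.6, DominanceCategory.NUMERATOR_DOMINANT: 0.4}
    g = {DominanceCategory.EQUAL: 0.2, DominanceCategory.DENOMINATOR_DOMINANT: 0.8}
    assert agreement_score(f, g) == pytest.approx(1 - 0.5 * (0.4 + 0.4 + 0.8))
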