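"""Surveillance metrics: schemes, incidence, mean ages, proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kdpanel.metrics import (
    AgeClass, AgeClassScheme, aggregate_to_coarse, adjusted_mean_age,
    age_adjusted_incidence, age_category_proportions, build_coarse_scheme,
    build_fine_scheme, crude_incidence, crude_mean_age,
)
from conftest import make_cases, make_pop


class TestSchemes:
    def test_fine_scheme_has_19_contiguous_classes(self):
        s = build_fine_scheme(10.5)
        assert len(s) == 19
        assert s.classes[0].lower == 0 and s.classes[0].upper == 3
        assert s.classes[0].midpoint == pytest.approx(0.125)
        assert s.classes[-1].upper is None
        assert s.classes[-1].midpoint == 10.5

    def test_oldest_midpoint_sensitivity_only_changes_last_class(self):
        a, b = build_fine_scheme(10.5), build_fine_scheme(15)
        assert a.classes[:-1] == b.classes[:-1]
        assert b.classes[-1].midpoint == 15

    def test_coarse_scheme_has_11_classes(self):
        s = build_coarse_scheme()
        assert len(s) == 11
        assert [c.midpoint for c in s.classes] == pytest.approx(
            [0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.5])

    def test_oldest_midpoint_must_exceed_ten(self):
        with pytest.raises(ValueError):
            build_fine_scheme(8)

    @pytest.mark.parametrize("classes", [
        # gap between classes
        (AgeClass("a", 0, 12, 0.5), AgeClass("b", 24, 36, 2.5)),
        # wrong midpoint
        (AgeClass("a", 0, 12, 0.7),),
        # open class not last
        (AgeClass("a", 0, None, 1.0), AgeClass("b", 0, 12, 0.5)),
    ])
    def test_invalid_schemes_rejected(self, classes):
        with pytest.raises(ValueError):
            AgeClassScheme(tuple(classes))


class TestAggregation:
    def test_sub_year_classes_collapse_into_under_one(self, fine_scheme):
        cases = make_cases(fine_scheme, {("A", 2000): {
            "0-2m": 3, "3-5m": 4, "6-8m": 2, "9-11m": 1}})
        coarse = aggregate_to_coarse(cases)
        assert len(coarse.scheme) == 11
        got = coarse.data.set_index("age_class")["count"]
        assert got.loc["<1y"] == 10

    def test_totals_conserved_on_random_panels(self, fine_scheme):
        rng = np.random.default_rng(0)
        entries = {("A", y): {c.label: int(rng.integers(0, 50))
                              for c in fine_scheme.classes}
                   for y in (2000, 2001, 2002)}
        cases = make_cases(fine_scheme, entries)
        coarse = aggregate_to_coarse(cases)
        pd.testing.assert_series_equal(cases.totals(), coarse.totals())

    def test_all_zero_panel_stays_zero(self, fine_scheme):
        cases = make_cases(fine_scheme,
                           {("A", 2000): {c.label: 0 for c in fine_scheme.classes}})
        assert aggregate_to_coarse(cases).data["count"].sum() == 0

    def test_unknown_class_label_rejected(self, fine_scheme):
        with pytest.raises(ValueError, match="age class"):
            make_cases(fine_scheme, {("A", 2000): {"nonsense": 1}})


class TestIncidence:
    def _pop(self, scheme, under5_total=100_000.0):
        per_class = {c.label: under5_total / 5 for c in scheme.classes
                     if c.upper is not None and c.upper <= 60}
        per_class[">=10y"] = 1.0  # present but outside the denominator
        n = len(scheme)
        return make_pop(scheme, {("A", 2000): per_class},
                        {c.label: (1.0 / n) for c in scheme.classes})

    def test_per_100k_of_under5_population(self, fine_scheme):
        coarse = build_coarse_scheme()
        cases = make_cases(coarse, {("A", 2000): {"<1y": 50}})
        pop = self._pop(coarse)
        assert crude_incidence(cases, pop).loc[("A", 2000)] == pytest.approx(50.0)

    def test_numerator_includes_all_ages(self):
        coarse = build_coarse_scheme()
        cases = make_cases(coarse, {("A", 2000): {">=10y": 10}})
        pop = self._pop(coarse, under5_total=200_000.0)
        assert crude_incidence(cases, pop).loc[("A", 2000)] == pytest.approx(5.0)

    def test_zero_cases_give_zero(self):
        coarse = build_coarse_scheme()
        cases = make_cases(coarse, {("A", 2000): {"<1y": 0}})
        assert crude_incidence(cases, self._pop(coarse)).loc[("A", 2000)] == 0.0

    def test_missing_under5_population_is_an_error(self):
        coarse = build_coarse_scheme()
        cases = make_cases(coarse, {("B", 2001): {"<1y": 5}})
        pop = self._pop(coarse)  # only region A
        with pytest.raises(ValueError, match="B"):
            crude_incidence(cases, pop)


class TestAdjustedIncidence:
    def test_hand_computed_two_class_example(self, two_class_scheme):
        # rates (1e-4, 3e-4) with equal standard shares -> 20 per 100,000
        cases = make_cases(two_class_scheme, {("A", 2000): {"young": 1, "old": 3}})
        pop = make_pop(two_class_scheme,
                       {("A", 2000): {"young": 10_000.0, "old": 10_000.0}},
                       {"young": 0.5, "old": 0.5})
        got = age_adjusted_incidence(cases, pop).loc[("A", 2000)]
        assert got == pytest.approx(20.0)

    def test_constant_rate_is_returned_unchanged(self, two_class_scheme):
        cases = make_cases(two_class_scheme,
                           {("A", 2000): {"young": 2, "old": 2}})
        pop = make_pop(two_class_scheme,
                       {("A", 2000): {"young": 8_000.0, "old": 8_000.0}},
                       {"young": 0.3, "old": 0.7})
        # equal class rates: 2/8000 in both classes
        got = age_adjusted_incidence(cases, pop).loc[("A", 2000)]
        assert got == pytest.approx(1e5 * 2 / 8000)

    def test_identity_structure_equals_crude_all_age_rate(self, two_class_scheme):
        # local proportions equal the standard -> direct standardization
        # reproduces the crude all-ages rate over the same population
        cases = make_cases(two_class_scheme, {("A", 2000): {"young": 7, "old": 3}})
        pop = make_pop(two_class_scheme,
                       {("A", 2000): {"young": 6_000.0, "old": 4_000.0}},
                       {"young": 0.6, "old": 0.4})
        got = age_adjusted_incidence(cases, pop).loc[("A", 2000)]
        assert got == pytest.approx(1e5 * 10 / 10_000)

    def test_zero_population_with_cases_is_an_error(self, two_class_scheme):
        cases = make_cases(two_class_scheme, {("A", 2000): {"young": 1, "old": 1}})
        pop = make_pop(two_class_scheme, {("A", 2000): {"young": 5_000.0}},
                       {"young": 0.5, "old": 0.5})
        with pytest.raises(ValueError, match="class population"):
            age_adjusted_incidence(cases, pop)


class TestCrudeMeanAge:
    def test_single_class_returns_its_midpoint(self, fine_scheme):
        cases = make_cases(fine_scheme, {("A", 2000): {"2y-2y5m": 12}})
        got = crude_mean_age(cases).loc[("A", 2000)]
        assert got == pytest.approx(fine_scheme["2y-2y5m"].midpoint)

    def test_weighted_mean_of_midpoints(self, two_class_scheme):
        # midpoints 0.5, 1.5 with counts 10, 30 -> 1.25
        cases = make_cases(two_class_scheme, {("A", 2000): {"young": 10, "old": 30}})
        assert crude_mean_age(cases).loc[("A", 2000)] == pytest.approx(1.25)

    def test_pooling_weights_by_counts_not_years(self, two_class_scheme):
        # per-year means 0.5 and 1.5 with counts 10 and 30 -> pooled 1.25
        cases = make_cases(two_class_scheme, {("A", 2000): {"young": 10},
                                              ("A", 2001): {"old": 30}})
        assert crude_mean_age(cases, pool_years=True).loc["A"] == pytest.approx(1.25)

    def test_zero_cases_yield_missing_not_zero(self, two_class_scheme):
        cases = make_cases(two_class_scheme, {("A", 2000): {"young": 0, "old": 0}})
        assert np.isnan(crude_mean_age(cases).loc[("A", 2000)])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(min_value=0, max_value=100),
                    min_size=19, max_size=19).filter(lambda c: sum(c) > 0))
    def test_bounded_by_extreme_midpoints(self, counts):
        scheme = build_fine_scheme(10.5)
        cases = make_cases(scheme, {("A", 2000): dict(zip(scheme.labels, counts))})
        m = crude_mean_age(cases).loc[("A", 2000)]
        assert 0.125 <= m <= 10.5

    def test_monotone_under_shift_to_older_classes(self, two_class_scheme):
        younger = make_cases(two_class_scheme, {("A", 2000): {"young": 30, "old": 10}})
        older = make_cases(two_class_scheme, {("A", 2000): {"young": 10, "old": 30}})
        assert crude_mean_age(older).loc[("A", 2000)] > \
            crude_mean_age(younger).loc[("A", 2000)]


class TestAdjustedMeanAge:
    def test_hand_computed_reweighting_example(self, two_class_scheme):
        # N=(10,10), S=(0.5,0.5), C=(0.8,0.2) -> weights (6.25, 25) -> 1.30
        cases = make_cases(two_class_scheme, {("A", 2000): {"young": 10, "old": 10}})
        pop = make_pop(two_class_scheme,
                       {("A", 2000): {"young": 8_000.0, "old": 2_000.0}},
                       {"young": 0.5, "old": 0.5})
        got = adjusted_mean_age(cases, pop).loc[("A", 2000)]
        assert got == pytest.approx(1.30)

    def test_reduces_to_crude_when_structure_matches_standard(self, two_class_scheme):
        rng = np.random.default_rng(3)
        for _ in range(5):
            counts = {"young": int(rng.integers(1, 40)),
                      "old": int(rng.integers(1, 40))}
            cases = make_cases(two_class_scheme, {("A", 2000): counts})
            pop = make_pop(two_class_scheme,
                           {("A", 2000): {"young": 3_500.0, "old": 6_500.0}},
                           {"young": 0.35, "old": 0.65})
            assert adjusted_mean_age(cases, pop).loc[("A", 2000)] == \
                pytest.approx(crude_mean_age(cases).loc[("A", 2000)])

    def test_invariant_to_population_scale(self, two_class_scheme):
        cases = make_cases(two_class_scheme, {("A", 2000): {"young": 4, "old": 9}})
        std = {"young": 0.5, "old": 0.5}
        p1 = make_pop(two_class_scheme,
                      {("A", 2000): {"young": 1_000.0, "old": 3_000.0}}, std)
        p3 = make_pop(two_class_scheme,
                      {("A", 2000): {"young": 3_000.0, "old": 9_000.0}}, std)
        assert adjusted_mean_age(cases, p1).loc[("A", 2000)] == \
            pytest.approx(adjusted_mean_age(cases, p3).loc[("A", 2000)])

    def test_zero_share_with_cases_is_an_error(self, two_class_scheme):
        cases = make_cases(two_class_scheme, {("A", 2000): {"young": 1, "old": 1}})
        pop = make_pop(two_class_scheme, {("A", 2000): {"old": 5_000.0}},
                       {"young": 0.5, "old": 0.5})
        with pytest.raises(ValueError, match="share"):
            adjusted_mean_age(cases, pop)


class TestAgeCategoryProportions:
    def test_all_infants_in_first_category(self, fine_scheme):
        cases = make_cases(fine_scheme, {("A", 2000): {"0-2m": 8}})
        row = age_category_proportions(cases).loc[("A", 2000)]
        assert row.tolist() == pytest.approx([100.0, 0.0, 0.0])

    def test_category_membership_by_lower_bound(self, fine_scheme):
        cases = make_cases(fine_scheme, {("A", 2000): {
            "3-5m": 5, "4y-4y11m": 5, "18-20m": 10}})
        row = age_category_proportions(cases).loc[("A", 2000)]
        assert row.tolist() == pytest.approx([25.0, 50.0, 25.0])

    def test_invariant_to_count_scaling(self, fine_scheme):
        base = {"3-5m": 2, "2y-2y5m": 5, ">=10y": 3}
        c1 = make_cases(fine_scheme, {("A", 2000): base})
        c3 = make_cases(fine_scheme,
                        {("A", 2000): {k: 3 * v for k, v in base.items()}})
        pd.testing.assert_frame_equal(age_category_proportions(c1),
                                      age_category_proportions(c3))

    def test_rows_sum_to_100(self, small_scenario_outputs):
        props = age_category_proportions(small_scenario_outputs["cases"])
        sums = props.dropna().sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)


class TestMetricConsistency:
    def test_adjusted_tracks_crude_on_proportional_panels(self, small_scenario_outputs):
        """Crude and adjusted incidence rank together when age structures
        are close to the standard."""
        from scipy.stats import spearmanr
        cases, pop = small_scenario_outputs["cases"], small_scenario_outputs["pop"]
        coarse = aggregate_to_coarse(cases)
        ci = crude_incidence(cases, pop)
        ai = age_adjusted_incidence(coarse, pop)
        rho = spearmanr(ci, ai.reindex(ci.index)).statistic
        assert rho > 0.9
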