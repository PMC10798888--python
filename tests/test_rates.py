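import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methscale import (
    DegenerateFitError,
    InsufficientCpGsError,
    InsufficientDataError,
    apply_inclusion_filters,
    chain_comparisons,
    fit_cpg_rate,
    fit_panel_rates,
    match_age_ranges,
    median_rate_ratio,
    order_species,
    select_common_age_related_cpgs,
)
from methscale.simulate import SimulationSpec, generate_power_law_scenario
from methscale.types import SpeciesTraitTable

from conftest import make_linear_panel, make_traits
from oracle import match_ages as oracle_match
from oracle import ols as oracle_ols


class TestFitCpGRate:
    def test_exact_linear_data(self):
        fit = fit_cpg_rate(np.array([0.0, 5.0, 10.0]),
                           0.3 + 0.01 * np.array([0.0, 5.0, 10.0]))
        assert fit.slope == pytest.approx(0.01, abs=1e-15)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_betas(self):
        fit = fit_cpg_rate(np.array([0.0, 1.0, 2.0]), np.full(3, 0.5))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0
        assert fit.mean_methylation == 0.5

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(0, 20, 30)
        betas = np.clip(0.4 + 0.008 * ages + rng.normal(0, 0.05, 30), 0, 1)
        fit = fit_cpg_rate(ages, betas)
        slope, intercept, r2, mean_y, n = oracle_ols(list(ages), list(betas))
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)
        assert fit.n_samples == n

    def test_missing_values_dropped_pairwise(self):
        ages = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        betas = 0.2 + 0.05 * ages
        betas[2] = np.nan
        fit = fit_cpg_rate(ages, betas)
        assert fit.n_samples == 4
        assert fit.slope == pytest.approx(0.05, abs=1e-12)

    def test_too_few_pairs_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_cpg_rate(np.array([0.0, 1.0]), np.array([0.1, 0.2]))

    def test_degenerate_ages_raise(self):
        with pytest.raises(DegenerateFitError):
            fit_cpg_rate(np.full(5, 3.0), np.linspace(0.1, 0.5, 5))


def test_panel_fit_agrees_with_scalar_fit():
    rng = np.random.default_rng(12)
    ages = rng.uniform(0, 15, 20)
    panel = make_linear_panel(
        "sp", rng.uniform(-0.02, 0.02, 8), ages, noise_sd=0.03, rng=rng
    )
    panel.betas[3, :10] = np.nan
    panel.betas[5, :] = np.nan  # fully missing -> invalid
    table = fit_panel_rates(panel)
    assert not table.loc["cpg_005", "valid"]
    for cpg in ["cpg_000", "cpg_003", "cpg_007"]:
        row = panel.betas[list(panel.cpg_ids).index(cpg)]
        scalar = fit_cpg_rate(ages, row, cpg)
        assert table.loc[cpg, "slope"] == pytest.approx(scalar.slope, abs=1e-12)
        assert table.loc[cpg, "r_squared"] == pytest.approx(
            scalar.r_squared, abs=1e-12
        )
        assert table.loc[cpg, "n"] == scalar.n_samples


class TestOrderSpecies:
    def make(self, **max_ages):
        return [
            make_linear_panel(sp, [0.001], np.linspace(0, a, 4))
            for sp, a in max_ages.items()
        ]

    def test_orders_by_maximum_observed_age(self):
        panels = self.make(mouse=2.8, rat=2.5, human=90.0)
        assert order_species(panels) == ["rat", "mouse", "human"]

    def test_ties_break_lexicographically(self):
        panels = self.make(zebu=10.0, ass=10.0)
        assert order_species(panels) == ["ass", "zebu"]

    def test_single_species_is_baseline(self):
        panels = self.make(rat=2.5)
        assert order_species(panels) == ["rat"]


class TestMatchAgeRanges:
    def test_nearby_sample_matches_at_first_candidate(self):
        shorter = make_linear_panel("s", [0.01], np.linspace(0, 10, 21))
        longer = make_linear_panel("l", [0.01],
                                   np.array([1.0, 5.0, 9.9, 30.0]))
        m = match_age_ranges(shorter, longer, shorter_lifespan=20.0)
        assert m.tolerance == pytest.approx(0.4)
        assert m.matched_max_age_shorter == 10.0
        assert m.matched_max_age_longer == 9.9
        assert m.shorter.max_age == 10.0
        assert m.longer.max_age == 9.9

    def test_exact_match_trims_nothing_above(self):
        shorter = make_linear_panel("s", [0.01], np.array([0.0, 4.0, 8.0]))
        longer = make_linear_panel("l", [0.01], np.array([2.0, 8.0, 40.0]))
        m = match_age_ranges(shorter, longer, shorter_lifespan=50.0)
        assert m.matched_max_age_shorter == m.matched_max_age_longer == 8.0
        assert m.shorter.n_samples == 3
        assert m.longer.n_samples == 2

    def test_no_candidate_within_tolerance_returns_none(self):
        shorter = make_linear_panel("s", [0.01], np.array([1.0, 2.0, 3.0]))
        longer = make_linear_panel("l", [0.01], np.array([5.5, 6.5, 40.0]))
        assert match_age_ranges(shorter, longer, shorter_lifespan=10.0) is None

    def test_falls_back_to_next_oldest_distinct_age(self):
        # max age 10 has no partner within tol 0.2; age 6 matches exactly
        shorter = make_linear_panel("s", [0.01], np.array([2.0, 6.0, 10.0]))
        longer = make_linear_panel("l", [0.01], np.array([6.0, 15.0, 30.0]))
        m = match_age_ranges(shorter, longer, shorter_lifespan=10.0)
        assert m.matched_max_age_shorter == 6.0
        assert m.matched_max_age_longer == 6.0
        assert m.shorter.n_samples == 2

    @given(
        shorter_ages=st.lists(
            st.floats(0, 20, allow_nan=False), min_size=2, max_size=12
        ),
        longer_ages=st.lists(
            st.floats(0, 60, allow_nan=False), min_size=2, max_size=12
        ),
        lifespan=st.floats(1, 120, allow_nan=False),
    )
    def test_matches_brute_force_scan(self, shorter_ages, longer_ages, lifespan):
        shorter = make_linear_panel(
            "s", [0.001], np.array(sorted(shorter_ages))
        )
        longer = make_linear_panel("l", [0.001], np.array(sorted(longer_ages)))
        result = match_age_ranges(shorter, longer, lifespan)
        expected = oracle_match(shorter_ages, longer_ages, lifespan)
        if expected is None:
            assert result is None
        else:
            assert (result.matched_max_age_shorter,
                    result.matched_max_age_longer) == expected


class TestInclusionFilters:
    def panel(self, n, max_age):
        return make_linear_panel("sp", [0.001], np.linspace(0, max_age, n))

    def test_all_boundaries_met_inclusively(self):
        traits = make_traits(sp=100.0)
        res = apply_inclusion_filters(self.panel(15, 30.0), traits,
                                      initial_n=25)
        assert res.passed

    def test_fourteen_restricted_samples_fail(self):
        traits = make_traits(sp=100.0)
        res = apply_inclusion_filters(self.panel(14, 30.0), traits,
                                      initial_n=25)
        assert not res.passed
        assert res.reason == "min_samples_after_restriction"

    def test_poor_lifespan_coverage_fails(self):
        traits = make_traits(sp=100.0)
        res = apply_inclusion_filters(self.panel(20, 20.0), traits,
                                      initial_n=25)
        assert not res.passed
        assert res.reason == "lifespan_coverage"

    def test_under_twenty_initial_samples_fail(self):
        traits = make_traits(sp=100.0)
        res = apply_inclusion_filters(self.panel(18, 30.0), traits,
                                      initial_n=19)
        assert res.reason == "min_initial_samples"

    def test_coverage_uses_raw_pre_rereferencing_age(self):
        # max re-referenced age 20 + ASM 5 = 25 = exactly 25% of 100
        traits = make_traits(sp=(100.0, 5.0))
        res = apply_inclusion_filters(self.panel(20, 20.0), traits,
                                      initial_n=25)
        assert res.passed


def fits_frame(**rows):
    """cpg -> (slope, r2, mean) shorthand for selection tests."""
    idx, data = [], {"slope": [], "r_squared": [], "mean_methylation": [],
                     "n": [], "valid": [], "intercept": []}
    for cpg, (slope, r2, mean) in rows.items():
        idx.append(cpg)
        data["slope"].append(slope)
        data["r_squared"].append(r2)
        data["mean_methylation"].append(mean)
        data["intercept"].append(0.5)
        data["n"].append(20)
        data["valid"].append(True)
    return pd.DataFrame(data, index=pd.Index(idx, name="cpg_id"))


class TestCpGSelection:
    def test_passing_cpg_included(self):
        a = fits_frame(cg1=(0.01, 0.25, 0.5))
        b = fits_frame(cg1=(0.02, 0.30, 0.6))
        assert list(select_common_age_related_cpgs(a, b, 0.2)) == ["cg1"]

    def test_boundary_mean_methylation_excluded(self):
        a = fits_frame(cg1=(0.01, 0.5, 0.95))
        b = fits_frame(cg1=(0.02, 0.5, 0.6))
        assert len(select_common_age_related_cpgs(a, b, 0.2)) == 0

    def test_opposite_directionality_excluded(self):
        a = fits_frame(cg1=(0.01, 0.5, 0.5))
        b = fits_frame(cg1=(-0.01, 0.5, 0.5))
        assert len(select_common_age_related_cpgs(a, b, 0.2)) == 0

    def test_threshold_applies_to_both_species(self):
        a = fits_frame(cg1=(0.01, 0.15, 0.5))
        b = fits_frame(cg1=(0.01, 0.50, 0.5))
        assert len(select_common_age_related_cpgs(a, b, 0.2)) == 0
        assert len(select_common_age_related_cpgs(a, b, 0.1)) == 1

    def test_direction_strata_partition_selection(self):
        a = fits_frame(cg1=(0.01, 0.5, 0.5), cg2=(-0.01, 0.5, 0.5),
                       cg3=(0.02, 0.5, 0.5))
        b = fits_frame(cg1=(0.01, 0.5, 0.5), cg2=(-0.02, 0.5, 0.5),
                       cg3=(0.01, 0.5, 0.5))
        full = set(select_common_age_related_cpgs(a, b, 0.2))
        hyper = set(select_common_age_related_cpgs(a, b, 0.2, "hyper"))
        hypo = set(select_common_age_related_cpgs(a, b, 0.2, "hypo"))
        assert hyper | hypo == full
        assert hyper & hypo == set()
        assert hyper == {"cg1", "cg3"} and hypo == {"cg2"}


class TestMedianRateRatio:
    def test_median_of_odd_ratio_set(self):
        a = fits_frame(c1=(0.02, 1, 0.5), c2=(0.01, 1, 0.5),
                       c3=(0.005, 1, 0.5))
        b = fits_frame(c1=(0.01, 1, 0.5), c2=(0.01, 1, 0.5),
                       c3=(0.01, 1, 0.5))
        comp = median_rate_ratio(a, b, np.array(["c1", "c2", "c3"]))
        np.testing.assert_allclose(sorted(comp.per_cpg_ratios),
                                   [0.5, 1.0, 2.0])
        assert comp.median_ratio == 1.0

    def test_worked_single_cpg_ratio(self):
        a = fits_frame(c1=(0.01, 1, 0.5))
        b = fits_frame(c1=(0.0094, 1, 0.5))
        comp = median_rate_ratio(a, b, np.array(["c1"]))
        assert comp.median_ratio == pytest.approx(0.94)

    def test_negative_slopes_give_positive_ratio(self):
        a = fits_frame(c1=(-0.02, 1, 0.5))
        b = fits_frame(c1=(-0.01, 1, 0.5))
        comp = median_rate_ratio(a, b, np.array(["c1"]))
        assert comp.median_ratio == pytest.approx(0.5)

    def test_even_count_uses_midpoint(self):
        a = fits_frame(c1=(0.01, 1, 0.5), c2=(0.01, 1, 0.5))
        b = fits_frame(c1=(0.01, 1, 0.5), c2=(0.02, 1, 0.5))
        comp = median_rate_ratio(a, b, np.array(["c1", "c2"]))
        assert comp.median_ratio == pytest.approx(1.5)

    def test_empty_selection_raises(self):
        a = fits_frame(c1=(0.01, 1, 0.5))
        with pytest.raises(InsufficientCpGsError):
            median_rate_ratio(a, a, np.array([]))


class TestChain:
    def test_identical_panels_give_unit_ratio(self):
        ages = np.linspace(0, 10, 25)
        slopes = np.random.default_rng(0).uniform(0.005, 0.03, 15)
        panels = {
            "a": make_linear_panel("a", slopes, ages),
            "b": make_linear_panel("b", slopes, ages),
        }
        traits = make_traits(a=20.0, b=20.0)
        series = chain_comparisons(panels, traits, 0.1, min_cpgs=5)
        np.testing.assert_allclose(series.cumulative_ratios, [1.0, 1.0],
                                   rtol=1e-12)

    def test_cumulative_is_prefix_product_of_medians(self, three_species_chain):
        panels, traits = three_species_chain
        series = chain_comparisons(panels, traits, 0.1)
        medians = [c.median_ratio for c in series.comparisons]
        np.testing.assert_allclose(
            np.log(series.cumulative_ratios),
            np.concatenate([[0.0], np.cumsum(np.log(medians))]),
            atol=1e-12,
        )
        assert series.cumulative_ratios[0] == 1.0

    def test_failing_middle_species_bridged(self, three_species_chain):
        panels, traits = three_species_chain
        # starve the middle species below the initial-sample filter
        panels_broken = dict(panels)
        panels_broken["sp_b"] = panels["sp_b"].subset_samples(
            np.arange(10)
        )
        bridged = chain_comparisons(panels_broken, traits, 0.1)
        direct = chain_comparisons(
            {k: panels[k] for k in ["sp_a", "sp_c"]}, traits, 0.1
        )
        assert bridged.species == direct.species == ["sp_a", "sp_c"]
        np.testing.assert_array_equal(
            bridged.cumulative_ratios, direct.cumulative_ratios
        )

    def test_unmatchable_species_dropped_from_chain(self):
        ages = np.linspace(0, 10, 25)
        slopes = np.full(12, 0.01)
        panels = {
            "a": make_linear_panel("a", slopes, ages),
            "b": make_linear_panel(
                "b", slopes, np.linspace(30.0, 40.0, 25)
            ),
            "c": make_linear_panel("c", slopes * 0.5,
                                   np.linspace(0, 10.5, 25)),
        }
        # species b has no sample anywhere near a's range
        traits = make_traits(a=40.0, b=160.0, c=40.0)
        series = chain_comparisons(panels, traits, 0.1)
        assert series.species == ["a", "c"]

    def test_scaling_down_one_species_rescales_adjacent_ratios_only(self):
        ages = np.linspace(0, 12, 24)
        rng = np.random.default_rng(8)
        slopes = rng.uniform(0.004, 0.02, 15)
        k = 0.7
        panels = {
            "a": make_linear_panel("a", slopes, ages),
            "b": make_linear_panel("b", slopes, ages + 1e-3),
            "c": make_linear_panel("c", slopes, ages + 2e-3),
            "d": make_linear_panel("d", slopes, ages + 3e-3),
        }
        scaled = dict(panels)
        scaled["b"] = make_linear_panel("b", slopes * k, ages + 1e-3)
        traits = make_traits(a=30.0, b=30.0, c=30.0, d=30.0)
        base = chain_comparisons(panels, traits, 0.1)
        pert = chain_comparisons(scaled, traits, 0.1)
        medians_base = [c.median_ratio for c in base.comparisons]
        medians_pert = [c.median_ratio for c in pert.comparisons]
        assert medians_pert[0] == pytest.approx(medians_base[0] * k, rel=1e-9)
        assert medians_pert[1] == pytest.approx(medians_base[1] / k, rel=1e-9)
        assert medians_pert[2] == pytest.approx(medians_base[2], rel=1e-9)
        np.testing.assert_allclose(
            pert.cumulative_ratios[[0, 2, 3]],
            base.cumulative_ratios[[0, 2, 3]],
            rtol=1e-9,
        )

    def test_noise_free_power_law_recovers_lifespan_ratios(self):
        spec = SimulationSpec(
            n_species=6, n_cpgs=60, samples_per_species=25,
            lifespans=(5.0, 8.0, 13.0, 21.0, 34.0, 55.0),
            true_exponent=-1.0, noise_sd=0.0,
            baseline_slope_mean=0.05, baseline_slope_sd=0.01,
            intercept_sd=0.05, sampled_fraction=0.5, seed=4,
        )
        panels, traits, _ = generate_power_law_scenario(spec)
        series = chain_comparisons(panels, traits, 0.1)
        lifespans = series.max_lifespans
        np.testing.assert_allclose(
            series.cumulative_ratios,
            (lifespans / lifespans[0]) ** -1.0,
            rtol=1e-9,
        )

    def test_fewer_than_two_surviving_species_raises(self):
        panels = {"a": make_linear_panel("a", [0.01],
                                         np.linspace(0, 10, 25))}
        with pytest.raises(InsufficientDataError):
            chain_comparisons(panels, make_traits(a=20.0), 0.1)

    def test_min_cpgs_violation_invalidates_threshold(self, three_species_chain):
        panels, traits = three_species_chain
        with pytest.raises(InsufficientCpGsError):
            chain_comparisons(panels, traits, 0.1, min_cpgs=50)
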