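"""Tests of the population exposure simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiprisk.exposure import (
    DemographicStratum,
    IntakeSpec,
    LognormalParams,
    aggregate_exposure,
    allocate_population,
    lognormal_params_from_moments,
    run_exposure_scenario,
    sample_truncated_normal,
    summarize_exposure,
)


class TestMomentTransform:
    def test_degenerate_sd(self):
        p = lognormal_params_from_moments(0.5, 0.0)
        assert p.meanlog == pytest.approx(np.log(0.5))
        assert p.sdlog == 0.0

    def test_root_vegetable_moments(self):
        # detect moments of the root-vegetable category: mean = SD = 0.013 ppm
        p = lognormal_params_from_moments(0.013, 0.013)
        assert p.meanlog == pytest.approx(np.log(0.013) - 0.5 * np.log(2), rel=1e-12)
        assert p.meanlog == pytest.approx(-4.68938, abs=1e-5)
        assert p.sdlog == pytest.approx(np.sqrt(np.log(2)), rel=1e-12)
        mean, sd = p.arithmetic_moments()
        assert mean == pytest.approx(0.013, rel=1e-9)
        assert sd == pytest.approx(0.013, rel=1e-9)

    @settings(deadline=None, max_examples=200)
    @given(
        mean=st.floats(1e-6, 1e4),
        ratio=st.floats(0.0, 50.0),
    )
    def test_round_trip_is_identity(self, mean, ratio):
        sd = mean * ratio
        p = lognormal_params_from_moments(mean, sd)
        m2, s2 = p.arithmetic_moments()
        assert m2 == pytest.approx(mean, rel=1e-9)
        assert s2 == pytest.approx(sd, rel=1e-9, abs=1e-12)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            lognormal_params_from_moments(0.0, 1.0)


class TestTruncatedNormal:
    def test_zero_sd_returns_clipped_mean(self):
        assert np.allclose(sample_truncated_normal(60, 0, 0, np.inf, 5, rng=1), 60)
        assert np.allclose(sample_truncated_normal(-5, 0, 0, 10, 3, rng=1), 0)

    def test_untruncated_limit(self):
        x = sample_truncated_normal(0, 1, -np.inf, np.inf, 1_000_000, rng=1)
        assert abs(x.mean()) < 0.01

    def test_half_normal_mean(self):
        x = sample_truncated_normal(0, 1, 0, np.inf, 1_000_000, rng=2)
        assert x.mean() == pytest.approx(np.sqrt(2 / np.pi), rel=0.01)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            sample_truncated_normal(0, 1, 1.0, 1.0, 10)


def _strata(weights, bw=60.0):
    return [
        DemographicStratum(age=i, sex="male", population_count=w, bw_mean=bw, bw_sd=5.0)
        for i, w in enumerate(weights)
    ]


class TestAllocation:
    def test_equal_split(self):
        counts = allocate_population(_strata([500, 500]), 100, min_per_stratum=10)
        assert list(counts) == [50, 50]

    def test_minimum_floor_engages(self):
        counts = allocate_population(_strata([999, 1]), 1000, min_per_stratum=10)
        assert list(counts) == [990, 10]

    def test_full_demographic_grid(self):
        strata = [
            DemographicStratum(age, sex, 1000 + age, 60.0, 8.0)
            for age in range(101)
            for sex in ("male", "female")
        ]
        counts = allocate_population(strata, 200_000, min_per_stratum=10)
        assert counts.sum() == 200_000
        assert counts.min() >= 10

    def test_infeasible_total(self):
        with pytest.raises(ValueError):
            allocate_population(_strata([1, 1, 1]), 20, min_per_stratum=10)

    @settings(deadline=None, max_examples=50)
    @given(
        weights=st.lists(st.integers(0, 10_000), min_size=2, max_size=30),
        n_total=st.integers(1000, 50_000),
    )
    def test_counts_sum_exactly(self, weights, n_total):
        if sum(weights) == 0:
            weights[0] = 1
        populated = sum(1 for w in weights if w > 0)
        counts = allocate_population(_strata(weights), n_total, min_per_stratum=10)
        assert counts.sum() == n_total
        assert all(c >= 10 for c, w in zip(counts, weights) if w > 0)
        assert populated * 10 <= n_total


class TestAggregateExposure:
    def test_zero_residues(self):
        assert aggregate_exposure(np.array([10.0, 20.0]), np.zeros(2), 60.0) == 0.0

    def test_single_category_hand_computed(self):
        # 258 g/day of produce at 1.69 ppm for a 74.1 kg adult
        out = aggregate_exposure(np.array([258.0]), np.array([1.69]), 74.1)
        assert out == pytest.approx(258 * 1.69 / (74.1 * 1000), rel=1e-12)
        assert out == pytest.approx(5.884e-3, rel=1e-3)

    def test_homogeneity_in_bodyweight(self):
        i, r = np.array([100.0, 50.0]), np.array([0.01, 0.02])
        assert aggregate_exposure(i, r, 140.0) == pytest.approx(
            aggregate_exposure(i, r, 70.0) / 2
        )

    @settings(deadline=None, max_examples=100)
    @given(
        intake=st.floats(0, 1000),
        residue=st.floats(0, 10),
        c=st.floats(0.1, 10),
    )
    def test_linearity_in_each_factor(self, intake, residue, c):
        base = aggregate_exposure(np.array([intake]), np.array([residue]), 60.0)
        assert aggregate_exposure(np.array([c * intake]), np.array([residue]), 60.0) == pytest.approx(c * base, rel=1e-9, abs=1e-300)
        assert aggregate_exposure(np.array([intake]), np.array([c * residue]), 60.0) == pytest.approx(c * base, rel=1e-9, abs=1e-300)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            aggregate_exposure(np.array([-1.0]), np.array([0.01]), 60.0)


def _two_stratum_population():
    return [
        DemographicStratum(30, "male", 500, 70.0, 0.0),
        DemographicStratum(30, "female", 500, 55.0, 0.0),
    ]


class TestScenario:
    def test_degenerate_draws_hand_computable(self):
        # zero-variance body weight/intake and point-mass residues: the
        # simulated exposure must equal the deterministic substitution value
        strata = _two_stratum_population()
        residues = {"A": LognormalParams(np.log(0.001), 0.0), "B": LognormalParams(np.log(0.002), 0.0)}
        intakes = [
            IntakeSpec("A", "LB", 100.0, 0.0),
            IntakeSpec("B", "LB", 50.0, 0.0),
        ]
        table = run_exposure_scenario(strata, residues, intakes, "LB", seed=1, n_total=100)
        male = table[table.sex == "male"]
        expected = (100 * 0.001 + 50 * 0.002) / (70.0 * 1000)
        assert np.allclose(male["exposure"], expected)

    def test_missing_category_raises(self):
        strata = _two_stratum_population()
        residues = {"A": LognormalParams(0.0, 0.1)}
        with pytest.raises(ValueError):
            run_exposure_scenario(strata, residues, [], "LB", seed=1, n_total=100)

    def test_lb_below_ub_when_ub_dominates(self):
        strata = _two_stratum_population()
        residues = {"A": LognormalParams(np.log(0.005), 0.5)}
        intakes = [IntakeSpec("A", "LB", 50.0, 20.0), IntakeSpec("A", "UB", 150.0, 20.0)]
        lb = run_exposure_scenario(strata, residues, intakes, "LB", seed=9, n_total=2000)
        ub = run_exposure_scenario(strata, residues, intakes, "UB", seed=9, n_total=2000)
        assert lb["exposure"].mean() < ub["exposure"].mean()

    def test_summary_partitions_population(self):
        strata = [
            DemographicStratum(age, sex, 100, 60.0, 5.0)
            for age in (1, 10, 40, 80)
            for sex in ("male", "female")
        ]
        residues = {"A": LognormalParams(np.log(0.002), 0.3)}
        intakes = [IntakeSpec("A", "LB", 30.0, 10.0)]
        table = run_exposure_scenario(strata, residues, intakes, "LB", seed=2, n_total=4000)
        summary = summarize_exposure(table).set_index("group")
        age_groups = [g for g in summary.index if g not in ("all", "male", "female")]
        assert summary.loc[age_groups, "n"].sum() == 4000
        assert summary.loc[["male", "female"], "n"].sum() == 4000
        assert summary.loc["all", "n"] == 4000
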