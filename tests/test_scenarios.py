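"""Scenario registry and data-generating process."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from rrsim.scenarios import (
    REGISTRY,
    ScenarioConstructionError,
    ScenarioSpec,
    SimulatedDataset,
    derive_intercept,
    draw_covariates,
    exposure_probability,
    fraction_exposed_at_max,
    get_scenario,
    outcome_probability,
    p_distribution_summary,
    registry_frame,
    rr2_scenarios,
    select_scenarios,
    simulate_dataset,
    unexposed_probability,
)


class TestRegistry:
    def test_all_28_scenarios_present_once(self):
        ids = [s.scenario_id for s in REGISTRY]
        assert len(ids) == 28
        assert len(set(ids)) == 28
        for family in ("I", "II", "III", "IV", "V", "VI", "VII"):
            assert sum(s.family == family for s in REGISTRY) == 4

    def test_variant1_untruncated(self):
        for spec in REGISTRY:
            assert (spec.variant == 1) == (spec.threshold == 0) == (spec.pct_at_max == 0)

    def test_log_link_max_probability_consistency(self):
        # inverse-link(intercept - threshold) * RR hits the design maximum
        # to the registry's 2-dp printing precision
        for spec in REGISTRY:
            if spec.link != "log":
                continue
            p_max = 3.0 * np.exp(spec.intercept - spec.threshold)
            assert p_max == pytest.approx(spec.max_p_exposed, abs=0.01)

    @pytest.mark.parametrize(
        "sid, expected",
        [("I-1", -1.38), ("I-2", -1.23), ("III-4", -0.55), ("VI-1", -0.76)],
    )
    def test_derive_intercept_matches_registry(self, sid, expected):
        spec = get_scenario(sid)
        derived = derive_intercept(spec.link, spec.max_p_exposed, 3.0, spec.threshold)
        assert derived == pytest.approx(expected, abs=0.01)

    def test_derive_intercept_probit_sign_exception(self):
        # the registry stores the printed -0.12 for VII-4; the derivation
        # gives +0.12 — a documented sign inconsistency, not silently fixed
        spec = get_scenario("VII-4")
        derived = derive_intercept("probit", 0.95, 3.0, 0.60)
        assert derived == pytest.approx(+0.12, abs=0.01)
        assert spec.intercept == -0.12

    def test_derive_intercept_rejects_degenerate_ratio(self):
        with pytest.raises(ValueError):
            derive_intercept("log", 1.5, 1.0, 0.0)

    def test_rr2_variants_only_families_iii_and_vii(self):
        arm = rr2_scenarios()
        assert len(arm) == 8
        assert {s.family for s in arm} == {"III", "VII"}
        assert all(s.true_rr == 2.0 for s in arm)
        with pytest.raises(ValueError):
            get_scenario("I-1", true_rr=2.0)

    def test_selection_globs(self):
        assert len(select_scenarios("all")) == 28
        assert [s.scenario_id for s in select_scenarios("III-*")] == [
            "III-1", "III-2", "III-3", "III-4",
        ]
        assert len(select_scenarios("III-*,VII-*")) == 8
        with pytest.raises(KeyError):
            select_scenarios("VIII-1")

    def test_registry_frame_roundtrip(self, tmp_path):
        frame = registry_frame()
        assert len(frame) == 28
        path = tmp_path / "registry.csv"
        frame.to_csv(path, index=False)
        assert path.read_text().count("\n") == 29


class TestProbabilities:
    def test_exposure_probability_values(self):
        assert exposure_probability(0, 0) == pytest.approx(0.26894, abs=1e-5)
        assert exposure_probability(1, 1) == pytest.approx(0.73106, abs=1e-5)

    def test_population_mean_exposure_is_half(self):
        rng = np.random.default_rng(11)
        z1, z2 = draw_covariates(10**6, rng)
        assert exposure_probability(z1, z2).mean() == pytest.approx(0.5, abs=0.002)

    def test_unexposed_probability_untruncated(self):
        spec = get_scenario("I-1")
        assert unexposed_probability(spec, 0, 0) == pytest.approx(
            np.exp(-1.38), abs=1e-12
        )

    def test_unexposed_probability_truncation_floor_active(self):
        # z1 + 3*z2 = 0.09 < 0.15, so the floor applies
        spec = get_scenario("I-2")
        assert unexposed_probability(spec, 0, 0.03) == pytest.approx(
            np.exp(-1.23 - 0.15), abs=1e-12
        )

    def test_truncation_tie_case(self):
        # index exactly at the threshold: max(t, t) = t, the floor applies
        # at equality (family IV so 2 * 0.05 = 0.10 is exact in binary)
        spec = get_scenario("IV-2")
        assert unexposed_probability(spec, 0, 0.05) == np.exp(spec.intercept - 0.10)

    @pytest.mark.parametrize(
        "sid, expected",
        [("I-1", 3 * np.exp(-1.38)), ("III-1", 3 * np.exp(-1.15))],
    )
    def test_outcome_probability_design_maximum(self, sid, expected):
        spec = get_scenario(sid)
        assert outcome_probability(spec, 1, 0, 0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(spec.max_p_exposed, abs=0.01)

    def test_unexposed_multiplier_is_one(self):
        spec = get_scenario("II-3")
        z2 = np.linspace(0, 1, 7)
        np.testing.assert_allclose(
            outcome_probability(spec, 0, 1, z2), unexposed_probability(spec, 1, z2)
        )

    def test_bad_custom_spec_raises(self):
        bad = ScenarioSpec(
            family="I", variant=1, link="log", intercept=-0.5, beta_z2=3,
            threshold=0.0, max_p_exposed=0.75, true_rr=3.0, pct_at_max=0.0,
        )
        with pytest.raises(ScenarioConstructionError):
            outcome_probability(bad, 1, 0, 0.0)

    @given(
        z1=st.integers(0, 1),
        z2=st.floats(0, 1),
        t_lo=st.floats(0, 0.5),
        t_hi=st.floats(0, 0.5),
    )
    def test_truncation_monotonicity(self, z1, z2, t_lo, t_hi):
        """Raising the floor can only lower the unexposed probability."""
        t_lo, t_hi = sorted((t_lo, t_hi))
        base = get_scenario("III-2")
        lo = dataclasses.replace(base, threshold=t_lo)
        hi = dataclasses.replace(base, threshold=t_hi)
        assert unexposed_probability(hi, z1, z2) <= unexposed_probability(lo, z1, z2)

    @given(z1=st.integers(0, 1), z2=st.floats(0, 1))
    def test_rr_identity_by_construction(self, z1, z2):
        spec = get_scenario("VII-3")
        p1 = outcome_probability(spec, 1, z1, z2)
        p0 = outcome_probability(spec, 0, z1, z2)
        assert p1 / p0 == pytest.approx(3.0, rel=1e-12)


class TestSimulation:
    def test_covariate_marginals(self):
        rng = np.random.default_rng(5)
        z1, z2 = draw_covariates(10**6, rng)
        assert set(np.unique(z1)) <= {0, 1}
        assert z2.min() >= 0 and z2.max() <= 1
        assert z1.mean() == pytest.approx(0.5, abs=0.002)
        assert z2.mean() == pytest.approx(0.5, abs=0.002)

    def test_draw_covariates_rejects_empty(self):
        with pytest.raises(ValueError):
            draw_covariates(0, np.random.default_rng(0))

    def test_simulate_dataset_reproducible(self):
        spec = get_scenario("III-1")
        a = simulate_dataset(spec, 500, 123)
        b = simulate_dataset(spec, 500, 123)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.z2, b.z2)
        c = simulate_dataset(spec, 500, 124)
        assert not np.array_equal(a.y, c.y)

    def test_p_true_bounds_and_conservation(self):
        spec = get_scenario("I-1")
        data = simulate_dataset(spec, 20_000, 3)
        assert np.all((data.p_true >= 0) & (data.p_true <= 1))
        # registry intercepts are printed to 2 dp, so the realised maximum is
        # 3*exp(alpha), within a cent of the design maximum
        assert data.p_true.max() <= 3 * np.exp(-1.38) + 1e-12
        assert data.p_true.max() <= spec.max_p_exposed + 0.01
        assert np.sum(data.y == 0) + np.sum(data.y == 1) == data.n

    def test_empirical_risk_ratio_near_three(self):
        # crude subgroup check: RR = 3 by construction
        data = simulate_dataset(get_scenario("III-1"), 10**6, 9)
        sub = (data.z1 == 0) & (data.z2 < 0.2)
        p1 = data.y[sub & (data.x == 1)].mean()
        p0 = data.y[sub & (data.x == 0)].mean()
        assert p1 / p0 == pytest.approx(3.0, rel=0.05)

    def test_csv_roundtrip(self, tmp_path):
        data = simulate_dataset(get_scenario("VI-2"), 100, 17)
        path = tmp_path / "cohort.csv"
        data.to_csv(path)
        back = SimulatedDataset.from_csv(path)
        assert back.scenario == data.scenario
        assert back.seed == 17
        np.testing.assert_array_equal(back.y, data.y)
        np.testing.assert_allclose(back.p_true, data.p_true)


class TestDesignCalibration:
    @pytest.mark.parametrize(
        "sid, expected", [("III-2", 1.4), ("I-2", 1.4), ("III-3", 2.8), ("III-4", 5.8)]
    )
    def test_fraction_exposed_at_max(self, sid, expected):
        frac = fraction_exposed_at_max(get_scenario(sid), n=400_000, seed=2)
        assert frac == pytest.approx(expected, abs=0.3)

    def test_untruncated_fraction_is_zero(self):
        assert fraction_exposed_at_max(get_scenario("II-1"), n=100, seed=0) == 0.0

    def test_p_distribution_spike_and_conservation(self):
        spec = get_scenario("III-4")
        summ = p_distribution_summary(spec, n=200_000, seed=4, bins=40)
        assert sum(summ.group_sizes.values()) == 200_000
        for grp in ("exposed", "unexposed"):
            assert summ.counts[grp].sum() == summ.group_sizes[grp]
        # spike of exposed subjects at the maximum probability ~ 5.8%
        assert summ.spike_pct["exposed"] == pytest.approx(5.8, abs=0.5)
        assert summ.p_max["exposed"] == pytest.approx(3 * np.exp(-0.55 - 0.60), abs=1e-9)

    def test_p_distribution_no_spike_untruncated(self):
        summ = p_distribution_summary(get_scenario("I-1"), n=10_000, seed=4)
        assert summ.spike_pct["exposed"] == 0.0
        assert summ.spike_pct["unexposed"] == 0.0
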