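"""Structure and statistical fidelity of the synthetic monitoring cohort."""

import dataclasses
import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from scalesia_csm import (
    CohortConfig,
    GrowthParams,
    SurvivalFixedEffects,
    SurvivalRandomEffects,
    death_hazard_from_marginal,
    generate_cohort,
)
from scalesia_csm.synthetic_cohort import (
    MIN_INITIAL_HEIGHT_CM,
    _truncnorm_rvs_matched,
    generate_cohort_frame,
    read_monitoring_csv,
    write_monitoring_csv,
)


class TestCohortStructure:
    def test_default_cohort_has_426_distinct_plants(self, default_frame):
        assert default_frame["plant_id"].nunique() == 426

    def test_generation_is_deterministic_for_a_fixed_seed(self):
        cfg = CohortConfig(n_plants=60, n_sites=3, seed=42)
        a = generate_cohort_frame(cfg)
        b = generate_cohort_frame(cfg)
        assert a.drop(columns="stem_circumferences").equals(
            b.drop(columns="stem_circumferences")
        )
        assert list(a["stem_circumferences"]) == list(b["stem_circumferences"])

    def test_record_count_is_at_study_scale_and_monotone_in_census_end(self):
        base = CohortConfig(seed=5)
        n_full = len(generate_cohort_frame(base))
        assert 3000 <= n_full <= 9000
        shorter = dataclasses.replace(base, census_end=dt.date(2021, 4, 30))
        assert len(generate_cohort_frame(shorter)) < n_full

    def test_height_present_iff_alive(self, default_frame):
        alive = default_frame["alive"]
        assert default_frame.loc[alive, "height"].notna().all()
        assert default_frame.loc[~alive, "height"].isna().all()

    def test_ages_are_nonnegative_and_dates_ordered(self, default_frame):
        assert (default_frame["age"] > 0).all()
        assert (default_frame["census_date"] > default_frame["planting_date"]).all()

    def test_absorbing_mode_death_is_permanent(self):
        cfg = CohortConfig(n_plants=300, n_sites=5, status_model="absorbing", seed=9)
        frame = generate_cohort_frame(cfg)
        for _, group in frame.groupby("plant_id"):
            status = group.sort_values("census_date")["alive"].to_numpy()
            assert not np.any(status[:-1] < status[1:])  # never dead -> alive

    def test_extreme_negative_age_slope_kills_every_plant_immediately(self):
        cfg = CohortConfig(
            n_plants=50,
            n_sites=3,
            status_model="absorbing",
            records_after_death=False,
            seed=1,
        )
        fixed = SurvivalFixedEffects(age_slope=-1e6)
        frame = generate_cohort_frame(cfg, None, fixed, SurvivalRandomEffects(0.0, 0.0))
        # every plant appears exactly once, as a death at its first census
        assert len(frame) == 50
        assert not frame["alive"].any()

    def test_records_list_interface_matches_frame(self):
        cfg = CohortConfig(n_plants=20, n_sites=2, seed=3)
        records = generate_cohort(cfg)
        frame = generate_cohort_frame(cfg)
        assert len(records) == len(frame)
        assert records[0].plant_id == frame["plant_id"].iloc[0]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_plants": 0},
            {"treatment_allocation": {}},
            {"treatment_allocation": {"Cocoon": 0.4, "Control": 0.4}},
            {"island_split": {"Santa Cruz": 1.2, "Floreana": -0.2}},
            {"monitoring_interval_months": 0},
            {"init_height_sd": -1.0},
            {"status_model": "zombie"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)


class TestInitialHeights:
    def test_truncated_draws_match_the_stated_moments(self):
        rng = np.random.default_rng(12345)
        h = _truncnorm_rvs_matched(rng, 20000, 35.52, 14.63, MIN_INITIAL_HEIGHT_CM)
        n = len(h)
        assert h.min() >= MIN_INITIAL_HEIGHT_CM
        assert abs(h.mean() - 35.52) < 3 * 14.63 / np.sqrt(n)
        assert abs(h.std(ddof=1) - 14.63) < 3 * 14.63 / np.sqrt(2 * n)


class TestDeathHazard:
    @pytest.mark.parametrize(
        "p_t, p_prev, expected",
        [(0.7, 0.7, 0.0), (0.0, 0.5, 1.0), (0.45, 0.9, 0.5)],
    )
    def test_known_values(self, p_t, p_prev, expected):
        assert death_hazard_from_marginal(p_t, p_prev) == pytest.approx(expected)

    def test_undefined_for_zero_previous_survival(self):
        with pytest.raises(ValueError, match="undefined"):
            death_hazard_from_marginal(0.1, 0.0)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=1e-6, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_result_is_a_probability(self, p_t, p_prev):
        assert 0.0 <= death_hazard_from_marginal(p_t, p_prev) <= 1.0


class TestMarginalSurvival:
    def _single_cohort_config(self, **kwargs):
        return CohortConfig(
            n_plants=10000,
            n_sites=kwargs.pop("n_sites", 4),
            treatment_allocation={"Cocoon": 0.5, "Control": 0.5},
            planting_window=(dt.date(2013, 5, 1), dt.date(2013, 5, 1)),
            census_end=dt.date(2017, 6, 1),
            **kwargs,
        )

    def test_hazard_generation_reproduces_the_marginal_curve_without_frailty(self):
        """10k plants, var=0: survivor fraction at age 4 equals the inverse logit."""
        cfg = self._single_cohort_config(status_model="absorbing", seed=3)
        fixed = SurvivalFixedEffects(
            treatment_contrasts={"Cocoon": 0.0, "Control": -0.223}
        )
        frame = generate_cohort_frame(cfg, None, fixed, SurvivalRandomEffects(0.0, 0.0))
        for treatment, contrast in (("Cocoon", 0.0), ("Control", -0.223)):
            sub = frame[frame["treatment"] == treatment]
            for target_age in (1.0, 4.0):
                ages = np.sort(sub["age"].unique())
                a = ages[np.argmin(np.abs(ages - target_age))]
                at_age = sub[sub["age"] == a]
                emp = at_age["alive"].mean()
                marginal = expit(3.932 + contrast - 0.234 * a)
                tol = 3 * np.sqrt(marginal * (1 - marginal) / len(at_age))
                assert abs(emp - marginal) < tol

    def test_population_survival_with_frailty_matches_the_integrated_marginal(self):
        """With random intercepts the marginal is the Gauss-Hermite integral."""
        cfg = self._single_cohort_config(
            n_sites=400, status_model="absorbing", seed=8
        )
        fixed = SurvivalFixedEffects(treatment_contrasts={"Cocoon": 0.0, "Control": 0.0})
        rand = SurvivalRandomEffects()  # default 0.812 / 0.994
        frame = generate_cohort_frame(cfg, None, fixed, rand)
        sigma = np.sqrt(rand.var_plant + rand.var_site)
        x, w = np.polynomial.hermite.hermgauss(60)
        ages = np.sort(frame["age"].unique())
        a = ages[np.argmin(np.abs(ages - 4.0))]
        at_age = frame[frame["age"] == a]
        emp = at_age["alive"].mean()
        eta = 3.932 - 0.234 * a
        oracle = float(np.sum(w * expit(eta + np.sqrt(2) * sigma * x)) / np.sqrt(np.pi))
        assert abs(emp - oracle) < 0.025


class TestCsvRoundTrip:
    def test_monitoring_table_round_trips_exactly(self, tmp_path, small_frame):
        path = tmp_path / "monitoring.csv"
        write_monitoring_csv(small_frame, path)
        back = read_monitoring_csv(path)
        assert back.drop(columns="stem_circumferences").equals(
            small_frame.drop(columns="stem_circumferences")
        )
        assert list(back["stem_circumferences"]) == list(small_frame["stem_circumferences"])


class TestGrowthParams:
    def test_mean_height_is_nondecreasing_and_capped(self):
        growth = GrowthParams()
        ages = np.linspace(0, 30, 400)
        h = growth.mean_height(ages)
        assert np.all(np.diff(h) >= -1e-12)
        assert h.max() <= 1500.0

    def test_asymptote_above_cap_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(asymptotic_height=2000.0)
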