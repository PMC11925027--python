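"""Single-replicate engine: pipeline rules, invariants, oracle equivalence."""

import numpy as np
import pytest

import vivforecast as vf
from vivforecast.engine import cohort_rng, penetration_rng

from _oracle import brute_force_forecast, random_degenerate_config
from conftest import stochastic_config


def forecast_as_dicts(f: vf.AnnualViVForecast) -> dict[str, dict[int, int]]:
    years = [int(y) for y in f.years]
    return {
        "TAVR": dict(zip(years, (int(c) for c in f.tavr_in_tavr))),
        "SAVR": dict(zip(years, (int(c) for c in f.tavr_in_savr))),
    }


class TestSimulateCohort:
    def test_empty_cohort(self, default_cfg):
        ev = vf.simulate_cohort(2000, "TAVR", 0, default_cfg, cohort_rng(1, "TAVR", 2000))
        assert ev.n_patients == 0
        assert ev.candidate_failure_years().size == 0

    def test_degenerate_all_candidates_fail_in_2005(self):
        cfg = vf.degenerate_config({2000: 100}, tavr_durability=5.0,
                                   survival_intermediate_high=10.0)
        ev = vf.simulate_cohort(2000, "TAVR", 100, cfg, cohort_rng(1, "TAVR", 2000))
        assert ev.candidate.all()
        assert (ev.failure_year == 2005).all()

    def test_durability_beyond_survival_removes_all_candidates(self):
        # valve outlives the patient -> no ViV candidates
        cfg = vf.degenerate_config({2000: 100}, tavr_durability=10.0,
                                   survival_intermediate_high=6.0)
        ev = vf.simulate_cohort(2000, "TAVR", 100, cfg, cohort_rng(1, "TAVR", 2000))
        assert not ev.candidate.any()
        assert ev.n_patients == 100  # retained for audit, flagged

    def test_failure_year_rounding_switch(self):
        cfg = vf.degenerate_config({2000: 10}, tavr_durability=5.6,
                                   survival_intermediate_high=20.0)
        ev = vf.simulate_cohort(2000, "TAVR", 10, cfg, cohort_rng(1, "TAVR", 2000))
        assert (ev.failure_year == 2005).all()  # floor
        cfg.failure_year_rounding = "half_up"
        ev = vf.simulate_cohort(2000, "TAVR", 10, cfg, cohort_rng(1, "TAVR", 2000))
        assert (ev.failure_year == 2006).all()


class TestApplyPenetration:
    def test_zero_everywhere(self):
        sched = vf.PenetrationSchedule.constant(0.0, 0.0)
        out = vf.apply_penetration({2005: 100, 2006: 50}, "TAVR", sched,
                                   penetration_rng(1, "TAVR"))
        assert out == {2005: 0, 2006: 0}

    def test_one_everywhere_is_identity(self):
        sched = vf.PenetrationSchedule.constant(1.0, 1.0)
        out = vf.apply_penetration({2005: 100, 2006: 50}, "TAVR", sched,
                                   penetration_rng(1, "TAVR"))
        assert out == {2005: 100, 2006: 50}

    def test_binomial_thinning_within_four_se(self):
        # 10,000 SAVR-failure candidates at 60% penetration: SE ~= 49
        sched = vf.PenetrationSchedule.constant(0.0, 0.60)
        out = vf.apply_penetration({2020: 10_000}, "SAVR", sched,
                                   penetration_rng(3, "SAVR"))
        assert abs(out[2020] - 6000) < 4 * 49


class TestSubtractRedo:
    def test_zero_redo_is_identity(self):
        out = vf.subtract_redo({2005: 100}, "SAVR", vf.RedoSurgerySeries())
        assert out == {2005: 100}

    def test_subtraction_and_clamp(self):
        redo = vf.RedoSurgerySeries(savr_after_savr={2005: 30, 2006: 25})
        out = vf.subtract_redo({2005: 100, 2006: 10}, "SAVR", redo)
        assert out == {2005: 70, 2006: 0}

    def test_redo_kind_matches_failure_type(self):
        redo = vf.RedoSurgerySeries(savr_after_savr={2005: 99},
                                    savr_after_tavr={2005: 1})
        out = vf.subtract_redo({2005: 10}, "TAVR", redo)
        assert out == {2005: 9}  # only the SAVR-after-TAVR count applies


class TestRunSingleReplicate:
    def test_degenerate_full_pipeline(self):
        cfg = vf.degenerate_config({2000: 100}, tavr_durability=5.0,
                                   survival_intermediate_high=10.0)
        f = vf.run_single_replicate(cfg, 1)
        d = forecast_as_dicts(f)
        assert d["TAVR"][2005] == 100
        assert sum(d["TAVR"].values()) == 100
        assert sum(d["SAVR"].values()) == 0

    def test_zero_penetration_gives_all_zeros(self):
        cfg = vf.degenerate_config({2000: 100}, penetration_tavr=0.0,
                                   penetration_savr=0.0)
        f = vf.run_single_replicate(cfg, 1)
        assert f.total_viv.sum() == 0

    def test_death_before_failure_gives_all_zeros(self):
        cfg = vf.degenerate_config({2000: 100}, tavr_durability=5.0,
                                   survival_intermediate_high=3.0)
        f = vf.run_single_replicate(cfg, 1)
        assert f.total_viv.sum() == 0

    def test_total_is_sum_of_categories(self):
        cfg = stochastic_config()
        f = vf.run_single_replicate(cfg, 99)
        assert (f.total_viv == f.tavr_in_savr + f.tavr_in_tavr).all()
        assert (f.total_viv >= 0).all()

    def test_conservation_no_patient_returns_twice(self):
        cfg = stochastic_config()
        f = vf.run_single_replicate(cfg, 42)
        assert f.tavr_in_tavr.sum() <= sum(cfg.tavr_volumes.counts.values())
        assert f.tavr_in_savr.sum() <= sum(cfg.savr_volumes.counts.values())

    def test_determinism_bit_identical(self):
        cfg = stochastic_config()
        a = vf.run_single_replicate(cfg, 7)
        b = vf.run_single_replicate(cfg, 7)
        assert (a.tavr_in_savr == b.tavr_in_savr).all()
        assert (a.tavr_in_tavr == b.tavr_in_tavr).all()
        c = vf.run_single_replicate(cfg, 8)
        assert (a.total_viv != c.total_viv).any()

    def test_redo_order_switch_changes_little_but_runs(self):
        cfg = stochastic_config()
        cfg.redo_before_penetration = False
        f = vf.run_single_replicate(cfg, 7)
        assert (f.total_viv >= 0).all()


class TestMonotonicity:
    @pytest.mark.parametrize("failure_type,anchor_index", [
        ("TAVR", 0), ("TAVR", 1), ("SAVR", 0), ("SAVR", 1),
    ])
    def test_raising_any_penetration_anchor_never_decreases_counts(
        self, failure_type, anchor_index
    ):
        cfg = stochastic_config()
        base = vf.run_single_replicate(cfg, 123)
        anchors = (cfg.penetration.tavr_failure if failure_type == "TAVR"
                   else cfg.penetration.savr_failure)
        raised = min(1.0, anchors[anchor_index][1] + 0.25)
        cfg.penetration = cfg.penetration.with_anchor(failure_type, anchor_index, raised)
        bumped = vf.run_single_replicate(cfg, 123)  # common random numbers
        assert (bumped.tavr_in_tavr >= base.tavr_in_tavr).all()
        assert (bumped.tavr_in_savr >= base.tavr_in_savr).all()


class TestOracleEquivalence:
    def test_engine_matches_brute_force_on_degenerate_scenarios(self):
        rng = np.random.default_rng(2024)
        for _ in range(5):
            cfg = random_degenerate_config(rng)
            engine = forecast_as_dicts(vf.run_single_replicate(cfg, cfg.master_seed))
            oracle = brute_force_forecast(cfg)
            assert engine == oracle
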