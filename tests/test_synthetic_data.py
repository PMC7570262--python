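from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from seedfate.packet_model import DesignRow, ExperimentDesign, records_to_frame
from seedfate.presets import calibrated_targets, default_scenario, table1_design
from seedfate.survival import stratum_survival
from seedfate.synthetic_data import (
    FateScenario,
    StratumHazards,
    hazards_from_pools,
    parameter_recovery_study,
    scenario_from_pools,
    simulate_experiment,
)


def one_stratum_scenario(hazards: StratumHazards, n_packets=12, seeds=20, seed=0,
                         **kwargs) -> FateScenario:
    design = ExperimentDesign(
        rows=(DesignRow("sp", "2015", n_packets, seeds),),
        microhabitats=("control",),
        collection_years=("2017", "2018"),
    )
    return FateScenario(
        design=design, hazards={("sp", "2015", "control"): hazards},
        rng_seed=seed, **kwargs,
    )


class TestSimulate:
    def test_no_hazard_everything_survives(self):
        scenario = one_stratum_scenario(StratumHazards((0.0, 0.0), (0.0, 0.0)))
        for rec in simulate_experiment(scenario):
            assert rec.n_retained == rec.seeds_sown
            assert rec.n_assayed == rec.n_retained
            assert rec.n_stained == rec.n_assayed
        ests = stratum_survival(simulate_experiment(scenario), ["species"])
        assert ests[0].survival == 1.0

    def test_same_seed_bit_identical(self, tiny_scenario):
        a = records_to_frame(simulate_experiment(tiny_scenario))
        b = records_to_frame(simulate_experiment(tiny_scenario))
        assert a.equals(b)

    def test_strata_are_independent_substreams(self, tiny_scenario):
        before = [r for r in simulate_experiment(tiny_scenario) if r.species == "sp_a"]
        altered = dataclasses.replace(
            tiny_scenario,
            hazards={
                **tiny_scenario.hazards,
                ("sp_b", "2015", "control"): StratumHazards((0.9, 0.9), (0.0, 0.0)),
            },
        )
        after = [r for r in simulate_experiment(altered) if r.species == "sp_a"]
        assert before == after

    def test_indivisible_design_rejected_naming_row(self):
        with pytest.raises(Exception, match="10"):
            ExperimentDesign(
                rows=(DesignRow("sp", "2015", 10, 5),),
                microhabitats=("control", "runoff", "shade"),
            )

    def test_retention_monotone_in_expend_hazard(self):
        """Raising p_expend weakly lowers simulated retention (seeded grid)."""
        retained = []
        for pe in (0.1, 0.3, 0.5, 0.7, 0.9):
            scenario = one_stratum_scenario(
                StratumHazards((pe, pe), (0.05, 0.05)), n_packets=40, seeds=30, seed=4
            )
            recs = simulate_experiment(scenario)
            year1 = [r for r in recs if r.burial_seasons == 1]
            retained.append(
                sum(r.n_retained for r in year1) / sum(r.seeds_sown for r in year1)
            )
        assert all(x >= y for x, y in zip(retained, retained[1:]))

    def test_pool_frequencies_converge_at_root_n_rate(self):
        hz = StratumHazards((0.4, 0.3), (0.2, 0.1))
        errors = {}
        for n_packets, seeds in ((8, 10), (128, 40)):
            scenario = one_stratum_scenario(hz, n_packets=n_packets, seeds=seeds, seed=9)
            recs = [r for r in simulate_experiment(scenario) if r.burial_seasons == 1]
            est = sum(r.n_retained for r in recs) / sum(r.seeds_sown for r in recs)
            truth = scenario.implied_pools("sp", "2015", "control", 1)["retained"]
            errors[n_packets * seeds] = abs(est - truth)
        n_small, n_big = sorted(errors)
        # error at 64x the sample size should drop by ~8; allow generous slack
        assert errors[n_big] < errors[n_small] + 3 * np.sqrt(0.25 / n_small)
        assert errors[n_big] < 3 * np.sqrt(0.25 / n_big)


class TestCalibration:
    def test_single_season_inversion_by_hand(self):
        hz = hazards_from_pools(retained=(0.5, 0.25), staining=(0.5, 0.5))
        assert hz.p_expend[0] == pytest.approx(0.5)
        assert hz.p_die[0] == pytest.approx(0.25)  # dead intact = 0.5 * (1 - 0.5)

    def test_round_trip_recovers_targets_exactly(self):
        targets = calibrated_targets()
        scenario = scenario_from_pools(table1_design(), targets)
        for (sp, co, mi), spec in targets.items():
            for season in (1, 2):
                pools = scenario.implied_pools(sp, co, mi, season)
                assert pools["retained"] == pytest.approx(
                    spec["retained"][season - 1], abs=1e-12
                )
                assert pools["staining_rate"] == pytest.approx(
                    spec["staining"][season - 1], abs=1e-12
                )

    def test_rising_staining_rate_needs_selective_dead_decay(self):
        hz = hazards_from_pools(retained=(0.4, 0.2), staining=(0.5, 0.8))
        assert hz.p_expend_dead is not None
        assert hz.p_expend_dead[1] > hz.p_expend[1]

    def test_infeasible_orderings_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            hazards_from_pools(retained=(0.3, 0.5), staining=(0.5, 0.5))
        with pytest.raises(ValueError, match="retained-live"):
            hazards_from_pools(retained=(0.4, 0.4), staining=(0.2, 0.9))

    def test_calibrated_rare_year1_pools_at_full_scale(self):
        """Pooled year-1 estimates track the generating pool values."""
        scenario = default_scenario(rng_seed=77)
        recs = [
            r
            for r in simulate_experiment(scenario)
            if r.species == "E_mohavense" and r.burial_seasons == 1
        ]
        sown = sum(r.seeds_sown for r in recs)
        expended = sum(r.n_expended for r in recs) / sown
        assayed = sum(r.n_assayed for r in recs)
        staining = sum(r.n_stained for r in recs) / assayed
        se_e = np.sqrt(0.673 * 0.327 / sown)
        se_s = np.sqrt(0.49 * 0.51 / assayed)
        assert expended == pytest.approx(0.673, abs=3 * se_e)
        assert staining == pytest.approx(0.490, abs=3 * se_s)


class TestRecoveryStudy:
    def test_two_replicates_suppresses_flags_with_warning(self, tiny_scenario):
        with pytest.warns(UserWarning, match="suppressed"):
            table = parameter_recovery_study(tiny_scenario, n_replicates=2, seed=1)
        assert not table["survival_flagged"].any()

    def test_variance_ordering_small_packets_noisier(self):
        scenario = default_scenario(assay_fraction=1.0)
        table = parameter_recovery_study(scenario, n_replicates=25, seed=3)
        sd = table.set_index(["species", "cohort", "burial_seasons", "microhabitat"])
        noisy = sd.loc[("E_wallacei", "2016", 1, "control"), "survival_sd"]
        tight = sd.loc[("E_mohavense", "2015", 1, "control"), "survival_sd"]
        assert noisy > tight

    def test_replicate_count_validated(self, tiny_scenario):
        with pytest.raises(ValueError):
            parameter_recovery_study(tiny_scenario, n_replicates=1, seed=0)
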