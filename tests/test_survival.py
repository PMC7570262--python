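from __future__ import annotations

import numpy as np
import pytest

from seedfate._round import round_half_up
from seedfate.survival import (
    SurvivalEstimate,
    aggregate_survival,
    bootstrap_survival_ci,
    estimate_from_counts,
    product_of_means,
    stratum_survival,
    survival_decline,
    survival_estimate,
)


def printed(group, survival_pct, pl=None, ps=None):
    """An estimate constructed from report-level (already rounded) values."""
    return SurvivalEstimate(
        group=group, pl=pl, ps=ps, survival=survival_pct / 100.0, aggregated=True
    )


class TestProduct:
    def test_identity_and_absorbing_zero(self):
        assert survival_estimate(1.0, 1.0) == 1.0
        assert survival_estimate(0.5, 0.0) == 0.0

    def test_product_of_published_rare_year2_rates(self):
        assert survival_estimate(0.16, 0.623) == pytest.approx(0.09968)

    @pytest.mark.parametrize("pl, ps", [(-0.1, 0.5), (0.5, 1.2), (2.0, 2.0)])
    def test_domain_errors(self, pl, ps):
        with pytest.raises(ValueError):
            survival_estimate(pl, ps)


class TestFromCounts:
    def test_counts_to_rates(self):
        est = estimate_from_counts({"g": 1}, 100, 40, 20, 8)
        assert est.pl == pytest.approx(0.40)
        assert est.ps == pytest.approx(0.40)
        assert est.survival == pytest.approx(0.16)

    def test_unrecovered_excluded_from_denominator(self, small_records):
        # pkt-001 modified: 10 sown, 6 expended, 3 retained, 1 unrecovered
        from seedfate.packet_model import PacketRecord

        rec = PacketRecord("p", "sp", "2015", "s", "1", "control", 1, "2017",
                           10, 6, 3, 3, 2)
        est = stratum_survival([rec], ["species"])[0]
        assert est.pl == pytest.approx(3 / 9)

    def test_retained_but_unassayed_is_an_error(self):
        with pytest.raises(ValueError, match="none assayed"):
            estimate_from_counts({}, 100, 40, 0, 0)

    def test_nothing_retained_gives_zero_survival(self):
        est = estimate_from_counts({}, 100, 0, 0, 0)
        assert est.survival == 0.0 and est.ps is None


class TestAggregation:
    def test_cross_species_year2_shade_mean(self):
        ests = [printed({"species": "rare"}, 14.0), printed({"species": "common"}, 5.3)]
        agg = aggregate_survival(ests, over=["species"])[0]
        assert agg.survival_pct == pytest.approx(9.65)
        assert round_half_up(agg.survival_pct, 1) == 9.7

    def test_cross_species_year2_control_mean(self):
        ests = [printed({"species": "rare"}, 5.6), printed({"species": "common"}, 1.0)]
        agg = aggregate_survival(ests, over=["species"])[0]
        assert round_half_up(agg.survival_pct, 1) == 3.3

    def test_mean_of_identical_values(self):
        ests = [printed({"species": s}, 7.7) for s in "abc"]
        agg = aggregate_survival(ests, over=["species"])[0]
        assert agg.survival_pct == pytest.approx(7.7)
        assert agg.n_strata == 3

    def test_order_invariance(self, calibrated_records):
        ests = stratum_survival(calibrated_records)
        fwd = aggregate_survival(ests, over=["cohort", "microhabitat"])
        rev = aggregate_survival(ests[::-1], over=["cohort", "microhabitat"])
        assert [(e.group, e.survival) for e in fwd] == [
            (e.group, e.survival) for e in rev
        ]

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            aggregate_survival([], over=["species"])

    def test_product_of_means_differs_from_mean_of_products(self):
        a = SurvivalEstimate({"g": "a"}, pl=0.9, ps=0.1, survival=0.09)
        b = SurvivalEstimate({"g": "b"}, pl=0.1, ps=0.9, survival=0.09)
        pooled = product_of_means([a, b])
        headline = aggregate_survival([a, b], over=["g"])[0].survival
        assert pooled == pytest.approx(0.25)
        assert headline == pytest.approx(0.09)
        assert abs(pooled - headline) > 0.1


class TestDecline:
    def test_no_decline_when_equal(self):
        assert survival_decline(0.25, 0.25) == 0.0

    def test_control_decline_from_one_decimal_inputs(self):
        assert survival_decline(18.9, 3.3) == pytest.approx(82.54, abs=0.01)

    def test_shade_decline_from_one_decimal_inputs(self):
        assert survival_decline(21.7, 9.7) == pytest.approx(55.3, abs=0.05)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            survival_decline(0.0, 0.0)


class TestBootstrap:
    def test_interval_brackets_point_estimate_and_is_deterministic(
        self, calibrated_records
    ):
        year1 = [r for r in calibrated_records
                 if r.burial_seasons == 1 and r.species == "E_mohavense"]
        ci = bootstrap_survival_ci(
            year1, grouping=["species"], n_resamples=300, seed=5
        )
        row = ci.iloc[0]
        assert row.ci_low <= row.survival <= row.ci_high
        ci2 = bootstrap_survival_ci(
            year1, grouping=["species"], n_resamples=300, seed=5
        )
        assert np.allclose(ci[["ci_low", "ci_high"]], ci2[["ci_low", "ci_high"]])


class TestConvergenceToTruth:
    def test_stratum_estimates_near_generating_probabilities(
        self, calibrated_records
    ):
        """Group survival converges on P(retained and live at collection)."""
        from seedfate.presets import default_scenario

        scenario = default_scenario()
        ests = stratum_survival(calibrated_records)
        checked = 0
        for est in ests:
            g = est.group
            if g["species"] != "E_mohavense" or g["cohort"] != "2015":
                continue
            truth = scenario.implied_pools(
                g["species"], g["cohort"], g["microhabitat"], g["burial_seasons"]
            )
            n = est.n_recovered
            se = np.sqrt(truth["survival"] * (1 - truth["survival"]) / n)
            assert abs(est.survival - truth["survival"]) < 4 * se + 0.02
            checked += 1
        assert checked == 6
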