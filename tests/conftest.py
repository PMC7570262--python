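from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from seedfate.packet_model import DesignRow, ExperimentDesign, PacketRecord
from seedfate.presets import default_scenario
from seedfate.synthetic_data import FateScenario, StratumHazards


@pytest.fixture
def small_records() -> list[PacketRecord]:
    """Three hand-written packets with easily hand-checked counts."""
    return [
        PacketRecord("pkt-001", "sp_a", "2015", "s1", "p1", "control", 1, "2017",
                     seeds_sown=10, n_expended=6, n_retained=4, n_assayed=4, n_stained=2),
        PacketRecord("pkt-002", "sp_a", "2015", "s1", "p2", "control", 1, "2017",
                     seeds_sown=10, n_expended=8, n_retained=2, n_assayed=2, n_stained=1),
        PacketRecord("pkt-003", "sp_a", "2015", "s1", "p1", "shade", 1, "2017",
                     seeds_sown=10, n_expended=2, n_retained=8, n_assayed=4, n_stained=3),
    ]


@pytest.fixture
def tiny_scenario() -> FateScenario:
    """A 24-packet, two-stratum scenario for fast end-to-end tests."""
    design = ExperimentDesign(
        rows=(DesignRow("sp_a", "2015", 12, 10), DesignRow("sp_b", "2015", 12, 10)),
        microhabitats=("control", "shade"),
        collection_years=("2017", "2018"),
    )
    hazards = {}
    for species, pe in (("sp_a", 0.5), ("sp_b", 0.2)):
        for micro in ("control", "shade"):
            hazards[(species, "2015", micro)] = StratumHazards(
                p_expend=(pe, pe), p_die=(0.1, 0.1)
            )
    return FateScenario(design=design, hazards=hazards, rng_seed=11)


@pytest.fixture(scope="session")
def calibrated_records():
    """One full-scale simulated experiment from the calibrated scenario."""
    from seedfate.synthetic_data import simulate_experiment

    return simulate_experiment(default_scenario(rng_seed=20150929))
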