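"""Default experiment design and calibrated fate scenario.

The design reproduces the real allocation: 540 packets and 4860 seeds in
four species x cohort rows (rare species: 90 packets x 18 seeds and
180 x 9; common species: 90 x 14 and 180 x 2), split into even thirds
over the three microhabitats and even halves over the two collection
years.

The default scenario pins each stratum's closed-form pools to the
reported pool percentages:

* year 1, both cohorts, no microhabitat effect —
  rare: retained 32.7%, staining 49.0%; common: retained 82.7%,
  staining 31.1%;
* year 2, staining unaffected by microhabitat (rare 62.3%, common
  11.4%) with microhabitat acting through retention, back-computed from
  the species x microhabitat survival percentages
  (rare: 5.6 / 9.6 / 14.0; common: 1.0 / 0.3 / 5.3 for
  control / runoff / shade).

Cohorts share one calibration (no per-cohort pool values are available
to separate them).
"""

from __future__ import annotations

from .packet_model import DesignRow, ExperimentDesign
from .schema import MICROHABITATS
from .synthetic_data import FateScenario, scenario_from_pools

RARE = "E_mohavense"
COMMON = "E_wallacei"
COHORTS = ("2015", "2016")

#: The published packet allocation: (species, cohort, packets, seeds/packet).
TABLE1_ROWS = (
    (RARE, "2015", 90, 18),
    (RARE, "2016", 180, 9),
    (COMMON, "2015", 90, 14),
    (COMMON, "2016", 180, 2),
)

#: Species-level year-1 pools (retained of sown; staining among retained).
YEAR1_POOLS = {
    RARE: {"retained": 0.327, "staining": 0.490},
    COMMON: {"retained": 0.827, "staining": 0.311},
}

#: Species-level year-2 staining rates (microhabitat-independent).
YEAR2_STAINING = {RARE: 0.623, COMMON: 0.114}

#: Species x microhabitat year-2 survival (proportion of the seed bank).
YEAR2_SURVIVAL = {
    RARE: {"control": 0.056, "runoff": 0.096, "shade": 0.140},
    COMMON: {"control": 0.010, "runoff": 0.003, "shade": 0.053},
}


def table1_design() -> ExperimentDesign:
    return ExperimentDesign(
        rows=tuple(DesignRow(*row) for row in TABLE1_ROWS),
        microhabitats=MICROHABITATS,
        collection_years=("2017", "2018"),
    )


def calibrated_targets() -> dict[tuple[str, str, str], dict[str, tuple[float, float]]]:
    """Per-stratum (retained, staining) targets for seasons 1 and 2."""
    targets = {}
    for species in (RARE, COMMON):
        r1 = YEAR1_POOLS[species]["retained"]
        ps1 = YEAR1_POOLS[species]["staining"]
        ps2 = YEAR2_STAINING[species]
        for cohort in COHORTS:
            for micro in MICROHABITATS:
                r2 = YEAR2_SURVIVAL[species][micro] / ps2
                targets[(species, cohort, micro)] = {
                    "retained": (r1, r2),
                    "staining": (ps1, ps2),
                }
    return targets


def default_scenario(
    rng_seed: int = 0,
    assay_fraction: float = 0.5,
    plots_per_site: int = 9,
) -> FateScenario:
    """The calibrated full-scale scenario (540 packets, 4860 seeds)."""
    return scenario_from_pools(
        table1_design(),
        calibrated_targets(),
        rng_seed=rng_seed,
        assay_fraction=assay_fraction,
        plots_per_site=plots_per_site,
    )
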