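"""Multistate simulator for buried seed packet experiments.

Each sown seed starts live with probability ``initial_viability`` and
then evolves season by season through three states: live intact, dead
intact, and expended (germinated or decayed — gone from the packet).
Per stratum (species x cohort x microhabitat) and season ``s``:

* a live intact seed is expended with probability ``p_expend[s]``, dies
  in place with ``p_die[s]``, and otherwise stays live intact;
* a dead intact seed is expended with ``p_expend_dead[s]`` (defaults to
  the live rate: seed-coat decay is viability-blind unless stated).

At collection, intact seeds form the retained pool; a seeded random
subsample of ``assay_fraction`` of them is assayed, and the stain
outcome is Bernoulli(sensitivity) for live seeds and
Bernoulli(1 - specificity) for dead ones.  The closed-form pool
probabilities implied by these hazards are available for calibration and
for bias checks, and :func:`scenario_from_pools` inverts them so a
scenario can be pinned to observed pool percentages.

Randomness: one root seed; each stratum draws from its own substream
keyed by a CRC of its labels, so adding or removing a stratum never
perturbs the others.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._round import round_half_up
from .packet_model import ExperimentDesign, PacketRecord


@dataclass(frozen=True)
class StratumHazards:
    """Per-season transition probabilities for one stratum.

    ``p_expend[s]`` and ``p_die[s]`` apply to live intact seeds in season
    ``s`` (0-indexed); ``p_expend_dead`` applies to dead intact seeds and
    defaults to ``p_expend``.
    """

    p_expend: tuple[float, ...]
    p_die: tuple[float, ...]
    p_expend_dead: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.p_expend) != len(self.p_die):
            raise ValueError("p_expend and p_die must cover the same seasons")
        for s, (pe, pd_) in enumerate(zip(self.p_expend, self.p_die)):
            if not (0 <= pe <= 1 and 0 <= pd_ <= 1 and pe + pd_ <= 1):
                raise ValueError(
                    f"season {s + 1}: need p_expend, p_die >= 0 with sum <= 1, "
                    f"got {pe}, {pd_}"
                )
        if self.p_expend_dead is not None:
            for s, pc in enumerate(self.p_expend_dead):
                if not 0 <= pc <= 1:
                    raise ValueError(f"season {s + 1}: p_expend_dead out of [0, 1]")

    def dead_rates(self) -> tuple[float, ...]:
        return self.p_expend_dead if self.p_expend_dead is not None else self.p_expend


@dataclass(frozen=True)
class FateScenario:
    """A complete simulated experiment: design, hazards, and assay plan."""

    design: ExperimentDesign
    hazards: dict[tuple[str, str, str], StratumHazards]  # (species, cohort, microhabitat)
    initial_viability: float = 1.0
    assay_fraction: float = 1.0
    stain_sensitivity: float = 1.0
    stain_specificity: float = 1.0
    rng_seed: int = 0
    plots_per_site: int = 9
    lost_locations: frozenset[tuple] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("initial_viability", "stain_sensitivity", "stain_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.assay_fraction <= 1.0:
            raise ValueError("assay_fraction must be in (0, 1]")

    def stratum_hazards(self, species: str, cohort: str, micro: str) -> StratumHazards:
        try:
            return self.hazards[(species, cohort, micro)]
        except KeyError:
            raise KeyError(
                f"no hazards for stratum ({species}, {cohort}, {micro})"
            ) from None

    def implied_pools(
        self, species: str, cohort: str, micro: str, seasons: int
    ) -> dict[str, float]:
        """Closed-form pool probabilities after ``seasons`` seasons.

        Returns retained, retained-live and retained-dead probabilities
        (per sown seed), the staining-positive probability among retained
        seeds given assay sensitivity/specificity, and the survival
        product they imply.
        """
        hz = self.stratum_hazards(species, cohort, micro)
        live = self.initial_viability
        dead = 1.0 - self.initial_viability
        dead_rates = hz.dead_rates()
        for s in range(seasons):
            new_dead = dead * (1.0 - dead_rates[s]) + live * hz.p_die[s]
            live = live * (1.0 - hz.p_expend[s] - hz.p_die[s])
            dead = new_dead
        retained = live + dead
        if retained > 0:
            p_stain = (
                live * self.stain_sensitivity
                + dead * (1.0 - self.stain_specificity)
            ) / retained
        else:
            p_stain = 0.0
        return {
            "retained": retained,
            "retained_live": live,
            "retained_dead": dead,
            "expended": 1.0 - retained,
            "staining_rate": p_stain,
            "survival": retained * p_stain,
        }


def _stratum_rng(root_seed: int, key: tuple[str, str, str]) -> np.random.Generator:
    crc = zlib.crc32("|".join(key).encode())
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(crc,)))


def simulate_experiment(scenario: FateScenario) -> list[PacketRecord]:
    """Simulate one packet experiment; identical seed gives identical output.

    Packets of each design row split into even thirds across
    microhabitats and even halves across the two collection years
    (burial durations) within each third; plots are assigned round-robin
    within a cell.  Locations listed in ``scenario.lost_locations`` —
    tuples of (species, cohort, microhabitat, collection_year, plot) —
    are dropped, mimicking packets lost in the field.
    """
    design = scenario.design
    micros = design.microhabitats
    years = design.collection_years
    records: list[PacketRecord] = []
    for row in design.rows:
        per_cell = row.n_packets // (len(micros) * len(years))
        site = f"site_{row.species}"
        for micro in micros:
            rng = _stratum_rng(scenario.rng_seed, (row.species, row.cohort, micro))
            for duration, year in enumerate(years, start=1):
                for i in range(per_cell):
                    plot = f"p{(i % scenario.plots_per_site) + 1:02d}"
                    location = (row.species, row.cohort, micro, year, plot)
                    counts = _simulate_packet(
                        rng, scenario, (row.species, row.cohort, micro),
                        row.seeds_per_packet, duration,
                    )
                    if location in scenario.lost_locations:
                        continue
                    packet_id = (
                        f"{row.species}-{row.cohort}-{micro}-y{year}-{plot}-{i:03d}"
                    )
                    records.append(
                        PacketRecord(
                            packet_id=packet_id,
                            species=row.species,
                            cohort=row.cohort,
                            site=site,
                            plot=plot,
                            microhabitat=micro,
                            burial_seasons=duration,
                            collection_year=year,
                            seeds_sown=row.seeds_per_packet,
                            **counts,
                        )
                    )
    return sorted(records, key=lambda r: r.packet_id)


def _simulate_packet(
    rng: np.random.Generator,
    scenario: FateScenario,
    stratum: tuple[str, str, str],
    n_seeds: int,
    seasons: int,
) -> dict[str, int]:
    hz = scenario.stratum_hazards(*stratum)
    dead_rates = hz.dead_rates()
    live = int(rng.binomial(n_seeds, scenario.initial_viability))
    dead = n_seeds - live
    expended = 0
    for s in range(seasons):
        # live intact: expended / die in place / stay live
        fates = rng.multinomial(
            live, [hz.p_expend[s], hz.p_die[s], 1.0 - hz.p_expend[s] - hz.p_die[s]]
        )
        expended += int(fates[0])
        newly_dead = int(fates[1])
        live = int(fates[2])
        dead_expended = int(rng.binomial(dead, dead_rates[s]))
        expended += dead_expended
        dead = dead - dead_expended + newly_dead
    retained = live + dead
    n_assayed = int(round_half_up(scenario.assay_fraction * retained, 0))
    n_assayed = min(n_assayed, retained)
    live_assayed = int(rng.hypergeometric(live, dead, n_assayed)) if n_assayed else 0
    stained = int(rng.binomial(live_assayed, scenario.stain_sensitivity))
    stained += int(
        rng.binomial(n_assayed - live_assayed, 1.0 - scenario.stain_specificity)
    )
    return {
        "n_expended": expended,
        "n_retained": retained,
        "n_assayed": n_assayed,
        "n_stained": stained,
    }


def hazards_from_pools(
    retained: tuple[float, float],
    staining: tuple[float, float],
    initial_viability: float = 1.0,
) -> StratumHazards:
    """Invert two seasons of pool targets into per-season hazards.

    ``retained[d]`` and ``staining[d]`` are the target retained
    proportion (of sown seeds) and staining rate (among retained) after
    season d+1.  When the staining rate declines or holds, the shared
    decay model (dead intact seeds expended at the live rate) solves the
    targets; a rising staining rate is only reachable through selective
    loss of dead seeds, so the inversion switches to a separate
    dead-seed expenditure rate with no additional in-place death.
    Infeasible orderings raise with the violated constraint named.
    """
    r1, r2 = retained
    ps1, ps2 = staining
    v0 = initial_viability
    for name, v in (("retained", r1), ("retained", r2), ("staining", ps1), ("staining", ps2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} target out of [0, 1]: {v}")
    if r2 > r1:
        raise ValueError(
            f"infeasible targets: year-2 retained ({r2}) exceeds year-1 retained "
            f"({r1}); retention is monotone non-increasing"
        )
    live1, live2 = r1 * ps1, r2 * ps2
    if live1 > v0:
        raise ValueError("infeasible targets: retained-live exceeds initial viability")
    if live2 > live1 + 1e-12:
        raise ValueError(
            f"infeasible targets: retained-live rises from {live1:.4g} to {live2:.4g}"
        )
    if v0 != 1.0:
        raise NotImplementedError(
            "pool inversion assumes all sown seeds start live (initial_viability=1)"
        )
    dead1 = r1 - live1
    # season 1: live seeds are expended w.p. a1 or die in place w.p. b1
    a1 = 1.0 - r1
    b1 = dead1
    # season 2, shared-decay model: a2 from the retention ratio
    if r1 == 0:
        return StratumHazards(p_expend=(a1, 0.0), p_die=(b1, 0.0))
    if ps2 <= ps1 or dead1 == 0:
        a2 = 1.0 - r2 / r1
        b2 = (r2 / r1) - (live2 / live1 if live1 > 0 else 0.0)
        if b2 < -1e-12:
            raise ValueError("infeasible targets under shared decay model")
        return StratumHazards(p_expend=(a1, a2), p_die=(b1, max(b2, 0.0)))
    # rising staining rate: dead seeds must decay faster than live seeds
    a2 = 1.0 - live2 / live1
    dead2 = r2 - live2
    c2 = 1.0 - dead2 / dead1
    if c2 < -1e-12:
        raise ValueError(
            "infeasible targets: retained-dead pool would have to grow without "
            "a source"
        )
    return StratumHazards(
        p_expend=(a1, a2),
        p_die=(b1, 0.0),
        p_expend_dead=(a1, max(c2, 0.0)),
    )


def scenario_from_pools(
    design: ExperimentDesign,
    targets: dict[tuple[str, str, str], dict[str, tuple[float, float]]],
    rng_seed: int = 0,
    assay_fraction: float = 1.0,
    plots_per_site: int = 9,
) -> FateScenario:
    """Build a scenario whose implied pools equal per-stratum targets.

    ``targets`` maps (species, cohort, microhabitat) to
    ``{"retained": (r1, r2), "staining": (ps1, ps2)}``.  The inversion is
    exact: round-tripping through :meth:`FateScenario.implied_pools`
    recovers every target to 1e-12.
    """
    hazards = {
        key: hazards_from_pools(spec["retained"], spec["staining"])
        for key, spec in targets.items()
    }
    return FateScenario(
        design=design,
        hazards=hazards,
        rng_seed=rng_seed,
        assay_fraction=assay_fraction,
        plots_per_site=plots_per_site,
    )


def parameter_recovery_study(
    scenario: FateScenario,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Bias check of (pl, ps, survival) estimators against implied truths.

    Simulates the scenario ``n_replicates`` times (replicate r uses root
    seed ``seed + r``), pools counts per stratum x duration, and compares
    the mean estimate with the closed-form truth.  A stratum is flagged
    when |bias| exceeds 3 SD / sqrt(n_replicates); with fewer than 10
    replicates the flag column is suppressed (all False) with a warning.
    """
    from .survival import stratum_survival

    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rows: dict[tuple, dict[str, list[float]]] = {}
    for r in range(n_replicates):
        records = simulate_experiment(replace(scenario, rng_seed=seed + r))
        for est in stratum_survival(records):
            key = tuple(sorted(est.group.items()))
            bucket = rows.setdefault(key, {"pl": [], "ps": [], "survival": []})
            bucket["pl"].append(est.pl)
            bucket["ps"].append(est.ps if est.ps is not None else np.nan)
            bucket["survival"].append(est.survival)

    flags_ok = n_replicates >= 10
    if not flags_ok:
        warnings.warn(
            "fewer than 10 replicates: bias flags suppressed", stacklevel=2
        )
    out = []
    for key, bucket in sorted(rows.items(), key=str):
        labels = dict(key)
        truth = scenario.implied_pools(
            labels["species"], labels["cohort"], labels["microhabitat"],
            int(labels["burial_seasons"]),
        )
        truths = {
            "pl": truth["retained"],
            "ps": truth["staining_rate"],
            "survival": truth["survival"],
        }
        row = dict(labels)
        for quantity, values in bucket.items():
            arr = np.asarray(values, dtype=float)
            mean = float(np.nanmean(arr))
            sd = float(np.nanstd(arr, ddof=1))
            bias = mean - truths[quantity]
            flagged = flags_ok and abs(bias) > 3.0 * sd / np.sqrt(n_replicates)
            row.update(
                {
                    f"{quantity}_truth": truths[quantity],
                    f"{quantity}_mean": mean,
                    f"{quantity}_sd": sd,
                    f"{quantity}_bias": bias,
                    f"{quantity}_flagged": bool(flagged),
                }
            )
        out.append(row)
    return pd.DataFrame(out)
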