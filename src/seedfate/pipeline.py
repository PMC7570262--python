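"""End-to-end orchestration: simulate -> account -> estimate -> test -> report.

One :class:`RunConfig` drives a deterministic run that writes the packet
table (when simulated), pool and survival summaries, Sankey flows, the
two regression deviance tables, the rank-test results, and a manifest
(seed, config hash, versions).  Re-running an identical config
reproduces identical numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .glm import fit_quasibinomial_glm
from .packet_model import (
    PacketRecord,
    merge_packets,
    read_packets,
    records_to_frame,
    write_packets,
)
from .pool_accounting import summarize_pools, sankey_export
from .presets import default_scenario
from .rank_tests import dunn_posthoc, kruskal_wallis, mann_whitney_u, normality_screen
from .scenario_io import load_scenario
from .schema import STRATUM_KEYS
from .survival import (
    aggregate_survival,
    estimates_to_frame,
    stratum_survival,
)
from .synthetic_data import parameter_recovery_study, simulate_experiment

logger = logging.getLogger(__name__)

GLM_FACTORS = ["collection_year", "species", "microhabitat", "cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (an existing packet CSV) or
    ``scenario_path`` / the built-in default scenario is used as the data
    source; the root ``seed`` is recorded in every output manifest.
    """

    out_dir: str
    seed: int = 0
    input_path: str | None = None
    scenario_path: str | None = None
    grouping: tuple[str, ...] = tuple(STRATUM_KEYS)
    adjustment: str = "bonferroni"
    decimals: int = 1
    glm_max_order: int | None = None
    assay_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.input_path and self.scenario_path:
            raise ValueError("provide either input_path or scenario_path, not both")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _location_table(records: Sequence[PacketRecord]) -> pd.DataFrame:
    """Merged-location frame with the GLM response/weight columns."""
    merged = merge_packets(records)
    frame = records_to_frame(merged)
    frame["n_recovered"] = frame["n_expended"] + frame["n_retained"]
    frame = frame[frame["n_recovered"] > 0].reset_index(drop=True)
    frame["prop_retained"] = frame["n_retained"] / frame["n_recovered"]
    with np.errstate(invalid="ignore"):
        frame["survival"] = np.where(
            frame["n_assayed"] > 0,
            frame["prop_retained"] * frame["n_stained"] / frame["n_assayed"],
            np.where(frame["n_retained"] == 0, 0.0, np.nan),
        )
    return frame


def seed_level_table(records: Sequence[PacketRecord]) -> pd.DataFrame:
    """One Bernoulli row per assayed seed (stain present / absent)."""
    frame = records_to_frame(records)
    frame = frame[frame["n_assayed"] > 0]
    rows = []
    for rec in frame.itertuples(index=False):
        labels = {
            "species": rec.species,
            "cohort": rec.cohort,
            "microhabitat": rec.microhabitat,
            "collection_year": rec.collection_year,
        }
        rows.extend([{**labels, "stained": 1.0}] * rec.n_stained)
        rows.extend([{**labels, "stained": 0.0}] * (rec.n_assayed - rec.n_stained))
    return pd.DataFrame(rows)


def rank_test_report(
    locations: pd.DataFrame, adjustment: str = "bonferroni"
) -> dict[str, object]:
    """Rank-based comparisons of location-level survival values.

    Within each burial duration: a normality screen, the rare-vs-common
    two-sample test, and the across-microhabitat test with pairwise
    post-hoc comparisons.
    """
    report: dict[str, object] = {}
    for duration, sub in locations.groupby("burial_seasons"):
        values = sub["survival"].dropna()
        entry: dict[str, object] = {}
        if values.size >= 3 and values.nunique() > 1:
            shapiro = normality_screen(values)
            entry["shapiro"] = _result_dict(shapiro)
        species = sorted(sub["species"].unique())
        if len(species) == 2:
            a = sub.loc[sub["species"] == species[0], "survival"].dropna()
            b = sub.loc[sub["species"] == species[1], "survival"].dropna()
            if a.size and b.size:
                res = mann_whitney_u(a, b)
                entry["species_mann_whitney"] = {
                    "comparison": f"{species[0]} vs {species[1]}",
                    **_result_dict(res),
                }
        micros = sorted(sub["microhabitat"].unique())
        groups = [
            sub.loc[sub["microhabitat"] == m, "survival"].dropna() for m in micros
        ]
        if len(groups) >= 2 and all(g.size for g in groups):
            kw = kruskal_wallis(*groups)
            entry["microhabitat_kruskal_wallis"] = _result_dict(kw)
            entry["microhabitat_dunn"] = [
                _result_dict(r)
                for r in dunn_posthoc(*groups, labels=micros, adjustment=adjustment)
            ]
        report[f"burial_seasons_{duration}"] = entry
    return report


def _result_dict(result) -> dict[str, object]:
    out = dataclasses.asdict(result)
    out["group_sizes"] = list(out["group_sizes"])
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if config.input_path:
        records = _stage("read")(read_packets)(config.input_path)
    else:
        if config.scenario_path:
            scenario = _stage("scenario")(load_scenario)(config.scenario_path)
            scenario = dataclasses.replace(scenario, rng_seed=config.seed)
        else:
            scenario = default_scenario(
                rng_seed=config.seed, assay_fraction=config.assay_fraction
            )
        records = _stage("simulate")(simulate_experiment)(scenario)
        written["packets"] = out / "packets.csv"
        write_packets(records, written["packets"])

    summaries = _stage("pools")(summarize_pools)(records, list(config.grouping))
    pool_rows = []
    for s in summaries:
        row = dict(s.group)
        row.update(
            n_total=s.n_total,
            expended_F=s.expended_F,
            retained_C=s.retained_C,
            n_assayed=s.n_assayed,
            retained_live_D=s.retained_live_D,
            retained_dead_E=s.retained_dead_E,
            unrecovered=s.unrecovered,
            prop_expended=s.prop_expended,
            prop_retained=s.prop_retained,
            staining_rate=s.prop_live_assay,
        )
        pool_rows.append(row)
    written["pools"] = out / "pool_summary.csv"
    pd.DataFrame(pool_rows).to_csv(written["pools"], index=False)

    estimates = _stage("survival")(stratum_survival)(records, list(config.grouping))
    species_level = aggregate_survival(estimates, over=["cohort", "microhabitat"])
    micro_level = aggregate_survival(estimates, over=["cohort", "species"])
    frame = pd.concat(
        [
            estimates_to_frame(estimates, config.decimals),
            estimates_to_frame(species_level, config.decimals),
            estimates_to_frame(micro_level, config.decimals),
        ],
        ignore_index=True,
    )
    written["survival"] = out / "survival.csv"
    frame.to_csv(written["survival"], index=False)

    written["sankey"] = out / "sankey.json"
    written["sankey"].write_text(json.dumps(sankey_export(summaries), indent=2))

    locations = _stage("merge")(_location_table)(records)
    factors = [f for f in GLM_FACTORS if locations[f].nunique() >= 2]
    if len(factors) < len(GLM_FACTORS):
        logger.warning(
            "single-level factor(s) dropped from GLMs: %s",
            sorted(set(GLM_FACTORS) - set(factors)),
        )
    if factors:
        deviance = _stage("glm_retention")(fit_quasibinomial_glm)(
            locations,
            response="prop_retained",
            factors=factors,
            weights="n_recovered",
            max_order=config.glm_max_order,
        )
        written["glm_retention"] = out / "deviance_retention.csv"
        deviance.table.to_csv(written["glm_retention"], index=False)

        seeds = seed_level_table(records)
        if len(seeds):
            staining = _stage("glm_staining")(fit_quasibinomial_glm)(
                seeds,
                response="stained",
                factors=[f for f in factors if seeds[f].nunique() >= 2],
                weights=None,
                max_order=config.glm_max_order,
            )
            written["glm_staining"] = out / "deviance_staining.csv"
            staining.table.to_csv(written["glm_staining"], index=False)

    tests = _stage("rank_tests")(rank_test_report)(locations, config.adjustment)
    written["rank_tests"] = out / "rank_tests.json"
    written["rank_tests"].write_text(json.dumps(tests, indent=2))

    config_dict = dataclasses.asdict(config)
    manifest = {
        "config": config_dict,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seedfate_version": __version__,
        "python": platform.python_version(),
        "outputs": {k: str(v.name) for k, v in written.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = manifest_path
    return written


def run_recovery(
    out_dir: str,
    n_replicates: int = 200,
    seed: int = 0,
    scenario_path: str | None = None,
    assay_fraction: float = 0.5,
) -> Path:
    """Parameter-recovery study on the (default or given) scenario."""
    scenario = (
        load_scenario(scenario_path)
        if scenario_path
        else default_scenario(assay_fraction=assay_fraction)
    )
    table = parameter_recovery_study(scenario, n_replicates=n_replicates, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "parameter_recovery.csv"
    table.to_csv(path, index=False)
    return path
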