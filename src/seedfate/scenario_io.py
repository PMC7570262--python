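"""Read and write fate scenarios as YAML/JSON documents.

A scenario file pins the experiment design and the per-stratum pool
targets; hazards are re-derived from the targets on load, so a file
round-trips through :func:`load_scenario` / :func:`dump_scenario`
without drift.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .packet_model import DesignRow, ExperimentDesign
from .synthetic_data import FateScenario, scenario_from_pools


def dump_scenario(
    targets: dict[tuple[str, str, str], dict[str, tuple[float, float]]],
    design: ExperimentDesign,
    path: str | Path,
    rng_seed: int = 0,
    assay_fraction: float = 1.0,
    plots_per_site: int = 9,
) -> None:
    doc = {
        "design": {
            "rows": [
                {
                    "species": r.species,
                    "cohort": r.cohort,
                    "n_packets": r.n_packets,
                    "seeds_per_packet": r.seeds_per_packet,
                }
                for r in design.rows
            ],
            "microhabitats": list(design.microhabitats),
            "collection_years": list(design.collection_years),
        },
        "targets": [
            {
                "species": sp,
                "cohort": co,
                "microhabitat": mi,
                "retained": list(spec["retained"]),
                "staining": list(spec["staining"]),
            }
            for (sp, co, mi), spec in sorted(targets.items())
        ],
        "assay_fraction": assay_fraction,
        "rng_seed": rng_seed,
        "plots_per_site": plots_per_site,
    }
    path = Path(path)
    text = (
        json.dumps(doc, indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(doc, sort_keys=False)
    )
    path.write_text(text)


def load_scenario(path: str | Path) -> FateScenario:
    path = Path(path)
    doc = (
        json.loads(path.read_text())
        if path.suffix == ".json"
        else yaml.safe_load(path.read_text())
    )
    design = ExperimentDesign(
        rows=tuple(
            DesignRow(
                species=str(r["species"]),
                cohort=str(r["cohort"]),
                n_packets=int(r["n_packets"]),
                seeds_per_packet=int(r["seeds_per_packet"]),
            )
            for r in doc["design"]["rows"]
        ),
        microhabitats=tuple(doc["design"].get("microhabitats", ("control", "runoff", "shade"))),
        collection_years=tuple(str(y) for y in doc["design"].get("collection_years", ("2017", "2018"))),
    )
    targets = {
        (str(t["species"]), str(t["cohort"]), str(t["microhabitat"])): {
            "retained": tuple(float(x) for x in t["retained"]),
            "staining": tuple(float(x) for x in t["staining"]),
        }
        for t in doc["targets"]
    }
    return scenario_from_pools(
        design,
        targets,
        rng_seed=int(doc.get("rng_seed", 0)),
        assay_fraction=float(doc.get("assay_fraction", 1.0)),
        plots_per_site=int(doc.get("plots_per_site", 9)),
    )
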