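"""Partition packet counts into seed-bank pools and proportional flow tables.

The accounting model follows each sown seed from the seed bank (100%)
into one of two observable pools at collection: the *expended* pool F
(germinated B or decayed A — indistinguishable at spring collection) and
the *retained* pool C (intact seeds).  Assayed retained seeds split into
retained live D (any stain) and retained dead E (no stain).  The live pool
G = B + D and dead pool H = A + E are only identifiable as intervals,
because A and B are not separately observed.  Flow tables are exported in
a Sankey-ready source/target/value form with exact mass conservation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .packet_model import PacketRecord, records_to_frame

logger = logging.getLogger(__name__)

_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class PoolSummary:
    """Counts and seed-bank proportions of the fate pools for one group.

    Proportions are relative to ``n_total`` (the group's seed bank);
    ``prop_live_assay`` is the assay-scope staining rate D / (D + E).
    """

    group: Mapping[str, object]
    n_total: int
    expended_F: int
    retained_C: int
    n_assayed: int
    retained_live_D: int
    retained_dead_E: int
    unrecovered: int

    def __post_init__(self) -> None:
        if self.expended_F + self.retained_C + self.unrecovered != self.n_total:
            raise ValueError("pools do not partition the seed bank")
        if self.retained_live_D + self.retained_dead_E != self.n_assayed:
            raise ValueError("live + dead assayed seeds must equal n_assayed")
        if self.n_assayed > self.retained_C:
            raise ValueError("n_assayed exceeds retained pool")

    @property
    def prop_expended(self) -> float:
        return self.expended_F / self.n_total

    @property
    def prop_retained(self) -> float:
        return self.retained_C / self.n_total

    @property
    def prop_unrecovered(self) -> float:
        return self.unrecovered / self.n_total

    @property
    def prop_live_assay(self) -> float | None:
        """Staining rate D/(D+E) among assayed seeds; None if nothing assayed."""
        if self.n_assayed == 0:
            return None
        return self.retained_live_D / self.n_assayed


@dataclass(frozen=True)
class SankeyFlow:
    source: str
    target: str
    value: float
    note: str = ""


@dataclass(frozen=True)
class PoolInterval:
    """An interval-valued pool plus its display convention point value."""

    low: float
    high: float
    display: float


def summarize_pools(
    records: Sequence[PacketRecord],
    grouping: Sequence[str] = (),
) -> list[PoolSummary]:
    """Sum packet counts into one :class:`PoolSummary` per group.

    ``grouping`` names any subset of the packet label fields; an empty
    grouping yields a single overall summary.  Groups partition the
    records, so re-aggregating subgroup counts reproduces a coarser
    grouping exactly.
    """
    if not records:
        raise ValueError("summarize_pools requires a non-empty record collection")
    frame = records_to_frame(records)
    for key in grouping:
        if key not in frame.columns:
            raise KeyError(f"unknown grouping key {key!r}")
    if grouping:
        grouped = frame.groupby(list(grouping), sort=True)
        items = []
        for k, g in grouped:
            key = k if isinstance(k, tuple) else (k,)
            key = tuple(v.item() if hasattr(v, "item") else v for v in key)
            items.append((dict(zip(grouping, key)), g))
    else:
        items = [({}, frame)]

    summaries = []
    for labels, g in items:
        if not len(g):
            logger.warning("empty group %s omitted from pool summary", labels)
            continue
        n_total = int(g["seeds_sown"].sum())
        expended = int(g["n_expended"].sum())
        retained = int(g["n_retained"].sum())
        assayed = int(g["n_assayed"].sum())
        stained = int(g["n_stained"].sum())
        summaries.append(
            PoolSummary(
                group=labels,
                n_total=n_total,
                expended_F=expended,
                retained_C=retained,
                n_assayed=assayed,
                retained_live_D=stained,
                retained_dead_E=assayed - stained,
                unrecovered=n_total - expended - retained,
            )
        )
    return summaries


def live_dead_pools(summary: PoolSummary) -> dict[str, PoolInterval]:
    """Live pool G = B + D and dead pool H = A + E, as seed-bank proportions.

    Germinated (B) and decayed (A) seeds cannot be told apart at
    collection, so G and H are intervals: the unobservable expended mass F
    may belong entirely to either.  The ``display`` value follows the
    equal-split convention (A = B = F/2) and is a visualization choice,
    not an estimate.  The staining rate D/(D+E) is scaled up from the
    assayed subset to all of C.
    """
    f = summary.prop_expended
    ps = summary.prop_live_assay
    if ps is None:
        ps = 0.0
        warnings.warn(
            "no assayed seeds: retained pool treated as unresolved (D = 0) "
            "in live/dead pool intervals",
            stacklevel=2,
        )
    d = summary.prop_retained * ps
    e = summary.prop_retained - d
    return {
        "live_G": PoolInterval(low=d, high=d + f, display=d + f / 2),
        "dead_H": PoolInterval(low=e, high=e + f, display=e + f / 2),
    }


def sankey_export(summaries: Iterable[PoolSummary]) -> list[dict[str, object]]:
    """Flatten pool summaries into Sankey source/target/value rows.

    Magnitudes are proportions of each group's seed bank.  The expended
    pool is displayed as an equal A/B split (tagged ``display_convention``
    in the note field); the retained pool routes through the assay node
    and splits by the staining rate D/(D+E) applied to all of C.  Mass is
    conserved at every internal node to within 1e-9.
    """
    rows: list[dict[str, object]] = []
    for summary in summaries:
        flows = group_flows(summary)
        for flow in flows:
            row = {"source": flow.source, "target": flow.target, "value": flow.value}
            if flow.note:
                row["note"] = flow.note
            row.update(summary.group)
            rows.append(row)
    return rows


def group_flows(summary: PoolSummary) -> list[SankeyFlow]:
    f = summary.prop_expended
    c = summary.prop_retained
    flows = []
    if f > 0:
        split = "display_convention: equal A/B split of expended pool F"
        flows.append(SankeyFlow("seed bank", "decayed A", f / 2, split))
        flows.append(SankeyFlow("seed bank", "germinated B", f / 2, split))
    if c > 0:
        flows.append(SankeyFlow("seed bank", "retained C", c))
        ps = summary.prop_live_assay
        if ps is None:
            logger.warning(
                "group %s: retained pool present but no seeds assayed; "
                "C terminates unsplit", summary.group,
            )
            flows.append(
                SankeyFlow("retained C", "assay", c, "unassayed: no live/dead split")
            )
        else:
            flows.append(SankeyFlow("retained C", "assay", c))
            flows.append(SankeyFlow("assay", "retained live D", c * ps))
            flows.append(SankeyFlow("assay", "retained dead E", c * (1.0 - ps)))
    _check_conservation(flows)
    return flows


def _check_conservation(flows: Sequence[SankeyFlow]) -> None:
    nodes: dict[str, list[float]] = {}
    for flow in flows:
        nodes.setdefault(flow.source, [0.0, 0.0])[1] += flow.value
        nodes.setdefault(flow.target, [0.0, 0.0])[0] += flow.value
    for name, (inflow, outflow) in nodes.items():
        if inflow > 0 and outflow > 0 and abs(inflow - outflow) > _CONSERVATION_TOL:
            raise AssertionError(
                f"Sankey node {name!r} violates conservation: "
                f"in {inflow!r} != out {outflow!r}"
            )


def flows_to_frame(rows: list[dict[str, object]]) -> pd.DataFrame:
    return pd.DataFrame(rows)
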