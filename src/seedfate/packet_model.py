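"""Packet-level data model for buried seed packet experiments.

A *packet* is a fabric sleeve of individually celled seeds buried in a
known microhabitat and exhumed after one or two growing seasons.  At
collection each seed is classified as *expended* (germinated or decayed:
split coat, radicle, or empty hull) or *retained* (intact); a subset of
retained seeds enters a tetrazolium staining assay where any visible stain
marks the seed as live.  This module holds the per-packet record type, its
validation rules, CSV I/O, experiment-design arithmetic, and the explicit
packet-merging step used before regression analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .schema import (
    BURIAL_SEASONS,
    COUNT_COLUMNS,
    MICROHABITATS,
    PACKET_COLUMNS,
    SchemaError,
    ValidationError,
)


@dataclass(frozen=True)
class PacketRecord:
    """One buried packet's stratum labels and per-class seed counts.

    Counts partition the sown seeds: ``n_expended`` (germinated or decayed,
    indistinguishable at collection), ``n_retained`` (intact), and an
    implicit unrecovered remainder ``seeds_sown - n_expended - n_retained``.
    ``n_assayed`` retained seeds entered the staining assay, of which
    ``n_stained`` showed any stain (scored live).
    """

    packet_id: str
    species: str
    cohort: str
    site: str
    plot: str
    microhabitat: str
    burial_seasons: int
    collection_year: str
    seeds_sown: int
    n_expended: int
    n_retained: int
    n_assayed: int
    n_stained: int

    def __post_init__(self) -> None:
        for name in COUNT_COLUMNS:
            value = getattr(self, name)
            if value < 0:
                raise ValidationError(
                    f"packet {self.packet_id!r}: {name} must be >= 0, got {value}"
                )
        if self.n_expended + self.n_retained > self.seeds_sown:
            raise ValidationError(
                f"packet {self.packet_id!r}: n_expended + n_retained exceeds seeds_sown"
            )
        if self.n_assayed > self.n_retained:
            raise ValidationError(
                f"packet {self.packet_id!r}: violates n_assayed <= n_retained"
            )
        if self.n_stained > self.n_assayed:
            raise ValidationError(
                f"packet {self.packet_id!r}: violates n_stained <= n_assayed"
            )
        if self.microhabitat not in MICROHABITATS:
            raise ValidationError(
                f"packet {self.packet_id!r}: unknown microhabitat "
                f"{self.microhabitat!r}; expected one of {MICROHABITATS}"
            )
        if self.burial_seasons not in BURIAL_SEASONS:
            raise ValidationError(
                f"packet {self.packet_id!r}: burial_seasons must be in "
                f"{BURIAL_SEASONS}, got {self.burial_seasons}"
            )

    @property
    def n_recovered(self) -> int:
        """Seeds accounted for at collection (expended + retained)."""
        return self.n_expended + self.n_retained

    @property
    def n_unrecovered(self) -> int:
        return self.seeds_sown - self.n_recovered


@dataclass(frozen=True)
class DesignRow:
    """One species x cohort row of the packet allocation."""

    species: str
    cohort: str
    n_packets: int
    seeds_per_packet: int

    @property
    def total_seeds(self) -> int:
        return self.n_packets * self.seeds_per_packet


@dataclass(frozen=True)
class ExperimentDesign:
    """Allocation of seed cohorts to packets and packets to strata."""

    rows: tuple[DesignRow, ...]
    microhabitats: tuple[str, ...] = MICROHABITATS
    collection_years: tuple[str, ...] = ("2017", "2018")
    split_rule: str = "even"

    def __post_init__(self) -> None:
        if self.split_rule == "even":
            n_cells = len(self.microhabitats) * len(self.collection_years)
            for row in self.rows:
                if row.n_packets % n_cells:
                    raise ValidationError(
                        f"design row ({row.species}, {row.cohort}): "
                        f"{row.n_packets} packets not divisible over "
                        f"{n_cells} microhabitat x collection-year cells"
                    )


def allocation_totals(design: ExperimentDesign) -> pd.DataFrame:
    """Per-row and grand totals of packets and seeds for a design.

    Returns a tidy frame with one row per design row plus a final
    ``total`` row; seeds per row are ``n_packets * seeds_per_packet``.
    """
    rows = [
        {
            "species": r.species,
            "cohort": r.cohort,
            "n_packets": r.n_packets,
            "seeds_per_packet": r.seeds_per_packet,
            "total_seeds": r.total_seeds,
        }
        for r in design.rows
    ]
    table = pd.DataFrame(
        rows,
        columns=["species", "cohort", "n_packets", "seeds_per_packet", "total_seeds"],
    )
    total = pd.DataFrame(
        [
            {
                "species": "total",
                "cohort": "",
                "n_packets": int(table["n_packets"].sum()) if len(table) else 0,
                "seeds_per_packet": pd.NA,
                "total_seeds": int(table["total_seeds"].sum()) if len(table) else 0,
            }
        ]
    )
    return pd.concat([table, total], ignore_index=True)


def records_to_frame(records: Iterable[PacketRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(r) for r in records], columns=list(PACKET_COLUMNS))
    return frame.sort_values("packet_id", kind="stable").reset_index(drop=True)


def frame_to_records(frame: pd.DataFrame) -> list[PacketRecord]:
    missing = [c for c in PACKET_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"packet table missing column(s): {', '.join(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        kwargs = {name: getattr(row, name) for name in PACKET_COLUMNS}
        for name in COUNT_COLUMNS + ("burial_seasons",):
            kwargs[name] = int(kwargs[name])
        for field in fields(PacketRecord):
            if field.type == "str":
                kwargs[field.name] = str(kwargs[field.name])
        records.append(PacketRecord(**kwargs))
    return sorted(records, key=lambda r: r.packet_id)


def read_packets(source: str | Path) -> list[PacketRecord]:
    """Read and validate a packet CSV; rows are returned ordered by packet_id.

    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` (naming the packet and rule) for an invariant
    violation.
    """
    frame = pd.read_csv(source, dtype={"cohort": str, "plot": str, "collection_year": str})
    return frame_to_records(frame)


def write_packets(records: Iterable[PacketRecord], target: str | Path) -> None:
    records_to_frame(records).to_csv(target, index=False)


def merge_packets(
    records: Sequence[PacketRecord],
    keys: Sequence[str] = (
        "species",
        "cohort",
        "site",
        "plot",
        "microhabitat",
        "burial_seasons",
        "collection_year",
    ),
) -> list[PacketRecord]:
    """Merge packets of the same cohort collected at the same location.

    Counts are summed within each key combination; the merged record's
    packet_id concatenates the member ids.  Merging is an explicit
    pre-analysis step (locations holding several packets of one cohort are
    a single observational unit for regression), never implicit.
    """
    frame = records_to_frame(records)
    label_cols = [c for c in PACKET_COLUMNS if c not in COUNT_COLUMNS
                  and c != "packet_id" and c not in keys]

    def collapse(values):
        unique = sorted(set(str(v) for v in values))
        return unique[0] if len(unique) == 1 else "+".join(unique)

    def collapse_seasons(values):
        unique = sorted(set(int(v) for v in values))
        if len(unique) > 1:
            raise ValueError(
                "cannot merge packets across burial durations; include "
                "burial_seasons in the merge keys"
            )
        return unique[0]

    aggregators = {
        c: (c, collapse_seasons if c == "burial_seasons" else collapse)
        for c in label_cols
    }
    grouped = frame.groupby(list(keys), sort=True, as_index=False).agg(
        packet_id=("packet_id", lambda ids: "+".join(sorted(ids))),
        **aggregators,
        **{c: (c, "sum") for c in COUNT_COLUMNS},
    )
    return frame_to_records(grouped)
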