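"""Column names and controlled vocabularies for packet-level seed-fate tables.

The packet CSV schema is shared by the simulator output and the analysis
input; column names are fixed here and unknown labels are rejected rather
than coerced.
"""

from __future__ import annotations

#: Admissible microhabitat labels: under the panel (shade), at the panel's
#: drip edge (runoff), and open ground (control).
MICROHABITATS: tuple[str, ...] = ("control", "runoff", "shade")

#: Admissible burial durations, in growing seasons.
BURIAL_SEASONS: tuple[int, ...] = (1, 2)

#: Ordered packet-table columns. One row per packet.
PACKET_COLUMNS: tuple[str, ...] = (
    "packet_id",
    "species",
    "cohort",
    "site",
    "plot",
    "microhabitat",
    "burial_seasons",
    "collection_year",
    "seeds_sown",
    "n_expended",
    "n_retained",
    "n_assayed",
    "n_stained",
)

#: Integer-count columns of the packet table.
COUNT_COLUMNS: tuple[str, ...] = (
    "seeds_sown",
    "n_expended",
    "n_retained",
    "n_assayed",
    "n_stained",
)

#: Stratum keys that identify an elementary analysis cell.
STRATUM_KEYS: tuple[str, ...] = ("species", "cohort", "microhabitat", "burial_seasons")


class SchemaError(ValueError):
    """A table is missing a required column."""


class ValidationError(ValueError):
    """A record violates a packet invariant."""
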