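"""Observation-event data model: validation, daily-best filtering, and
pivoting events into per-stratum abundance matrices.

The observational unit is a *selection event*: one day's stable aggregation
of birds at a site, recorded as one row per (species, behavior class) with a
head count. Downstream stages consume the event x node-label abundance
matrix produced by :func:`pivot_abundance`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._constants import (
    BEHAVIOR_CLASSES,
    GUILDS,
    HABITATS,
    NODES_PER_SPECIES,
    REGIMES,
)

logger = logging.getLogger(__name__)

EVENT_COLUMNS = (
    "event_id",
    "date",
    "site_id",
    "regime",
    "habitat",
    "species_id",
    "behavior_class",
    "count",
)

CATALOG_COLUMNS = ("species_id", "scientific_name", "guild")


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """A row violates the closed vocabularies or the catalog."""


@dataclass(frozen=True)
class CatalogEntry:
    species_id: str
    scientific_name: str
    guild: str


@dataclass(frozen=True)
class SpeciesCatalog:
    """The closed species universe; node labels are species x behavior class."""

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.species_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate species_id in catalog")
        for e in self.entries:
            if e.guild not in GUILDS:
                raise ValidationError(
                    f"unknown guild {e.guild!r} for species {e.species_id!r}"
                )

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(e.species_id for e in self.entries)

    @property
    def guild_of(self) -> dict[str, str]:
        return {e.species_id: e.guild for e in self.entries}

    def node_labels(self) -> tuple[tuple[str, str], ...]:
        """All (species_id, behavior_class) pairs, catalog order major."""
        return tuple(
            (sp, bc) for sp in self.species_ids for bc in BEHAVIOR_CLASSES
        )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ObservationEvent:
    """One counted sighting within a selection event."""

    event_id: str
    date: _date
    site_id: str
    regime: str
    habitat: str
    species_id: str
    behavior_class: str
    count: int


@dataclass
class AbundanceMatrix:
    """Event x node-label count matrix for one (regime, habitat) stratum.

    Columns span the full node universe (|catalog| x 5), so species never
    seen in the stratum contribute all-zero columns and remain isolates in
    the derived network.
    """

    regime: str
    habitat: str
    data: pd.DataFrame = field(repr=False)

    @property
    def labels(self) -> list[tuple[str, str]]:
        return list(self.data.columns)

    @property
    def n_events(self) -> int:
        return len(self.data)


def read_catalog(path) -> SpeciesCatalog:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in CATALOG_COLUMNS:
            if col not in header:
                raise SchemaError(f"catalog is missing column {col!r}")
        entries = tuple(
            CatalogEntry(row["species_id"], row["scientific_name"], row["guild"])
            for row in reader
        )
    return SpeciesCatalog(entries)


def read_events(path, catalog: SpeciesCatalog) -> list[ObservationEvent]:
    """Parse and validate an observation-event CSV.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`ValidationError` (citing the 1-based data row number) when a
    row uses an unknown token or a negative count. Row order is preserved.
    """
    known_species = set(catalog.species_ids)
    events: list[ObservationEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in EVENT_COLUMNS:
            if col not in header:
                raise SchemaError(f"events file is missing column {col!r}")
        for i, row in enumerate(reader, start=1):
            events.append(_parse_row(row, i, known_species))
    return events


def _parse_row(
    row: dict[str, str], rownum: int, known_species: set[str]
) -> ObservationEvent:
    def bad(msg: str) -> ValidationError:
        return ValidationError(f"row {rownum}: {msg}")

    if row["regime"] not in REGIMES:
        raise bad(f"unknown regime {row['regime']!r}")
    if row["habitat"] not in HABITATS:
        raise bad(f"unknown habitat {row['habitat']!r}")
    if row["behavior_class"] not in BEHAVIOR_CLASSES:
        raise bad(f"unknown behavior_class {row['behavior_class']!r}")
    if row["species_id"] not in known_species:
        raise bad(f"species {row['species_id']!r} not in catalog")
    try:
        count = int(row["count"])
    except ValueError:
        raise bad(f"count {row['count']!r} is not an integer") from None
    if count < 0:
        raise bad(f"negative count {count}")
    try:
        day = _date.fromisoformat(row["date"])
    except ValueError:
        raise bad(f"date {row['date']!r} is not ISO-8601") from None
    return ObservationEvent(
        event_id=row["event_id"],
        date=day,
        site_id=row["site_id"],
        regime=row["regime"],
        habitat=row["habitat"],
        species_id=row["species_id"],
        behavior_class=row["behavior_class"],
        count=count,
    )


def write_events(events: Iterable[ObservationEvent], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for ev in events:
            writer.writerow(
                [
                    ev.event_id,
                    ev.date.isoformat(),
                    ev.site_id,
                    ev.regime,
                    ev.habitat,
                    ev.species_id,
                    ev.behavior_class,
                    ev.count,
                ]
            )


def filter_daily_best(
    events: Sequence[ObservationEvent],
) -> list[ObservationEvent]:
    """Keep, per (site, day), only the selection event with most species.

    Richness ties are broken by total individual count, then by
    lexicographically smallest event id. Idempotent; preserves input order
    among retained rows.
    """
    richness: dict[tuple[str, _date, str], set[str]] = {}
    totals: dict[tuple[str, _date, str], int] = {}
    for ev in events:
        key = (ev.site_id, ev.date, ev.event_id)
        richness.setdefault(key, set()).add(ev.species_id)
        totals[key] = totals.get(key, 0) + ev.count

    winners: dict[tuple[str, _date], str] = {}
    for (site, day, eid), species in richness.items():
        rank = (len(species), totals[(site, day, eid)])
        cur = winners.get((site, day))
        if cur is None:
            winners[(site, day)] = eid
            continue
        cur_rank = (
            len(richness[(site, day, cur)]),
            totals[(site, day, cur)],
        )
        # higher richness wins, then higher total, then smaller event_id
        if rank > cur_rank or (rank == cur_rank and eid < cur):
            winners[(site, day)] = eid

    return [
        ev for ev in events if winners[(ev.site_id, ev.date)] == ev.event_id
    ]


def pivot_abundance(
    events: Sequence[ObservationEvent],
    catalog: SpeciesCatalog,
    regime: str,
    habitat: str,
) -> AbundanceMatrix:
    """Sum counts into an event x (species, behavior class) matrix.

    One row per event that has at least one observation in the stratum;
    duplicate (event, species, behavior) rows are summed.
    """
    if regime not in REGIMES:
        raise ValidationError(f"unknown regime {regime!r}")
    if habitat not in HABITATS:
        raise ValidationError(f"unknown habitat {habitat!r}")

    labels = catalog.node_labels()
    in_stratum = [
        ev for ev in events if ev.regime == regime and ev.habitat == habitat
    ]
    event_ids: list[str] = []
    for ev in in_stratum:
        if ev.event_id not in event_ids:
            event_ids.append(ev.event_id)

    columns = pd.MultiIndex.from_tuples(
        labels, names=["species_id", "behavior_class"]
    )
    if in_stratum:
        long = pd.DataFrame(
            {
                "event_id": [ev.event_id for ev in in_stratum],
                "species_id": [ev.species_id for ev in in_stratum],
                "behavior_class": [ev.behavior_class for ev in in_stratum],
                "count": [ev.count for ev in in_stratum],
            }
        )
        frame = (
            long.pivot_table(
                index="event_id",
                columns=["species_id", "behavior_class"],
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .reindex(index=event_ids, columns=columns, fill_value=0)
            .astype(np.int64)
        )
        frame.index.name = "event_id"
    else:
        frame = pd.DataFrame(
            np.zeros((0, len(labels)), dtype=np.int64),
            index=pd.Index([], name="event_id"),
            columns=columns,
        )

    if not event_ids:
        logger.info("no events in stratum (%s, %s)", regime, habitat)
    assert frame.shape[1] == len(catalog) * NODES_PER_SPECIES
    return AbundanceMatrix(regime=regime, habitat=habitat, data=frame)
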