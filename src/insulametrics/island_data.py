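"""The island/archipelago dataset: records, CSV I/O, and derived quantities.

The packaged fixture holds the eight western/central Mediterranean islands
and archipelagos of the endemism analysis (Corsica, Crete, Sardinia, Sicily,
Cyprus, and the Malta, Balearic and Tuscan archipelagos), with:

* ``Topography`` — topographic complexity (index of roughness), metres;
* ``Isolation`` — fraction of the 300 km survey disc free of neighbouring land;
* ``Area`` — surface area, km²;
* ``Population`` — human population density, individuals per km²;
* ``Spp`` — total number of vascular-plant taxa (count);
* ``Endemics`` — number of restricted endemic taxa (count);
* ``Prop`` — derived proportion of endemic taxa, ``Endemics / Spp``.

Modelling always uses the exact ratio for ``Prop``; the 1-decimal percentage
is presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ValidationError

#: Canonical column order for island CSV files.
COLUMNS = ["Island", "Topography", "Isolation", "Area", "Population", "Spp", "Endemics"]
PREDICTORS = ("Area", "Topography", "Isolation", "Population")


@dataclass(frozen=True)
class IslandRecord:
    """One island or archipelago (suffix ``(a)`` in the name marks archipelagos)."""

    name: str
    topography: float      # m
    isolation: float       # fraction in [0, 1]
    area: float            # km^2
    population_density: float  # individuals / km^2
    spp: int
    endemics: int

    def __post_init__(self) -> None:
        if self.spp < 0 or self.endemics < 0:
            raise ValidationError(f"{self.name}: counts must be non-negative")
        if self.endemics > self.spp:
            raise ValidationError(
                f"{self.name}: endemics ({self.endemics}) exceed total taxa ({self.spp})"
            )
        if not 0.0 <= self.isolation <= 1.0:
            raise ValidationError(f"{self.name}: isolation {self.isolation} outside [0, 1]")
        if self.area <= 0 or self.topography <= 0 or self.population_density <= 0:
            raise ValidationError(
                f"{self.name}: area, topography and population density must be positive"
            )

    @property
    def is_archipelago(self) -> bool:
        return self.name.rstrip().endswith("(a)")

    @property
    def prop(self) -> float:
        return derive_prop(self)


@dataclass
class IslandTable:
    """Ordered collection of island records plus opaque extra columns."""

    records: list[IslandRecord]
    provenance: str = ""
    extras: pd.DataFrame | None = None  # extra CSV columns, preserved verbatim

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValidationError("island names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> IslandRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        """Modelling frame: canonical columns plus derived ``Prop``."""
        df = pd.DataFrame(
            {
                "Island": [r.name for r in self.records],
                "Topography": [r.topography for r in self.records],
                "Isolation": [r.isolation for r in self.records],
                "Area": [r.area for r in self.records],
                "Population": [r.population_density for r in self.records],
                "Spp": [r.spp for r in self.records],
                "Endemics": [r.endemics for r in self.records],
            }
        )
        df["Prop"] = df["Endemics"] / df["Spp"]
        return df


def derive_prop(record: IslandRecord) -> float:
    """Proportion of endemic taxa, endemics / spp (exact ratio)."""
    if record.spp == 0:
        raise ValidationError(f"{record.name}: proportion undefined for spp = 0")
    return record.endemics / record.spp


def derive_density(population_count: float, area_km2: float) -> float:
    """Population density (individuals per km²) from a head count and an area."""
    if area_km2 <= 0:
        raise ValidationError(f"area must be positive, got {area_km2}")
    return population_count / area_km2


def format_prop_percent(prop: float) -> str:
    """Render a proportion the way the source table prints it: 1-dp percent."""
    return f"{prop * 100:.1f}%"


def _table_from_frame(df: pd.DataFrame, provenance: str) -> IslandTable:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    records = [
        IslandRecord(
            name=str(row.Island),
            topography=float(row.Topography),
            isolation=float(row.Isolation),
            area=float(row.Area),
            population_density=float(row.Population),
            spp=int(row.Spp),
            endemics=int(row.Endemics),
        )
        for row in df.itertuples(index=False)
    ]
    extra_cols = [c for c in df.columns if c not in COLUMNS and c != "Prop"]
    extras = df[extra_cols].reset_index(drop=True) if extra_cols else None
    return IslandTable(records=records, provenance=provenance, extras=extras)


def load_fixture() -> IslandTable:
    """The packaged eight-row Mediterranean dataset."""
    with resources.files("insulametrics.data").joinpath("table3.csv").open() as fh:
        df = pd.read_csv(fh)
    table = _table_from_frame(df, provenance="table3")
    assert len(table) == 8
    return table


def read_island_csv(path: str | Path) -> IslandTable:
    df = pd.read_csv(path)
    return _table_from_frame(df, provenance=str(path))


def write_island_csv(table: IslandTable, path: str | Path) -> None:
    df = table.to_dataframe().drop(columns=["Prop"])
    if table.extras is not None:
        for c in table.extras.columns:
            df[c] = table.extras[c].values
    df.to_csv(path, index=False)
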