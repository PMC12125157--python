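"""Harmonization of heterogeneous literature concentration records.

Literature-extracted metal(loid) measurements arrive on mixed bases
(dry vs. fresh weight), with left-censored entries reported only as a
detection/quantification bound, and with widely varying per-study sample
sizes.  This module normalizes them to a common fresh-weight basis,
substitutes censored bounds by half their value, aggregates per species
by sample-size weighting, and attaches the two classification axes
(habitat and feeding behaviour) from an explicit species catalog.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .toxdata import (
    METALS,
    Feeding,
    Habitat,
    Metal,
    ToxTable,
    parse_feeding,
    parse_habitat,
    parse_metal,
)

Censoring = Literal["measured", "LOD", "LOQ", "BDL"]
Basis = Literal["dry", "wet"]

DEFAULT_MOISTURE_PCT = 80.0


class ConcentrationRecord(BaseModel, frozen=True):
    """One literature-extracted measurement of one metal in one species.

    ``value`` is the reported mean concentration in ug/g on ``basis``;
    for censored records it is the reported bound (LOD/LOQ/BDL).
    ``moisture_pct`` is the moisture assumed for dry-to-fresh conversion;
    if omitted for a dry-basis record the 80% default applies.
    ``sample_n`` is the number of fish pooled into the reported mean and
    becomes the record's weight during species aggregation.
    """

    species: str = Field(min_length=1)
    metal: Metal
    value: float = Field(ge=0)
    basis: Basis = "wet"
    censoring: Censoring = "measured"
    moisture_pct: float | None = Field(default=None, ge=0, lt=100)
    sample_n: int = Field(default=1, ge=1)
    source_id: str = ""

    @field_validator("metal", mode="before")
    @classmethod
    def _coerce_metal(cls, v: object) -> Metal:
        return parse_metal(v) if isinstance(v, str) else v  # type: ignore[arg-type]


class SpeciesCatalogEntry(BaseModel, frozen=True):
    """Catalog row assigning one species to a habitat and feeding class.

    A species tolerating several habitats appears once per habitat and
    yields one profile per (species, habitat) stratum.
    """

    species: str = Field(min_length=1)
    habitat: Habitat
    feeding: Feeding
    aliases: tuple[str, ...] = ()

    @field_validator("habitat", mode="before")
    @classmethod
    def _coerce_habitat(cls, v: object) -> Habitat:
        return parse_habitat(v) if isinstance(v, str) else v  # type: ignore[arg-type]

    @field_validator("feeding", mode="before")
    @classmethod
    def _coerce_feeding(cls, v: object) -> Feeding:
        return parse_feeding(v) if isinstance(v, str) else v  # type: ignore[arg-type]


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-(species, habitat) fresh-weight concentration vector.

    ``conc`` maps each metal with at least one record to its sample-size
    weighted mean (ug/g fresh weight); ``support`` carries the total
    number of fish behind each mean.
    """

    species: str
    habitat: Habitat
    feeding: Feeding
    conc: Mapping[Metal, float] = field(default_factory=dict)
    support: Mapping[Metal, int] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, Habitat]:
        return (self.species, self.habitat)


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics over species-level values for one class/metal."""

    n: int
    min: float
    max: float
    mean: float
    sd: float | None  # n-1 denominator; absent for n=1
    median: float


def normalize_name(name: str) -> str:
    """Case-fold and collapse whitespace for species-name matching."""
    return " ".join(name.split()).casefold()


def substitute_censored(record: ConcentrationRecord) -> float:
    """Half-bound substitution for left-censored records.

    Measured values pass through; LOD/LOQ/BDL bounds are multiplied by
    0.5, the standard substitution for left-censored concentration data.
    """
    if record.censoring == "measured":
        return record.value
    return record.value * 0.5


def dry_to_wet(c_dry: float, moisture_pct: float = DEFAULT_MOISTURE_PCT) -> float:
    """Convert a dry-weight concentration to fresh weight.

    C_w = C_d * (100 - moisture%) / 100.  The default 80% moisture is the
    conventional assumption for fish muscle when a study reports none.
    """
    if not 0 <= moisture_pct < 100:
        raise ValueError(f"moisture_pct must be in [0, 100), got {moisture_pct}")
    if c_dry < 0:
        raise ValueError("concentration must be non-negative")
    return c_dry * (100.0 - moisture_pct) / 100.0


def harmonized_value(record: ConcentrationRecord) -> float:
    """Censor-substitute then basis-convert one record to fresh weight."""
    value = substitute_censored(record)
    if record.basis == "dry":
        moisture = (
            record.moisture_pct
            if record.moisture_pct is not None
            else DEFAULT_MOISTURE_PCT
        )
        value = dry_to_wet(value, moisture)
    return value


def weighted_mean(values: Sequence[tuple[float, int]]) -> float | None:
    """Sample-size weighted mean: sum(C_i * N_i) / sum(N_i).

    Returns ``None`` for an empty input — absence of data is never
    reported as a zero concentration.
    """
    if not values:
        return None
    for c, n in values:
        if n < 1:
            raise ValueError(f"sample_n must be >= 1, got {n}")
        if c < 0:
            raise ValueError(f"concentration must be non-negative, got {c}")
    total_n = sum(n for _, n in values)
    return sum(c * n for c, n in values) / total_n


def build_catalog(
    entries: Iterable[SpeciesCatalogEntry],
) -> dict[str, list[SpeciesCatalogEntry]]:
    """Index catalog entries by normalized species name and alias.

    Raises on conflicting duplicates (same species+habitat mapped to
    different feeding classes, or the same normalized key re-used with
    different species spellings resolving differently).
    """
    index: dict[str, list[SpeciesCatalogEntry]] = {}
    seen: dict[tuple[str, Habitat], SpeciesCatalogEntry] = {}
    for entry in entries:
        key = (normalize_name(entry.species), entry.habitat)
        if key in seen:
            if seen[key].feeding != entry.feeding:
                raise ValueError(
                    f"conflicting catalog entries for {entry.species!r} "
                    f"in {entry.habitat}"
                )
            continue
        seen[key] = entry
        for name in (entry.species, *entry.aliases):
            index.setdefault(normalize_name(name), []).append(entry)
    return index


def build_profiles(
    records: Iterable[ConcentrationRecord],
    catalog: Iterable[SpeciesCatalogEntry],
) -> tuple[list[SpeciesProfile], list[ConcentrationRecord]]:
    """Aggregate harmonized records into per-(species, habitat) profiles.

    Each record is censor-substituted, converted to fresh weight, and
    pooled per metal by sample-size weighting.  Records whose species
    does not resolve in the catalog (after alias/case normalization) are
    returned in the rejects list; the run continues without them.  A
    species catalogued in two habitats receives the same records in both
    of its profiles, since literature records do not carry the habitat of
    the sampled population.
    """
    index = build_catalog(catalog)
    pools: dict[tuple[str, Habitat], dict[Metal, list[tuple[float, int]]]] = {}
    entry_for: dict[tuple[str, Habitat], SpeciesCatalogEntry] = {}
    rejects: list[ConcentrationRecord] = []

    for record in records:
        matches = index.get(normalize_name(record.species))
        if not matches:
            rejects.append(record)
            continue
        value = harmonized_value(record)
        for entry in matches:
            key = (entry.species, entry.habitat)
            entry_for[key] = entry
            pools.setdefault(key, {}).setdefault(record.metal, []).append(
                (value, record.sample_n)
            )

    profiles = []
    for key in sorted(pools, key=lambda k: (k[0], k[1].value)):
        entry = entry_for[key]
        conc = {}
        support = {}
        for metal, pairs in pools[key].items():
            wm = weighted_mean(pairs)
            assert wm is not None
            conc[metal] = wm
            support[metal] = sum(n for _, n in pairs)
        profiles.append(
            SpeciesProfile(
                species=entry.species,
                habitat=entry.habitat,
                feeding=entry.feeding,
                conc=conc,
                support=support,
            )
        )
    return profiles, rejects


def summarize_category(
    profiles: Iterable[SpeciesProfile],
    axis: Literal["habitat", "feeding"],
    class_label: Habitat | Feeding | str,
) -> dict[Metal, SummaryStats]:
    """Descriptive statistics per metal over one class's species profiles.

    Each species-level weighted mean counts as one data point; the class
    mean is unweighted across species.  sd uses the n-1 denominator and
    is absent for a single data point; the median of an even count is the
    midpoint of the two central values.
    """
    if axis == "habitat":
        label = parse_habitat(class_label) if isinstance(class_label, str) else class_label
        selected = [p for p in profiles if p.habitat == label]
    elif axis == "feeding":
        label = parse_feeding(class_label) if isinstance(class_label, str) else class_label
        selected = [p for p in profiles if p.feeding == label]
    else:
        raise ValueError(f"axis must be 'habitat' or 'feeding', got {axis!r}")

    out: dict[Metal, SummaryStats] = {}
    for metal in METALS:
        values = sorted(p.conc[metal] for p in selected if metal in p.conc)
        if not values:
            continue
        n = len(values)
        mean = sum(values) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        else:
            sd = None
        mid = n // 2
        median = values[mid] if n % 2 else (values[mid - 1] + values[mid]) / 2
        out[metal] = SummaryStats(n, values[0], values[-1], mean, sd, median)
    return out


def mpl_flags(
    conc: Mapping[Metal, float] | SpeciesProfile, toxref: ToxTable
) -> dict[Metal, int]:
    """Exceedance flags against the maximum permissible limits.

    Flag 1 iff the fresh-weight concentration *strictly* exceeds the MPL;
    a concentration exactly at the limit is compliant (flag 0).  Metals
    absent from the input are absent from the output.
    """
    if isinstance(conc, SpeciesProfile):
        conc = conc.conc
    flags = {}
    for metal, value in conc.items():
        mpl = toxref[metal].mpl
        if mpl is None:
            continue
        flags[metal] = 1 if value > mpl else 0
    return flags


# ---------------------------------------------------------------- CSV I/O

def read_records_csv(path) -> tuple[list[ConcentrationRecord], list[dict]]:
    """Read a ``records.csv`` file; returns (records, row-level errors)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"species", "metal", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records.csv missing columns: {sorted(missing)}")
    records, errors = [], []
    for i, row in df.iterrows():
        raw: dict = {
            "species": row["species"],
            "metal": row["metal"],
            "value": float(row["value"]),
        }
        if row.get("basis", ""):
            raw["basis"] = row["basis"]
        if row.get("censoring", ""):
            raw["censoring"] = row["censoring"]
        if row.get("moisture_pct", ""):
            raw["moisture_pct"] = float(row["moisture_pct"])
        if row.get("sample_n", ""):
            raw["sample_n"] = int(float(row["sample_n"]))
        if row.get("source_id", ""):
            raw["source_id"] = row["source_id"]
        try:
            records.append(ConcentrationRecord(**raw))
        except Exception as exc:  # noqa: BLE001 - row-level report
            errors.append({"row": int(i) + 2, "error": str(exc)})
    return records, errors


def read_catalog_csv(path) -> list[SpeciesCatalogEntry]:
    """Read a ``catalog.csv`` file (aliases |-separated)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries = []
    for _, row in df.iterrows():
        aliases = tuple(a for a in row.get("aliases", "").split("|") if a)
        entries.append(
            SpeciesCatalogEntry(
                species=row["species"],
                habitat=row["habitat"],
                feeding=row["feeding"],
                aliases=aliases,
            )
        )
    return entries


def profiles_to_frame(profiles: Iterable[SpeciesProfile]) -> pd.DataFrame:
    """Wide per-profile table: one row per (species, habitat), metal columns."""
    rows = []
    for p in profiles:
        row: dict = {
            "species": p.species,
            "habitat": p.habitat.value,
            "feeding": p.feeding.value,
        }
        for m in METALS:
            row[m.value] = p.conc.get(m)
            row[f"{m.value}_n"] = p.support.get(m)
        rows.append(row)
    return pd.DataFrame(rows)
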