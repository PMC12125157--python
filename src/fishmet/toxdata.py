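"""Toxicological reference values, exposure parameters, and controlled vocabularies.

Every downstream stage consumes the constants defined here: the nine
metal(loid)s tracked in Bangladeshi dietary fish, the two fish
classification axes (habitat salinity and feeding behaviour), per-metal
oral reference doses (RfDo), oral carcinogenic slope factors (SF),
maximum permissible limits (MPL) in fish tissue, and the adult exposure
scenario (ingestion rate, body weight, exposure frequency/duration).

A note on RfDo units: the reference doses are the standard USEPA oral
reference doses on the mg/(kg body weight)/day scale, which is the same
numeric scale as the chronic daily intake computed by
:mod:`fishmet.risk_engine` (concentrations in ug/g fresh weight times the
1e-3 factor land on mg/kg/day).  The hazard quotient is therefore the
plain ratio CDI / RfDo with no further conversion.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping


class Metal(str, enum.Enum):
    """The nine metal(loid)s, in fixed alphabetical order.

    The ordering is part of the public contract: report columns, tie-breaks
    for the limiting metal of a safe-consumption limit, and attribution
    rankings all use it.
    """

    As = "As"
    Cd = "Cd"
    Cr = "Cr"
    Cu = "Cu"
    Hg = "Hg"
    Mn = "Mn"
    Ni = "Ni"
    Pb = "Pb"
    Zn = "Zn"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


METALS: tuple[Metal, ...] = tuple(Metal)


class Habitat(str, enum.Enum):
    """Salinity-adaptation classes. ``seawater`` is accepted as an input alias."""

    freshwater = "freshwater"
    saltwater = "saltwater"
    euryhaline = "euryhaline"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Feeding(str, enum.Enum):
    """Feeding-behaviour classes."""

    omnivorous = "omnivorous"
    carnivorous = "carnivorous"
    herbivorous = "herbivorous"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


_HABITAT_ALIASES = {"seawater": Habitat.saltwater, "marine": Habitat.saltwater}


def parse_habitat(label: str) -> Habitat:
    """Resolve a habitat label, accepting the 'seawater' alias for saltwater."""
    key = label.strip().lower()
    if key in _HABITAT_ALIASES:
        return _HABITAT_ALIASES[key]
    try:
        return Habitat(key)
    except ValueError:
        raise ValueError(f"unknown habitat label: {label!r}") from None


def parse_feeding(label: str) -> Feeding:
    key = label.strip().lower()
    try:
        return Feeding(key)
    except ValueError:
        raise ValueError(f"unknown feeding label: {label!r}") from None


def parse_metal(symbol: str) -> Metal:
    try:
        return Metal(symbol.strip())
    except ValueError:
        raise ValueError(f"unknown metal symbol: {symbol!r}") from None


@dataclass(frozen=True)
class ToxRef:
    """Per-metal toxicological reference values.

    Attributes
    ----------
    metal:
        The metal(loid).
    rfdo:
        Oral reference dose, mg/kg/day scale (see module docstring); > 0.
    sf:
        Oral carcinogenic slope factor, per (mg/kg/day); ``None`` for
        metals with no published slope factor (Cu, Hg, Mn, Zn).  A missing
        slope factor means the cancer risk is *undefined*, never zero.
    mpl:
        Maximum permissible limit in fish tissue, ug/g fresh weight.
    """

    metal: Metal
    rfdo: float
    sf: float | None = None
    mpl: float | None = None

    def __post_init__(self) -> None:
        if not self.rfdo > 0:
            raise ValueError(f"rfdo must be positive for {self.metal}, got {self.rfdo}")
        if self.sf is not None and not self.sf > 0:
            raise ValueError(f"sf must be positive for {self.metal}, got {self.sf}")
        if self.mpl is not None and not self.mpl > 0:
            raise ValueError(f"mpl must be positive for {self.metal}, got {self.mpl}")


_DEFAULT_RFDO = {
    Metal.As: 0.0003,
    Metal.Cd: 0.001,
    Metal.Cr: 1.5,
    Metal.Cu: 0.04,
    Metal.Hg: 0.0003,
    Metal.Mn: 0.14,
    Metal.Ni: 0.02,
    Metal.Pb: 0.0035,
    Metal.Zn: 0.3,
}

# Slope factors exist for the five IRIS-listed carcinogens only.
_DEFAULT_SF = {
    Metal.As: 1.5,
    Metal.Cd: 0.38,
    Metal.Cr: 0.5,
    Metal.Ni: 1.7,
    Metal.Pb: 0.0085,
}

_DEFAULT_MPL = {
    Metal.As: 1.0,
    Metal.Cd: 0.05,
    Metal.Cr: 1.0,
    Metal.Cu: 30.0,
    Metal.Hg: 0.1,
    Metal.Mn: 1.0,
    Metal.Ni: 80.0,
    Metal.Pb: 0.3,
    Metal.Zn: 30.0,
}

ToxTable = Mapping[Metal, ToxRef]


def load_toxref(
    overrides: Mapping[Metal | str, Mapping[str, float]] | str | Path | None = None,
) -> ToxTable:
    """Return the nine-metal reference table, defaults merged under overrides.

    Parameters
    ----------
    overrides:
        Either a mapping ``{metal: {"rfdo": ..., "sf": ..., "mpl": ...}}``
        naming only known metals, or a path to a ``toxref.csv`` file with
        columns ``metal, rfdo, sf, mpl`` (empty cell = keep default /
        absent).  ``None`` returns the built-in defaults.

    Returns
    -------
    An immutable mapping Metal -> ToxRef covering all nine metals.
    """
    table = {
        m: ToxRef(m, _DEFAULT_RFDO[m], _DEFAULT_SF.get(m), _DEFAULT_MPL[m])
        for m in METALS
    }
    if overrides is None:
        return MappingProxyType(table)
    if isinstance(overrides, (str, Path)):
        overrides = _read_toxref_csv(overrides)
    for key, fields in overrides.items():
        metal = parse_metal(key if isinstance(key, str) else key.value)
        updates = {k: v for k, v in dict(fields).items() if v is not None}
        unknown = set(updates) - {"rfdo", "sf", "mpl"}
        if unknown:
            raise ValueError(f"unknown toxref fields for {metal}: {sorted(unknown)}")
        table[metal] = replace(table[metal], **updates)
    return MappingProxyType(table)


def _read_toxref_csv(path: str | Path) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            fields = {
                k: float(row[k]) for k in ("rfdo", "sf", "mpl") if row.get(k, "") != ""
            }
            out[row["metal"]] = fields
    return out


def write_toxref_csv(table: ToxTable, path: str | Path) -> None:
    """Write a reference table in the ``toxref.csv`` exchange schema."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metal", "rfdo", "sf", "mpl"])
        for m in METALS:
            ref = table[m]
            writer.writerow(
                [
                    m.value,
                    repr(ref.rfdo),
                    "" if ref.sf is None else repr(ref.sf),
                    "" if ref.mpl is None else repr(ref.mpl),
                ]
            )


@dataclass(frozen=True)
class ExposureParams:
    """Adult dietary exposure scenario for Bangladeshi fish consumers.

    ef: exposure frequency, days/year; ed: exposure duration, years;
    fir: fish ingestion rate, g/person/day; bw: body weight, kg;
    at: averaging time for non-carcinogens, days (365 x ed by default,
    so ef*ed/at = 1 exactly and the chronic daily intake reduces to
    fir * C / bw * 1e-3).
    """

    ef: float = 365.0
    ed: float = 70.0
    fir: float = 62.6
    bw: float = 60.0
    at: float = 365.0 * 70.0

    def __post_init__(self) -> None:
        for name in ("ef", "ed", "fir", "bw", "at"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def default_exposure() -> ExposureParams:
    """The default adult scenario: 365 d/yr for 70 yr, 62.6 g/day, 60 kg."""
    return ExposureParams()


def load_exposure(path: str | Path) -> ExposureParams:
    """Read an ``exposure.json`` override file (keys ef, ed, fir, bw, at)."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    known = {"ef", "ed", "fir", "bw", "at"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown exposure keys: {sorted(unknown)}")
    return ExposureParams(**{k: float(v) for k, v in raw.items()})
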