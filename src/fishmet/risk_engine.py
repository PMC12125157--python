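"""USEPA-style dietary exposure and risk computation for fish metal(loid)s.

Implements the chronic daily intake (CDI), target hazard quotient (THQ),
hazard index (HI), lifetime carcinogenic risk (CR), and the inversion of
the hazard quotient to a per-species safe daily consumption limit.

    CDI = (EF * ED * FIR * C) / (BW * AT) * 1e-3      [mg/kg/day]
    THQ = CDI / RfDo
    CR  = CDI * SF                                    (standard form)
    FIR_safe = (BW * RfDo * AT) / (EF * ED * C) * 1e3 [g/day], i.e. THQ=1

Two CR variants are provided.  ``cr_standard`` is the USEPA convention
CDI x SF and is the default everywhere.  ``cr_as_printed`` additionally
divides by RfDo (equivalently THQ x SF); some published assessments
print their CR equation in that form, and keeping both makes the
arithmetic auditable.  Metals without a slope factor (Cu, Hg, Mn, Zn)
have *undefined* — not zero — cancer risk and are skipped by cumulative
sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .harmonize import SpeciesProfile
from .toxdata import METALS, ExposureParams, Metal, ToxTable, default_exposure

THQ_THRESHOLD = 1.0
CR_UNACCEPTABLE = 1e-4
CR_GOAL = 1e-6


def cdi(c: float, p: ExposureParams | None = None) -> float:
    """Chronic daily intake (mg/kg/day) from a fresh-weight concentration (ug/g)."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    p = p or default_exposure()
    return (p.ef * p.ed * p.fir * c) / (p.bw * p.at) * 1e-3


def thq(
    c: float, metal: Metal, toxref: ToxTable, p: ExposureParams | None = None
) -> float:
    """Target hazard quotient: CDI / RfDo. Linear in the concentration."""
    return cdi(c, p) / toxref[metal].rfdo


def hazard_index(
    conc: Mapping[Metal, float] | SpeciesProfile,
    toxref: ToxTable,
    p: ExposureParams | None = None,
) -> tuple[float, dict[Metal, float]]:
    """Cumulative THQ over the metals present in the input.

    Returns (HI, per-metal THQ).  Absent metals contribute nothing — they
    are unknown, not zero.
    """
    if isinstance(conc, SpeciesProfile):
        conc = conc.conc
    if not conc:
        raise ValueError("hazard_index requires at least one metal")
    per_metal = {m: thq(c, m, toxref, p) for m, c in conc.items()}
    return sum(per_metal.values()), per_metal


def cr_standard(
    c: float, metal: Metal, toxref: ToxTable, p: ExposureParams | None = None
) -> float | None:
    """Lifetime carcinogenic risk, CDI x SF; ``None`` if no slope factor."""
    sf = toxref[metal].sf
    if sf is None:
        return None
    return cdi(c, p) * sf


def cr_as_printed(
    c: float, metal: Metal, toxref: ToxTable, p: ExposureParams | None = None
) -> float | None:
    """Audit variant dividing by RfDo as well: THQ x SF.

    Equals ``cr_standard / rfdo`` identically; retained for checking
    published tables computed with that equation, never used in default
    reports.
    """
    sf = toxref[metal].sf
    if sf is None:
        return None
    return thq(c, metal, toxref, p) * sf


def cumulative_cr(
    conc: Mapping[Metal, float] | SpeciesProfile,
    toxref: ToxTable,
    p: ExposureParams | None = None,
    variant: str = "standard",
) -> tuple[float, dict[Metal, float]]:
    """Sum of CR over the slope-factor metals present in the input."""
    if isinstance(conc, SpeciesProfile):
        conc = conc.conc
    fn = cr_standard if variant == "standard" else cr_as_printed
    per_metal = {}
    for m, c in conc.items():
        value = fn(c, m, toxref, p)
        if value is not None:
            per_metal[m] = value
    return sum(per_metal.values()), per_metal


@dataclass(frozen=True)
class RiskResult:
    """Per-metal exposure/risk for one subject (a species or a category mean)."""

    subject: str
    cdi: Mapping[Metal, float]
    thq: Mapping[Metal, float]
    cr: Mapping[Metal, float]  # slope-factor metals only
    hi: float
    cr_total: float
    thq_exceeded: bool  # any single THQ > 1
    cr_exceeded: bool  # cumulative CR > 1e-4


def assess(
    subject: str,
    conc: Mapping[Metal, float] | SpeciesProfile,
    toxref: ToxTable,
    p: ExposureParams | None = None,
    cr_variant: str = "standard",
) -> RiskResult:
    """Full non-carcinogenic + carcinogenic screen for one concentration vector."""
    if isinstance(conc, SpeciesProfile):
        conc = conc.conc
    hi, per_thq = hazard_index(conc, toxref, p)
    cr_total, per_cr = cumulative_cr(conc, toxref, p, variant=cr_variant)
    per_cdi = {m: cdi(c, p) for m, c in conc.items()}
    return RiskResult(
        subject=subject,
        cdi=per_cdi,
        thq=per_thq,
        cr=per_cr,
        hi=hi,
        cr_total=cr_total,
        thq_exceeded=any(v > THQ_THRESHOLD for v in per_thq.values()),
        cr_exceeded=cr_total > CR_UNACCEPTABLE,
    )


# ------------------------------------------------------- safe-limit inversion

@dataclass(frozen=True)
class SafeLimit:
    """Per-metal allowable daily intakes and the binding minimum.

    ``overall_fir`` is the largest daily fish intake (g/day) at which no
    metal's hazard quotient exceeds 1; ``limiting_metal`` attains it.
    """

    subject: str
    per_metal_fir: Mapping[Metal, float]
    limiting_metal: Metal
    overall_fir: float


def safe_fir(
    c: float, metal: Metal, toxref: ToxTable, p: ExposureParams | None = None
) -> float:
    """Daily intake (g/day) at which the metal's THQ is exactly 1.

    FIR = (BW * RfDo * AT) / (EF * ED * C) * 1e3.  A zero concentration
    imposes no limit and returns +inf (the metal can never be binding).
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    p = p or default_exposure()
    if c == 0:
        return float("inf")
    return (p.bw * toxref[metal].rfdo * p.at) / (p.ef * p.ed * c) * 1e3


def species_safe_limit(
    profile: SpeciesProfile | Mapping[Metal, float],
    toxref: ToxTable,
    p: ExposureParams | None = None,
    subject: str | None = None,
) -> SafeLimit:
    """Safe consumption limit for one species: the minimum per-metal FIR.

    Ties for the limiting metal break by the fixed metal ordering, so
    output is deterministic.
    """
    if isinstance(profile, SpeciesProfile):
        subject = subject or profile.species
        conc = profile.conc
    else:
        subject = subject or ""
        conc = profile
    if not conc or all(c == 0 for c in conc.values()):
        raise ValueError("safe limit requires at least one positive concentration")
    per_metal = {m: safe_fir(c, m, toxref, p) for m, c in conc.items()}
    limiting = min(
        (m for m in METALS if m in per_metal), key=lambda m: (per_metal[m], METALS.index(m))
    )
    return SafeLimit(
        subject=subject,
        per_metal_fir=per_metal,
        limiting_metal=limiting,
        overall_fir=per_metal[limiting],
    )


def category_safe_limit(
    profiles: Iterable[SpeciesProfile],
    toxref: ToxTable,
    p: ExposureParams | None = None,
) -> float:
    """Unweighted mean of the species-level overall safe limits in a class."""
    limits = [species_safe_limit(pr, toxref, p).overall_fir for pr in profiles]
    if not limits:
        raise ValueError("category_safe_limit requires a non-empty class")
    return sum(limits) / len(limits)


# ------------------------------------------------------------------ tables

def risk_table(
    results: Iterable[RiskResult], toxref: ToxTable, cr_variant: str = "standard"
) -> pd.DataFrame:
    """Long-format risk table (one row per subject x metal) for ``risk.csv``."""
    rows = []
    for r in results:
        for m in METALS:
            if m not in r.thq:
                continue
            rows.append(
                {
                    "subject": r.subject,
                    "metal": m.value,
                    "cdi": r.cdi[m],
                    "thq": r.thq[m],
                    "cr": r.cr.get(m),
                    "cr_variant": cr_variant if m in r.cr else None,
                    "thq_flag": int(r.thq[m] > THQ_THRESHOLD),
                }
            )
    return pd.DataFrame(rows)


def safelimit_table(limits: Iterable[SafeLimit]) -> pd.DataFrame:
    """Wide per-species safe-limit table for ``safelimits.csv``."""
    rows = []
    for sl in limits:
        row: dict = {"subject": sl.subject}
        for m in METALS:
            v = sl.per_metal_fir.get(m)
            row[f"fir_{m.value}"] = v
        row["limiting_metal"] = sl.limiting_metal.value
        row["overall_fir"] = sl.overall_fir
        rows.append(row)
    return pd.DataFrame(rows)
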