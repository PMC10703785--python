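"""Mineral composition tables and nutrient change relative to a reference.

Concentrations for ten minerals (Ca, P, K, Na, Al, Cu, Fe, Mg, Mn, S) are
carried in ppm together with an energy density in Cal/g air-dry basis (ADB)
and duplicate-analysis standard deviations. Below-detection cells written
as ``<x`` are kept as censored entries with the detection bound.

The nutrient-change statistic for a pathway is the unweighted arithmetic
mean of the per-mineral signed percent changes against a reference profile
(normally the raw-unstored sample, RW-US); censored minerals are excluded
from the mean unless a bound/2 substitution is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .pathways import PathwayID

__all__ = [
    "MINERALS",
    "MineralProfile",
    "ChangeReport",
    "read_mineral_profiles",
    "percent_change",
    "profile_change",
]

#: canonical mineral order of the composition tables
MINERALS = ("Ca", "P", "K", "Na", "Al", "Cu", "Fe", "Mg", "Mn", "S")


@dataclass(frozen=True)
class MineralProfile:
    """Mineral concentrations (ppm) and calories (Cal/g ADB) for a pathway."""

    pathway: PathwayID
    calories: float
    concentration: Mapping[str, float]
    sd: Mapping[str, float] = field(default_factory=dict)
    censored: frozenset[str] = frozenset()
    calories_sd: float = 0.0

    def __post_init__(self) -> None:
        missing = set(MINERALS) - set(self.concentration) - set(self.censored)
        if missing:
            raise ValueError(f"profile {self.pathway} missing minerals: {sorted(missing)}")
        for m, v in self.concentration.items():
            if v < 0:
                raise ValueError(f"negative concentration for {m}: {v}")
        for m, v in self.sd.items():
            if v < 0:
                raise ValueError(f"negative sd for {m}: {v}")

    def minerals(self, include_censored: bool = False) -> tuple[str, ...]:
        if include_censored:
            return MINERALS
        return tuple(m for m in MINERALS if m not in self.censored)


@dataclass(frozen=True)
class ChangeReport:
    """Signed percent changes of a pathway's minerals vs a reference.

    ``aggregate_pct`` is the unweighted arithmetic mean of ``pct_change``
    over ``minerals_used``; positive values are gains.
    """

    pathway: PathwayID
    reference: PathwayID
    pct_change: Mapping[str, float]
    aggregate_pct: float
    minerals_used: tuple[str, ...]
    calories_pct: float

    def recompute_aggregate(self) -> float:
        return sum(self.pct_change[m] for m in self.minerals_used) / len(self.minerals_used)


def percent_change(value: float, reference: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``.

    Positive means gain. ``reference`` must be strictly positive.
    """
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return 100.0 * (value - reference) / reference


def _parse_cell(raw: object) -> tuple[float, bool]:
    """Parse a concentration cell; ``"<x"`` marks a censored value with bound x."""
    if isinstance(raw, str) and raw.strip().startswith("<"):
        return float(raw.strip()[1:]), True
    value = float(raw)  # type: ignore[arg-type]
    return value, False


def read_mineral_profiles(path: str | Path) -> list[MineralProfile]:
    """Read a mineral-composition CSV into :class:`MineralProfile` rows.

    Expected schema: ``pathway,duration_weeks,calories,calories_sd,
    Ca,Ca_sd,...,S,S_sd``; ``<x`` cells are allowed in concentration
    columns and become censored entries carrying the detection bound.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    required = {"pathway", "duration_weeks", "calories"} | set(MINERALS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    profiles: list[MineralProfile] = []
    for _, row in df.iterrows():
        pathway = PathwayID.parse(row["pathway"], int(row["duration_weeks"]))
        conc: dict[str, float] = {}
        sd: dict[str, float] = {}
        censored: set[str] = set()
        for m in MINERALS:
            value, is_censored = _parse_cell(row[m])
            if is_censored:
                censored.add(m)
                conc[m] = value  # detection bound, flagged censored
            else:
                if value < 0:
                    raise ValueError(f"{path}: negative concentration {m}={value}")
                conc[m] = value
            sd_col = f"{m}_sd"
            if sd_col in df.columns and not pd.isna(row[sd_col]):
                sd[m] = float(row[sd_col])
        cal_sd = float(row["calories_sd"]) if "calories_sd" in df.columns else 0.0
        profiles.append(
            MineralProfile(
                pathway=pathway,
                calories=float(row["calories"]),
                concentration=conc,
                sd=sd,
                censored=frozenset(censored),
                calories_sd=cal_sd,
            )
        )
    return profiles


def profile_change(
    profile: MineralProfile,
    reference: MineralProfile,
    censored_as_half_bound: bool = False,
) -> ChangeReport:
    """Per-mineral and aggregate percent change of ``profile`` vs ``reference``.

    Minerals censored in either profile are excluded from the aggregate
    unless ``censored_as_half_bound`` substitutes bound/2 for the censored
    concentration. Calories change is reported separately and never enters
    the mineral aggregate.
    """
    if set(profile.concentration) != set(reference.concentration):
        raise ValueError(
            "mineral sets differ between profile "
            f"{profile.pathway} and reference {reference.pathway}"
        )

    censored = set(profile.censored) | set(reference.censored)
    pct: dict[str, float] = {}
    used: list[str] = []
    for m in MINERALS:
        v, r = profile.concentration[m], reference.concentration[m]
        if m in censored:
            if not censored_as_half_bound:
                continue
            if m in profile.censored:
                v = v / 2.0
            if m in reference.censored:
                r = r / 2.0
        pct[m] = percent_change(v, r)
        used.append(m)
    if not used:
        raise ValueError("no usable minerals after censoring exclusions")
    aggregate = sum(pct[m] for m in used) / len(used)
    return ChangeReport(
        pathway=profile.pathway,
        reference=reference.pathway,
        pct_change=pct,
        aggregate_pct=aggregate,
        minerals_used=tuple(used),
        calories_pct=percent_change(profile.calories, reference.calories),
    )


def change_table(
    profiles: Iterable[MineralProfile],
    reference: MineralProfile,
    censored_as_half_bound: bool = False,
) -> pd.DataFrame:
    """Aggregate change report for many profiles as a tidy DataFrame."""
    rows = []
    for p in profiles:
        if p.pathway == reference.pathway:
            continue
        rep = profile_change(p, reference, censored_as_half_bound)
        rows.append(
            {
                "pathway": p.pathway.label,
                "duration_weeks": p.pathway.duration_weeks,
                "aggregate_pct": rep.aggregate_pct,
                "calories_pct": rep.calories_pct,
                "n_minerals": len(rep.minerals_used),
            }
        )
    return pd.DataFrame(rows)


def _isclose_report(report: ChangeReport, tol: float = 1e-9) -> bool:
    """True when the stored aggregate matches its recomputation."""
    return math.isclose(report.aggregate_pct, report.recompute_aggregate(), abs_tol=tol)
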