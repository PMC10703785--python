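"""Linear life-cycle impact characterization: midpoints, endpoints, ratios.

Inventory flows are mapped to 18 midpoint impact categories by a linear
characterization matrix (score_c = sum_f amount_f * factor_{f,c}), the
midpoints normalized against per-person reference values, and translated
to three endpoint areas of protection — human health (DALY), ecosystem
quality (species.yr) and resource availability (USD2013). A contribution
table attributes each category's score to flows, pooling contributions
under a cutoff (default 0.1%) into "other".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .energy import Inventory
from .pathways import PathwayID

__all__ = [
    "CATEGORIES",
    "CATEGORY_UNITS",
    "ENDPOINTS",
    "ENDPOINT_UNITS",
    "CharacterizationModel",
    "MidpointResult",
    "EndpointResult",
    "characterize",
    "normalize",
    "to_endpoint",
    "contribution_table",
    "damage_ratio",
]

#: the 18 midpoint impact categories, by conventional abbreviation
CATEGORIES = (
    "FPM", "FRS", "FEW", "FET", "GW", "HCT", "HNCT", "IR", "LU",
    "ME", "MET", "MRS", "OFHH", "OFTE", "SOD", "TAD", "TET", "WC",
)

CATEGORY_UNITS: dict[str, str] = {
    "FPM": "kg PM2.5 eq",
    "FRS": "kg oil eq",
    "FEW": "kg 1,4-DCB",
    "FET": "kg P eq",
    "GW": "kg CO2 eq",
    "HCT": "kg 1,4-DCB",
    "HNCT": "kg 1,4-DCB",
    "IR": "kBq Co-60 eq",
    "LU": "m2a crop eq",
    "ME": "kg 1,4-DCB",
    "MET": "kg N eq",
    "MRS": "kg Cu eq",
    "OFHH": "kg NOx eq",
    "OFTE": "kg NOx eq",
    "SOD": "kg CFC11 eq",
    "TAD": "kg SO2 eq",
    "TET": "kg 1,4-DCB",
    "WC": "m3",
}

ENDPOINTS = ("human_health", "ecosystems", "resources")
ENDPOINT_UNITS = {
    "human_health": "DALY",
    "ecosystems": "species.yr",
    "resources": "USD2013",
}


@dataclass
class CharacterizationModel:
    """Flow->midpoint and midpoint->endpoint factor matrices.

    midpoint_factors: DataFrame indexed by flow name with the 18 category
    columns; endpoint_factors: DataFrame indexed by category with the
    three endpoint columns; normalization_refs: per-person reference per
    category (all > 0).
    """

    midpoint_factors: pd.DataFrame
    endpoint_factors: pd.DataFrame
    normalization_refs: pd.Series
    category_units: Mapping[str, str] = field(default_factory=lambda: dict(CATEGORY_UNITS))
    flow_units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.midpoint_factors.columns)
        if missing:
            raise ValueError(f"midpoint factors missing categories: {sorted(missing)}")
        missing = set(CATEGORIES) - set(self.endpoint_factors.index)
        if missing:
            raise ValueError(f"endpoint factors missing categories: {sorted(missing)}")
        missing = set(ENDPOINTS) - set(self.endpoint_factors.columns)
        if missing:
            raise ValueError(f"endpoint factors missing endpoints: {sorted(missing)}")
        if not np.isfinite(self.midpoint_factors[list(CATEGORIES)].to_numpy()).all():
            raise ValueError("non-finite midpoint factors")


@dataclass
class MidpointResult:
    """Scores in the 18 midpoint categories for one pathway, per FU."""

    pathway: PathwayID
    score: pd.Series  # index = CATEGORIES

    def __post_init__(self) -> None:
        self.score = self.score.reindex(list(CATEGORIES))
        if self.score.isna().any():
            missing = list(self.score.index[self.score.isna()])
            raise ValueError(f"midpoint result missing categories: {missing}")


@dataclass(frozen=True)
class EndpointResult:
    """Endpoint damage scores for one pathway, per functional unit."""

    pathway: PathwayID
    human_health: float  # DALY
    ecosystems: float  # species.yr
    resources: float  # USD2013

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "human_health": self.human_health,
                "ecosystems": self.ecosystems,
                "resources": self.resources,
            }
        )


def _check_units(inv: Inventory, model: CharacterizationModel) -> None:
    for flow, unit in model.flow_units.items():
        have = inv.units.get(flow)
        if have is not None and have != unit:
            raise ValueError(
                f"unit mismatch for flow {flow!r}: inventory carries "
                f"{have!r}, factors expect {unit!r}"
            )


def characterize(inv: Inventory, model: CharacterizationModel) -> MidpointResult:
    """Linear midpoint characterization of an inventory.

    Flows without a factor row contribute zero and raise a warning.
    """
    _check_units(inv, model)
    unmatched = [f for f in inv.flows if f not in model.midpoint_factors.index]
    if unmatched:
        warnings.warn(
            f"flows without characterization factors (zero contribution): {unmatched}",
            stacklevel=2,
        )
    amounts = pd.Series(inv.flows, dtype=float).reindex(
        model.midpoint_factors.index, fill_value=0.0
    )
    scores = model.midpoint_factors[list(CATEGORIES)].mul(amounts, axis=0).sum(axis=0)
    return MidpointResult(pathway=inv.pathway, score=scores)


def normalize(mid: MidpointResult, model: CharacterizationModel) -> pd.Series:
    """Dimensionless person-equivalent scores: score / normalization ref."""
    refs = model.normalization_refs.reindex(list(CATEGORIES))
    if (refs <= 0).any() or refs.isna().any():
        bad = list(refs.index[(refs <= 0) | refs.isna()])
        raise ValueError(f"normalization references must be > 0; bad: {bad}")
    return mid.score / refs


def to_endpoint(mid: MidpointResult, model: CharacterizationModel) -> EndpointResult:
    """Translate midpoint scores to the three endpoint areas of protection."""
    ep = model.endpoint_factors.loc[list(CATEGORIES), list(ENDPOINTS)]
    totals = ep.mul(mid.score, axis=0).sum(axis=0)
    return EndpointResult(
        pathway=mid.pathway,
        human_health=float(totals["human_health"]),
        ecosystems=float(totals["ecosystems"]),
        resources=float(totals["resources"]),
    )


def contribution_table(
    inv: Inventory,
    model: CharacterizationModel,
    cutoff: float = 0.001,
) -> pd.DataFrame:
    """Per-flow share of each category score, with sub-cutoff pooling.

    Shares sum to 1 per category before the cutoff; flows contributing
    less than ``cutoff`` (fraction) to a category are pooled into an
    ``other`` row. Categories with zero total score carry all-zero shares.
    """
    if not 0 <= cutoff < 1:
        raise ValueError(f"cutoff must be in [0, 1), got {cutoff}")
    amounts = pd.Series(inv.flows, dtype=float).reindex(
        model.midpoint_factors.index, fill_value=0.0
    )
    contrib = model.midpoint_factors[list(CATEGORIES)].mul(amounts, axis=0)
    totals = contrib.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = contrib.div(totals.where(totals != 0), axis=1).fillna(0.0)

    kept = shares.where(shares >= cutoff, 0.0)
    other = shares.where(shares < cutoff, 0.0).sum(axis=0)
    kept.loc["other"] = other
    return kept


def damage_ratio(a: EndpointResult, b: EndpointResult) -> tuple[dict[str, float], float]:
    """Per-endpoint damage ratios a/b and their unweighted mean."""
    num, den = a.as_series(), b.as_series()
    if (den <= 0).any():
        bad = list(den.index[den <= 0])
        raise ValueError(f"denominator endpoints must be > 0; bad: {bad}")
    ratios = num / den
    return dict(ratios), float(ratios.mean())
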