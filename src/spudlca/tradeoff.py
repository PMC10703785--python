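"""TOPSIS decision modelling over storage-and-processing pathways.

Alternatives (pathways) are scored on five criteria in two groups:
environment — human health damage (minimize), resource depletion
(minimize), ecosystem damage (minimize) — and nutrition — aggregate
mineral gain/loss (maximize) and calories (maximize). Group-level
preference weights ([0.8, 0.2] environment-priority, [0.2, 0.8]
nutrition-priority, [0.5, 0.5] equal) are split equally among each
group's criteria. TOPSIS vector-normalizes each criterion column,
applies the realized weights, and ranks alternatives by relative
closeness C = D-/(D+ + D-) to the ideal/anti-ideal points; pathways
whose scores differ by at most a practical-significance band (default
|dC| <= 0.01) are treated as equivalent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .impact import EndpointResult
from .nutrition import ChangeReport

__all__ = [
    "Direction",
    "Criterion",
    "DecisionMatrix",
    "WeightScheme",
    "TopsisResult",
    "CONTEXT_WEIGHTS",
    "DEFAULT_CRITERIA",
    "build_decision_matrix",
    "expand_weights",
    "topsis_scores",
    "rank_with_equivalence",
]


class Direction(str, enum.Enum):
    MINIMIZE = "minimize"
    MAXIMIZE = "maximize"


@dataclass(frozen=True)
class Criterion:
    name: str
    group: str  # "environment" | "nutrition"
    direction: Direction


#: the default five-criterion set
DEFAULT_CRITERIA: tuple[Criterion, ...] = (
    Criterion("human_health_damage", "environment", Direction.MINIMIZE),
    Criterion("resource_depletion", "environment", Direction.MINIMIZE),
    Criterion("ecosystem_damage", "environment", Direction.MINIMIZE),
    Criterion("mineral_gain_loss", "nutrition", Direction.MAXIMIZE),
    Criterion("calories", "nutrition", Direction.MAXIMIZE),
)

#: consumer priority contexts -> (environment, nutrition) group weights
CONTEXT_WEIGHTS: dict[str, tuple[float, float]] = {
    "environment": (0.8, 0.2),
    "nutrition": (0.2, 0.8),
    "equal": (0.5, 0.5),
}


@dataclass
class DecisionMatrix:
    """Alternatives x criteria values with objective directions."""

    values: pd.DataFrame  # index = alternative labels, columns = criterion names
    criteria: Sequence[Criterion] = DEFAULT_CRITERIA

    def __post_init__(self) -> None:
        names = [c.name for c in self.criteria]
        missing = set(names) - set(self.values.columns)
        if missing:
            raise ValueError(f"decision matrix missing criterion columns: {sorted(missing)}")
        self.values = self.values[names]
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValueError(f"missing cells for alternatives: {bad}")


@dataclass(frozen=True)
class WeightScheme:
    """Hierarchical weights: group-level preferences split within groups."""

    group_weights: Mapping[str, float]  # {"environment": w, "nutrition": 1-w}
    within_group: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.group_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group weights must sum to 1, got {total}")


@dataclass
class TopsisResult:
    """Closeness coefficients, ranks and equivalence classes."""

    scores: pd.Series  # alternative -> closeness in [0, 1]
    ranks: pd.Series  # rank 1 = best (highest closeness)
    equivalence_classes: list[list[str]] = field(default_factory=list)
    threshold: float = 0.01


def expand_weights(
    group_weights: Mapping[str, float] | Sequence[float],
    criteria: Sequence[Criterion] = DEFAULT_CRITERIA,
) -> pd.Series:
    """Realized per-criterion weights from group-level preferences.

    Each group's weight is split equally among its criteria; the result
    sums to 1. A bare [w_env, w_nut] pair is accepted.
    """
    if not isinstance(group_weights, Mapping):
        env, nut = group_weights
        group_weights = {"environment": env, "nutrition": nut}
    total = sum(group_weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"group weights must sum to 1, got {total}")
    counts: dict[str, int] = {}
    for c in criteria:
        counts[c.group] = counts.get(c.group, 0) + 1
    weights = {}
    for c in criteria:
        if c.group not in group_weights:
            raise ValueError(f"no group weight for {c.group!r}")
        weights[c.name] = group_weights[c.group] / counts[c.group]
    return pd.Series(weights)


def build_decision_matrix(
    endpoints: Mapping[str, EndpointResult],
    changes: Mapping[str, ChangeReport],
    calories: Mapping[str, float],
    criteria: Sequence[Criterion] = DEFAULT_CRITERIA,
) -> DecisionMatrix:
    """Assemble the five-criterion decision matrix from pipeline outputs.

    Keys of the three mappings are alternative labels; every alternative
    must appear in all three. Endpoint units (DALY, species.yr, USD2013)
    pass through unchanged.
    """
    rows = {}
    for alt, ep in endpoints.items():
        if alt not in changes:
            raise ValueError(f"alternative {alt!r} missing a mineral change report")
        if alt not in calories:
            raise ValueError(f"alternative {alt!r} missing calories")
        rows[alt] = {
            "human_health_damage": ep.human_health,
            "resource_depletion": ep.resources,
            "ecosystem_damage": ep.ecosystems,
            "mineral_gain_loss": changes[alt].aggregate_pct,
            "calories": calories[alt],
        }
    return DecisionMatrix(values=pd.DataFrame.from_dict(rows, orient="index"), criteria=criteria)


def topsis_scores(
    matrix: DecisionMatrix,
    weights: WeightScheme | Mapping[str, float] | Sequence[float] | pd.Series,
) -> TopsisResult:
    """Closeness coefficients by the canonical TOPSIS formulation.

    Columns are vector-normalized (divided by their Euclidean norm),
    weighted, and compared against the ideal point (column max for
    maximize criteria, min for minimize) and anti-ideal (reversed);
    C = D-/(D+ + D-), higher is better.
    """
    if isinstance(weights, WeightScheme):
        w = expand_weights(weights.group_weights, matrix.criteria)
    elif isinstance(weights, pd.Series):
        w = weights
    elif isinstance(weights, Mapping):
        w = pd.Series(weights)
    else:
        w = expand_weights(weights, matrix.criteria)
    names = [c.name for c in matrix.criteria]
    w = w.reindex(names)
    if w.isna().any():
        raise ValueError("weights missing for some criteria")

    X = matrix.values[names].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("TOPSIS needs at least 2 alternatives")
    norms = np.linalg.norm(X, axis=0)
    if (norms == 0).any():
        zero = [names[j] for j in np.flatnonzero(norms == 0)]
        raise ValueError(f"all-zero criterion columns cannot be normalized: {zero}")

    V = (X / norms) * w.to_numpy()
    maximize = np.array([c.direction is Direction.MAXIMIZE for c in matrix.criteria])
    ideal = np.where(maximize, V.max(axis=0), V.min(axis=0))
    anti = np.where(maximize, V.min(axis=0), V.max(axis=0))
    d_pos = np.linalg.norm(V - ideal, axis=1)
    d_neg = np.linalg.norm(V - anti, axis=1)
    denom = d_pos + d_neg
    # identical alternatives in a degenerate matrix: D+ = D- = 0
    if (denom == 0).all():
        raise ValueError("degenerate matrix: all alternatives identical")
    closeness = np.divide(d_neg, denom, out=np.full_like(denom, 0.5), where=denom != 0)

    scores = pd.Series(closeness, index=matrix.values.index, name="closeness")
    ranks = scores.rank(ascending=False, method="min").astype(int)
    return TopsisResult(scores=scores, ranks=ranks)


def rank_with_equivalence(
    result: TopsisResult,
    threshold: float = 0.01,
    relative: bool = False,
) -> pd.DataFrame:
    """Descending ranking with practical-equivalence classes.

    Adjacent alternatives whose closeness scores differ by at most
    ``threshold`` (absolute by default; relative to the larger score if
    ``relative``) are chained into one equivalence class (transitive
    closure over adjacent pairs).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    ordered = result.scores.sort_values(ascending=False)
    labels = list(ordered.index)
    classes: list[list[str]] = []
    current = [labels[0]] if labels else []
    for prev, nxt in zip(labels, labels[1:]):
        gap = ordered[prev] - ordered[nxt]
        if relative and ordered[prev] != 0:
            gap = gap / abs(ordered[prev])
        if gap <= threshold + 1e-15:
            current.append(nxt)
        else:
            classes.append(current)
            current = [nxt]
    if current:
        classes.append(current)

    class_of = {alt: i + 1 for i, group in enumerate(classes) for alt in group}
    frame = pd.DataFrame(
        {
            "alternative": labels,
            "closeness": [ordered[a] for a in labels],
            "rank": range(1, len(labels) + 1),
            "equivalence_class": [class_of[a] for a in labels],
        }
    )
    result.equivalence_classes = classes
    result.threshold = threshold
    return frame
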