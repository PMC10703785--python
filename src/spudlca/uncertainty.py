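"""Pedigree-matrix lognormal Monte Carlo uncertainty propagation.

Each foreground flow carries five data-quality scores (reliability,
completeness, temporal, geographic and technological correlation, each
1-5) that map through an indicator factor table to per-indicator
uncertainty factors U_i; together with a basic geometric SD U_b they
combine into the flow's geometric standard deviation

    gsd = exp( sqrt( sum_i ln(U_i)^2 + ln(U_b)^2 ) ).

Monte Carlo iterations perturb every flow amount with an independent
median-preserving lognormal draw (median = deterministic amount,
geometric SD = gsd), re-characterize, and summarize each midpoint
category with mean, SD, the coefficient of variation CV = 100*sd/mean,
and 5th/95th percentile bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .energy import Inventory
from .impact import CATEGORIES, CharacterizationModel, characterize, normalize

__all__ = [
    "PEDIGREE_FACTORS",
    "PedigreeScores",
    "UncertaintySummary",
    "pedigree_gsd",
    "sample_lognormal",
    "monte_carlo_impacts",
    "cv",
    "percentile_bounds",
    "sensitivity",
]

#: indicator uncertainty factors per quality score 1..5, following the
#: classic ecoinvent pedigree convention; overridable per call.
PEDIGREE_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "reliability": (1.00, 1.05, 1.10, 1.20, 1.50),
    "completeness": (1.00, 1.02, 1.05, 1.10, 1.20),
    "temporal": (1.00, 1.03, 1.10, 1.20, 1.50),
    "geographic": (1.00, 1.01, 1.02, 1.05, 1.10),
    "technological": (1.00, 1.05, 1.20, 1.50, 2.00),
}


@dataclass(frozen=True)
class PedigreeScores:
    """Data-quality scores (1 best .. 5 worst) plus a basic geometric SD."""

    reliability: int = 1
    completeness: int = 1
    temporal: int = 1
    geographic: int = 1
    technological: int = 1
    basic_uncertainty: float = 1.0

    def __post_init__(self) -> None:
        for name in ("reliability", "completeness", "temporal", "geographic", "technological"):
            score = getattr(self, name)
            if score not in (1, 2, 3, 4, 5):
                raise ValueError(f"{name} score must be in 1..5, got {score}")
        if self.basic_uncertainty < 1.0:
            raise ValueError(
                f"basic_uncertainty must be a geometric SD >= 1, got {self.basic_uncertainty}"
            )


@dataclass(frozen=True)
class UncertaintySummary:
    """Monte Carlo summary for one impact category."""

    category: str
    mean: float
    sd: float
    cv_pct: float
    lower: float  # 5th percentile
    upper: float  # 95th percentile
    n_iterations: int


def pedigree_gsd(
    scores: PedigreeScores,
    factors: Mapping[str, tuple[float, ...]] | None = None,
) -> float:
    """Geometric standard deviation implied by a pedigree scoring."""
    table = factors or PEDIGREE_FACTORS
    ssq = np.log(scores.basic_uncertainty) ** 2
    for name, row in table.items():
        u = row[getattr(scores, name) - 1]
        ssq += np.log(u) ** 2
    return float(np.exp(np.sqrt(ssq)))


def sample_lognormal(
    median: float,
    gsd: float,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Median-preserving lognormal draws: geometric mean -> median,
    geometric SD -> gsd. ``seed`` may be an int or a Generator (so a
    caller can share one stream across flows)."""
    if median <= 0:
        raise ValueError(f"median must be > 0, got {median}")
    if gsd < 1:
        raise ValueError(f"geometric SD must be >= 1, got {gsd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if gsd == 1.0:
        return np.full(n, median)
    return rng.lognormal(mean=np.log(median), sigma=np.log(gsd), size=n)


def cv(samples=None, mean: float | None = None, sd: float | None = None) -> float:
    """Coefficient of variation in percent: 100*sd/mean.

    Accepts either a sample array or an explicit (mean, sd) pair.
    """
    if samples is not None:
        arr = np.asarray(samples, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if mean is None or sd is None:
        raise ValueError("provide samples or both mean and sd")
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def percentile_bounds(samples, lo: float = 5.0, hi: float = 95.0) -> tuple[float, float]:
    """(lo, hi) percentile bounds via linear interpolation between order
    statistics."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples for percentile bounds")
    lower, upper = np.percentile(arr, [lo, hi], method="linear")
    return float(lower), float(upper)


def monte_carlo_impacts(
    inv: Inventory,
    model: CharacterizationModel,
    pedigree: Mapping[str, PedigreeScores],
    n: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[UncertaintySummary]]:
    """Propagate flow uncertainty through characterization.

    Every iteration draws an independent lognormal multiplier for each
    flow (median at the deterministic amount, gsd from that flow's
    pedigree; flows without pedigree entries stay fixed), re-characterizes
    and records all 18 category scores.

    Returns the (n x 18) sample frame and per-category summaries.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 iterations, got {n}")
    rng = np.random.default_rng(seed)
    flow_names = list(inv.flows)
    gsds = np.array(
        [pedigree_gsd(pedigree[f]) if f in pedigree else 1.0 for f in flow_names]
    )
    amounts = np.array([inv.flows[f] for f in flow_names], dtype=float)

    factors = (
        model.midpoint_factors.reindex(flow_names, fill_value=0.0)[list(CATEGORIES)]
        .to_numpy(dtype=float)
    )
    sigmas = np.log(gsds)
    # flows with zero deterministic amount or gsd 1 are left unperturbed
    multipliers = np.where(
        (sigmas > 0) & (amounts > 0),
        rng.lognormal(mean=0.0, sigma=np.broadcast_to(sigmas, (n, len(flow_names)))),
        1.0,
    )
    samples = (multipliers * amounts) @ factors  # (n, 18)
    frame = pd.DataFrame(samples, columns=list(CATEGORIES))

    summaries = []
    for cat in CATEGORIES:
        col = frame[cat].to_numpy()
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        lower, upper = percentile_bounds(col)
        summaries.append(
            UncertaintySummary(
                category=cat,
                mean=mean,
                sd=sd,
                cv_pct=cv(mean=mean, sd=sd) if mean != 0 else 0.0,
                lower=lower,
                upper=upper,
                n_iterations=n,
            )
        )
    return frame, summaries


def summary_frame(summaries: list[UncertaintySummary], seed: int | None = None) -> pd.DataFrame:
    """Summaries as a ``category,mean,sd,cv_pct,p5,p95,n,seed`` table."""
    df = pd.DataFrame(
        {
            "category": [s.category for s in summaries],
            "mean": [s.mean for s in summaries],
            "sd": [s.sd for s in summaries],
            "cv_pct": [s.cv_pct for s in summaries],
            "p5": [s.lower for s in summaries],
            "p95": [s.upper for s in summaries],
            "n": [s.n_iterations for s in summaries],
        }
    )
    if seed is not None:
        df["seed"] = seed
    return df


def sensitivity(
    model_run: Callable[[Mapping[str, float]], "pd.Series | None"],
    baseline_params: Mapping[str, float],
    parameter: str,
    model: CharacterizationModel | None = None,
    delta: float = 0.10,
    top_k: int = 5,
) -> pd.DataFrame:
    """One-at-a-time sensitivity of the top normalized categories.

    ``model_run`` maps a parameter dict to a midpoint score Series (18
    categories). The named parameter is perturbed by +/-``delta``
    (fractional) and the percent change of each of the ``top_k`` highest
    normalized baseline categories is recorded; a category is flagged
    responsive when |change| >= 100*delta.
    """
    if parameter not in baseline_params:
        raise KeyError(f"unknown scenario parameter {parameter!r}")
    base_scores = model_run(baseline_params)
    if model is not None:
        from .impact import MidpointResult
        from .pathways import PathwayID

        ranked = normalize(
            MidpointResult(pathway=PathwayID.parse("RW-US"), score=base_scores), model
        )
    else:
        ranked = base_scores
    top = ranked.sort_values(ascending=False).head(top_k).index

    rows = []
    for sign in (+1.0, -1.0):
        perturbed = dict(baseline_params)
        perturbed[parameter] = perturbed[parameter] * (1.0 + sign * delta)
        new_scores = model_run(perturbed)
        for cat in top:
            base = base_scores[cat]
            change = 100.0 * (new_scores[cat] - base) / base if base != 0 else 0.0
            rows.append(
                {
                    "parameter": parameter,
                    "delta_pct": 100.0 * sign * delta,
                    "category": cat,
                    "change_pct": change,
                    "responsive": abs(change) >= 100.0 * delta - 1e-12,
                }
            )
    return pd.DataFrame(rows)
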