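"""End-to-end orchestration: nutrition -> inventory -> impact ->
uncertainty -> trade-off, with reproducible, fully logged runs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .energy import ScenarioConfig, build_inventory, inventory_frame
from .impact import characterize, normalize, to_endpoint
from .nutrition import MineralProfile, profile_change
from .pathways import PathwayID, Processing, default_pathways
from .synthetic import (
    GeneratorConfig,
    gen_characterization_model,
    gen_pedigree_scores,
    load_paper_fixtures,
)
from .tradeoff import (
    CONTEXT_WEIGHTS,
    build_decision_matrix,
    expand_weights,
    rank_with_equivalence,
    topsis_scores,
)
from .uncertainty import monte_carlo_impacts, summary_frame

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    output_dir: Path = Path("spudlca_out")
    seed: int = 0
    mc_iterations: int = 1000  # 0 skips the uncertainty stage
    contexts: tuple[str, ...] = ("environment", "nutrition", "equal")
    duration_weeks: int = 2
    cutoff: float = 0.001
    equivalence_threshold: float = 0.01
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    generator: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        if self.mc_iterations < 0:
            raise ValueError("mc_iterations must be >= 0")
        self.output_dir = Path(self.output_dir)
        unknown = set(self.contexts) - set(CONTEXT_WEIGHTS)
        if unknown:
            raise ValueError(f"unknown priority contexts: {sorted(unknown)}")


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    """3-significant-digit scientific notation view of numeric columns."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda x: f"{x:.3E}")
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle to ``cfg.output_dir``.

    Outputs per-pathway nutrient-change, inventory, midpoint, normalized
    and endpoint tables, Monte Carlo summaries (unless skipped), per-context
    TOPSIS rankings with equivalence flags, and a JSON run log. Both a
    human-readable 3-digit view and a full-precision file are written for
    each numeric table. Deterministic given (config, seed).
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        fixtures = load_paper_fixtures()
        gen_cfg = cfg.generator or GeneratorConfig(
            seed=cfg.seed, duration_weeks=cfg.duration_weeks
        )
        model = gen_characterization_model(gen_cfg)
        pedigree = gen_pedigree_scores(gen_cfg)
        pathways = default_pathways(cfg.duration_weeks)

        stage = "nutrition"
        reference = fixtures.profile("RW-US", 0)
        profiles: dict[str, MineralProfile] = {}
        for p in pathways:
            profiles[p.label] = fixtures.profile(p.label, p.duration_weeks)
        changes = {
            label: profile_change(p, reference)
            for label, p in profiles.items()
            if label != "RW-US"
        }
        nut = pd.DataFrame(
            [
                {
                    "pathway": label,
                    "aggregate_pct": rep.aggregate_pct,
                    "calories_pct": rep.calories_pct,
                    "n_minerals": len(rep.minerals_used),
                }
                for label, rep in changes.items()
            ]
        )
        written["nutrition"] = _write(nut, out / "nutrient_change.csv")

        stage = "inventory"
        inventories = {p.label: build_inventory(p, cfg.scenario) for p in pathways}
        written["inventory"] = _write(inventory_frame(inventories), out / "inventory.csv")

        stage = "impact"
        midpoints = {k: characterize(inv, model) for k, inv in inventories.items()}
        endpoints = {k: to_endpoint(mid, model) for k, mid in midpoints.items()}
        mid_df = pd.DataFrame({k: m.score for k, m in midpoints.items()}).T
        mid_df.index.name = "pathway"
        written["midpoint"] = _write(mid_df.reset_index(), out / "midpoint.csv")
        norm_df = pd.DataFrame({k: normalize(m, model) for k, m in midpoints.items()}).T
        norm_df.index.name = "pathway"
        written["normalized"] = _write(norm_df.reset_index(), out / "midpoint_normalized.csv")
        ep_df = pd.DataFrame({k: e.as_series() for k, e in endpoints.items()}).T
        ep_df.index.name = "pathway"
        written["endpoint"] = _write(ep_df.reset_index(), out / "endpoint.csv")

        if cfg.mc_iterations > 0:
            stage = "uncertainty"
            frames = []
            for i, (label, inv) in enumerate(sorted(inventories.items())):
                _, summaries = monte_carlo_impacts(
                    inv, model, pedigree, n=cfg.mc_iterations, seed=cfg.seed + i
                )
                sdf = summary_frame(summaries, seed=cfg.seed + i)
                sdf.insert(0, "pathway", label)
                frames.append(sdf)
            written["uncertainty"] = _write(
                pd.concat(frames, ignore_index=True), out / "uncertainty.csv"
            )

        stage = "tradeoff"
        calories = {
            label: p.calories for label, p in profiles.items() if label != "RW-US"
        }
        matrix = build_decision_matrix(
            {k: v for k, v in endpoints.items() if k in changes}, changes, calories
        )
        for context in cfg.contexts:
            weights = expand_weights(CONTEXT_WEIGHTS[context])
            ranking = rank_with_equivalence(
                topsis_scores(matrix, weights), threshold=cfg.equivalence_threshold
            )
            written[f"ranking_{context}"] = _write(
                ranking, out / f"ranking_{context}.csv"
            )

        stage = "log"
        log = {
            "spudlca_version": __version__,
            "seed": cfg.seed,
            "mc_iterations": cfg.mc_iterations,
            "duration_weeks": cfg.duration_weeks,
            "contexts": list(cfg.contexts),
            "cutoff": cfg.cutoff,
            "equivalence_threshold": cfg.equivalence_threshold,
            "scenario_defaults": {
                k: v for k, v in vars(cfg.scenario).items() if not isinstance(v, dict)
            },
            "outputs": {k: str(v) for k, v in written.items()},
        }
        log_path = out / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
        written["log"] = log_path
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}; partial outputs in {out}"
        ) from exc
    return written


def _write(df: pd.DataFrame, path: Path) -> Path:
    """Write the 3-digit display CSV plus a full-precision twin."""
    _fmt(df).to_csv(path, index=False)
    df.to_csv(path.with_suffix(".full.csv"), index=False)
    return path
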