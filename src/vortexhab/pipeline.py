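"""End-to-end habitat-vorticity pipeline.

Orchestrates the stages in a fixed order: materialise transect grids
(synthetic scenarios or CSV velocity slices), compute vorticity summaries for
the full section and the near-bed layer, contrast the spawning and
non-spawning cell distributions with the rank-sum test, score the restoration
candidates against the natural spawning reference with the vague-set model,
and write one reproducible report (CSV summaries + JSON + log). All
randomness derives from one global seed fanned out to per-section sub-seeds,
so adding a section never perturbs the existing ones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError, VortexHabError
from .grids import CrossSectionGrid
from .ranksum import RankSumResult, compare_groups
from .synthetic import (
    ScenarioSpec,
    build_section_geometry,
    evaluate_velocity,
    generate_scenario,
)
from .vague import SimilarityReport, SuitabilityIntervals, score_reach
from .vorticity import (
    DEFAULT_LAYER_HEIGHT,
    SectionSummary,
    compute_cell_vorticity,
    summarize_reach,
)

__all__ = [
    "SectionConfig",
    "PipelineConfig",
    "RunReport",
    "default_demo_config",
    "section_seed",
    "read_velocity_slices",
    "write_grid_csv",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger("vortexhab")

GRID_COLUMNS = ["section_id", "y", "z", "dy", "dz", "v_y", "v_z", "wet", "z_bed"]


def section_seed(global_seed: int, index: int) -> int:
    """Deterministic per-section sub-seed; stable under appending sections."""
    ss = np.random.SeedSequence(entropy=[int(global_seed), int(index)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class SectionConfig:
    """One transect: either a CSV path, a fully specified scenario, or a
    label + generator params (seeded from the global seed by position)."""

    section_id: str
    label: str
    path: str | None = None
    scenario: ScenarioSpec | None = None
    params: dict | None = None

    def to_dict(self) -> dict:
        d = {"section_id": self.section_id, "label": self.label}
        if self.path:
            d["path"] = self.path
        if self.scenario is not None:
            d["scenario"] = self.scenario.to_dict()
        if self.params:
            d["params"] = dict(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SectionConfig":
        scenario = d.get("scenario")
        return cls(
            section_id=d["section_id"],
            label=d["label"],
            path=d.get("path"),
            scenario=ScenarioSpec.from_dict(scenario) if scenario else None,
            params=d.get("params"),
        )


@dataclass
class PipelineConfig:
    sections: list[SectionConfig]
    layer_height: float = DEFAULT_LAYER_HEIGHT
    alpha: float = 0.05
    sided: str = "lower"
    intervals: SuitabilityIntervals = field(default_factory=SuitabilityIntervals)
    outdir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.layer_height <= 0:
            raise ValueError("layer height must be positive")
        for s in self.sections:
            if s.label not in ("spawning", "transition", "nonspawning"):
                raise ValueError(f"section {s.section_id}: unknown label {s.label!r}")

    def to_dict(self) -> dict:
        return {
            "sections": [s.to_dict() for s in self.sections],
            "layer_height": self.layer_height,
            "alpha": self.alpha,
            "sided": self.sided,
            "intervals": {
                "appropriate": list(self.intervals.appropriate),
                "boundary": list(self.intervals.boundary),
                "rising_anchor": self.intervals.rising_anchor,
                "third_branch_anchor": self.intervals.third_branch_anchor,
            },
            "outdir": self.outdir,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        iv = d.get("intervals") or {}
        return cls(
            sections=[SectionConfig.from_dict(s) for s in d["sections"]],
            layer_height=d.get("layer_height", DEFAULT_LAYER_HEIGHT),
            alpha=d.get("alpha", 0.05),
            sided=d.get("sided", "lower"),
            intervals=SuitabilityIntervals(
                appropriate=tuple(iv.get("appropriate", (0.17, 0.35))),
                boundary=tuple(iv.get("boundary", (0.02, 1.0))),
                rising_anchor=iv.get("rising_anchor", 0.2),
                third_branch_anchor=iv.get("third_branch_anchor", 0.1),
            ),
            outdir=d.get("outdir", "results"),
            seed=d.get("seed", 0),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def default_demo_config(seed: int = 0, outdir: str = "results") -> PipelineConfig:
    """Demo reach: 3 spawning + 2 transition + 3 non-spawning synthetic
    sections, calibrated to the section means observed in natural reaches."""
    layout = [
        ("A", "spawning", 0.26),
        ("B", "spawning", 0.30),
        ("C", "spawning", 0.23),
        ("N", "transition", 0.177),
        ("M", "transition", 0.157),
        ("D", "nonspawning", 0.10),
        ("E", "nonspawning", 0.10),
        ("F", "nonspawning", 0.10),
    ]
    sections = [
        SectionConfig(
            section_id=sid, label=label, params={"target_mean": target}
        )
        for sid, label, target in layout
    ]
    return PipelineConfig(sections=sections, outdir=outdir, seed=seed)


# ---------------------------------------------------------------------------
# grid CSV I/O
# ---------------------------------------------------------------------------


def write_grid_csv(grid: CrossSectionGrid, section_id: str, path: str | Path) -> None:
    """Write a grid as one CSV row per cell (header, UTF-8, '.' decimals)."""
    yy, zz = grid.meshgrid()
    df = pd.DataFrame(
        {
            "section_id": section_id,
            "y": yy.ravel(),
            "z": zz.ravel(),
            "dy": grid.dy,
            "dz": grid.dz,
            "v_y": grid.v_y.ravel(),
            "v_z": grid.v_z.ravel(),
            "wet": grid.wet.ravel().astype(int),
            "z_bed": np.broadcast_to(grid.z_bed[None, :], yy.shape).ravel(),
        }
    )
    # %.17g keeps every float64 bit-exact through the text round-trip
    df.to_csv(path, index=False, float_format="%.17g")


def _grid_from_frame(df: pd.DataFrame, origin: str) -> tuple[str, CrossSectionGrid]:
    sids = df["section_id"].unique()
    if len(sids) != 1:
        raise SchemaError(f"{origin}: expected exactly one section_id, got {list(sids)}")
    dup = df.duplicated(subset=["y", "z"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 0-based
        raise SchemaError(f"{origin}: duplicate (y, z) cells at lines {lines}")
    y = np.sort(df["y"].unique())
    z = np.sort(df["z"].unique())
    if len(y) * len(z) != len(df):
        raise SchemaError(f"{origin}: cells do not form a full structured grid")
    bad_rows = df[
        df["wet"].astype(bool)
        & (~np.isfinite(df["v_y"]) | ~np.isfinite(df["v_z"]))
    ]
    if len(bad_rows):
        lines = (bad_rows.index + 2).tolist()[:10]
        raise SchemaError(
            f"{origin}: non-finite velocities on wet cells at lines {lines}"
        )
    piv = df.set_index(["z", "y"]).sort_index()
    shape = (len(z), len(y))
    v_y = piv["v_y"].to_numpy().reshape(shape)
    v_z = piv["v_z"].to_numpy().reshape(shape)
    wet = piv["wet"].to_numpy().astype(bool).reshape(shape)
    z_bed = piv["z_bed"].to_numpy().reshape(shape)[0, :]
    moving_dry = (~wet) & ((v_y != 0) | (v_z != 0))
    if moving_dry.any():
        logger.warning(
            "%s: %d dry cells carry velocity; ignored downstream",
            origin,
            int(moving_dry.sum()),
        )
    dy = float(df["dy"].iloc[0])
    dz = float(df["dz"].iloc[0])
    grid = CrossSectionGrid(
        y=y,
        z=z,
        dy=dy,
        dz=dz,
        v_y=np.where(wet, v_y, 0.0),
        v_z=np.where(wet, v_z, 0.0),
        wet=wet,
        z_bed=z_bed,
        water_surface=float(z.max() + dz / 2.0),
    )
    return str(sids[0]), grid


def read_velocity_slices(
    paths: Sequence[str | Path],
) -> list[tuple[str, CrossSectionGrid]]:
    """Read and validate grid CSV files; returns (section_id, grid) pairs."""
    out = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in GRID_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        out.append(_grid_from_frame(df, str(path)))
    return out


# ---------------------------------------------------------------------------
# run + report
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    summaries: list[SectionSummary]
    aggregates: dict
    ranksum: RankSumResult | None
    similarity: dict[str, SimilarityReport]
    restoration: dict | None
    config_echo: dict
    seed: int
    version: str
    log_lines: list[str] = field(default_factory=list)

    def summaries_frame(self) -> pd.DataFrame:
        rows = [
            {
                "section_id": s.section_id,
                "label": s.label,
                "layer": s.layer,
                "left": s.left,
                "middle": s.middle,
                "right": s.right,
                "mean": s.mean,
            }
            for s in self.summaries
        ]
        return pd.DataFrame(rows)


def _materialize(config: PipelineConfig) -> list[tuple[str, str, CrossSectionGrid]]:
    sections: list[tuple[str, str, CrossSectionGrid]] = []
    for idx, sec in enumerate(config.sections):
        if sec.path is not None:
            (sid, grid), = read_velocity_slices([sec.path])
            sections.append((sec.section_id or sid, sec.label, grid))
            continue
        if sec.scenario is not None:
            spec = sec.scenario
        else:
            spec = generate_scenario(
                sec.label, sec.params, seed=section_seed(config.seed, idx)
            )
        grid = build_section_geometry(spec.bed, spec.ny, spec.nz, spec.water_surface)
        grid = evaluate_velocity(spec, grid)
        sections.append((sec.section_id, sec.label, grid))
    return sections


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and return a self-contained report.

    Stage order: materialise -> vorticity summaries -> rank-sum comparison ->
    similarity scoring. A stage failure aborts with the stage name attached.
    """
    log_lines: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    stage = "materialise"
    try:
        sections = _materialize(config)
        note(f"[materialise] {len(sections)} sections ready (seed {config.seed})")

        stage = "vorticity"
        summaries, aggregates = summarize_reach(
            sections, layer_height=config.layer_height
        )
        ratio = aggregates["ratio_spawning_to_nonspawning"].get("full")
        note(
            "[vorticity] group means (full): "
            + ", ".join(
                f"{k}={v:.5f}" for k, v in aggregates["group_means"]["full"].items()
            )
            + (f"; spawning/non-spawning ratio {ratio:.2f}" if ratio else "")
        )

        stage = "comparison"
        labels = [label for _, label, _ in sections]
        if "spawning" in labels and "nonspawning" in labels:
            fields = [compute_cell_vorticity(g) for _, _, g in sections]
            ranksum = compare_groups(
                fields,
                labels,
                alpha=config.alpha,
                sided=config.sided,
            )
            note(
                f"[comparison] W={ranksum.W:.1f} Z={ranksum.Z:.2f} "
                f"({ranksum.sided}-tailed, alpha={ranksum.alpha}): "
                + ("reject H0" if ranksum.reject else "no rejection")
            )
        else:
            ranksum = None
            note("[comparison] skipped: need both a spawning and a non-spawning group")

        stage = "similarity"
        gm = aggregates["group_means"]["full"]
        similarity: dict[str, SimilarityReport] = {}
        restoration = None
        if "spawning" in gm:
            natural = gm["spawning"]
            for other in ("transition", "nonspawning"):
                if other in gm:
                    similarity[other] = score_reach(
                        gm[other], natural, config.intervals
                    )
            if "transition" in similarity and "nonspawning" in similarity:
                sim_prev = similarity["nonspawning"].sim
                sim_after = similarity["transition"].sim
                scored = score_reach(
                    gm["transition"], natural, config.intervals,
                    sim_previous=sim_prev,
                )
                restoration = {
                    "sim_previous": sim_prev,
                    "sim_after": sim_after,
                    "rate_pct": scored.rate_pct,
                    "effective": scored.effective,
                }
                note(
                    f"[similarity] transition-vs-natural SIM={sim_after:.3f} "
                    f"({similarity['transition'].similarity_class}); "
                    f"restoration rate {scored.rate_pct:+.1f}% "
                    f"-> {'effective' if scored.effective else 'not effective'}"
                )
    except VortexHabError as err:
        raise VortexHabError(f"pipeline stage '{stage}' failed: {err}") from err

    return RunReport(
        summaries=summaries,
        aggregates=aggregates,
        ranksum=ranksum,
        similarity=similarity,
        restoration=restoration,
        config_echo=config.to_dict(),
        seed=config.seed,
        version=__version__,
        log_lines=log_lines,
    )


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write summaries.csv, comparison.json, similarity.json and run.log.

    Numeric summary cells are fixed at 5 decimals so reruns are byte-stable;
    similarity.json is omitted (and noted in the log) when no similarity
    stage ran.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    df = report.summaries_frame()
    for col in ("left", "middle", "right", "mean"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.5f}")
    p = outdir / "summaries.csv"
    p.write_text(df.to_csv(index=False))
    written.append(p)

    comparison = {
        "rank_sum": report.ranksum.to_dict() if report.ranksum else None,
        "aggregates": report.aggregates,
        "config": report.config_echo,
        "seed": report.seed,
        "version": report.version,
    }
    p = outdir / "comparison.json"
    p.write_text(json.dumps(comparison, indent=2, sort_keys=True) + "\n")
    written.append(p)

    log_lines = list(report.log_lines)
    if report.similarity:
        sim = {k: v.to_dict() for k, v in report.similarity.items()}
        if report.restoration:
            sim["restoration"] = report.restoration
        p = outdir / "similarity.json"
        p.write_text(json.dumps(sim, indent=2, sort_keys=True) + "\n")
        written.append(p)
    else:
        log_lines.append("[report] no similarity stage ran; similarity.json omitted")

    p = outdir / "run.log"
    p.write_text("\n".join(log_lines) + "\n")
    written.append(p)
    return written
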