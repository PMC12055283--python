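"""End-to-end study orchestration: shapes + trajectories -> results table.

Organized as a model/results pair in the statsmodels style:

* :class:`SettlingStudy` holds the data (outlines and settling
  trajectories) together with a :class:`StudyConfig`; ``fit()`` runs
  morphometrics, terminal-speed estimation, trial aggregation and regime
  classification for every shape.
* :class:`StudyResults` carries the per-shape table, study-level summary
  ranges, a text ``summary()``, a markdown report, CSV export and scatter
  plots.

Every relative speed is normalized by the disc control's mean settling
speed, so the control row has relative speed exactly 1.  Shapes whose
morphometrics or speed estimation fail are logged, excluded and counted in
the report (rows_out + excluded = shapes_in).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import NormalizationConfig, Outline, normalize_area
from .io_formats import RESULT_COLUMNS, write_results_csv
from .kinematics import (
    FluidContext,
    SpeedEstimateConfig,
    Trajectory,
    aggregate_trials,
    estimate_terminal_speed,
)
from .metrics import morphometrics

__all__ = ["StudyConfig", "SettlingStudy", "StudyResults", "classify_regime", "run_study"]

logger = logging.getLogger(__name__)

HIGH_SYMMETRY = "high"
LOW_SYMMETRY = "low"


def classify_regime(S: float, threshold: float = 0.75) -> str:
    """Classify a shape into the fast (high-symmetry) or slow regime.

    ``high`` iff S > threshold, strictly: the boundary value S = 0.75 goes
    to the low-symmetry regime (a convention; the regimes are separated
    only "roughly" at 0.75 and the boundary must land somewhere).
    """
    if not 0.0 < S <= 1.0:
        raise ValueError(f"S must be in (0, 1], got {S}")
    return HIGH_SYMMETRY if S > threshold else LOW_SYMMETRY


@dataclass(frozen=True)
class StudyConfig:
    """Study-level constants.

    ``blade_area`` is the constant blade area (mm²) every outline is
    re-normalized to at ingest, the study's single source of truth for
    scale.  ``symmetry_threshold`` splits the settling regimes.
    """

    control_shape_id: str = "disc"
    symmetry_threshold: float = 0.75
    blade_area: float = 100.0
    seed: int = 0
    fluid: FluidContext = field(default_factory=FluidContext)
    speed_config: SpeedEstimateConfig = field(default_factory=SpeedEstimateConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.symmetry_threshold < 1.0:
            raise ValueError("symmetry_threshold must be in (0, 1)")
        if not self.blade_area > 0:
            raise ValueError("blade_area must be > 0")


class SettlingStudy:
    """Model object: a set of shapes with their settling trajectories.

    Parameters
    ----------
    shapes
        Outlines, one per shape; labels are the shape ids.
    trajectories
        Either a list of :class:`Trajectory` or a long DataFrame with
        columns ``shape_id, trial_id, t_s, x_mm, z_mm``.
    config
        Study constants; the control shape id must be present.
    """

    def __init__(
        self,
        shapes: list[Outline],
        trajectories: list[Trajectory] | pd.DataFrame,
        config: StudyConfig = StudyConfig(),
    ):
        self.config = config
        self.shapes = {o.label: o for o in shapes}
        if len(self.shapes) != len(shapes):
            raise ValueError("shape labels must be unique")
        if config.control_shape_id not in self.shapes:
            raise ValueError(
                f"control shape {config.control_shape_id!r} not present in study"
            )
        if isinstance(trajectories, pd.DataFrame):
            self.trajectories = self._frame_to_trajectories(trajectories)
        else:
            self.trajectories = list(trajectories)

    @classmethod
    def from_dataframe(
        cls,
        shapes: list[Outline],
        trajectories: pd.DataFrame,
        config: StudyConfig = StudyConfig(),
    ) -> "SettlingStudy":
        return cls(shapes, trajectories, config)

    @staticmethod
    def _frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
        out = []
        for (sid, tid), grp in df.groupby(["shape_id", "trial_id"], sort=True):
            out.append(
                Trajectory(
                    t=grp["t_s"].to_numpy(),
                    x=grp["x_mm"].to_numpy(),
                    z=grp["z_mm"].to_numpy(),
                    shape_id=str(sid),
                    trial_id=int(tid),
                )
            )
        return out

    def fit(self) -> "StudyResults":
        """Run the full analysis and return a :class:`StudyResults`."""
        cfg = self.config
        by_shape: dict[str, list[Trajectory]] = {}
        for tr in self.trajectories:
            by_shape.setdefault(tr.shape_id, []).append(tr)

        # terminal speed per trial, then aggregate per shape
        speeds: dict[str, list[float]] = {}
        excluded: dict[str, str] = {}
        for sid, trs in by_shape.items():
            if sid not in self.shapes:
                logger.warning("trajectories for unknown shape_id %r ignored", sid)
                continue
            vals = []
            for tr in trs:
                try:
                    v, _, _ = estimate_terminal_speed(tr, cfg.speed_config)
                    vals.append(v)
                except Exception as exc:
                    logger.warning("trial %s/%s failed: %s", sid, tr.trial_id, exc)
            if vals:
                speeds[sid] = vals
            else:
                excluded[sid] = "no trial produced a terminal speed"

        if cfg.control_shape_id not in speeds:
            raise ValueError(
                f"control shape {cfg.control_shape_id!r} has no usable trials"
            )
        control_mean = float(np.mean(speeds[cfg.control_shape_id]))

        rows = []
        for sid in self.shapes:
            if sid not in speeds:
                if sid not in excluded:
                    excluded[sid] = "no trajectories supplied"
                continue
            outline = normalize_area(
                self.shapes[sid], NormalizationConfig(cfg.blade_area)
            )
            try:
                morph = morphometrics(outline, NormalizationConfig(cfg.blade_area))
            except Exception as exc:
                logger.warning("morphometrics failed for %s: %s", sid, exc)
                excluded[sid] = f"morphometrics failed: {exc}"
                continue
            summ = aggregate_trials(speeds[sid], control_mean, cfg.fluid)
            regime = classify_regime(morph.S, cfg.symmetry_threshold)
            logger.info(
                "shape %s: S=%.3f L=%.3f n=%d VS=%.3f rel=%.3f regime=%s",
                sid, morph.S, morph.L, summ.n_trials, summ.mean_speed,
                summ.relative_speed, regime,
            )
            rows.append(
                {
                    "shape_id": sid,
                    "provenance": self.shapes[sid].provenance,
                    "S": morph.S,
                    "L": morph.L,
                    "area_mm2": morph.area,
                    "VS_mm_s": summ.mean_speed,
                    "sem": summ.sem,
                    "relative_speed": summ.relative_speed,
                    "reynolds": summ.reynolds,
                    "regime": regime,
                }
            )
        table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        return StudyResults(
            model=self,
            table=table,
            control_mean=control_mean,
            excluded=excluded,
            n_shapes_in=len(self.shapes),
        )


@dataclass
class StudyResults:
    """Fitted study: per-shape table plus study-level summaries."""

    model: SettlingStudy
    table: pd.DataFrame
    control_mean: float
    excluded: dict[str, str]
    n_shapes_in: int

    # ---------------------------------------------------------- summaries

    def regime_envelopes(self) -> pd.DataFrame:
        """Min/max/quartiles of relative speed per symmetry regime."""
        return (
            self.table.groupby("regime")["relative_speed"]
            .describe(percentiles=[0.25, 0.5, 0.75])
            .reset_index()
        )

    def ranges(self) -> dict[str, tuple[float, float]]:
        t = self.table
        return {
            "S": (float(t["S"].min()), float(t["S"].max())),
            "L": (float(t["L"].min()), float(t["L"].max())),
            "relative_speed": (
                float(t["relative_speed"].min()),
                float(t["relative_speed"].max()),
            ),
        }

    def summary(self) -> str:
        """Human-readable study summary (statsmodels-style text block)."""
        r = self.ranges()
        env = self.regime_envelopes()
        lines = [
            "Settling study results",
            "=" * 54,
            f"shapes in: {self.n_shapes_in}   analysed: {len(self.table)}   "
            f"excluded: {len(self.excluded)}",
            f"control: {self.model.config.control_shape_id!r}  "
            f"mean speed {self.control_mean:.3f} mm/s",
            f"S range: [{r['S'][0]:.2f}, {r['S'][1]:.2f}]   "
            f"L range: [{r['L'][0]:.2f}, {r['L'][1]:.2f}]",
            f"relative speed range: [{r['relative_speed'][0]:.3f}, "
            f"{r['relative_speed'][1]:.3f}]",
            "",
            "relative speed by symmetry regime "
            f"(threshold S = {self.model.config.symmetry_threshold:g}):",
        ]
        for _, row in env.iterrows():
            lines.append(
                f"  {row['regime']:>4}: n={int(row['count']):3d}  "
                f"min={row['min']:.3f}  q25={row['25%']:.3f}  med={row['50%']:.3f}  "
                f"q75={row['75%']:.3f}  max={row['max']:.3f}"
            )
        return "\n".join(lines)

    def report_markdown(self) -> str:
        """Markdown report with the summary block and exclusion list."""
        parts = ["# Settling study report", "", "```", self.summary(), "```", ""]
        if self.excluded:
            parts.append("## Excluded shapes")
            parts.append("")
            for sid, why in sorted(self.excluded.items()):
                parts.append(f"- `{sid}`: {why}")
            parts.append("")
        return "\n".join(parts)

    def to_csv(self, path: str | Path) -> None:
        write_results_csv(self.table, path)

    # ------------------------------------------------------------ plots

    def plot_shape_speed(self, ax=None):
        """Scatter of S vs L coloured by relative settling speed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        sc = ax.scatter(
            self.table["L"], self.table["S"], c=self.table["relative_speed"],
            cmap="viridis", s=25,
        )
        ax.axhline(self.model.config.symmetry_threshold, ls="--", c="grey", lw=1)
        ax.set_xlabel("lobedness L")
        ax.set_ylabel("symmetry S")
        ax.figure.colorbar(sc, ax=ax, label="relative settling speed")
        return ax

    def plot_regimes(self, ax=None):
        """Relative speed vs S with the regime threshold marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for regime, grp in self.table.groupby("regime"):
            ax.scatter(grp["S"], grp["relative_speed"], s=25, label=regime)
        ax.axvline(self.model.config.symmetry_threshold, ls="--", c="grey", lw=1)
        ax.set_xlabel("symmetry S")
        ax.set_ylabel("relative settling speed")
        ax.legend(title="regime")
        return ax


def run_study(
    shapes: list[Outline],
    trajectories: list[Trajectory] | pd.DataFrame,
    config: StudyConfig = StudyConfig(),
) -> StudyResults:
    """Convenience wrapper: build a :class:`SettlingStudy` and fit it."""
    return SettlingStudy(shapes, trajectories, config).fit()
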