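"""Readers and writers for every format the pipeline touches.

Binary mask images in, outline CSV in/out, trajectory CSV in/out, results
CSV out, and millimetre-scale SVG out (cut lines for a laser cutter).  All
text formats are UTF-8 with LF endings, '.' decimal separator and floats
at 6 significant digits, so outputs are byte-stable given fixed inputs.
"""

from __future__ import annotations

import io
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .geometry import DEFAULT_RESOLUTION, Outline, resample_outline
from .kinematics import Trajectory

__all__ = [
    "FormatError",
    "EmptyMaskError",
    "read_mask_outline",
    "read_outline_csv",
    "write_outline_csv",
    "export_svg",
    "read_svg_outlines",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_results_csv",
    "read_results_csv",
    "RESULT_COLUMNS",
]

#: Fixed schema of the per-shape results table (one row per shape).
RESULT_COLUMNS = [
    "shape_id",
    "provenance",
    "S",
    "L",
    "area_mm2",
    "VS_mm_s",
    "sem",
    "relative_speed",
    "reynolds",
    "regime",
]

_FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


class EmptyMaskError(ValueError):
    """A mask image contains no foreground pixels."""


# ---------------------------------------------------------------- masks


def read_mask_outline(
    image: np.ndarray, mm_per_pixel: float, resolution: int = DEFAULT_RESOLUTION
) -> Outline:
    """Extract the blade outline from a binary (or thresholdable) mask.

    Contours are traced at the 0.5 iso-level with marching squares, which
    gives sub-pixel vertices and reduces pixelation bias in the symmetry
    statistic.  The largest closed contour is kept (smaller foreground
    specks are ignored); coordinates are converted to mm with x along
    columns and y along rows.
    """
    if not mm_per_pixel > 0:
        raise ValueError("mm_per_pixel must be > 0")
    img = np.asarray(image, dtype=float)
    if img.max() > 1.0:
        img = img / img.max()
    if not np.any(img > 0.5):
        raise EmptyMaskError("mask has no foreground pixels")
    padded = np.pad(img, 1)  # close contours that touch the border
    contours = measure.find_contours(padded, 0.5)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if not closed:
        raise EmptyMaskError("no closed foreground contour found")

    def _area(c: np.ndarray) -> float:
        x, y = c[:, 1], c[:, 0]
        return abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    best = max(closed, key=_area)
    verts = np.column_stack([best[:-1, 1], best[:-1, 0]]) * mm_per_pixel
    outline = Outline(verts, provenance="species")
    return resample_outline(outline, resolution)


# ---------------------------------------------------------- outline CSV


def write_outline_csv(outline: Outline, path: str | Path) -> None:
    """Write an outline as ``x_mm,y_mm`` CSV with '#' metadata header."""
    lines = [f"# label: {outline.label}", f"# provenance: {outline.provenance}", "x_mm,y_mm"]
    for x, y in outline.vertices:
        lines.append(f"{x:.9f},{y:.9f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_outline_csv(path: str | Path) -> Outline:
    """Read an outline CSV; vertices round-trip within 1e-9 mm.

    Metadata lines start with '#'; the column header ``x_mm,y_mm`` is
    required; the decimal separator is '.' (a ',' decimal dialect is
    rejected with a clear message).
    """
    label, provenance = "", "species"
    rows: list[tuple[float, float]] = []
    text = Path(path).read_text(encoding="utf-8")
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(label|provenance)\s*:\s*(.*)", line)
            if m:
                if m.group(1) == "label":
                    label = m.group(2)
                else:
                    provenance = m.group(2)
            continue
        if not header_seen:
            if line.replace(" ", "") != "x_mm,y_mm":
                raise FormatError(f"line {lineno}: expected header 'x_mm,y_mm', got {line!r}")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(
                f"line {lineno}: expected two comma-separated values "
                f"(note: decimal separator must be '.', not ','), got {line!r}"
            )
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric row {line!r}") from None
    if len(rows) < 3:
        raise FormatError(f"outline needs >= 3 points, file has {len(rows)}")
    return Outline(np.asarray(rows), label=label, provenance=provenance)  # type: ignore[arg-type]


# ----------------------------------------------------------------- SVG


def export_svg(
    outlines: Sequence[Outline], path: str | Path, scale: float = 1.0, margin: float = 2.0
) -> None:
    """Write outlines as a millimetre-scale SVG of stroke-only cut paths.

    SVG user units equal millimetres (the document width/height carry
    explicit ``mm`` units and the viewBox matches), so the file prints or
    laser-cuts at physical scale.  ``scale`` multiplies all coordinates.
    """
    polys = [o.vertices * scale for o in outlines]
    if polys:
        allv = np.vstack(polys)
        minx, miny = allv.min(axis=0) - margin
        maxx, maxy = allv.max(axis=0) + margin
    else:
        minx = miny = 0.0
        maxx = maxy = 2 * margin
    w, h = maxx - minx, maxy - miny
    buf = io.StringIO()
    buf.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    buf.write(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.6g}mm" height="{h:.6g}mm" '
        f'viewBox="{minx:.6g} {miny:.6g} {w:.6g} {h:.6g}">\n'
    )
    for outline, verts in zip(outlines, polys):
        pts = " L ".join(f"{x:.6f} {y:.6f}" for x, y in verts)
        buf.write(
            f'  <path id="{outline.label or "outline"}" d="M {pts} Z" '
            'fill="none" stroke="black" stroke-width="0.1"/>\n'
        )
    buf.write("</svg>\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_svg_outlines(path: str | Path) -> list[Outline]:
    """Re-import outlines from an SVG written by :func:`export_svg`."""
    text = Path(path).read_text(encoding="utf-8")
    outlines = []
    for m in re.finditer(r'<path id="([^"]*)" d="M ([^"]+?) ?Z"', text):
        label, d = m.group(1), m.group(2)
        coords = np.asarray(
            [[float(v) for v in pt.split()] for pt in d.split(" L ")]
        )
        outlines.append(Outline(coords, label=label))
    return outlines


# ----------------------------------------------------- trajectory CSV


def write_trajectory_csv(trajectories: Iterable[Trajectory] | pd.DataFrame, path: str | Path) -> None:
    """Write trajectories as ``shape_id,trial_id,t_s,x_mm,z_mm`` CSV."""
    if isinstance(trajectories, pd.DataFrame):
        df = trajectories[["shape_id", "trial_id", "t_s", "x_mm", "z_mm"]]
    else:
        frames = [
            pd.DataFrame(
                {
                    "shape_id": tr.shape_id,
                    "trial_id": tr.trial_id,
                    "t_s": tr.t,
                    "x_mm": tr.x,
                    "z_mm": tr.z,
                }
            )
            for tr in trajectories
        ]
        df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_trajectory_csv(path: str | Path) -> list[Trajectory]:
    """Read a trajectory CSV into one Trajectory per (shape_id, trial_id)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse trajectory CSV: {exc}") from exc
    required = {"shape_id", "trial_id", "t_s", "x_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"trajectory CSV missing columns: {sorted(missing)}")
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


# -------------------------------------------------------- results CSV


def write_results_csv(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the per-shape results table with a fixed column order.

    Missing required columns raise :class:`FormatError`; extra columns are
    appended after the standard ones in sorted order.  Floats at 6
    significant digits for byte-stable output.
    """
    missing = [c for c in RESULT_COLUMNS if c not in rows.columns]
    if missing:
        raise FormatError(f"results table missing columns: {missing}")
    extra = sorted(c for c in rows.columns if c not in RESULT_COLUMNS)
    df = rows[RESULT_COLUMNS + extra]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_results_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results CSV missing columns: {missing}")
    return df
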