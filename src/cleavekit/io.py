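"""File formats: contour CSV, pose CSV, flat key-value config, manifests.

Contour CSV carries an optional header comment
``# unit=um axis_origin=<x,y> axis_dir=<dx,dy>`` followed by one ``x,y``
vertex per row; plain two-column files (with or without an ``x,y`` header
row) and whitespace-delimited ImageJ-style point lists are also accepted.
All floating-point output uses 12 significant digits so write/read
round-trips stay well inside the geometric tolerances.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry2d import Contour, rot90
from .spindle_metrics import AxisFrame, SpindlePose

FLOAT_FMT = "{:.12g}"

POSE_COLUMNS = ["cell_id", "pax", "pay", "pvx", "pvy", "platex", "platey"]


def _fmt(x: float) -> str:
    return FLOAT_FMT.format(float(x))


def write_contour_csv(contour: Contour, path) -> None:
    """Write one contour; the axis frame (if any) goes in the header comment."""
    lines = []
    frame = contour.axis_frame
    if frame is not None:
        lines.append(
            "# unit=um"
            f" axis_origin={_fmt(frame.origin[0])},{_fmt(frame.origin[1])}"
            f" axis_dir={_fmt(frame.av_direction[0])},{_fmt(frame.av_direction[1])}"
        )
    lines.append("x,y")
    lines.extend(f"{_fmt(x)},{_fmt(y)}" for x, y in contour.vertices)
    Path(path).write_text("\n".join(lines) + "\n")


_AXIS_RE = re.compile(
    r"axis_origin=(?P<ox>[^,\s]+),(?P<oy>\S+)\s+axis_dir=(?P<dx>[^,\s]+),(?P<dy>\S+)"
)


def read_contour_csv(path, axis_frame: AxisFrame | None = None) -> Contour:
    """Read a contour CSV or an ImageJ-style point list.

    A frame parsed from the header comment is used unless ``axis_frame``
    is supplied; the header frame's sign reference is the AV direction
    rotated by -90 degrees (the canonical positive-tilt side).
    """
    text = Path(path).read_text()
    frame = axis_frame
    vertices = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _AXIS_RE.search(line)
            if m and frame is None:
                av = np.array([float(m["dx"]), float(m["dy"])])
                frame = AxisFrame(
                    origin=np.array([float(m["ox"]), float(m["oy"])]),
                    av_direction=av,
                    sign_reference=-rot90(av),
                )
            continue
        fields = [f for f in re.split(r"[,\s]+", line) if f]
        if fields[0].lower() in ("x", "index"):  # header row
            continue
        if len(fields) < 2:
            raise ParameterError(f"{path}: row {lineno}: expected two columns")
        try:
            vertices.append((float(fields[-2]), float(fields[-1])))
        except ValueError as exc:
            raise ParameterError(f"{path}: row {lineno}: {exc}") from exc
    if not vertices:
        raise ParameterError(f"{path}: no vertex rows found")
    return Contour(vertices, axis_frame=frame)


def write_pose_csv(poses: dict, path, stages: dict | None = None) -> None:
    """Write poses keyed by cell_id; optional parallel ``stages`` mapping."""
    cols = POSE_COLUMNS + (["stage"] if stages else [])
    lines = [",".join(cols)]
    for cell_id, pose in poses.items():
        row = [str(cell_id)] + [
            _fmt(v) for v in (*pose.pole_animal, *pose.pole_vegetal, *pose.plate)
        ]
        if stages:
            row.append(str(stages[cell_id]))
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pose_csv(path) -> pd.DataFrame:
    """Read a pose table; missing plate columns default to the midpoint.

    Returns a DataFrame with a ``pose`` column of :class:`SpindlePose`
    objects plus ``cell_id`` and any extra columns (e.g. ``stage``).
    """
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: missing pose columns {missing}")
    poses = []
    for idx, row in df.iterrows():
        plate = None
        if "platex" in df.columns and not (
                pd.isna(row.get("platex")) or pd.isna(row.get("platey"))):
            plate = (row["platex"], row["platey"])
        try:
            poses.append(SpindlePose(pole_animal=(row["pax"], row["pay"]),
                                     pole_vegetal=(row["pvx"], row["pvy"]),
                                     plate=plate))
        except Exception as exc:
            raise ParameterError(f"{path}: row {idx + 2}: {exc}") from exc
    out = df.drop(columns=[c for c in POSE_COLUMNS[1:] if c in df.columns])
    out["pose"] = poses
    return out


def read_config(path) -> dict:
    """Flat ``key = value`` config file; values parsed as JSON when possible."""
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParameterError(f"{path}: line {lineno}: expected key = value")
        key, _, value = line.partition("=")
        value = value.strip()
        try:
            out[key.strip()] = json.loads(value)
        except json.JSONDecodeError:
            out[key.strip()] = value
    return out


def write_manifest(path, command: str, config: dict, seed: int | None) -> None:
    """Record what produced the artifacts in a directory."""
    from . import __version__

    manifest = {
        "package": "cleavekit",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def write_dataset(dataset, outdir) -> None:
    """Export a synthetic dataset: contour CSVs, pose CSV, truth table, manifest."""
    from dataclasses import asdict

    from .synthetic_data import STAGES, ground_truth_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contours = outdir / "contours"
    contours.mkdir(exist_ok=True)
    pose_rows = ["cell_id,stage," + ",".join(POSE_COLUMNS[1:])]
    for cell in dataset.cells:
        write_contour_csv(cell.contour, contours / f"{cell.cell_id}.csv")
        for stage in STAGES:
            p = cell.observed_pose[stage]
            pose_rows.append(",".join(
                [cell.cell_id, stage]
                + [_fmt(v) for v in (*p.pole_animal, *p.pole_vegetal, *p.plate)]))
    (outdir / "poses.csv").write_text("\n".join(pose_rows) + "\n")
    ground_truth_table(dataset).to_csv(outdir / "truth.csv", index=False,
                                       float_format="%.12g")
    cfg = asdict(dataset.config)
    write_manifest(outdir / "manifest.json", "generate", cfg,
                   dataset.config.seed)
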