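"""Reading and writing landmark annotation files.

Supports the 300w-style ``.pts`` dialect (header ``version``/``n_points``,
brace-delimited ``x y`` lines, conventionally 1-based coordinates) and the
package's own 17-landmark CSV/JSON manifests.  On read, ``.pts`` coordinates
are shifted by -1 into the package's 0-based pixel-center convention; on
write they are shifted back by +1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, LandmarkSchema, LandmarkSet17

__all__ = ["read_pts", "write_pts", "read_manifest", "write_manifest", "PtsParseError"]

PTS_OFFSET = 1.0  # .pts files are 1-based


class PtsParseError(ValueError):
    """Malformed .pts file."""


def read_pts(path) -> np.ndarray:
    """Parse a ``.pts`` annotation file into an (N, 2) array of (u, v).

    Coordinates are converted to the 0-based convention.  Raises
    :class:`PtsParseError` naming the offending line on malformed headers and
    on ``n_points`` mismatches.
    """
    lines = Path(path).read_text().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_content():
        for no, raw in it:
            s = raw.strip()
            if s:
                return no, s
        return None, None

    no, s = next_content()
    if s is None or not s.lower().startswith("version"):
        raise PtsParseError(f"line {no}: expected 'version' header, got {s!r}")
    no, s = next_content()
    if s is None or not s.lower().startswith("n_points"):
        raise PtsParseError(f"line {no}: expected 'n_points' header, got {s!r}")
    try:
        n_points = int(s.split(":")[1])
    except (IndexError, ValueError) as exc:
        raise PtsParseError(f"line {no}: unreadable n_points in {s!r}") from exc
    no, s = next_content()
    if s != "{":
        raise PtsParseError(f"line {no}: expected '{{', got {s!r}")

    pts: list[tuple[float, float]] = []
    for no, raw in it:
        s = raw.strip()
        if not s:
            continue
        if s == "}":
            break
        parts = s.split()
        if len(parts) != 2:
            raise PtsParseError(f"line {no}: expected 'x y', got {s!r}")
        try:
            pts.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise PtsParseError(f"line {no}: non-numeric coordinate in {s!r}") from exc
    else:
        raise PtsParseError("missing closing '}'")

    if len(pts) != n_points:
        raise PtsParseError(
            f"n_points declares {n_points} but file contains {len(pts)} coordinate lines"
        )
    return np.asarray(pts, dtype=float) - PTS_OFFSET


def write_pts(path, points: np.ndarray, version: int = 1) -> None:
    """Write points to a ``.pts`` file (converted back to 1-based)."""
    pts = np.asarray(points, dtype=float) + PTS_OFFSET
    out = [f"version: {version}", f"n_points: {len(pts)}", "{"]
    out += [f"{u:.6f} {v:.6f}" for u, v in pts]
    out.append("}")
    Path(path).write_text("\n".join(out) + "\n")


def _coord_columns(schema: LandmarkSchema) -> list[str]:
    cols = []
    for lid in schema.landmark_ids:
        cols += [f"{lid}_u", f"{lid}_v"]
    return cols


def write_manifest(
    path,
    records: list[tuple[str, LandmarkSet17]],
    schema: LandmarkSchema = DEFAULT_SCHEMA,
) -> None:
    """Write a 17-landmark manifest (CSV or JSON by extension).

    One row per image: source_id, 34 coordinate columns, 17 visibility flags.
    """
    rows = []
    for source_id, lm in records:
        row: dict[str, object] = {"source_id": source_id}
        for k, lid in enumerate(schema.landmark_ids):
            row[f"{lid}_u"] = lm.coords[k, 0]
            row[f"{lid}_v"] = lm.coords[k, 1]
        for k, lid in enumerate(schema.landmark_ids):
            row[f"{lid}_visible"] = bool(lm.visibility[k])
        rows.append(row)
    path = Path(path)
    df = pd.DataFrame(rows)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1, default=float))
    else:
        df.to_csv(path, index=False)


def read_manifest(
    path, schema: LandmarkSchema = DEFAULT_SCHEMA
) -> list[tuple[str, LandmarkSet17]]:
    """Read a manifest written by :func:`write_manifest`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = [c for c in ["source_id", *_coord_columns(schema)] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing[:5]}")
    records = []
    for _, row in df.iterrows():
        coords = np.array(
            [[row[f"{lid}_u"], row[f"{lid}_v"]] for lid in schema.landmark_ids], dtype=float
        )
        vis = np.array(
            [bool(row.get(f"{lid}_visible", True)) for lid in schema.landmark_ids]
        )
        records.append((str(row["source_id"]), LandmarkSet17(coords, vis)))
    return records
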