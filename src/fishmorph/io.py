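"""File formats: TPS landmark files, coordinate/measurement CSV, PNG masks.

All readers produce y-up coordinates; set ``image_coords=True`` when the file
stores raw image (y-down) coordinates so the y axis is flipped on ingestion.
Writers emit deterministic column order and fixed 6-decimal precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .shapes import (
    ANCHOR_NAMES,
    LANDMARK_NAMES,
    MEASUREMENT_NAMES,
    LandmarkConfig,
    MeasurementRecord,
    OutlineShape,
    ShapeError,
)

_FMT = "%.6f"


class FormatError(ValueError):
    """Raised when a file does not parse in the expected dialect."""


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def read_tps(path, image_coords: bool = False, n_expected: int = 12) -> list[LandmarkConfig]:
    """Read landmark configurations from a TPS file.

    A record is ``LM=k`` followed by ``k`` coordinate lines and an optional
    ``ID=`` trailer; ``IMAGE=``/``SCALE=`` lines are ignored.
    """
    path = Path(path)
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read TPS file {path}: {exc}") from exc

    configs: list[LandmarkConfig] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM="):
            raise FormatError(f"{path}: expected 'LM=' header, got {line!r}")
        k = int(line.split("=", 1)[1])
        coords = []
        while len(coords) < k and i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                continue
            parts = row.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: bad coordinate line {row!r}")
            coords.append([float(parts[0]), float(parts[1])])
        rec_id, species = "", ""
        while i < len(lines):
            row = lines[i].strip()
            if row.upper().startswith(("ID=", "IMAGE=", "SCALE=", "SPECIES=")):
                key, val = row.split("=", 1)
                if key.upper() == "ID":
                    rec_id = val.strip()
                elif key.upper() == "SPECIES":
                    species = val.strip()
                i += 1
            else:
                break
        if len(coords) != k:
            raise FormatError(
                f"{path}: record '{rec_id or len(configs)}' declares LM={k} "
                f"but has {len(coords)} coordinate lines"
            )
        if k != n_expected:
            raise FormatError(
                f"{path}: record '{rec_id or len(configs)}' has {k} landmarks, "
                f"expected {n_expected}"
            )
        arr = np.asarray(coords, dtype=float)
        if image_coords:
            arr[:, 1] = -arr[:, 1]
        configs.append(LandmarkConfig(coords=arr, id=rec_id, species=species))
    return configs


def write_tps(configs: list[LandmarkConfig], path) -> None:
    out = []
    for cfg in configs:
        out.append(f"LM={len(cfg.coords)}")
        for x, y in cfg.coords:
            out.append(f"{_FMT % x} {_FMT % y}")
        out.append(f"ID={cfg.id}")
        if cfg.species:
            out.append(f"SPECIES={cfg.species}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# landmark CSV (columns id,species,lm1_x,lm1_y,...)
# ---------------------------------------------------------------------------

def read_landmarks_csv(path, image_coords: bool = False) -> list[LandmarkConfig]:
    df = pd.read_csv(path)
    k = len(LANDMARK_NAMES)
    cols = [f"lm{i}_{ax}" for i in range(1, k + 1) for ax in ("x", "y")]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing[:4]}...")
    configs = []
    for _, row in df.iterrows():
        arr = row[cols].to_numpy(dtype=float).reshape(k, 2)
        if image_coords:
            arr[:, 1] = -arr[:, 1]
        configs.append(
            LandmarkConfig(
                coords=arr,
                id=str(row.get("id", "")),
                species=str(row.get("species", "")),
            )
        )
    return configs


def write_landmarks_csv(configs: list[LandmarkConfig], path) -> None:
    k = len(LANDMARK_NAMES)
    cols = [f"lm{i}_{ax}" for i in range(1, k + 1) for ax in ("x", "y")]
    rows = []
    for cfg in configs:
        rows.append(
            {"id": cfg.id, "species": cfg.species}
            | dict(zip(cols, (float(_FMT % v) for v in cfg.coords.ravel())))
        )
    pd.DataFrame(rows, columns=["id", "species"] + cols).to_csv(
        path, index=False, float_format=_FMT
    )


def read_landmarks(path, dialect: str = "csv", image_coords: bool = False):
    """Read landmark configurations (``dialect`` in {"tps", "csv"})."""
    if dialect == "tps":
        return read_tps(path, image_coords=image_coords)
    if dialect == "csv":
        return read_landmarks_csv(path, image_coords=image_coords)
    raise FormatError(f"unknown landmark dialect {dialect!r}")


# ---------------------------------------------------------------------------
# outline CSV + anchors
# ---------------------------------------------------------------------------

def write_outline_csv(shape: OutlineShape, path) -> None:
    df = pd.DataFrame(shape.points, columns=["x", "y"])
    df.to_csv(path, index=False, float_format=_FMT)
    if shape.anchors is not None:
        Path(str(path) + ".anchors.json").write_text(
            json.dumps({k: int(shape.anchors[k]) for k in ANCHOR_NAMES}, indent=1)
        )


def read_outline_csv(path, anchors: dict[str, int] | None = None,
                     image_coords: bool = False, id: str = "", species: str = "") -> OutlineShape:
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise FormatError(f"{path}: outline CSV needs columns x,y")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if image_coords:
        pts[:, 1] = -pts[:, 1]
    anchor_file = Path(str(path) + ".anchors.json")
    if anchors is None and anchor_file.exists():
        anchors = {k: int(v) for k, v in json.loads(anchor_file.read_text()).items()}
    return OutlineShape(points=pts, anchors=anchors, id=id, species=species)


def snap_anchors(shape: OutlineShape, coords: np.ndarray) -> OutlineShape:
    """Attach anchors given as 5 (x, y) pairs, snapped to nearest vertices.

    ``coords`` rows follow :data:`fishmorph.shapes.ANCHOR_NAMES` order. The
    outline is rolled so that the snapped ``snout_tip`` is at index 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (5, 2):
        raise ShapeError("anchor coordinates must be a (5, 2) array")
    d2 = ((shape.points[None, :, :] - coords[:, None, :]) ** 2).sum(-1)
    idx = d2.argmin(axis=1)
    roll = int(idx[0])
    pts = np.roll(shape.points, -roll, axis=0)
    idx = (idx - roll) % len(shape.points)
    anchors = dict(zip(ANCHOR_NAMES, (int(i) for i in idx)))
    return OutlineShape(points=pts, anchors=anchors, id=shape.id, species=shape.species)


# ---------------------------------------------------------------------------
# measurements CSV
# ---------------------------------------------------------------------------

def read_measurements_csv(path) -> pd.DataFrame:
    """Measurement table indexed by individual, one column per measurement."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing measurement columns {missing}")
    return df


def write_measurements_csv(records: list[MeasurementRecord] | pd.DataFrame, path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            [{"id": r.id, "species": r.species} | r.values for r in records]
        )
    cols = ["id", "species"] + [c for c in MEASUREMENT_NAMES if c in df.columns]
    df[cols].to_csv(path, index=False, float_format=_FMT)


# ---------------------------------------------------------------------------
# PNG masks
# ---------------------------------------------------------------------------

def read_mask(path) -> np.ndarray:
    """8-bit PNG -> boolean foreground mask (threshold 128)."""
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


def write_mask(mask: np.ndarray, path) -> None:
    Image.fromarray(np.where(np.asarray(mask) > 0, 255, 0).astype(np.uint8)).save(path)
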