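"""CSV/JSON readers and writers shared by the CLI subcommands.

All CSV output is comma-separated UTF-8 with a mandatory header row and
"." decimal; floating-point values are written with a fixed 12 significant
digits so reruns diff cleanly and models survive a CSV round trip.  JSON
artifacts carry a ``schema`` tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import LinearCalibration
from .geostats import KrigingSurface, VariogramModel
from .imaging import ROISpec

FLOAT_FORMAT = "%.12g"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_standards(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"concentration_mg_per_L", "mean_v"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"standards CSV missing columns: {sorted(missing)}")
    return df


def read_replicates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    rep_cols = [c for c in df.columns if c.startswith("rep_")]
    if len(rep_cols) < 2:
        raise ValueError("replicates CSV needs >= 2 rep_* columns")
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"x", "y", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"samples CSV missing columns: {sorted(missing)}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def load_model(path: str | Path) -> LinearCalibration:
    return LinearCalibration.from_dict(read_json(path))


def save_model(model: LinearCalibration, path: str | Path) -> None:
    write_json(model.to_dict(), path)


def load_roi(path: str | Path) -> ROISpec:
    return ROISpec.from_dict(read_json(path))


def load_variogram(path: str | Path) -> VariogramModel:
    return VariogramModel.from_dict(read_json(path))


def write_surface(surface: KrigingSurface, out_dir: str | Path) -> None:
    """ASCII-grid-style CSV (header JSON + matrix) plus a tidy per-cell CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(
        {
            "schema": "nitracolor.surface/1",
            "origin": list(surface.origin),
            "cell_size": surface.cell_size,
            "n_cols": surface.n_cols,
            "n_rows": surface.n_rows,
        },
        out / "grid.json",
    )
    np.savetxt(out / "predictions.csv", surface.predictions, delimiter=",", fmt=FLOAT_FORMAT)
    np.savetxt(out / "variance.csv", surface.variance, delimiter=",", fmt=FLOAT_FORMAT)
    centers = surface.cell_centers()
    tidy = pd.DataFrame(
        {
            "x": centers[:, 0],
            "y": centers[:, 1],
            "prediction": surface.predictions.ravel(),
            "variance": surface.variance.ravel(),
        }
    )
    write_csv(tidy, out / "cells.csv")
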