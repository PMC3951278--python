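"""Plain-text serialisation of contours, patterns, models and maps.

Formats: polygons as CSV (contour_id, vertex_index, x_mm, y_mm; loops
stored open), point patterns / bundle sets as CSV (source_id, x_mm, y_mm),
contour tables as CSV (factor columns + x1..x_nv, y1..y_nv), linear models
as JSON, intensity grids as a whitespace matrix with a JSON grid-spec
sidecar, masks as PNG with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import Polygon
from .intensity import GridSpec, IntensityGrid
from .segmentation import LabelledMask
from .shape_model import ContourLinearModel, ContourTable


# ---- polygons ------------------------------------------------------------

def write_polygons_csv(polygons: dict[str, Polygon], path) -> None:
    frames = []
    for cid, p in polygons.items():
        frames.append(pd.DataFrame({
            "contour_id": cid,
            "vertex_index": np.arange(p.n_vertices),
            "x_mm": p.xy[:, 0], "y_mm": p.xy[:, 1]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_polygons_csv(path) -> dict[str, Polygon]:
    df = pd.read_csv(path)
    out = {}
    for cid, grp in df.groupby("contour_id", sort=False):
        grp = grp.sort_values("vertex_index")
        out[str(cid)] = Polygon(grp[["x_mm", "y_mm"]].to_numpy())
    return out


# ---- point patterns ------------------------------------------------------

def write_points_csv(points_by_id: dict[str, np.ndarray], path) -> None:
    frames = [pd.DataFrame({"source_id": sid, "x_mm": pts[:, 0], "y_mm": pts[:, 1]})
              for sid, pts in points_by_id.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_points_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {str(sid): grp[["x_mm", "y_mm"]].to_numpy()
            for sid, grp in df.groupby("source_id", sort=False)}


# ---- contour table -------------------------------------------------------

def write_contour_table_csv(table: ContourTable, path) -> None:
    n_v = table.n_v
    cols = [f"x{i + 1}" for i in range(n_v)] + [f"y{i + 1}" for i in range(n_v)]
    df = pd.concat([table.factors.reset_index(drop=True),
                    pd.DataFrame(table.coords, columns=cols)], axis=1)
    df.to_csv(path, index=False)


def read_contour_table_csv(path) -> ContourTable:
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c[0] in "xy" and c[1:].isdigit()]
    n_v = len(coord_cols) // 2
    cols = [f"x{i + 1}" for i in range(n_v)] + [f"y{i + 1}" for i in range(n_v)]
    factors = df[[c for c in df.columns if c not in coord_cols]]
    return ContourTable(df[cols].to_numpy(float), factors, n_v)


# ---- linear model --------------------------------------------------------

def model_to_json(m: ContourLinearModel, path) -> None:
    doc = {
        "n_v": m.n_v,
        "cuts": list(m.cuts),
        "mu": m.mu.tolist(),
        "alpha": {k: v.tolist() for k, v in m.alpha.items()},
        "beta": {k: v.tolist() for k, v in m.beta.items()},
        "stem_effects": {f"{g}/{s}": v.tolist()
                         for (g, s), v in m.stem_effects.items()},
    }
    Path(path).write_text(json.dumps(doc))


def model_from_json(path) -> ContourLinearModel:
    doc = json.loads(Path(path).read_text())
    return ContourLinearModel(
        mu=np.array(doc["mu"]),
        alpha={k: np.array(v) for k, v in doc["alpha"].items()},
        beta={k: np.array(v) for k, v in doc["beta"].items()},
        stem_effects={tuple(k.split("/", 1)): np.array(v)
                      for k, v in doc["stem_effects"].items()},
        residuals=np.zeros((0, 2 * doc["n_v"])),
        n_v=doc["n_v"], cuts=tuple(doc["cuts"]))


# ---- intensity grids -----------------------------------------------------

def write_grid(grid: IntensityGrid, base_path) -> None:
    base = Path(base_path)
    np.savetxt(base.with_suffix(".txt"), np.where(grid.mask, grid.values, np.nan),
               fmt="%.6g")
    spec = {"x0": grid.grid.x0, "y0": grid.grid.y0, "dx": grid.grid.dx,
            "dy": grid.grid.dy, "nx": grid.grid.nx, "ny": grid.grid.ny}
    base.with_suffix(".json").write_text(json.dumps(spec))


def read_grid(base_path) -> IntensityGrid:
    base = Path(base_path)
    values = np.loadtxt(base.with_suffix(".txt"))
    spec = GridSpec(**json.loads(base.with_suffix(".json").read_text()))
    mask = ~np.isnan(values)
    return IntensityGrid(np.nan_to_num(values), mask, spec)


# ---- masks ---------------------------------------------------------------

def write_mask_png(m: LabelledMask, base_path) -> None:
    base = Path(base_path)
    iio.imwrite(base.with_suffix(".png"),
                (np.asarray(m.mask, bool) * np.uint8(255)))
    base.with_suffix(".json").write_text(json.dumps(
        {"resolution": m.resolution, "source_id": m.source_id}))


def read_mask_png(base_path) -> LabelledMask:
    base = Path(base_path)
    mask = np.asarray(iio.imread(base.with_suffix(".png"))) > 0
    side = json.loads(base.with_suffix(".json").read_text())
    return LabelledMask(mask, side["resolution"], side.get("source_id", ""))
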