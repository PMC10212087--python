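"""File formats: TIFF sequences, GeoJSON outlines, CSV tables, JSON results.

Conventions fixed for bit-reproducible diffs: step-indexed TIFF filenames
zero-padded to 4 digits; CSV with comma separator, '.' decimal, UTF-8 and
a header row; JSON with sorted keys.  Images are written as 16-bit
grayscale (intensities in [0, 1] scaled to the full uint16 range).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape

from ._errors import ValidationError
from .morphometry import CellPolygon, TemPanel
from .tracking import DeflectionSeries, TipTrajectory


def write_image_sequence(frames: np.ndarray, out_dir, prefix: str = "step") -> list[Path]:
    """Write one 16-bit grayscale TIFF per step: ``{prefix}_0000.tif``…"""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, frame in enumerate(frames):
        arr = np.clip(frame, 0.0, 1.0)
        path = out_dir / f"{prefix}_{j:04d}.tif"
        tifffile.imwrite(path, (arr * 65535).round().astype(np.uint16))
        paths.append(path)
    return paths


def read_image_sequence(in_dir, prefix: str = "step") -> np.ndarray:
    """Read a step-indexed TIFF/PNG sequence back to a float stack in [0, 1]."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob(f"{prefix}_*.tif")) + sorted(in_dir.glob(f"{prefix}_*.png"))
    if not paths:
        raise ValidationError(f"no {prefix}_*.tif/png frames in {in_dir}")
    frames = []
    for p in paths:
        if p.suffix == ".tif":
            arr = tifffile.imread(p)
        else:
            from imageio.v3 import imread
            arr = imread(p)
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        frames.append(arr.astype(float) / (info.max if info else 1.0))
    return np.stack(frames)


def write_trajectory_csv(path, loaded: TipTrajectory, reference: TipTrajectory,
                         deflections: DeflectionSeries) -> None:
    """One row per tip per step: positions, scores and deflections."""
    rows = []
    for run, traj in (("loaded", loaded), ("reference", reference)):
        for j in range(traj.n_frames):
            for t, tip in enumerate(("top", "bottom")):
                defl = deflections.deflections_um[j, t] if run == "loaded" else 0.0
                rows.append({"run": run, "step": j, "tip": tip,
                             "y_px": traj.positions_px[j, t, 0],
                             "x_px": traj.positions_px[j, t, 1],
                             "score": traj.scores[j, t],
                             "deflection_um": defl})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curve_csv(path, compression_um, force_n) -> None:
    pd.DataFrame({"step": np.arange(len(compression_um)),
                  "delta_um": compression_um,
                  "force_nN": np.asarray(force_n) * 1e9}).to_csv(path, index=False)


def read_curve_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["delta_um"].to_numpy(), df["force_nN"].to_numpy() * 1e-9


def write_estimate_json(path, estimate) -> None:
    Path(path).write_text(json.dumps({
        "E_pa": estimate.youngs_modulus_pa,
        "residual_nN": estimate.residual_n * 1e9,
        "n_points": estimate.n_points,
        "method": estimate.method,
    }, sort_keys=True, indent=2) + "\n")


def write_ground_truth_json(path, truth) -> None:
    Path(path).write_text(json.dumps({
        "deflection_um": truth.deflection_um.tolist(),
        "force_n": truth.force_n.tolist(),
        "compression_um": truth.compression_um.tolist(),
        "separation_um": truth.separation_um.tolist(),
        "reference_positions_px": truth.reference_positions_px.tolist(),
        "loaded_positions_px": truth.loaded_positions_px.tolist(),
        "pixel_pitch_um": truth.pixel_pitch_um,
        "seed": truth.seed,
    }, sort_keys=True) + "\n")


def cells_to_geojson(cells, panel_id: int | None = None) -> dict:
    """CellPolygon list → GeoJSON FeatureCollection (cell + nucleus features)."""
    features = []
    for cell in cells:
        props = {"cell_id": cell.cell_id, "role": "cell", "region": cell.region,
                 "clipped": bool(cell.clipped)}
        if panel_id is not None:
            props["panel_id"] = panel_id
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(cell.cell)})
        if cell.nucleus is not None:
            nprops = dict(props, role="nucleus")
            features.append({"type": "Feature", "properties": nprops,
                             "geometry": mapping(cell.nucleus)})
    return {"type": "FeatureCollection", "features": features}


def write_cells_geojson(path, cells, panel_id: int | None = None) -> None:
    Path(path).write_text(json.dumps(cells_to_geojson(cells, panel_id),
                                     sort_keys=True) + "\n")


def read_cells_geojson(path) -> list[CellPolygon]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValidationError("expected a GeoJSON FeatureCollection")
    by_id: dict[int, dict] = {}
    for feat in doc["features"]:
        props = feat["properties"]
        rec = by_id.setdefault(props["cell_id"], {"props": props})
        rec[props["role"]] = shape(feat["geometry"])
    cells = []
    for cid in sorted(by_id):
        rec = by_id[cid]
        if "cell" not in rec:
            raise ValidationError(f"cell_id {cid} has no 'cell' outline")
        cells.append(CellPolygon(cell_id=cid, cell=rec["cell"],
                                 nucleus=rec.get("nucleus"),
                                 region=rec["props"].get("region"),
                                 clipped=bool(rec["props"].get("clipped", False))))
    return cells


def read_cells_csv(path) -> list[CellPolygon]:
    """CSV outline format: cell_id, role, vertex_index, x_um, y_um."""
    df = pd.read_csv(path)
    required = {"cell_id", "role", "vertex_index", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValidationError(f"outline CSV needs columns {sorted(required)}")
    cells = []
    for cid, group in df.groupby("cell_id"):
        geoms = {}
        for role, g in group.groupby("role"):
            g = g.sort_values("vertex_index")
            geoms[role] = Polygon(np.column_stack([g["x_um"], g["y_um"]]))
        if "cell" not in geoms:
            raise ValidationError(f"cell_id {cid} has no 'cell' outline")
        cells.append(CellPolygon(cell_id=int(cid), cell=geoms["cell"],
                                 nucleus=geoms.get("nucleus")))
    return cells


def write_panels_csv(path, panels) -> None:
    pd.DataFrame([{
        "panel_id": p.panel_id, "x_start_um": p.x_start_um, "x_end_um": p.x_end_um,
        "y_start_um": p.y_start_um, "y_end_um": p.y_end_um,
        "edge_flag": int(p.contains_spheroid_edge),
    } for p in panels]).to_csv(path, index=False)


def read_panels_csv(path) -> list[TemPanel]:
    df = pd.read_csv(path)
    return [TemPanel(panel_id=int(r.panel_id), x_start_um=r.x_start_um,
                     x_end_um=r.x_end_um, y_start_um=getattr(r, "y_start_um", 0.0),
                     y_end_um=getattr(r, "y_end_um", 0.0),
                     contains_spheroid_edge=bool(r.edge_flag))
            for r in df.itertuples()]


def write_summary(out_dir, summary) -> None:
    out_dir = Path(out_dir)
    summary.areas.to_csv(out_dir / "areas.csv", index=False)
    summary.densities.to_csv(out_dir / "densities.csv", index=False)
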