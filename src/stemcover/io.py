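"""Readers and writers for the pipeline's tabular and geospatial artifacts.

Conventions: dates are ISO-8601 strings; cell ids are integers with
``cell_id = iy * n_x + ix`` (0-based from the south-west corner); all
fractions are decimals in [0, 1] — percentages appear only in reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .world import CATEGORY_GROUPS, HABITAT_CLASSES, WorldGrid

_GROUP_COLS = ["fraction_I_IV", "fraction_V_VI", "fraction_undesignated"]


# --- world -----------------------------------------------------------------


def write_world(world: WorldGrid, path: str | Path) -> None:
    df = world.cells.copy()
    df.attrs = {}
    df.insert(0, "n_x", world.n_x)
    df.insert(1, "n_y", world.n_y)
    df.insert(2, "cell_size_km", world.cell_size_km)
    df.to_csv(path, index=False)


def read_world(path: str | Path) -> WorldGrid:
    df = pd.read_csv(path)
    n_x, n_y, size = int(df["n_x"].iloc[0]), int(df["n_y"].iloc[0]), float(df["cell_size_km"].iloc[0])
    cells = df.drop(columns=["n_x", "n_y", "cell_size_km"]).reset_index(drop=True)
    return WorldGrid(cells=cells, n_x=n_x, n_y=n_y, cell_size_km=size)


# --- checklists ------------------------------------------------------------


def write_checklists(checklists: pd.DataFrame, path: str | Path) -> None:
    checklists.to_csv(path, index=False)


def read_checklists(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("list_length", "record_total"):
        if col in df:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


# --- protected layer -------------------------------------------------------


def write_protected_layer(layer: pd.DataFrame, path: str | Path) -> None:
    layer.to_csv(path, index=False)


def read_protected_layer(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "fraction_total" not in df:
        df["fraction_total"] = df[[c for c in _GROUP_COLS if c in df]].sum(axis=1)
    return df


# --- protected polygons (WDPA-dialect GeoJSON) -----------------------------

_WDPA_FIELDS = {
    "STATUS": "status",
    "DESIG_TYPE": "desig_type",
    "DESIG_ENG": "designation",
    "IUCN_CAT": "iucn_cat",
    "REP_AREA": "rep_area_km2",
}


def read_protected_geojson(path: str | Path) -> pd.DataFrame:
    """Protected-area features from GeoJSON with WDPA-style attributes."""
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj.get("features", []):
        props = feat.get("properties", {}) or {}
        row = {out: props.get(src) for src, out in _WDPA_FIELDS.items()}
        geom = feat.get("geometry")
        row["geometry"] = shape(geom) if geom else None
        rows.append(row)
    return pd.DataFrame(rows)


def write_protected_geojson(features: pd.DataFrame, path: str | Path) -> None:
    out = {"type": "FeatureCollection", "features": []}
    inverse = {v: k for k, v in _WDPA_FIELDS.items()}
    for _, row in features.iterrows():
        props = {inverse[c]: row[c] for c in features.columns if c in inverse}
        geom = row.get("geometry")
        out["features"].append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(geom) if geom is not None else None,
            }
        )
    Path(path).write_text(json.dumps(out))


# --- predictions / coverage / occupancy ------------------------------------


def write_predictions(preds: pd.DataFrame, path: str | Path) -> None:
    preds.to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_occupancy(occ, path: str | Path) -> None:
    """True-occupancy oracle as long CSV (species_id, day, cell_id, occupancy)."""
    days, cells = np.nonzero(occ.occupancy)
    pd.DataFrame(
        {
            "species_id": occ.species_id,
            "day": days + 1,
            "cell_id": cells,
            "occupancy": occ.occupancy[days, cells],
        }
    ).to_csv(path, index=False)


# --- validation ------------------------------------------------------------


def validate_inputs(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Schema/range checks per input file.

    ``paths`` maps kind ('world' | 'checklists' | 'protected') to a file.
    Returns a frame with columns file, kind, passed, problems.
    """
    reports = []
    for kind, path in paths.items():
        problems: list[str] = []
        try:
            if kind == "world":
                w = read_world(path)
                fr = w.cells[list(HABITAT_CLASSES)].to_numpy()
                if ((fr < 0) | (fr > 1)).any():
                    problems.append("habitat fraction outside [0, 1]")
                if (fr.sum(axis=1) > 1 + 1e-9).any():
                    problems.append("habitat fractions sum above 1")
                if w.cells["cell_id"].duplicated().any():
                    problems.append("duplicate cell ids")
                if len(w.cells) != w.n_x * w.n_y:
                    problems.append("grid incomplete")
            elif kind == "checklists":
                df = read_checklists(path)
                required = {"cell_id", "date", "type"}
                missing = required - set(df.columns)
                if missing:
                    problems.append(f"missing columns: {sorted(missing)}")
                else:
                    try:
                        pd.to_datetime(df["date"], format="%Y-%m-%d")
                    except (ValueError, TypeError):
                        problems.append("dates not ISO-8601")
                    bad_type = set(df["type"]) - {"complete", "casual", "pseudo_complete"}
                    if bad_type:
                        problems.append(f"unknown checklist types: {sorted(bad_type)}")
                    casual = df[df["type"] == "casual"]
                    if "record_total" in df and (casual["record_total"] < 1).any():
                        rows = casual.index[casual["record_total"] < 1].tolist()[:3]
                        problems.append(f"record_total < 1 at rows {rows}")
                    complete = df[df["type"] != "casual"]
                    if "list_length" in df and (complete["list_length"] < 0).any():
                        problems.append("negative list_length")
            elif kind == "protected":
                df = read_protected_layer(path)
                for col in (*_GROUP_COLS, "fraction_total"):
                    if col in df and ((df[col] < 0) | (df[col] > 1 + 1e-9)).any():
                        rows = df.index[(df[col] < 0) | (df[col] > 1 + 1e-9)].tolist()[:3]
                        problems.append(f"{col} outside [0, 1] at rows {rows}")
            else:
                problems.append(f"unknown input kind {kind!r}")
        except FileNotFoundError:
            problems.append("file not found")
        except Exception as exc:  # malformed file: report, don't crash
            problems.append(f"unreadable: {exc}")
        reports.append(
            {"file": str(path), "kind": kind, "passed": not problems,
             "problems": "; ".join(problems)}
        )
    return pd.DataFrame(reports)


# --- map export ------------------------------------------------------------


def export_weekly_map(preds: pd.DataFrame, world: WorldGrid, path: str | Path) -> None:
    """Static PNG of one species-week occurrence surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.full(world.n_cells, np.nan)
    grid[preds["cell_id"].to_numpy()] = preds["p_occ"].to_numpy()
    img = grid.reshape(world.n_y, world.n_x)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(img, origin="lower", cmap="viridis", vmin=0)
    fig.colorbar(im, ax=ax, label="p(occurrence)")
    sp = preds["species_id"].iloc[0] if len(preds) else ""
    wk = preds["week"].iloc[0] if len(preds) else ""
    ax.set_title(f"{sp} week {wk}")
    fig.savefig(path, dpi=100)
    plt.close(fig)


CATEGORY_GROUP_NAMES = CATEGORY_GROUPS
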