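"""Protected-area processing and occurrence-weighted coverage.

The coverage statistic weights each grid cell's protected fraction by the
share of the species' weekly summed occurrence in that cell: if a square
holds 10% of the summed occurrence and half of it is protected, the square
contributes 5 percentage points of protection.  Weekly coverage is compared
to a range-adjusted target interpolated loglinearly from 100% (range <=
1000 km^2) down to a policy baseline of 17% (2020 CBD) or 30% (2030 CBD)
for ranges >= 250,000 km^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box, shape
from shapely.ops import unary_union
from shapely.validation import make_valid

from .world import CATEGORY_GROUPS, WorldGrid

# WDPA attribute dialect ------------------------------------------------------

KEEP_STATUS = {"Designated", "Inscribed", "Established"}
DROP_DESIGNATIONS = {"UNESCO-MAB Biosphere Reserve"}
DROP_DESIG_TYPES = {"Not Assigned", "Not Reported", "Not Defined", "Not Applicable"}
IUCN_PRIORITY = ["Ia", "Ib", "II", "III", "IV", "V", "VI", "unassigned"]
_UNASSIGNED_LABELS = {"Not Assigned", "Not Reported", "Not Applicable", "unassigned", "", None}

GROUP_OF_CATEGORY = {
    "Ia": "I-IV", "Ib": "I-IV", "II": "I-IV", "III": "I-IV", "IV": "I-IV",
    "V": "V-VI", "VI": "V-VI", "unassigned": "undesignated",
}

GROUP_COLUMNS = {
    "I-IV": "fraction_I_IV",
    "V-VI": "fraction_V_VI",
    "undesignated": "fraction_undesignated",
}


def _normalise_category(cat) -> str:
    if cat in _UNASSIGNED_LABELS or (isinstance(cat, float) and math.isnan(cat)):
        return "unassigned"
    cat = str(cat)
    if cat in GROUP_OF_CATEGORY:
        return cat
    raise KeyError(f"unknown IUCN category label: {cat!r}")


def clean_protected_polygons(features: pd.DataFrame) -> pd.DataFrame:
    """Apply standard WDPA cleaning to a protected-area feature table.

    ``features`` needs columns ``geometry`` (shapely geometry or GeoJSON
    mapping), ``status``, ``desig_type``, ``designation``, ``iucn_cat``
    and optionally ``rep_area_km2`` for point features.  Removes features
    that are not implemented (status other than Designated / Inscribed /
    Established), biosphere reserves, OECMs, features whose designation
    type is not assigned/reported/defined, and points without a reported
    area; buffers remaining points to circles of their reported area and
    repairs invalid geometries.
    """
    rows = []
    for _, f in features.iterrows():
        status = f.get("status")
        if status not in KEEP_STATUS:
            continue
        if f.get("designation") in DROP_DESIGNATIONS:
            continue
        desig_type = f.get("desig_type")
        if desig_type in DROP_DESIG_TYPES or desig_type == "OECM":
            continue
        geom = f["geometry"]
        if geom is not None and not hasattr(geom, "geom_type"):
            geom = shape(geom)
        rep_area = f.get("rep_area_km2")
        has_area = rep_area is not None and np.isfinite(rep_area) and rep_area > 0
        if geom is None or geom.is_empty:
            if not has_area:
                warnings.warn("dropping feature with neither geometry nor area", stacklevel=2)
                continue
            warnings.warn("dropping feature with no geometry", stacklevel=2)
            continue
        if geom.geom_type in ("Point", "MultiPoint"):
            if not has_area:
                continue  # point location without an area specified
            radius = math.sqrt(rep_area / math.pi)
            geom = geom.buffer(radius, quad_segs=64)
        if not geom.is_valid:
            geom = make_valid(geom)
        rows.append({"geometry": geom, "iucn_cat": _normalise_category(f.get("iucn_cat"))})
    return pd.DataFrame(rows, columns=["geometry", "iucn_cat"])


def dissolve_by_priority(cleaned: pd.DataFrame) -> pd.DataFrame:
    """Resolve overlaps so stricter IUCN designations win.

    Dissolves progressively from Ia to VI and finally unassigned sites:
    each category keeps only the ground not already claimed by a stricter
    one.  Returns one row per category *group* (I-IV, V-VI, undesignated)
    with a disjoint geometry and its area.
    """
    if len(cleaned):
        cleaned = cleaned.assign(iucn_cat=[_normalise_category(c) for c in cleaned["iucn_cat"]])
    claimed = None
    group_geoms: dict[str, list] = {g: [] for g in CATEGORY_GROUPS}
    for cat in IUCN_PRIORITY:
        geoms = [g for g, c in zip(cleaned.get("geometry", []), cleaned.get("iucn_cat", [])) if c == cat]
        if not geoms:
            continue
        merged = unary_union(geoms)
        if claimed is not None:
            merged = merged.difference(claimed)
        claimed = merged if claimed is None else unary_union([claimed, merged])
        if not merged.is_empty:
            group_geoms[GROUP_OF_CATEGORY[cat]].append(merged)
    rows = []
    for g in CATEGORY_GROUPS:
        geom = unary_union(group_geoms[g]) if group_geoms[g] else None
        rows.append({"group": g, "geometry": geom, "area_km2": 0.0 if geom is None else geom.area})
    return pd.DataFrame(rows)


def intersect_pa_grid(dissolved: pd.DataFrame, world: WorldGrid) -> pd.DataFrame:
    """Per-cell protected fraction per category group.

    Intersects each grid cell's square with each group's dissolved
    geometry; fraction = intersected area / cell area.  Returns the
    protected-layer frame (cell_id + one fraction column per group +
    ``fraction_total``).
    """
    cells = world.cells
    half = world.cell_size_km / 2.0
    out = pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()})
    for g in CATEGORY_GROUPS:
        row = dissolved[dissolved["group"] == g]
        geom = row["geometry"].iloc[0] if len(row) else None
        if geom is None or geom.is_empty:
            out[GROUP_COLUMNS[g]] = 0.0
            continue
        fracs = np.zeros(len(cells))
        for i, (x, y) in enumerate(zip(cells["x_km"], cells["y_km"])):
            cell_box = box(x - half, y - half, x + half, y + half)
            if geom.intersects(cell_box):
                fracs[i] = geom.intersection(cell_box).area / world.cell_area_km2
        out[GROUP_COLUMNS[g]] = np.clip(fracs, 0.0, 1.0)
    out["fraction_total"] = out[[GROUP_COLUMNS[g] for g in CATEGORY_GROUPS]].sum(axis=1)
    return out


def filter_layer(layer: pd.DataFrame, include: tuple[str, ...] | list[str]) -> pd.DataFrame:
    """Protected layer restricted to a subset of category groups.

    E.g. ``include=("I-IV", "undesignated")`` drops the weakly protected
    V-VI sites while keeping sites of unreported category, the variant
    used to test sensitivity to protection strength.
    """
    include = tuple(include)
    if not include:
        raise ValueError("include set must not be empty")
    unknown = set(include) - set(CATEGORY_GROUPS)
    if unknown:
        raise ValueError(f"unknown category groups: {sorted(unknown)}")
    out = layer[["cell_id"]].copy()
    total = np.zeros(len(layer))
    for g in CATEGORY_GROUPS:
        col = GROUP_COLUMNS[g]
        vals = layer[col].to_numpy(dtype=float) if col in layer else np.zeros(len(layer))
        if g in include:
            out[col] = vals
            total += vals
        else:
            out[col] = 0.0
    out["fraction_total"] = total
    return out


# ---------------------------------------------------------------------------
# Coverage metrics
# ---------------------------------------------------------------------------


def _fractions_for(predictions: pd.DataFrame, layer: pd.DataFrame) -> np.ndarray:
    frac = layer.set_index("cell_id")["fraction_total"]
    return frac.reindex(predictions["cell_id"].to_numpy()).fillna(0.0).to_numpy()


def percent_protected(predictions: pd.DataFrame, layer: pd.DataFrame) -> float:
    """Occurrence-weighted protected percentage for one species-week.

    100 * sum_i(p_i * a_i) / sum_i(p_i) with p_i the cell's occurrence
    probability and a_i its protected fraction; assumes birds are evenly
    spread within each 10-km square.  Undefined (error) when the summed
    occurrence is zero — the species is outside the study area that week.
    """
    p = predictions["p_occ"].to_numpy(dtype=float)
    p = np.where(np.isfinite(p), p, 0.0)
    total = p.sum()
    if total <= 0:
        raise ValueError("summed occurrence is zero; coverage undefined this week")
    a = _fractions_for(predictions, layer)
    return float(100.0 * np.sum(p * a) / total)


def percent_protected_thresholded(
    predictions: pd.DataFrame, layer: pd.DataFrame, cell_threshold: float
) -> float:
    """Coverage under a binary protected/unprotected cell classification.

    A cell counts as fully protected iff its protected fraction is >=
    ``cell_threshold`` (conventional choices 0.10 and 0.50), else fully
    unprotected; then occurrence-weighted as usual.
    """
    if not (0.0 < cell_threshold <= 1.0):
        raise ValueError("cell_threshold must lie in (0, 1]")
    a = _fractions_for(predictions, layer)
    binary = layer.copy()
    hard = (a >= cell_threshold).astype(float)
    tmp = predictions[["cell_id", "p_occ"]].copy()
    binary = pd.DataFrame({"cell_id": tmp["cell_id"], "fraction_total": hard})
    return percent_protected(tmp, binary)


def weekly_range_area(predictions: pd.DataFrame, cell_area_km2: float = 100.0) -> float:
    """Weekly range area: cell area times the count of cells with p > 0."""
    p = predictions["p_occ"].to_numpy(dtype=float)
    return float(cell_area_km2 * np.count_nonzero(np.nan_to_num(p) > 0))


#: Interpolation thresholds of the range-adjusted target (km^2).
TARGET_AREA_LO = 1_000.0
TARGET_AREA_HI = 250_000.0


def range_adjusted_target(area_km2: float, base_pct: float = 17.0) -> float:
    """Range-adjusted protection target (percent of range to protect).

    100% for ranges at or below 1000 km^2, the policy baseline
    (17% for the 2020 CBD framework, 30% for 2030) at or above
    250,000 km^2, loglinear in between; continuous and non-increasing,
    independent of the logarithm base.
    """
    if area_km2 < 0:
        raise ValueError("area must be >= 0")
    if base_pct not in (17.0, 30.0, 17, 30):
        warnings.warn(f"non-standard policy baseline {base_pct}%", stacklevel=2)
    if area_km2 <= TARGET_AREA_LO:
        return 100.0
    if area_km2 >= TARGET_AREA_HI:
        return float(base_pct)
    frac = (math.log(area_km2) - math.log(TARGET_AREA_LO)) / (
        math.log(TARGET_AREA_HI) - math.log(TARGET_AREA_LO)
    )
    return float(100.0 + (base_pct - 100.0) * frac)


@dataclass
class SeasonWindow:
    """Weeks over which a species is considered present in the study area."""

    species_id: str
    first_week: int
    last_week: int

    def contains(self, week: int) -> bool:
        return self.first_week <= week <= self.last_week


def season_window(
    weekly_summed_occurrence: pd.Series | np.ndarray,
    cutoff: float = 0.25,
    species_id: str = "",
) -> SeasonWindow:
    """Span of weeks with summed occurrence >= ``cutoff`` x its maximum.

    The window runs from the earliest to the latest qualifying week;
    interior weeks that dip below the cutoff stay inside (they are real
    presence, e.g. incubation-period detectability lows).  Errors on an
    all-zero series.
    """
    if isinstance(weekly_summed_occurrence, pd.Series):
        weeks = weekly_summed_occurrence.index.to_numpy()
        vals = weekly_summed_occurrence.to_numpy(dtype=float)
    else:
        vals = np.asarray(weekly_summed_occurrence, dtype=float)
        weeks = np.arange(1, len(vals) + 1)
    vals = np.nan_to_num(vals)
    mx = vals.max()
    if mx <= 0:
        raise ValueError("all-zero summed occurrence; no season window")
    ok = vals >= cutoff * mx
    return SeasonWindow(species_id, int(weeks[ok][0]), int(weeks[ok][-1]))


def season_of_week(week: int) -> str:
    """Broad seasonal category: spring passage (weeks <=18), breeding
    (19-31), autumn passage (>=32); weeks 1-4 and 49-53 extend the nearest
    passage category."""
    if not 1 <= week <= 53:
        raise ValueError(f"week must be in 1..53, got {week}")
    if week <= 18:
        return "spring"
    if week <= 31:
        return "breeding"
    return "autumn"


def coverage_table(
    predictions: pd.DataFrame,
    layer: pd.DataFrame,
    cell_area_km2: float = 100.0,
    cutoff: float = 0.25,
    target_bases: tuple[float, float] = (17.0, 30.0),
) -> pd.DataFrame:
    """Per species-week coverage, range, targets and adequacy.

    ``predictions`` holds stacked weekly surfaces (cell_id, week,
    species_id, p_occ, ...).  Weeks outside a species' season window are
    excluded.  Returns one row per retained species-week with columns
    species_id, week, summed_occ, range_km2, pct_protected, target17,
    target30, adequate17, adequate30, season.
    """
    rows = []
    for sp, sp_pred in predictions.groupby("species_id"):
        weekly_sum = (
            sp_pred.assign(p=lambda d: np.nan_to_num(d["p_occ"]))
            .groupby("week")["p"].sum()
        )
        window = season_window(weekly_sum, cutoff=cutoff, species_id=str(sp))
        for week, wk_pred in sp_pred.groupby("week"):
            if not window.contains(int(week)):
                continue
            pct = percent_protected(wk_pred, layer)
            area = weekly_range_area(wk_pred, cell_area_km2)
            t17 = range_adjusted_target(area, target_bases[0])
            t30 = range_adjusted_target(area, target_bases[1])
            rows.append(
                {
                    "species_id": sp,
                    "week": int(week),
                    "summed_occ": float(weekly_sum.loc[week]),
                    "range_km2": area,
                    "pct_protected": pct,
                    "target17": t17,
                    "target30": t30,
                    "adequate17": pct >= t17,
                    "adequate30": pct >= t30,
                    "season": season_of_week(int(week)),
                }
            )
    return pd.DataFrame(rows)


def species_means(coverage: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean coverage and range over in-window weeks."""
    return (
        coverage.groupby("species_id")
        .agg(
            mean_pct_protected=("pct_protected", "mean"),
            mean_range_km2=("range_km2", "mean"),
            n_weeks=("week", "count"),
        )
        .reset_index()
    )
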