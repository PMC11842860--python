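"""Promote casual records to pseudo-complete lists.

Casual records carry no effort information beyond the cell-day total of
observer x species combinations.  A random-forest regression of complete-list
length on location, month, elevation and habitat gives the expected length of
a complete list for every (cell, month); a casual cell-day whose record total
is equal to or more than that expectation is treated as a pseudo-complete
list, with the union of its casually recorded species as presences and all
other modelled species as absences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .world import HABITAT_CLASSES, WorldGrid

#: Covariates of the list-length model: coordinates, month, elevation, habitat.
LIST_LENGTH_FEATURES = ["x_km", "y_km", "month", "elevation", *HABITAT_CLASSES]


@dataclass
class ListLengthModel:
    """Fitted expected-complete-list-length regressor.

    Predictions are finite and >= 0 for any (cell, month) on the training
    world.  ``r2_in_sample`` is the in-sample coefficient of determination.
    """

    regressor: RandomForestRegressor
    world: WorldGrid
    feature_names: list[str] = field(default_factory=lambda: list(LIST_LENGTH_FEATURES))
    n_training: int = 0
    seed: int = 0
    r2_in_sample: float = float("nan")

    def predict(self, cell_ids: np.ndarray, months: np.ndarray) -> np.ndarray:
        """Expected complete-list length for paired arrays of cells/months."""
        cell_ids = np.asarray(cell_ids)
        months = np.asarray(months)
        cells = self.world.cells.set_index("cell_id")
        missing = set(np.unique(cell_ids)) - set(cells.index)
        if missing:
            raise KeyError(f"unknown cell ids: {sorted(missing)[:5]}")
        sub = cells.loc[cell_ids]
        X = pd.DataFrame(
            {
                "x_km": sub["x_km"].to_numpy(),
                "y_km": sub["y_km"].to_numpy(),
                "month": months,
            }
        )
        X["elevation"] = sub["elevation"].to_numpy()
        for h in HABITAT_CLASSES:
            X[h] = sub[h].to_numpy()
        pred = self.regressor.predict(X[self.feature_names])
        return np.maximum(pred, 0.0)


def _month_of_day(day_of_year: np.ndarray, year: int = 2018) -> np.ndarray:
    start = pd.Timestamp(year=year, month=1, day=1)
    dates = start + pd.to_timedelta(np.asarray(day_of_year) - 1, unit="D")
    return dates.month.to_numpy() if hasattr(dates, "month") else np.array([d.month for d in dates])


def fit_list_length_model(
    complete_lists: pd.DataFrame,
    world: WorldGrid,
    seed: int = 0,
    n_estimators: int = 100,
    min_lists: int = 50,
    **rf_kwargs,
) -> ListLengthModel:
    """Fit the random-forest list-length model on complete lists.

    Requires at least ``min_lists`` complete lists spanning >= 2 calendar
    months.  Deterministic for a fixed seed.
    """
    lists = complete_lists[complete_lists["type"] == "complete"]
    if len(lists) < min_lists:
        raise ValueError(
            f"need >= {min_lists} complete lists to fit the list-length model, got {len(lists)}"
        )
    months = pd.Series(_month_of_day(lists["day_of_year"].to_numpy()))
    if months.nunique() < 2:
        raise ValueError("complete lists must span at least 2 months")

    merged = lists.merge(world.cells, on="cell_id", how="left", suffixes=("", "_w"))
    X = pd.DataFrame({"x_km": merged["x_km"], "y_km": merged["y_km"], "month": months.to_numpy()})
    X["elevation"] = merged["elevation"].to_numpy()
    for h in HABITAT_CLASSES:
        X[h] = merged[h].to_numpy()
    y = merged["list_length"].to_numpy(dtype=float)

    rf = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, **rf_kwargs
    )
    rf.fit(X[LIST_LENGTH_FEATURES], y)
    r2 = float(rf.score(X[LIST_LENGTH_FEATURES], y))
    return ListLengthModel(
        regressor=rf, world=world, n_training=len(lists), seed=seed, r2_in_sample=r2
    )


def predict_expected_length(model: ListLengthModel, cell_id: int, month: int) -> float:
    """Expected complete-list length for one (cell, month)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return float(model.predict(np.array([cell_id]), np.array([month]))[0])


def promote_casual_records(
    casual: pd.DataFrame, model: ListLengthModel, year: int = 2018
) -> pd.DataFrame:
    """Turn qualifying casual cell-days into pseudo-complete lists.

    A cell-day is promoted iff its summed record total is equal to or more
    than the predicted complete-list length for that cell/month (inclusive
    comparison on the real-valued prediction; no rounding).  Promoted rows
    carry type ``pseudo_complete``, the record total as the list total and
    the union of casually recorded species as presences; non-promoted
    cell-days are dropped.
    """
    casual = casual[casual["type"] == "casual"]
    if len(casual) == 0:
        return casual.iloc[0:0].copy()

    sp_cols = [c for c in casual.columns if c.startswith("sp_")]
    agg = {"record_total": "sum", "day_of_year": "first"}
    for c in sp_cols:
        agg[c] = "max"
    grouped = (
        casual.groupby(["cell_id", "date"], as_index=False, sort=True).agg(agg)
    )
    months = _month_of_day(grouped["day_of_year"].to_numpy(), year=year)
    expected = model.predict(grouped["cell_id"].to_numpy(), months)
    keep = grouped["record_total"].to_numpy() >= expected

    out = grouped.loc[keep].copy()
    out["type"] = "pseudo_complete"
    out["list_length"] = out["record_total"].astype(float)
    out["record_total"] = np.nan
    cols = ["cell_id", "date", "day_of_year", "type", "list_length", "record_total", *sp_cols]
    return out[cols].reset_index(drop=True)


def merge_lists(complete: pd.DataFrame, pseudo: pd.DataFrame) -> pd.DataFrame:
    """Concatenate complete and pseudo-complete streams for model fitting.

    Complete lists pass through untouched; the merged frame is the STEM
    training input ("data type" distinguishes the two streams).
    """
    complete = complete[complete["type"] == "complete"]
    return pd.concat([complete, pseudo], ignore_index=True)
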