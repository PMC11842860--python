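"""Spatiotemporal Exploratory Model (STEM) ensemble.

STEM handles non-stationary species-environment relationships by tiling the
space-time extent with large blocks ("stixels", default 500 km x 500 km x
40 days), fitting an independent boosted-tree base model inside each block,
and repeating with ``n`` randomly offset tilings (partitions).  A prediction
at a location/date averages all base models whose stixel contains it; the
between-model variance and the count of covering models (ensemble support)
quantify reliability.  Averaged occurrence probabilities below a floor
(default 0.01) are set to zero, since such values reflect a handful of
occurrences rather than the population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score

from .world import CLIMATE_COVARIATES, HABITAT_CLASSES, WorldGrid, species_column

#: Base-model covariates: position, time, effort, data type, environment.
STEM_FEATURES = [
    "x_km",
    "y_km",
    "year",
    "day_of_year",
    "list_length",
    "is_complete",
    "elevation",
    *HABITAT_CLASSES,
    *CLIMATE_COVARIATES,
]


@dataclass(frozen=True)
class Extent:
    """Spatial + temporal bounds of the modelled domain."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    day_min: int = 1
    day_max: int = 366

    def __post_init__(self) -> None:
        if self.xmax <= self.xmin or self.ymax <= self.ymin or self.day_max < self.day_min:
            raise ValueError("degenerate extent")

    @classmethod
    def from_world(cls, world: WorldGrid, day_min: int = 1, day_max: int = 366) -> "Extent":
        xmin, ymin, xmax, ymax = world.extent_km
        return cls(xmin, ymin, xmax, ymax, day_min, day_max)


@dataclass(frozen=True)
class StixelPartition:
    """One randomly offset complete tiling of the extent by stixels.

    Stixel boundaries follow the ``floor((coord - offset) / width)``
    convention, so indices may be negative for clipped edge stixels; within
    one partition every point of the extent belongs to exactly one stixel.
    """

    partition_id: int
    offset_x: float
    offset_y: float
    offset_t: float
    width_km: float = 500.0
    height_km: float = 500.0
    depth_days: float = 40.0
    extent: Extent | None = None


@dataclass
class GbmParams:
    """Boosted-tree base-learner settings (gbm-style naming).

    Defaults are the production configuration: 1000 trees, bag fraction
    0.95, interaction depth 3; the learning rate is not part of that
    recipe and defaults to 0.1.  Reduced-tree configurations are used for
    fast test runs.
    """

    n_trees: int = 1000
    learning_rate: float = 0.1
    bag_fraction: float = 0.95
    interaction_depth: int = 3


class _ConstantModel:
    """Degenerate base model for single-class stixels."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.p)


class _GbmModel:
    def __init__(self, clf: GradientBoostingClassifier):
        self.clf = clf

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(X)[:, 1]


@dataclass
class BaseModel:
    partition_id: int
    index: tuple[int, int, int]
    model: object  # exposes predict_proba_pos
    n_training_lists: int


@dataclass
class StemEnsemble:
    species_id: str
    world: WorldGrid
    partitions: list[StixelPartition]
    models: dict[tuple[int, int, int, int], BaseModel]  # key (pid, ix, iy, it)
    feature_names: list[str] = field(default_factory=lambda: list(STEM_FEATURES))
    floor: float = 0.01
    n_skipped_stixels: int = 0

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)


def build_partitions(
    extent: Extent,
    width_km: float = 500.0,
    height_km: float | None = None,
    depth_days: float = 40.0,
    n_partitions: int = 10,
    seed: int = 0,
) -> list[StixelPartition]:
    """Draw ``n_partitions`` independent uniformly offset stixel tilings."""
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    if width_km <= 0 or depth_days <= 0:
        raise ValueError("stixel dimensions must be positive")
    height_km = width_km if height_km is None else height_km
    rng = np.random.default_rng(seed)
    parts = []
    for pid in range(n_partitions):
        parts.append(
            StixelPartition(
                partition_id=pid,
                offset_x=float(rng.uniform(0, width_km)),
                offset_y=float(rng.uniform(0, height_km)),
                offset_t=float(rng.uniform(0, depth_days)),
                width_km=width_km,
                height_km=height_km,
                depth_days=depth_days,
                extent=extent,
            )
        )
    return parts


def assign_stixel(
    partition: StixelPartition,
    x_km: np.ndarray | float,
    y_km: np.ndarray | float,
    day_of_year: np.ndarray | float,
) -> np.ndarray:
    """Stixel index triples (ix, iy, it) for points; shape (n, 3).

    Index convention: ``floor((coord - offset) / width)`` per dimension;
    the temporal axis is linear over day-of-year (no wrap at new year).
    Scalar inputs give a shape-(3,) result.
    """
    scalar = np.isscalar(x_km) and np.isscalar(y_km) and np.isscalar(day_of_year)
    x = np.atleast_1d(np.asarray(x_km, dtype=float))
    y = np.atleast_1d(np.asarray(y_km, dtype=float))
    t = np.atleast_1d(np.asarray(day_of_year, dtype=float))
    if partition.extent is not None:
        e = partition.extent
        pad = 1e-9
        ok = (
            (x >= e.xmin - pad) & (x <= e.xmax + pad)
            & (y >= e.ymin - pad) & (y <= e.ymax + pad)
            & (t >= e.day_min - pad) & (t <= e.day_max + pad)
        )
        if not ok.all():
            bad = np.argmax(~ok)
            raise ValueError(
                f"point ({x[bad]}, {y[bad]}, day {t[bad]}) lies outside the extent"
            )
    ix = np.floor((x - partition.offset_x) / partition.width_km).astype(int)
    iy = np.floor((y - partition.offset_y) / partition.height_km).astype(int)
    it = np.floor((t - 1 - partition.offset_t) / partition.depth_days).astype(int)
    out = np.column_stack([ix, iy, it])
    return out[0] if scalar else out


def _design_matrix(lists: pd.DataFrame, world: WorldGrid, year: int = 2018) -> pd.DataFrame:
    cov = world.cells[["cell_id", "x_km", "y_km", "elevation", *HABITAT_CLASSES, *CLIMATE_COVARIATES]]
    m = lists.merge(cov, on="cell_id", how="left")
    if "year" not in m.columns:
        m["year"] = pd.to_datetime(m["date"]).dt.year if "date" in m.columns else year
    m["is_complete"] = (m["type"] == "complete").astype(float)
    return m


def fit_base_models(
    lists: pd.DataFrame,
    world: WorldGrid,
    partitions: list[StixelPartition],
    species_id: str,
    min_lists: int = 30,
    gbm: GbmParams | None = None,
    seed: int = 0,
    floor: float = 0.01,
) -> StemEnsemble:
    """Fit one boosted-tree base model per sufficiently populated stixel.

    ``lists`` is the merged complete + pseudo-complete stream carrying a
    ``sp_<species_id>`` presence column.  Stixels with fewer than
    ``min_lists`` training lists are skipped; stixels whose lists are all
    one class get a constant-probability base model.
    """
    gbm = gbm or GbmParams()
    sp_col = species_column(species_id)
    if sp_col not in lists.columns:
        raise KeyError(f"lists lack a presence column {sp_col!r}")

    m = _design_matrix(lists, world)
    X_all = m[STEM_FEATURES].to_numpy(dtype=float)
    y_all = m[sp_col].to_numpy(dtype=int)
    x = m["x_km"].to_numpy()
    yy = m["y_km"].to_numpy()
    t = m["day_of_year"].to_numpy()

    models: dict[tuple[int, int, int, int], BaseModel] = {}
    n_skipped = 0
    for part in partitions:
        idx = assign_stixel(part, x, yy, t)
        keys = pd.DataFrame(idx, columns=["ix", "iy", "it"])
        for (ix, iy, it), grp in keys.groupby(["ix", "iy", "it"]).groups.items():
            rows = np.asarray(grp)
            if len(rows) < min_lists:
                n_skipped += 1
                continue
            ys = y_all[rows]
            if ys.min() == ys.max():
                model: object = _ConstantModel(float(ys[0]))
            else:
                clf = GradientBoostingClassifier(
                    n_estimators=gbm.n_trees,
                    learning_rate=gbm.learning_rate,
                    subsample=gbm.bag_fraction,
                    max_depth=gbm.interaction_depth,
                    random_state=seed + 104729 * part.partition_id + 7919 * (ix % 97)
                    + 911 * (iy % 89) + (it % 83),
                )
                clf.fit(X_all[rows], ys)
                model = _GbmModel(clf)
            key = (part.partition_id, int(ix), int(iy), int(it))
            models[key] = BaseModel(part.partition_id, (int(ix), int(iy), int(it)), model, len(rows))

    if not models:
        raise RuntimeError("no stixel met the minimum-data requirement; nothing to fit")
    return StemEnsemble(
        species_id=species_id,
        world=world,
        partitions=partitions,
        models=models,
        floor=floor,
        n_skipped_stixels=n_skipped,
    )


def _ensemble_raw(
    ensemble: StemEnsemble, X: np.ndarray, x: np.ndarray, y: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point mean / sample variance / support over covering base models."""
    n = len(X)
    sums = np.zeros(n)
    sumsq = np.zeros(n)
    support = np.zeros(n, dtype=int)
    for part in ensemble.partitions:
        idx = assign_stixel(part, x, y, t)
        keys = pd.DataFrame(idx, columns=["ix", "iy", "it"])
        for (ix, iy, it), grp in keys.groupby(["ix", "iy", "it"]).groups.items():
            bm = ensemble.models.get((part.partition_id, int(ix), int(iy), int(it)))
            if bm is None:
                continue
            rows = np.asarray(grp)
            p = bm.model.predict_proba_pos(X[rows])
            sums[rows] += p
            sumsq[rows] += p**2
            support[rows] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(support > 0, sums / np.maximum(support, 1), np.nan)
        var = np.where(
            support > 1,
            (sumsq - support * mean**2) / np.maximum(support - 1, 1),
            np.where(support == 1, 0.0, np.nan),
        )
    return mean, np.maximum(var, 0.0), support


#: Standardised prediction conditions: an average complete list.
REFERENCE = {"list_length": 25.0, "year": 2018.0, "is_complete": 1.0}


def mid_week_day(week: int) -> int:
    """Representative day of a 7-day week (week 1 = Jan 1-7): its 4th day.

    Week 53 is a 2-day stub (days 365-366); its representative day is
    clamped to 366.
    """
    if not 1 <= week <= 53:
        raise ValueError(f"week must be in 1..53, got {week}")
    return min((week - 1) * 7 + 4, 366)


def week_of_day(day_of_year: int) -> int:
    return min((int(day_of_year) - 1) // 7 + 1, 53)


def predict_occurrence(
    ensemble: StemEnsemble,
    week: int,
    cells: np.ndarray | None = None,
    reference: dict | None = None,
) -> pd.DataFrame:
    """Weekly occurrence surface under standardised effort conditions.

    Evaluates every covering base model at the mid-week day with the
    reference covariates (list total 25, year 2018, complete list),
    averages, takes the between-model sample variance and the support
    count, then floors averaged probabilities below ``ensemble.floor`` to
    zero.  Cells with support 0 are returned with ``missing=True`` and NaN
    probability.
    """
    ref = dict(REFERENCE)
    if reference:
        ref.update(reference)
    world = ensemble.world
    if cells is None:
        cells = world.cells["cell_id"].to_numpy()
    cells = np.asarray(cells)
    day = mid_week_day(week)

    cov = world.cells.set_index("cell_id").loc[cells]
    frame = pd.DataFrame(
        {
            "x_km": cov["x_km"].to_numpy(),
            "y_km": cov["y_km"].to_numpy(),
            "year": ref["year"],
            "day_of_year": float(day),
            "list_length": ref["list_length"],
            "is_complete": ref["is_complete"],
            "elevation": cov["elevation"].to_numpy(),
        }
    )
    for h in (*HABITAT_CLASSES, *CLIMATE_COVARIATES):
        frame[h] = cov[h].to_numpy()
    X = frame[STEM_FEATURES].to_numpy(dtype=float)

    mean, var, support = _ensemble_raw(
        ensemble, X, frame["x_km"].to_numpy(), frame["y_km"].to_numpy(),
        np.full(len(cells), float(day)),
    )
    p = mean.copy()
    floored = (support > 0) & (p < ensemble.floor)
    p[floored] = 0.0
    return pd.DataFrame(
        {
            "cell_id": cells,
            "week": week,
            "species_id": ensemble.species_id,
            "p_occ": p,
            "variance": var,
            "support": support,
            "missing": support == 0,
        }
    )


def predict_for_checklists(ensemble: StemEnsemble, lists: pd.DataFrame) -> pd.DataFrame:
    """Ensemble probabilities at observed checklists (their own covariates)."""
    m = _design_matrix(lists, ensemble.world)
    X = m[STEM_FEATURES].to_numpy(dtype=float)
    mean, var, support = _ensemble_raw(
        ensemble, X, m["x_km"].to_numpy(), m["y_km"].to_numpy(),
        m["day_of_year"].to_numpy(dtype=float),
    )
    out = lists.copy()
    out["p_occ"] = mean
    out["variance"] = var
    out["support"] = support
    return out


# ---------------------------------------------------------------------------
# Environmental blocking & cross-validation
# ---------------------------------------------------------------------------


def environmental_blocks(
    checklists: pd.DataFrame, world: WorldGrid, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Assign each checklist to one of ``k`` environmental blocks.

    Blocks are k-means clusters of the standardised cell covariates, so
    training and test folds occupy distinct regions of environmental space
    (a stricter test of transferability than random folds).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cov_cols = world.covariate_columns()
    cell_cov = world.cells[["cell_id", *cov_cols]]
    profiles = cell_cov[cov_cols].to_numpy(dtype=float)
    n_distinct = len(np.unique(profiles, axis=0))
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct covariate profiles; cannot build {k} blocks"
        )
    mu = profiles.mean(axis=0)
    sd = profiles.std(axis=0)
    sd[sd == 0] = 1.0
    z = (profiles - mu) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    cell_fold = km.fit_predict(z)
    fold_of_cell = pd.Series(cell_fold, index=cell_cov["cell_id"].to_numpy())
    folds = fold_of_cell.loc[checklists["cell_id"].to_numpy()].to_numpy()
    return folds


def cross_validate(
    lists: pd.DataFrame,
    world: WorldGrid,
    partitions: list[StixelPartition],
    species_id: str,
    k: int = 5,
    seed: int = 0,
    min_lists: int = 30,
    gbm: GbmParams | None = None,
    floor: float = 0.01,
) -> dict:
    """k-fold environmental-block cross-validation of the STEM ensemble.

    Per fold: fit on the other blocks, score held-out detections /
    non-detections with AUC.  Folds whose test data contain a single class
    yield an undefined AUC and are excluded from the mean (with a warning).
    Returns ``{"fold_auc": [...], "mean_auc": float, "n_test": [...]}``.
    """
    sp_col = species_column(species_id)
    folds = environmental_blocks(lists, world, k=k, seed=seed)
    fold_auc: list[float] = []
    n_test: list[int] = []
    for f in range(k):
        test = lists[folds == f]
        train = lists[folds != f]
        labels = test[sp_col].to_numpy(dtype=int)
        if len(test) == 0 or labels.min() == labels.max():
            warnings.warn(f"fold {f}: single-class test data; AUC undefined", stacklevel=2)
            fold_auc.append(float("nan"))
            n_test.append(len(test))
            continue
        ens = fit_base_models(
            train, world, partitions, species_id,
            min_lists=min_lists, gbm=gbm, seed=seed, floor=floor,
        )
        pred = predict_for_checklists(ens, test)
        ok = pred["support"].to_numpy() > 0
        if labels[ok].min() == labels[ok].max():
            warnings.warn(f"fold {f}: single-class covered test data", stacklevel=2)
            fold_auc.append(float("nan"))
            n_test.append(int(ok.sum()))
            continue
        fold_auc.append(float(roc_auc_score(labels[ok], pred["p_occ"].to_numpy()[ok])))
        n_test.append(int(ok.sum()))
    defined = [a for a in fold_auc if np.isfinite(a)]
    return {
        "fold_auc": fold_auc,
        "mean_auc": float(np.mean(defined)) if defined else float("nan"),
        "n_test": n_test,
    }
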