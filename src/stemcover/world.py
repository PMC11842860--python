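"""Synthetic study-area grid: covariates, protected layer, species occupancy, effort.

The analysis operates on an equal-area 10-km grid (EPSG:3035-like), so the
synthetic world uses abstract planar km coordinates on a rectangular grid.
Cell (0, 0) sits at the south-west corner; cell centres are at
``(i + 0.5) * cell_size_km``; ``cell_id = iy * n_x + ix`` (0-based, row-major
from the south-west).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

#: Copernicus-derived land-cover classes used as habitat fractions.
HABITAT_CLASSES = (
    "crops",
    "grass",
    "bare",
    "seasonal_water",
    "trees",
    "shrubs",
    "urban",
    "permanent_water",
    "moss_lichen",
)

#: Continuous (non-fraction) covariates carried by the world grid.
CLIMATE_COVARIATES = ("temperature", "rainfall")

DAYS_PER_YEAR = 366


@dataclass
class WorldGrid:
    """Rectangular study-area grid with per-cell environmental covariates.

    ``cells`` holds one row per cell: ``cell_id``, ``x_km``, ``y_km``,
    one column per habitat class (fractions in [0, 1] summing to <= 1),
    ``elevation`` (m) and climate covariates.
    """

    cells: pd.DataFrame
    n_x: int
    n_y: int
    cell_size_km: float = 10.0

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def extent_km(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid in km."""
        return (0.0, 0.0, self.n_x * self.cell_size_km, self.n_y * self.cell_size_km)

    def covariate_columns(self) -> list[str]:
        return ["elevation", *HABITAT_CLASSES, *CLIMATE_COVARIATES]

    def cell_xy(self, cell_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinates (km) for an array of cell ids."""
        cell_id = np.asarray(cell_id)
        ix = cell_id % self.n_x
        iy = cell_id // self.n_x
        return (ix + 0.5) * self.cell_size_km, (iy + 0.5) * self.cell_size_km


@dataclass
class TrueOccupancy:
    """Ground-truth occupancy surface for one simulated species.

    ``occupancy[day - 1, cell_id]`` is the probability that the species
    occupies the cell on that day of year.  Zero outside the species'
    presence period; ground truth for parameter-recovery tests only.
    """

    species_id: str
    occupancy: np.ndarray  # (n_days, n_cells)
    arrival_day: int
    departure_day: int

    @property
    def n_days(self) -> int:
        return self.occupancy.shape[0]

    def weekly_mean(self) -> np.ndarray:
        """Mean daily occupancy per ISO-style week (week 1 = Jan 1-7).

        Returns an array of shape (53, n_cells).
        """
        out = np.zeros((53, self.occupancy.shape[1]))
        for w in range(53):
            days = np.arange(w * 7, min((w + 1) * 7, self.n_days))
            if len(days):
                out[w] = self.occupancy[days].mean(axis=0)
        return out


@dataclass
class EffortConfig:
    """Observer-effort parameters for the checklist simulator.

    events_per_cell_day
        Expected number of sampling events per cell per day (Poisson rate).
    p_complete
        Probability that an event is a complete list (vs casual recording).
    base_richness, richness_trees_effect
        Background (non-focal) species richness on complete lists is
        1 + Poisson(base_richness + richness_trees_effect * trees_fraction):
        richer communities in wooded cells, which gives the list-length
        model a recoverable signal.
    casual_rate
        Mean observer x species combination total for a casual cell-day.
    detectability
        Per-species probability that an occupying bird makes it onto a
        complete list, in (0, 1].
    casual_report_rate
        Extra thinning applied to casual detections (casual observers
        record an unknown subset of what they see).
    habitat_bias
        Mapping habitat class -> log-weight applied to observer placement
        (e.g. ``{"urban": 1.0}`` oversamples towns, as citizen-science
        effort does).
    """

    events_per_cell_day: float = 0.035
    p_complete: float = 0.6
    base_richness: float = 8.0
    richness_trees_effect: float = 10.0
    casual_rate: float = 15.0
    detectability: float = 0.8
    casual_report_rate: float = 0.8
    habitat_bias: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.events_per_cell_day < 0 or self.casual_rate < 0:
            raise ValueError("effort rates must be >= 0")
        if not (0.0 < self.detectability <= 1.0):
            raise ValueError("detectability must lie in (0, 1]")
        if not (0.0 <= self.p_complete <= 1.0):
            raise ValueError("p_complete must lie in [0, 1]")


def _smooth_field(rng: np.random.Generator, n_x: int, n_y: int, sigma: float = 3.0) -> np.ndarray:
    """Spatially autocorrelated standard-normal-ish field, flattened row-major."""
    raw = rng.standard_normal((n_y, n_x))
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="nearest")
    sd = sm.std()
    if sd > 0:
        sm = (sm - sm.mean()) / sd
    return sm.ravel()


def make_world(n_x: int, n_y: int, cell_size_km: float = 10.0, seed: int = 0) -> WorldGrid:
    """Generate a rectangular world grid with autocorrelated covariates.

    Habitat fractions are built from smoothed noise fields pushed through a
    softmax-style normalisation so that each cell's nine fractions sum to
    <= 1 (the remainder is unclassified cover).  Elevation and climate are
    independent smooth fields; temperature falls with elevation and with
    northing, as it does over Europe.
    """
    if n_x < 2 or n_y < 2:
        raise ValueError(f"grid dimensions must be >= 2, got ({n_x}, {n_y})")
    if cell_size_km <= 0:
        raise ValueError("cell_size_km must be positive")

    rng = np.random.default_rng(seed)
    n = n_x * n_y
    cell_id = np.arange(n)
    ix = cell_id % n_x
    iy = cell_id // n_x
    x_km = (ix + 0.5) * cell_size_km
    y_km = (iy + 0.5) * cell_size_km

    elevation = np.maximum(0.0, 400.0 + 350.0 * _smooth_field(rng, n_x, n_y) + 0.02 * y_km)

    # Habitat mixture: one smooth propensity field per class, softmax-scaled,
    # then shrunk by a per-cell "classified" share < 1.
    logits = np.column_stack(
        [_smooth_field(rng, n_x, n_y, sigma=2.5) for _ in HABITAT_CLASSES]
    )
    # Mild class prevalence differences: crops/grass/trees dominate real landscapes.
    prevalence = np.log(
        np.array([3.0, 2.5, 0.6, 0.2, 3.0, 1.0, 0.8, 0.3, 0.15])
    )
    expl = np.exp(1.5 * logits + prevalence)
    shares = expl / expl.sum(axis=1, keepdims=True)
    classified = 0.85 + 0.1 * (1.0 / (1.0 + np.exp(-_smooth_field(rng, n_x, n_y))))
    fractions = shares * classified[:, None]

    norm_y = y_km / y_km.max()
    temperature = (
        14.0 - 6.0 * norm_y - 0.004 * elevation + 1.0 * _smooth_field(rng, n_x, n_y)
    )
    rainfall = np.maximum(
        0.0, 700.0 + 200.0 * _smooth_field(rng, n_x, n_y) + 0.3 * elevation
    )

    cells = pd.DataFrame({"cell_id": cell_id, "x_km": x_km, "y_km": y_km})
    for j, h in enumerate(HABITAT_CLASSES):
        cells[h] = fractions[:, j]
    cells["elevation"] = elevation
    cells["temperature"] = temperature
    cells["rainfall"] = rainfall
    return WorldGrid(cells=cells, n_x=n_x, n_y=n_y, cell_size_km=float(cell_size_km))


# ---------------------------------------------------------------------------
# Protected layer
# ---------------------------------------------------------------------------

CATEGORY_GROUPS = ("I-IV", "V-VI", "undesignated")
_GROUP_COLUMNS = {
    "I-IV": "fraction_I_IV",
    "V-VI": "fraction_V_VI",
    "undesignated": "fraction_undesignated",
}


def make_protected_layer(
    world: WorldGrid,
    total_fraction: float,
    category_mix: dict[str, float] | None = None,
    farmland_bias: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell protected fractions split by IUCN category group.

    ``total_fraction`` is the area-weighted mean protected share of the
    study area.  ``farmland_bias`` shifts protection propensity by
    ``farmland_bias * crops_fraction`` on the logit scale: negative values
    emulate the documented tendency of protected areas to avoid land that
    is suitable for agriculture.

    Returns a frame with columns ``cell_id``, ``fraction_I_IV``,
    ``fraction_V_VI``, ``fraction_undesignated``; the three group fractions
    are disjoint shares of the cell and sum to the cell's total protected
    fraction.
    """
    if not (0.0 <= total_fraction <= 1.0):
        raise ValueError("total_fraction must lie in [0, 1]")
    if category_mix is None:
        # Study-area split among protected land: 28.5 / 20.5 / 51.1 %.
        category_mix = {"I-IV": 0.285, "V-VI": 0.205, "undesignated": 0.51}
    mix = np.array([category_mix.get(g, 0.0) for g in CATEGORY_GROUPS], dtype=float)
    if abs(mix.sum() - 1.0) > 1e-6:
        raise ValueError("category_mix must sum to 1")

    rng = np.random.default_rng(seed)
    n = world.n_cells
    out = pd.DataFrame({"cell_id": world.cells["cell_id"].to_numpy()})
    if total_fraction == 0.0:
        for col in _GROUP_COLUMNS.values():
            out[col] = 0.0
        out["fraction_total"] = 0.0
        return out

    propensity = (
        _smooth_field(rng, world.n_x, world.n_y, sigma=2.0)
        + farmland_bias * world.cells["crops"].to_numpy()
    )
    base = 1.0 / (1.0 + np.exp(-propensity))

    # Monotone power transform of the propensity; solve the exponent by
    # bisection so the area-weighted mean hits total_fraction.
    def mean_at(gamma: float) -> float:
        return float(np.mean(base**gamma))

    lo, hi = 1e-6, 60.0
    if mean_at(lo) < total_fraction:
        fractions = np.full(n, total_fraction)
    else:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mean_at(mid) > total_fraction:
                lo = mid
            else:
                hi = mid
        fractions = base ** (0.5 * (lo + hi))

    # Split each cell's protection among the category groups with mild
    # spatial structure (distinct smooth fields -> softmax weights).
    glogits = np.column_stack(
        [_smooth_field(rng, world.n_x, world.n_y, sigma=2.0) for _ in CATEGORY_GROUPS]
    )
    gw = np.exp(glogits + np.log(np.maximum(mix, 1e-12)))
    gw /= gw.sum(axis=1, keepdims=True)
    for j, g in enumerate(CATEGORY_GROUPS):
        out[_GROUP_COLUMNS[g]] = fractions * gw[:, j]
    out["fraction_total"] = fractions
    return out


# ---------------------------------------------------------------------------
# Species occupancy
# ---------------------------------------------------------------------------


@dataclass
class Phenology:
    """Seasonal timing and movement of a simulated trans-Saharan migrant.

    Days are day-of-year.  The occupancy centroid enters from the south at
    ``arrival_day``, travels north to the breeding latitude by
    ``breeding_start``, holds through ``breeding_end``, and returns south by
    ``departure_day`` — the double-passage pattern whose weekly surfaces the
    occurrence model has to track.
    """

    arrival_day: int = 75
    breeding_start: int = 135
    breeding_end: int = 225
    departure_day: int = 290
    breeding_lat_frac: float = 0.75  # breeding centroid as a fraction of grid height
    spread_km: float = 160.0  # latitudinal s.d. of the occupancy band
    peak_occupancy: float = 0.9

    def __post_init__(self) -> None:
        if not (self.arrival_day < self.breeding_start <= self.breeding_end < self.departure_day):
            raise ValueError("phenology days must satisfy arrival < breeding <= departure")


def _centroid_y(ph: Phenology, day: np.ndarray, height_km: float) -> np.ndarray:
    """Latitudinal centroid (km) of the occupancy band per day."""
    breed_y = ph.breeding_lat_frac * height_km
    entry_y = 0.1 * height_km
    day = np.asarray(day, dtype=float)
    up = np.clip((day - ph.arrival_day) / (ph.breeding_start - ph.arrival_day), 0, 1)
    down = np.clip((day - ph.breeding_end) / (ph.departure_day - ph.breeding_end), 0, 1)
    return entry_y + (breed_y - entry_y) * up - (breed_y - entry_y) * down


def _season_amplitude(ph: Phenology, day: np.ndarray) -> np.ndarray:
    """Seasonal amplitude: 0 -> passage level -> breeding peak -> 0.

    During passage only part of the population is inside the study area at
    once (the rest is strung out along the flyway), so occupancy peaks on
    the breeding grounds: passage amplitude is ``peak / (1 + boost)`` and
    the full peak is reached between breeding_start and breeding_end.
    """
    day = np.asarray(day, dtype=float)
    ramp = 20.0
    boost = 0.6
    rise = np.clip((day - ph.arrival_day) / ramp, 0, 1)
    fall = np.clip((ph.departure_day - day) / ramp, 0, 1)
    base = np.minimum(rise, fall)
    b_up = np.clip((day - ph.breeding_start) / 15.0, 0, 1)
    b_down = np.clip((ph.breeding_end + 15.0 - day) / 15.0, 0, 1)
    breeding = np.minimum(b_up, b_down)
    amp = ph.peak_occupancy / (1.0 + boost) * base * (1.0 + boost * breeding)
    amp[(day < ph.arrival_day) | (day > ph.departure_day)] = 0.0
    return amp


def simulate_species(
    world: WorldGrid,
    phenology: Phenology | None = None,
    covariate_effects: dict[str, float] | None = None,
    species_id: str = "SP1",
    seed: int = 0,
    n_days: int = DAYS_PER_YEAR,
) -> TrueOccupancy:
    """Daily true-occupancy surface for one migrating species.

    Occupancy(day, cell) = seasonal amplitude x latitudinal band around the
    moving centroid x logistic habitat suitability from
    ``covariate_effects`` (coefficients on world covariate columns,
    centred).  All values lie in [0, 1]; zero before arrival and after
    departure.
    """
    ph = phenology or Phenology()
    effects = covariate_effects if covariate_effects is not None else {"trees": 8.0, "crops": -4.0}
    if ph.arrival_day >= ph.departure_day:
        raise ValueError("arrival day must precede departure day")

    _, height = world.n_x * world.cell_size_km, world.n_y * world.cell_size_km
    y = world.cells["y_km"].to_numpy()

    lin = np.zeros(world.n_cells)
    for cov, beta in effects.items():
        vals = world.cells[cov].to_numpy(dtype=float)
        lin += beta * (vals - vals.mean())
    suitability = 1.0 / (1.0 + np.exp(-lin))

    days = np.arange(1, n_days + 1)
    amp = _season_amplitude(ph, days)  # (n_days,)
    cy = _centroid_y(ph, days, height)  # (n_days,)
    band = np.exp(-0.5 * ((y[None, :] - cy[:, None]) / ph.spread_km) ** 2)
    occ = amp[:, None] * band * suitability[None, :]
    return TrueOccupancy(
        species_id=species_id,
        occupancy=np.clip(occ, 0.0, 1.0),
        arrival_day=ph.arrival_day,
        departure_day=ph.departure_day,
    )


# ---------------------------------------------------------------------------
# Effort / checklist simulation
# ---------------------------------------------------------------------------

CHECKLIST_BASE_COLUMNS = ["cell_id", "date", "day_of_year", "type", "list_length", "record_total"]


def species_column(species_id: str) -> str:
    return f"sp_{species_id}"


def simulate_effort(
    world: WorldGrid,
    occupancies: list[TrueOccupancy],
    cfg: EffortConfig | None = None,
    dates: tuple[int, int] = (1, DAYS_PER_YEAR),
    year: int = 2018,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a year of checklist submissions over the world grid.

    Returns a checklist frame with one row per complete list and one row
    per casual cell-day (carrying the observer x species combination
    total).  Complete rows have ``list_length`` = focal presences +
    background richness; casual rows have ``record_total`` and the species
    flags mark which focal species were casually reported.
    """
    cfg = cfg or EffortConfig()
    d0, d1 = dates
    if d1 < d0:
        raise ValueError("empty date range")
    for occ in occupancies:
        if d1 > occ.n_days:
            raise ValueError("dates extend beyond the simulated occupancy period")

    rng = np.random.default_rng(seed)
    n = world.n_cells

    bias = np.zeros(n)
    for h, w in cfg.habitat_bias.items():
        bias += w * world.cells[h].to_numpy()
    weights = np.exp(bias)
    weights *= n / weights.sum()  # mean weight 1 keeps the global rate interpretable

    trees = world.cells["trees"].to_numpy()
    richness_mu = np.maximum(0.1, cfg.base_richness + cfg.richness_trees_effect * trees)

    days = np.arange(d0, d1 + 1)
    n_events = rng.poisson(cfg.events_per_cell_day * weights[None, :], size=(len(days), n))
    day_idx, cell_idx = np.nonzero(n_events)
    counts = n_events[day_idx, cell_idx]

    rows: dict[str, list] = {c: [] for c in CHECKLIST_BASE_COLUMNS}
    sp_cols = [species_column(o.species_id) for o in occupancies]
    for c in sp_cols:
        rows[c] = []

    start = pd.Timestamp(year=year, month=1, day=1)
    for d_i, c_i, k in zip(day_idx, cell_idx, counts):
        day = days[d_i]
        date_str = (start + pd.Timedelta(days=int(day) - 1)).date().isoformat()
        n_complete = rng.binomial(int(k), cfg.p_complete)
        n_casual_events = int(k) - n_complete
        for _ in range(n_complete):
            pres = []
            for occ in occupancies:
                p = occ.occupancy[day - 1, c_i] * cfg.detectability
                pres.append(int(rng.random() < p))
            background = 1 + rng.poisson(richness_mu[c_i])
            rows["cell_id"].append(int(c_i))
            rows["date"].append(date_str)
            rows["day_of_year"].append(int(day))
            rows["type"].append("complete")
            rows["list_length"].append(int(background + sum(pres)))
            rows["record_total"].append(np.nan)
            for col, v in zip(sp_cols, pres):
                rows[col].append(v)
        if n_casual_events > 0:
            total = 0
            pres = [0] * len(occupancies)
            for _ in range(n_casual_events):
                total += 1 + rng.poisson(cfg.casual_rate)
                for j, occ in enumerate(occupancies):
                    p = occ.occupancy[day - 1, c_i] * cfg.detectability * cfg.casual_report_rate
                    if rng.random() < p:
                        pres[j] = 1
            rows["cell_id"].append(int(c_i))
            rows["date"].append(date_str)
            rows["day_of_year"].append(int(day))
            rows["type"].append("casual")
            rows["list_length"].append(np.nan)
            rows["record_total"].append(int(total))
            for col, v in zip(sp_cols, pres):
                rows[col].append(v)

    return pd.DataFrame(rows)


def habitat_representation(checklists: pd.DataFrame, world: WorldGrid) -> pd.DataFrame:
    """Observed vs expected effort share per habitat class.

    For each habitat class, the ratio of the effort-weighted mean habitat
    fraction (over sampling events) to the area-weighted mean fraction
    (over all cells).  Ratio 1 means effort samples the habitat in
    proportion to its availability; the citizen-science literature reports
    urban over- and forest under-representation.
    """
    if len(checklists) == 0:
        raise ValueError("need at least one checklist")
    merged = checklists.merge(
        world.cells[["cell_id", *HABITAT_CLASSES]], on="cell_id", how="left"
    )
    out = []
    for h in HABITAT_CLASSES:
        expected = float(world.cells[h].mean())
        observed = float(merged[h].mean())
        if expected <= 0:
            out.append({"habitat": h, "observed": observed, "expected": expected,
                        "ratio": np.nan, "defined": False})
        else:
            out.append({"habitat": h, "observed": observed, "expected": expected,
                        "ratio": observed / expected, "defined": True})
    return pd.DataFrame(out)
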