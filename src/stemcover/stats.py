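"""Association models linking coverage to season, habitat and population trend.

Three analyses, all on the weekly coverage table and a species-metadata
table:

* a linear mixed model of weekly percent protected on standardised weekly
  range size and season, with a random intercept per species;
* a linear model of per-species mean coverage on broad habitat class
  (farmland / forest / other) with Tukey-adjusted pairwise contrasts;
* a linear regression of long-term population trend — as
  log10((100 + trend%) / 100), so the same geometric change is symmetric
  about zero — on mean coverage and mean range size, optionally adding one
  of habitat, migration distance class or log body mass (at most three
  predictors, given ~28 species).

The model specifications and transformations are the contribution here; the
estimators are standard mixed-model / least-squares machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

HABITAT_LEVELS = ("farmland", "forest", "other")
MIGRATION_LEVELS = ("long", "short")


@dataclass
class ModelFit:
    """Uniform container for fitted-model summaries."""

    kind: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    n: int
    df_resid: float
    random_effect_var: float | None = None
    group_means: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "kind": self.kind,
            "params": self.params,
            "bse": self.bse,
            "pvalues": self.pvalues,
            "n": self.n,
            "df_resid": self.df_resid,
        }
        if self.random_effect_var is not None:
            out["random_effect_var"] = self.random_effect_var
        if self.group_means is not None:
            out["group_means"] = self.group_means.to_dict(orient="records")
        if self.contrasts is not None:
            out["contrasts"] = self.contrasts.to_dict(orient="records")
        out.update(self.extra)
        return out


def trend_to_log_ratio(trend_pct: float | np.ndarray) -> float | np.ndarray:
    """log10((100 + trend%) / 100): 0 for stable, symmetric for doubling/halving."""
    arr = np.asarray(trend_pct, dtype=float)
    if np.any(arr <= -100):
        raise ValueError("trend_pct must exceed -100%")
    out = np.log10((100.0 + arr) / 100.0)
    return float(out) if np.isscalar(trend_pct) else out


def fit_coverage_lmm(weekly: pd.DataFrame) -> ModelFit:
    """Mixed model: weekly % protected ~ z(range) + season + (1 | species).

    Range size enters standardised (z-score); the raw-scale slope
    (``beta_range_raw`` = scaled beta / SD of range) is reported alongside.
    Season is a three-level categorical (spring reference).  Also reports
    per-season means with standard errors.
    """
    d = weekly.copy()
    if d["species_id"].nunique() < 2:
        raise ValueError("need >= 2 species for a random-intercept model")
    if d["season"].nunique() < 2:
        raise ValueError("need >= 2 season levels")
    sd = float(d["range_km2"].std(ddof=0))
    if sd == 0:
        sd = 1.0
    d["z_range"] = (d["range_km2"] - d["range_km2"].mean()) / sd
    d["season"] = pd.Categorical(d["season"], categories=["spring", "breeding", "autumn"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("pct_protected ~ z_range + season", d, groups=d["species_id"])
        res = model.fit(reml=True)

    season_means = (
        d.groupby("season", observed=True)["pct_protected"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_pct", "sem": "se"})
    )
    params = {k: float(v) for k, v in res.params.items()}
    return ModelFit(
        kind="coverage_lmm",
        params=params,
        bse={k: float(v) for k, v in res.bse.items()},
        pvalues={k: float(v) for k, v in res.pvalues.items()},
        n=len(d),
        df_resid=float(res.df_resid),
        random_effect_var=float(res.cov_re.iloc[0, 0]),
        group_means=season_means,
        extra={
            "n_species": int(d["species_id"].nunique()),
            "beta_range_raw": params.get("z_range", 0.0) / sd,
            "range_sd": sd,
        },
    )


def habitat_contrasts(summaries: pd.DataFrame, alpha: float = 0.05) -> ModelFit:
    """Mean coverage ~ habitat, with Tukey HSD pairwise contrasts.

    Habitat levels with fewer than two species are excluded (warned).
    Returns the overall F-test, per-habitat means with SEs, and the Tukey
    table of pairwise mean differences.
    """
    d = summaries.copy()
    counts = d["habitat"].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"excluding habitat levels with < 2 species: {small}", stacklevel=2)
        d = d[~d["habitat"].isin(small)]
    if d["habitat"].nunique() < 2:
        raise ValueError("need >= 2 habitat levels with >= 2 species each")

    res = smf.ols("mean_pct_protected ~ C(habitat)", d).fit()
    means = (
        d.groupby("habitat")["mean_pct_protected"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_pct", "sem": "se"})
    )
    if float(res.model.endog.var()) < 1e-24:
        # Constant response: Tukey is vacuous; report null contrasts.
        pairs = []
        levels = sorted(d["habitat"].unique())
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                pairs.append({"group1": levels[i], "group2": levels[j],
                              "meandiff": 0.0, "p_adj": 1.0, "reject": False})
        tukey_df = pd.DataFrame(pairs)
        f_stat, f_pvalue = 0.0, 1.0
    else:
        tk = pairwise_tukeyhsd(
            d["mean_pct_protected"].to_numpy(), d["habitat"].to_numpy(), alpha=alpha
        )
        levels = list(tk.groupsunique)
        g1, g2 = zip(*[(levels[i], levels[j]) for i, j in zip(*np.triu_indices(len(levels), 1))])
        tukey_df = pd.DataFrame(
            {
                "group1": g1,
                "group2": g2,
                "meandiff": tk.meandiffs,
                "p_adj": tk.pvalues,
                "lower": tk.confint[:, 0],
                "upper": tk.confint[:, 1],
                "reject": tk.reject,
            }
        )
        f_stat, f_pvalue = float(res.fvalue), float(res.f_pvalue)
    return ModelFit(
        kind="habitat_contrasts",
        params={k: float(v) for k, v in res.params.items()},
        bse={k: float(v) for k, v in res.bse.items()},
        pvalues={k: float(v) for k, v in res.pvalues.items()},
        n=len(d),
        df_resid=float(res.df_resid),
        group_means=means,
        contrasts=tukey_df,
        extra={"f_stat": f_stat, "f_pvalue": f_pvalue},
    )


_COVARIATE_COLUMNS = {
    "habitat": "C(habitat)",
    "migration": "C(migration)",
    "body_mass_log": "body_mass_log",
}


def fit_trend_lm(
    summaries: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    exclude_short: bool = False,
    min_n: int = 10,
) -> ModelFit:
    """Trend (log10 ratio) ~ mean coverage + mean range [+ one covariate].

    ``summaries`` needs species_id, mean_pct_protected, mean_range_km2 and
    trend_pct (plus habitat / migration / body_mass_g when requested).
    ``exclude_short=True`` refits without short-distance migrants to check
    that the coverage association is not a migration-distance surrogate.
    At most three predictors beyond the intercept are allowed, given the
    small species sample.
    """
    unknown = set(covariates) - set(_COVARIATE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    if len(covariates) > 1:
        raise ValueError("at most one covariate beyond coverage and range (3 predictors total)")

    d = summaries.dropna(subset=["trend_pct"]).copy()
    if exclude_short:
        d = d[d["migration"] != "short"]
    if len(d) < min_n:
        raise ValueError(f"need >= {min_n} species with trends, got {len(d)}")
    d["trend_log_ratio"] = trend_to_log_ratio(d["trend_pct"].to_numpy())
    if "body_mass_log" in covariates:
        d["body_mass_log"] = np.log(d["body_mass_g"].astype(float))

    terms = ["mean_pct_protected", "mean_range_km2"] + [
        _COVARIATE_COLUMNS[c] for c in covariates
    ]
    formula = "trend_log_ratio ~ " + " + ".join(terms)
    res = smf.ols(formula, d).fit()
    return ModelFit(
        kind="trend_lm",
        params={k: float(v) for k, v in res.params.items()},
        bse={k: float(v) for k, v in res.bse.items()},
        pvalues={k: float(v) for k, v in res.pvalues.items()},
        n=int(res.nobs),
        df_resid=float(res.df_resid),
        extra={
            "r_squared": float(res.rsquared),
            "coverage_slope": float(res.params["mean_pct_protected"]),
            "coverage_se": float(res.bse["mean_pct_protected"]),
            "coverage_p": float(res.pvalues["mean_pct_protected"]),
            "excluded_short": bool(exclude_short),
        },
    )


def build_species_summaries(
    coverage: pd.DataFrame, species_meta: pd.DataFrame
) -> pd.DataFrame:
    """Join per-species coverage means with the metadata table.

    ``species_meta`` columns: species_id, trend_pct, habitat, migration,
    body_mass_g.  Habitat and migration labels are validated against the
    closed vocabularies.
    """
    from .coverage import species_means

    bad_h = set(species_meta["habitat"].dropna()) - set(HABITAT_LEVELS)
    if bad_h:
        raise ValueError(f"unknown habitat labels: {sorted(bad_h)}")
    if "migration" in species_meta:
        bad_m = set(species_meta["migration"].dropna()) - set(MIGRATION_LEVELS)
        if bad_m:
            raise ValueError(f"unknown migration labels: {sorted(bad_m)}")
    return species_means(coverage).merge(species_meta, on="species_id", how="left")
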