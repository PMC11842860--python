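"""Association models on a synthetic coverage table.

Plants known effects — farmland species less covered, population trend
rising with coverage — and shows the three analyses recovering them: the
weekly coverage mixed model, habitat contrasts with Tukey adjustment, and
the trend-vs-coverage regression on log10 trend ratios.
"""

import numpy as np
import pandas as pd

from stemcover import fit_coverage_lmm, fit_trend_lm, habitat_contrasts

rng = np.random.default_rng(0)

# Weekly coverage table: 30 species x 40 weeks, spring 2 points higher.
rows = []
for s in range(30):
    base = 20 + rng.normal(0, 2)
    for week in range(6, 46):
        season = "spring" if week <= 18 else ("breeding" if week <= 31 else "autumn")
        rows.append({
            "species_id": f"S{s}", "week": week, "season": season,
            "range_km2": rng.uniform(5e5, 4e6),
            "pct_protected": base + (2.0 if season == "spring" else 0.0) + rng.normal(0, 1),
        })
weekly = pd.DataFrame(rows)
lmm = fit_coverage_lmm(weekly)
means = lmm.group_means.set_index("season")
print("coverage ~ z(range) + season + (1|species):")
for season in ("spring", "breeding", "autumn"):
    print(f"  {season:8s} mean {means.loc[season, 'mean_pct']:.1f} "
          f"+/- {means.loc[season, 'se']:.2f} %")

# Species summaries: farmland mean 17%, forest/other 22%.
summaries = []
for hab, mu in (("farmland", 17.0), ("forest", 22.0), ("other", 22.0)):
    for i in range(10):
        cov = mu + rng.normal(0, 2)
        lr = 0.005 * cov + rng.normal(0, 0.05)
        summaries.append({
            "species_id": f"{hab}{i}", "habitat": hab,
            "mean_pct_protected": cov, "mean_range_km2": rng.uniform(1e6, 4e6),
            "trend_pct": 100 * (10**lr - 1), "migration": "long",
        })
summaries = pd.DataFrame(summaries)

hc = habitat_contrasts(summaries)
print("\nTukey contrasts of mean coverage by habitat:")
print(hc.contrasts[["group1", "group2", "meandiff", "p_adj"]].round(3).to_string(index=False))

lm = fit_trend_lm(summaries.iloc[:28])
print(f"\ntrend (log10 ratio) ~ coverage + range, n={lm.n}: "
      f"slope {lm.extra['coverage_slope']:.4f} +/- {lm.extra['coverage_se']:.4f} "
      f"(p={lm.extra['coverage_p']:.3g}); planted slope 0.005")
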