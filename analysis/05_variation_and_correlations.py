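#!/usr/bin/env python
"""Clonal variation, its change over time, and trait correlations.

Summarizes each population (microcosm) by clone means and SDs, compares
week-1 vs week-13 clonal SDs per species and trait, fits the random-
intercept repeated-measures approximation for treatment effects on trait
means, and computes the growth-rate vs mortality / yield correlations
among week-13 clones.  Writes population_summaries.csv,
variation_trends.csv, repeated_model_<trait>.csv and correlations.csv
under results/.
"""

from pathlib import Path

import pandas as pd

from serialpulse.errors import SerialPulseError
from serialpulse.stats import (
    fit_repeated_model,
    summarize_populations,
    trait_correlation,
    variation_trend,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
TRAITS = ["max_growth_rate", "yield_od", "proportional_mortality", "biofilm"]


def main() -> None:
    traits = pd.read_csv(ROOT / "traits.csv")
    evolved = traits[traits.week != 0]
    summaries = summarize_populations(evolved, traits=TRAITS)
    summaries.to_csv(ROOT / "population_summaries.csv", index=False)

    print("clonal-variation change, week 1 -> week 13 (population SDs):")
    rows = []
    for species, sp_sum in summaries.groupby("species"):
        for trait in TRAITS:
            try:
                trend = variation_trend(sp_sum, trait)
            except SerialPulseError:
                continue
            rows.append(
                {"species": species, "trait": trait,
                 "mean_sd_week1": trend.mean_sd_early, "se_week1": trend.se_sd_early,
                 "mean_sd_week13": trend.mean_sd_late, "se_week13": trend.se_sd_late,
                 "t": trend.comparison.t, "df": trend.comparison.df,
                 "p": trend.comparison.p}
            )
            marker = " *" if trend.comparison.p < 0.05 else ""
            print(f"  {species:>13} {trait:<24} "
                  f"{trend.mean_sd_early:.4f} +- {trend.se_sd_early:.4f} -> "
                  f"{trend.mean_sd_late:.4f} +- {trend.se_sd_late:.4f} "
                  f"(p={trend.comparison.p:.4f}){marker}")
    pd.DataFrame(rows).to_csv(ROOT / "variation_trends.csv", index=False)

    print("\nrepeated-measures treatment effects on trait means (p < 0.05 terms):")
    for trait in TRAITS:
        for species, sp_sum in summaries.groupby("species"):
            rep = fit_repeated_model(sp_sum, trait)
            rep.table.insert(0, "species", species)
            rep.table.to_csv(ROOT / f"repeated_model_{trait}_{species}.csv", index=False)
            hits = rep.table[(rep.table.p < 0.05) & (rep.table.term != "Intercept")]
            for _, row in hits.iterrows():
                print(f"  {species:>13} {trait:<24} {row['term']:<40} p={row['p']:.4f}")

    print("\nweek-13 clone-level correlations (growth rate vs ...):")
    corr_rows = []
    final = traits[traits.week == 13]
    for species, cell in final.groupby("species"):
        for other in ("proportional_mortality", "yield_od"):
            sub = cell[["max_growth_rate", other]].dropna()
            res = trait_correlation(sub["max_growth_rate"], sub[other])
            corr_rows.append({"species": species, "against": other,
                              "r": res.r, "p": res.p, "n": res.n})
            print(f"  {species:>13} vs {other:<24} r={res.r:+.3f} "
                  f"N={res.n} p={res.p:.3g}")
    pd.DataFrame(corr_rows).to_csv(ROOT / "correlations.csv", index=False)


if __name__ == "__main__":
    main()
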