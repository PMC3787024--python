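#!/usr/bin/env python
"""Ancestor-vs-evolved contrasts with Bonferroni control.

For each species, trait, and treatment cell (pulse x diversity x week),
compares the evolved clones to the 10 ancestral clones with the two-tailed
Welch test and flags significance at the Bonferroni-adjusted threshold
alpha/4 = 0.0125 (four treatment contrasts per trait per time point).
Writes results/ancestor_contrasts.csv and prints the significant rows.
"""

from pathlib import Path

import pandas as pd

from serialpulse.stats import ancestor_vs_evolved, bonferroni

ROOT = Path(__file__).resolve().parents[1] / "results"
TRAITS = ["max_growth_rate", "yield_od", "proportional_mortality", "biofilm"]


def main() -> None:
    traits = pd.read_csv(ROOT / "traits.csv")
    bf = bonferroni(0.05, 4)
    print(f"family alpha 0.05 over 4 contrasts -> per-test threshold "
          f"{bf.alpha_adjusted:.4f} (family-wise error "
          f"{100*bf.fwe_uncorrected:.2f}% -> {100*bf.fwe_corrected:.2f}%)\n")
    rows = []
    for species, sp in traits.groupby("species"):
        anc = sp[sp.week == 0]
        for trait in TRAITS:
            for (pulse, diversity, week), cell in sp[sp.week != 0].groupby(
                ["pulse", "diversity", "week"]
            ):
                res = ancestor_vs_evolved(
                    anc[trait].dropna(),
                    evolved_values=cell[trait].dropna(),
                    alpha_adjusted=bf.alpha_adjusted,
                )
                rows.append(
                    {"species": species, "trait": trait, "pulse": pulse,
                     "diversity": diversity, "week": week,
                     "ancestor_mean": res.mean_a, "evolved_mean": res.mean_b,
                     "t": res.t, "df": res.df, "p": res.p,
                     "significant": res.significant}
                )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "ancestor_contrasts.csv", index=False)
    sig = table[table.significant]
    print(f"{len(sig)} of {len(table)} contrasts significant at p < "
          f"{bf.alpha_adjusted:.4f}:")
    with pd.option_context("display.width", 120):
        print(sig.round({"ancestor_mean": 4, "evolved_mean": 4, "t": 2,
                         "df": 1, "p": 4}).to_string(index=False))


if __name__ == "__main__":
    main()
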