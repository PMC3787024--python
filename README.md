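# serialpulse

Simulation and analysis of serial-transfer evolution experiments under
pulsed resources, with clone-level growth-curve trait extraction and the
statistics used to compare ancestral and evolved bacterial clones.

The package is built around a two-species microcosm system: a copiotroph
(*Serratia marcescens*, Monod parameters r_max = 0.418 h⁻¹,
K_s = 1.72 g L⁻¹) and an oligotroph (*Novosphingobium capsulatum*,
r_max = 0.103 h⁻¹, K_s = 0.29 g L⁻¹) grown alone or together under weekly
resource pulses that renew either 99.9 % (large pulse) or 70 % (small
pulse) of the culture volume.  It provides:

- **`serialpulse.batch`** — Monod batch dynamics
  (μ(R) = r_max·R/(K_s+R); dR/dt = −Σ μᵢNᵢ/Yᵢ; dNᵢ/dt = (μᵢ−dᵢ)Nᵢ),
  the exact weekly transfer operator N → f·N, R → f·R + (1−f)·R_fresh,
  the 13-week serial-transfer loop, and Monod curve fitting.
- **`serialpulse.growth_curves`** — a synthetic-data generator for
  week-long clone OD curves (lag → Monod growth → peak → death phase,
  with partial dead-cell opacity and lognormal reader noise), biofilm
  endpoints, and full factorial experiment datasets with treatment-
  structured clonal variation.
- **`serialpulse.traits`** — the four fitness traits per clone:
  steepest-window maximum growth rate (30 points = 2.5 h at 5-min
  sampling, variance-weighted log-OLS), yield (despiked maximum biomass),
  total and proportional mortality (max − end; (max − end)/max), and the
  crystal-violet biofilm summary.
- **`serialpulse.stats`** — per-population clone means and SDs (clonal
  variation), Welch/Satterthwaite ancestor-vs-evolved contrasts with
  Bonferroni family-wise control (α/4 = 0.0125), clonal-variation trend
  tests, Pearson trait correlations, and a random-intercept
  repeated-measures approximation for treatment effects.
- **`serialpulse.io` / `serialpulse.cli`** — wide/long plate-table
  parsing with fail-fast validation, INI-style run configs, manifests,
  and a `serialpulse` command with `simulate`, `extract`, `analyze` and
  `pipeline` subcommands.

The numbered scripts under `analysis/` chain these stages into the full
study: long-term dynamics, clone assays, trait extraction, ancestor
contrasts, and variation/correlation analyses, writing tables under
`results/`.

## Worked example

```python
import numpy as np
from serialpulse import (
    ANCESTOR_PARAMS, AssayConfig, bonferroni, extract_traits,
    generate_od_curve, monod_rate, S_MARCESCENS,
)

# per-capita growth rate at half saturation is half of r_max
print(monod_rate(1.72, S_MARCESCENS))          # 0.209

# simulate one ancestral copiotroph clone for a week and extract traits
curve = generate_od_curve(ANCESTOR_PARAMS["S_marcescens"], AssayConfig(), seed=1)
traits = extract_traits(curve, biofilm_signal=0.8)
print(round(traits.max_growth_rate, 3))        # 0.167
print(round(traits.yield_od, 3))               # 0.918
print(round(traits.proportional_mortality, 3)) # 0.236

# four contrasts per trait and time point at family alpha 0.05
bf = bonferroni(0.05, 4)
print(bf.alpha_adjusted)                       # 0.0125
print(round(100 * bf.fwe_uncorrected, 2))      # 18.55
print(round(100 * bf.fwe_corrected, 2))        # 4.91
```

The extracted growth rate (0.167 h⁻¹) sits near the Monod rate at the
assay's 1 g L⁻¹ resource loading, μ(1) = 0.418·1/(1.72+1) ≈ 0.154 h⁻¹,
rather than the saturated maximum 0.418 h⁻¹; the proportional mortality 0.236 is
the OD decline after the growth peak, attenuated by the opacity of dead
biomass.  The full pipeline on the default factorial dataset
(`analysis/02`–`05`) reproduces the system's qualitative outcome
structure: evolved copiotroph clones grow slower, die less and make more
biofilm in monoculture, and the clonal spread of oligotroph growth rates
roughly doubles between weeks 1 and 13.

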