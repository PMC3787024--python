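"""Monte-Carlo calibration studies: estimator recovery, test calibration,
power of the clone-level pipeline, and reference integrators.

These are the simulation studies the test suite and the acceptance script
run at different problem sizes; each function is a pure function of its
arguments and seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .batch import (
    BatchState,
    SpeciesParams,
    fit_monod,
    monod_rate,
    simulate_batch,
)
from .growth_curves import (
    ANCESTOR_PARAMS,
    AssayConfig,
    CloneParams,
    TreatmentDesign,
    TreatmentGroup,
    default_clonal_sd_table,
    derive_seed,
    generate_od_curve,
    sample_clone_params,
)
from .stats import ancestor_vs_evolved, summarize_populations, variation_trend
from .traits import extract_traits, max_growth_rate

__all__ = [
    "rk4_reference",
    "monod_fit_roundtrip",
    "growth_rate_recovery",
    "welch_type1_error",
    "mortality_effect_power",
    "variation_trend_power",
]


def rk4_reference(
    state: BatchState,
    species: list[SpeciesParams],
    duration_h: float,
    step_h: float = 0.01,
):
    """Fixed-step classical Runge-Kutta integration of the batch ODE.

    Brute-force reference for the adaptive integrator; returns
    (times, R, N) with N of shape (n_times, n_species).
    """
    r = np.array([sp.r_max for sp in species])
    K = np.array([sp.K_s for sp in species])
    Y = np.array([sp.yield_coeff for sp in species])
    d = np.array([sp.death_rate for sp in species])

    def rhs(y):
        R = max(y[0], 0.0)
        N = np.clip(y[1:], 0.0, None)
        mu = r * R / (K + R)
        return np.concatenate(([-np.sum(mu * N / Y)], (mu - d) * N))

    n_steps = int(np.ceil(duration_h / step_h))
    h = duration_h / n_steps
    y = np.concatenate(([state.R], state.N)).astype(float)
    times = np.empty(n_steps + 1)
    out = np.empty((n_steps + 1, y.size))
    times[0], out[0] = 0.0, y
    for i in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        times[i + 1], out[i + 1] = (i + 1) * h, y
    return times, out[:, 0], out[:, 1:]


def monod_fit_roundtrip(
    species: SpeciesParams,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Fit the Monod curve to rates generated from known parameters.

    Default gradient: 10 concentrations spanning 0.1-1.0 g/L, the range of
    the original hay-extract rate measurements.
    """
    if concentrations is None:
        concentrations = np.linspace(0.1, 1.0, 10)
    concentrations = np.asarray(concentrations, dtype=float)
    rates = monod_rate(concentrations, species)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rates = rates * np.exp(noise_sd * rng.standard_normal(rates.shape))
    return fit_monod(concentrations, rates)


def _fast_growth_params(base: CloneParams) -> CloneParams:
    """Clone params in the resource-saturated regime (K_s << R0)."""
    return dataclasses.replace(base, K_s=0.01)


def growth_rate_recovery(
    n_clones: int,
    noise_sd: float,
    seed: int,
    duration_h: float = 48.0,
    species_id: str = "S_marcescens",
    clonal_sigma: float = 0.15,
) -> np.ndarray:
    """Relative errors of the steepest-window estimator vs true r_max.

    Clones are drawn lognormally around the ancestral r_max with K_s set
    far below the starting resource so the early growth phase is
    exponential at r_max; returns |estimate - true| / true per clone.
    """
    base = _fast_growth_params(ANCESTOR_PARAMS[species_id])
    assay = AssayConfig(duration_h=duration_h, od_noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    errors = np.empty(n_clones)
    for i in range(n_clones):
        z = rng.standard_normal()
        true_r = base.r_max * float(np.exp(clonal_sigma * z - 0.5 * clonal_sigma**2))
        params = dataclasses.replace(base, r_max=true_r)
        curve = generate_od_curve(params, assay, derive_seed(seed, "curve", i))
        est = max_growth_rate(curve).rate
        errors[i] = abs(est - true_r) / true_r
    return errors


def welch_type1_error(
    n_reps: int,
    n1: int = 10,
    n2: int = 9,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the two-sample mode under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.standard_normal(n1)
        y = rng.standard_normal(n2)
        res = ancestor_vs_evolved(x, evolved_values=y, alpha_adjusted=alpha)
        rejections += res.p < alpha
    return rejections / n_reps


def mortality_effect_power(
    n_reps: int,
    seed: int,
    n_clones: int = 10,
    death_rate_ratio: float = 0.5,
    alpha: float = 0.05,
    clonal_sigma: float = 0.08,
    duration_h: float = 168.0,
) -> float:
    """Power of the extract->test pipeline for a death-rate reduction.

    Each replicate simulates an ancestral S. marcescens clone set and an
    evolved set whose mean death rate is scaled by ``death_rate_ratio``,
    extracts proportional mortality from the OD curves, and applies the
    two-sample comparison.  A success is p < alpha with the evolved group
    showing the lower mortality.
    """
    base = ANCESTOR_PARAMS["S_marcescens"]
    evolved_mean = dataclasses.replace(
        base, death_rate=base.death_rate * death_rate_ratio
    )
    assay = AssayConfig(duration_h=duration_h)
    design = TreatmentDesign(
        n_clones=n_clones,
        base_params={"S_marcescens": base, "S_marcescens_evolved": evolved_mean},
        species_set=("S_marcescens", "S_marcescens_evolved"),
        effect_table={
            TreatmentGroup.ancestor("S_marcescens"): {},
            TreatmentGroup.ancestor("S_marcescens_evolved"): {},
        },
        clonal_sd_table={
            TreatmentGroup.ancestor("S_marcescens"): clonal_sigma,
            TreatmentGroup.ancestor("S_marcescens_evolved"): clonal_sigma,
        },
    )
    successes = 0
    for rep in range(n_reps):
        groups = {}
        for label in ("S_marcescens", "S_marcescens_evolved"):
            clones = sample_clone_params(
                design,
                TreatmentGroup.ancestor(label),
                derive_seed(seed, "params", rep, label),
            )
            morts = []
            for ci, cp in enumerate(clones):
                curve = generate_od_curve(
                    cp, assay, derive_seed(seed, "od", rep, label, ci)
                )
                morts.append(extract_traits(curve).proportional_mortality)
            groups[label] = np.asarray(morts)
        res = ancestor_vs_evolved(
            groups["S_marcescens"],
            evolved_values=groups["S_marcescens_evolved"],
            alpha_adjusted=alpha,
        )
        successes += (res.p < alpha) and (res.mean_a > res.mean_b)
    return successes / n_reps


def variation_trend_power(
    n_experiments: int,
    seed: int,
    sigma_ratio: float = 2.0,
    base_sigma: float = 0.30,
    n_clones: int = 10,
    n_replicates: int = 3,
    alpha: float = 0.05,
    duration_h: float = 48.0,
) -> float:
    """Power of the full pipeline to detect a clonal-variation increase.

    Each simulated experiment builds the N. capsulatum arm of the design
    with the week-13 lognormal sigma of the growth rate scaled by
    ``sigma_ratio`` relative to week 1, runs curve generation, trait
    extraction, per-population summaries, and the week-1-vs-week-13 SD
    comparison.  A success is p < alpha with SD increasing.
    """
    species = "N_capsulatum"
    sd_table = default_clonal_sd_table(
        species_set=(species,), growth_sigma={species: base_sigma}
    )
    for grp in list(sd_table):
        entry = dict(sd_table[grp])
        entry["r_max"] = base_sigma * (sigma_ratio if grp.week == 13 else 1.0)
        sd_table[grp] = entry
    design = TreatmentDesign(
        species_set=(species,),
        n_clones=n_clones,
        n_replicates=n_replicates,
        clonal_sd_table=sd_table,
    )
    assay = AssayConfig(duration_h=duration_h)

    successes = 0
    for rep in range(n_experiments):
        rows = []
        for group in design.groups():
            if group.is_ancestor:
                continue
            for r in range(1, design.n_replicates + 1):
                gid = (rep, group.pulse, group.diversity, group.week, r)
                clones = sample_clone_params(
                    design, group, derive_seed(seed, "params", *gid)
                )
                for ci, cp in enumerate(clones):
                    curve = generate_od_curve(
                        cp, assay, derive_seed(seed, "od", *gid, ci)
                    )
                    rate = max_growth_rate(curve).rate
                    rows.append(
                        {
                            "species": species,
                            "pulse": group.pulse,
                            "diversity": group.diversity,
                            "week": group.week,
                            "replicate": r,
                            "max_growth_rate": rate,
                        }
                    )
        import pandas as pd

        traits_table = pd.DataFrame(rows)
        summaries = summarize_populations(traits_table, traits=["max_growth_rate"])
        trend = variation_trend(summaries, "max_growth_rate", alpha=alpha)
        increased = trend.mean_sd_late > trend.mean_sd_early
        successes += (trend.comparison.p < alpha) and increased
    return successes / n_experiments
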