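"""Synthetic clone-level growth assays with the full treatment structure.

Emulates the week-long plate-reader fitness assays of a pulsed-resource
serial-transfer experiment: each clone grows in fresh medium after a lag,
depletes the resource under Monod kinetics, peaks, and then declines at a
constant per-capita death rate.  Observed OD is

    OD(t) = blank + N_live(t) + phi * N_dead(t),

where phi is the fraction of dead biomass that still scatters light
(partial dead-cell opacity keeps OD-based "mortality" distinct from cell
death), optionally multiplied by lognormal plate-reader noise.

Clone-to-clone parameter variation is lognormal and mean-preserving around
treatment-cell means; treatment effects are multiplicative shifts of the
ancestral species parameters.  The default effect table encodes the
qualitative outcome structure of the study system: evolved S. marcescens
clones die more slowly and grow somewhat slower (with extra biofilm in
monoculture), N. capsulatum grows faster after co-evolution with a
competitor, and the clonal spread of its growth rate doubles by week 13.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .batch import BatchState, SpeciesParams, simulate_batch
from .errors import ConfigError, ValidationError
from .traits import ODCurve

__all__ = [
    "CloneParams",
    "AssayConfig",
    "TreatmentGroup",
    "TreatmentDesign",
    "ExperimentDataset",
    "ANCESTOR_PARAMS",
    "default_effect_table",
    "default_clonal_sd_table",
    "default_design",
    "group_mean_params",
    "sample_clone_params",
    "generate_od_curve",
    "generate_biofilm_signal",
    "generate_experiment",
    "derive_seed",
]

_VARIED_FIELDS = ("r_max", "K_s", "yield_coeff", "death_rate", "lag_h", "biofilm_mu")


@dataclass(frozen=True)
class CloneParams:
    """Growth, death and biofilm parameters of a single clone.

    r_max, K_s : Monod parameters (h^-1, g L^-1).
    yield_coeff : OD-equivalent biomass per g L^-1 resource consumed.
    death_rate : per-capita decline rate after resource exhaustion, h^-1.
    lag_h : lag before growth starts, h.
    biofilm_mu : mean crystal-violet endpoint signal, absorbance units.
    inoculum_od : initial OD-equivalent biomass in the assay well.
    """

    species_id: str
    r_max: float
    K_s: float
    yield_coeff: float
    death_rate: float
    lag_h: float
    biofilm_mu: float
    inoculum_od: float

    def __post_init__(self) -> None:
        for name in ("r_max", "K_s", "yield_coeff", "inoculum_od"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("death_rate", "lag_h", "biofilm_mu"):
            if not (getattr(self, name) >= 0):
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_species(self, death_rate: float | None = None) -> SpeciesParams:
        return SpeciesParams(
            r_max=self.r_max,
            K_s=self.K_s,
            yield_coeff=self.yield_coeff,
            death_rate=self.death_rate if death_rate is None else death_rate,
            name=self.species_id,
        )


#: Ancestral clone parameters.  Monod r_max/K_s are the hay-extract
#: estimates; yield, death, lag, biofilm and inoculum are generator choices
#: reproducing the ancestral phenotype ordering (the oligotroph
#: N. capsulatum: higher yield, lower mortality, less biofilm).
ANCESTOR_PARAMS: dict[str, CloneParams] = {
    "S_marcescens": CloneParams(
        species_id="S_marcescens",
        r_max=0.418,
        K_s=1.72,
        yield_coeff=0.9,
        death_rate=0.008,
        lag_h=2.0,
        biofilm_mu=0.8,
        inoculum_od=0.005,
    ),
    "N_capsulatum": CloneParams(
        species_id="N_capsulatum",
        r_max=0.103,
        K_s=0.29,
        yield_coeff=1.1,
        death_rate=0.002,
        lag_h=3.0,
        biofilm_mu=0.3,
        inoculum_od=0.005,
    ),
}


@dataclass(frozen=True)
class AssayConfig:
    """Plate-reader assay setup: one week of OD readings every 5 minutes."""

    duration_h: float = 168.0
    sample_interval_min: float = 5.0
    od_noise_sd: float = 0.01        # multiplicative lognormal sigma
    blank_od: float = 0.05           # additive background OD
    dead_cell_opacity: float = 0.5   # phi: fraction of dead biomass seen as OD
    medium_R: float = 1.0            # fresh-medium resource, g L^-1
    biofilm_noise_sd: float = 0.1    # lognormal sigma of the biofilm endpoint

    def __post_init__(self) -> None:
        if not (self.duration_h > 0 and self.sample_interval_min > 0):
            raise ValidationError("duration_h and sample_interval_min must be > 0")
        if not (0.0 <= self.dead_cell_opacity <= 1.0):
            raise ValidationError(
                f"dead_cell_opacity must be in [0, 1], got {self.dead_cell_opacity}"
            )
        if self.od_noise_sd < 0 or self.biofilm_noise_sd < 0 or self.blank_od < 0:
            raise ValidationError("noise sigmas and blank OD must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.duration_h * 60.0 / self.sample_interval_min)) + 1

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval_min / 60.0


@dataclass(frozen=True)
class TreatmentGroup:
    """One cell of the design: species x pulse x diversity x sampling week.

    week 0 with pulse/diversity "ancestor" denotes the ancestral clone set.
    """

    species: str
    pulse: str       # "large" | "small" | "ancestor"
    diversity: str   # "mono" | "co" | "ancestor"
    week: int        # 0 (ancestor), 1 or 13

    @classmethod
    def ancestor(cls, species: str) -> "TreatmentGroup":
        return cls(species=species, pulse="ancestor", diversity="ancestor", week=0)

    @property
    def is_ancestor(self) -> bool:
        return self.week == 0


def default_effect_table(
    species_set=("S_marcescens", "N_capsulatum"),
    pulses=("large", "small"),
    diversities=("mono", "co"),
    weeks=(1, 13),
) -> dict[TreatmentGroup, dict[str, float]]:
    """Multiplicative treatment shifts of clone-parameter means.

    Encodes the study system's qualitative outcomes: evolved S. marcescens
    has half the ancestral death rate and a slower growth rate (more
    biofilm in monoculture); N. capsulatum grows faster after co-culture,
    with a further increase under large pulses by week 13, and its biofilm
    first rises then partly falls back.
    """
    table: dict[TreatmentGroup, dict[str, float]] = {}
    for species in species_set:
        table[TreatmentGroup.ancestor(species)] = {}
        for pulse in pulses:
            for diversity in diversities:
                for week in weeks:
                    g = TreatmentGroup(species, pulse, diversity, week)
                    if species == "S_marcescens":
                        eff = {"r_max": 0.85, "death_rate": 0.5}
                        if diversity == "mono":
                            eff["biofilm_mu"] = 1.3
                    else:
                        eff = {}
                        if diversity == "co":
                            eff["r_max"] = 1.15
                        if week == 13 and pulse == "large":
                            eff["r_max"] = eff.get("r_max", 1.0) * 1.10
                        eff["biofilm_mu"] = 1.3 if week == 1 else 1.15
                    table[g] = eff
    return table


def default_clonal_sd_table(
    species_set=("S_marcescens", "N_capsulatum"),
    pulses=("large", "small"),
    diversities=("mono", "co"),
    weeks=(1, 13),
    base_sigma: float = 0.08,
    growth_sigma: dict[str, float] | None = None,
) -> dict[TreatmentGroup, dict[str, float] | float]:
    """Lognormal sigma of clone parameters per treatment cell.

    A common base sigma for most parameters (clonal variation is generally
    low), with species-specific growth-rate spread: the N. capsulatum
    growth rate has clone-level CV ~0.3 — the magnitude implied by its
    reported week-1 clonal SD (~0.033 on a ~0.1 h^-1 trait) — and that
    spread doubles by week 13, the one trait whose clonal variation
    increased during the experiment.
    """
    if growth_sigma is None:
        growth_sigma = {"S_marcescens": 0.10, "N_capsulatum": 0.30}
    table: dict[TreatmentGroup, dict[str, float] | float] = {}
    for species in species_set:
        g_sigma = growth_sigma.get(species, base_sigma)
        base_entry = {f: base_sigma for f in _VARIED_FIELDS}
        base_entry["r_max"] = g_sigma
        table[TreatmentGroup.ancestor(species)] = dict(base_entry)
        for pulse in pulses:
            for diversity in diversities:
                for week in weeks:
                    g = TreatmentGroup(species, pulse, diversity, week)
                    entry = dict(base_entry)
                    if species == "N_capsulatum" and week == 13:
                        entry["r_max"] = 2.0 * g_sigma
                    table[g] = entry
    return table


@dataclass
class TreatmentDesign:
    """Factorial design of the clone assays.

    2 species x 2 pulse magnitudes x mono/co-culture x weeks 1 and 13 x
    3 replicate microcosms, plus one ancestral clone set per species.
    """

    species_set: tuple[str, ...] = ("S_marcescens", "N_capsulatum")
    pulses: tuple[str, ...] = ("large", "small")
    diversities: tuple[str, ...] = ("mono", "co")
    weeks: tuple[int, ...] = (1, 13)
    n_replicates: int = 3
    n_clones: int = 10
    clone_bounds: tuple[int, int] = (6, 19)
    base_params: dict[str, CloneParams] = field(
        default_factory=lambda: dict(ANCESTOR_PARAMS)
    )
    effect_table: dict[TreatmentGroup, dict[str, float]] | None = None
    clonal_sd_table: dict[TreatmentGroup, dict[str, float] | float] | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError(f"n_replicates must be >= 1, got {self.n_replicates}")
        lo, hi = self.clone_bounds
        if not (lo <= self.n_clones <= hi):
            raise ValidationError(
                f"n_clones must lie in [{lo}, {hi}], got {self.n_clones}"
            )
        if self.effect_table is None:
            self.effect_table = default_effect_table(
                self.species_set, self.pulses, self.diversities, self.weeks
            )
        if self.clonal_sd_table is None:
            self.clonal_sd_table = default_clonal_sd_table(
                self.species_set, self.pulses, self.diversities, self.weeks
            )

    def groups(self) -> list[TreatmentGroup]:
        """All treatment cells: ancestors first, then the evolved factorial."""
        out = [TreatmentGroup.ancestor(sp) for sp in self.species_set]
        for species in self.species_set:
            for pulse in self.pulses:
                for diversity in self.diversities:
                    for week in self.weeks:
                        out.append(TreatmentGroup(species, pulse, diversity, week))
        return out


def default_design(**overrides) -> TreatmentDesign:
    return TreatmentDesign(**overrides)


def _sigma_for(design: TreatmentDesign, group: TreatmentGroup, field_name: str) -> float:
    entry = design.clonal_sd_table[group]
    sigma = entry.get(field_name, 0.0) if isinstance(entry, dict) else float(entry)
    if sigma < 0:
        raise ValidationError(f"clonal sigma must be >= 0, got {sigma} for {field_name}")
    return sigma


def group_mean_params(design: TreatmentDesign, group: TreatmentGroup) -> CloneParams:
    """Treatment-cell mean parameters: species base x multiplicative effect."""
    if group not in design.effect_table:
        raise ConfigError(f"unknown treatment group {group!r}")
    if group.species not in design.base_params:
        raise ConfigError(f"unknown species {group.species!r}")
    base = design.base_params[group.species]
    effects = design.effect_table[group]
    updates = {name: getattr(base, name) * mult for name, mult in effects.items()}
    return replace(base, **updates)


def derive_seed(master_seed: int, *ids) -> int:
    """Stable child seed from a master seed and a tuple of identifiers.

    Hash-based so that any subset of the experiment (one population, one
    clone) can be regenerated without generating the rest.
    """
    key = repr((int(master_seed),) + tuple(ids)).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def sample_clone_params(
    design: TreatmentDesign, group: TreatmentGroup, seed: int
) -> list[CloneParams]:
    """Draw ``design.n_clones`` parameter sets for one treatment cell.

    Each varied field is drawn mean-preserving lognormally around the cell
    mean: value = mean * exp(sigma*Z - sigma^2/2).  Sigma 0 returns the
    mean exactly; a fixed seed returns identical lists.
    """
    if group not in design.clonal_sd_table:
        raise ConfigError(f"unknown treatment group {group!r}")
    mean = group_mean_params(design, group)
    rng = np.random.default_rng(seed)
    clones = []
    for _ in range(design.n_clones):
        updates = {}
        for name in _VARIED_FIELDS:
            sigma = _sigma_for(design, group, name)
            m = getattr(mean, name)
            z = rng.standard_normal()  # always drawn: keeps the stream aligned
            updates[name] = m * float(np.exp(sigma * z - 0.5 * sigma**2))
        clones.append(replace(mean, **updates))
    return clones


#: Resource concentration below which growth is treated as ceased (g L^-1).
EXHAUSTION_THRESHOLD = 1e-6


def generate_od_curve(
    params: CloneParams, assay: AssayConfig, seed: int
) -> ODCurve:
    """Simulate one clone's week-long OD curve on the uniform sampling grid.

    Three phases: flat lag, Monod-limited growth integrated with the batch
    core until the resource falls below ``EXHAUSTION_THRESHOLD``, then
    exponential decline of live biomass at ``death_rate`` with dead biomass
    retaining opacity phi.  ``od_noise_sd = 0`` gives the noiseless curve.
    The returned curve's ``meta`` records the growth-cessation time and
    true peak biomass.
    """
    times = assay.times_h
    rng = np.random.default_rng(seed)
    n0 = params.inoculum_od
    lag = params.lag_h

    live = np.full(times.shape, n0, dtype=float)
    dead = np.zeros_like(times)
    cessation_h = None
    peak = n0

    grow_span = assay.duration_h - lag
    if grow_span > 0:
        traj = simulate_batch(
            BatchState(R=assay.medium_R, N=[n0]),
            [params.as_species(death_rate=0.0)],
            grow_span,
            exhaustion_threshold=EXHAUSTION_THRESHOLD,
            stop_at_exhaustion=True,
        )
        if not np.all(np.isfinite(traj.N)):
            raise ValidationError(f"non-finite growth trajectory for {params}")
        t_c = traj.exhaustion_t  # relative to end of lag
        rel = times - lag
        growth_limit = np.inf if t_c is None else t_c
        growing = (rel > 0) & (rel <= growth_limit)
        if np.any(growing):
            live[growing] = traj.sol(rel[growing])[1]
        if t_c is not None:
            peak = float(traj.sol(t_c)[1])
            cessation_h = lag + t_c
            declining = rel > t_c
            tau = rel[declining] - t_c
            surv = np.exp(-params.death_rate * tau)
            live[declining] = peak * surv
            dead[declining] = peak * (1.0 - surv)
        else:
            peak = float(live.max())

    od_true = assay.blank_od + live + assay.dead_cell_opacity * dead
    if assay.od_noise_sd > 0:
        od = od_true * np.exp(assay.od_noise_sd * rng.standard_normal(times.shape))
    else:
        od = od_true
    if not np.all(np.isfinite(od)):
        raise ValidationError(f"non-finite OD generated for {params}")
    return ODCurve(
        times=times,
        od=od,
        blank_od=assay.blank_od,
        sample_interval_min=assay.sample_interval_min,
        meta={
            "growth_cessation_h": cessation_h,
            "peak_od_true": peak,
            "species_id": params.species_id,
        },
    )


def generate_biofilm_signal(
    params: CloneParams, seed: int, noise_sd: float = 0.1
) -> float:
    """Noisy non-negative crystal-violet endpoint around ``biofilm_mu``.

    Mean-preserving lognormal: E[signal] = biofilm_mu; noise_sd = 0 (or
    biofilm_mu = 0) returns biofilm_mu exactly.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if params.biofilm_mu == 0 or noise_sd == 0:
        return float(params.biofilm_mu)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal()
    return float(params.biofilm_mu * np.exp(noise_sd * z - 0.5 * noise_sd**2))


@dataclass
class CloneRecord:
    """One assayed clone: treatment metadata, true parameters, data."""

    group: TreatmentGroup
    replicate: int
    clone: int
    params: CloneParams
    curve: ODCurve
    biofilm: float

    def meta(self) -> dict:
        return {
            "species": self.group.species,
            "pulse": self.group.pulse,
            "diversity": self.group.diversity,
            "week": self.group.week,
            "replicate": self.replicate,
            "clone": self.clone,
        }


@dataclass
class ExperimentDataset:
    """Full synthetic clone-assay dataset plus its run manifest."""

    records: list[CloneRecord]
    manifest: dict

    def metadata(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = rec.meta()
            row["biofilm_signal"] = rec.biofilm
            for f in fields(CloneParams):
                if f.name != "species_id":
                    row[f"true_{f.name}"] = getattr(rec.params, f.name)
            rows.append(row)
        return pd.DataFrame(rows)

    def od_long(self) -> pd.DataFrame:
        frames = []
        for rec in self.records:
            df = pd.DataFrame(
                {"time_h": rec.curve.times, "od": rec.curve.od}
            )
            for k, v in rec.meta().items():
                df[k] = v
            frames.append(df)
        cols = ["species", "pulse", "diversity", "week", "replicate", "clone",
                "time_h", "od"]
        return pd.concat(frames, ignore_index=True)[cols]

    def biofilm_table(self) -> pd.DataFrame:
        rows = [dict(rec.meta(), biofilm_signal=rec.biofilm) for rec in self.records]
        return pd.DataFrame(rows)


def generate_experiment(
    design: TreatmentDesign, assay: AssayConfig, seed: int
) -> ExperimentDataset:
    """Generate the full factorial of clone assays.

    Evolved cells get ``n_replicates`` microcosms each with ``n_clones``
    clones; each ancestral clone set has ``n_clones`` clones (replicate 0).
    Seeding is hierarchical from the master seed, so any population or
    clone is independently reproducible.
    """
    records: list[CloneRecord] = []
    for group in design.groups():
        reps = [0] if group.is_ancestor else range(1, design.n_replicates + 1)
        for rep in reps:
            gid = (group.species, group.pulse, group.diversity, group.week, rep)
            clones = sample_clone_params(
                design, group, derive_seed(seed, "params", *gid)
            )
            for ci, cp in enumerate(clones, start=1):
                records.append(
                    CloneRecord(
                        group=group,
                        replicate=rep,
                        clone=ci,
                        params=cp,
                        curve=generate_od_curve(
                            cp, assay, derive_seed(seed, "od", *gid, ci)
                        ),
                        biofilm=generate_biofilm_signal(
                            cp,
                            derive_seed(seed, "biofilm", *gid, ci),
                            noise_sd=assay.biofilm_noise_sd,
                        ),
                    )
                )
    manifest = {
        "master_seed": int(seed),
        "n_records": len(records),
        "design": {
            "species_set": list(design.species_set),
            "pulses": list(design.pulses),
            "diversities": list(design.diversities),
            "weeks": list(design.weeks),
            "n_replicates": design.n_replicates,
            "n_clones": design.n_clones,
        },
        "assay": {
            "duration_h": assay.duration_h,
            "sample_interval_min": assay.sample_interval_min,
            "od_noise_sd": assay.od_noise_sd,
            "blank_od": assay.blank_od,
            "dead_cell_opacity": assay.dead_cell_opacity,
            "medium_R": assay.medium_R,
            "biofilm_noise_sd": assay.biofilm_noise_sd,
        },
    }
    return ExperimentDataset(records=records, manifest=manifest)
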