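"""Synthetic clone sampling, OD-curve generation, and dataset assembly."""

import dataclasses

import numpy as np
import pytest

from serialpulse.errors import ConfigError, ValidationError
from serialpulse.growth_curves import (
    ANCESTOR_PARAMS,
    AssayConfig,
    TreatmentDesign,
    TreatmentGroup,
    generate_biofilm_signal,
    generate_experiment,
    generate_od_curve,
    group_mean_params,
    sample_clone_params,
)
from serialpulse.traits import extract_traits, max_growth_rate, mortality, yield_max


def zero_sd_design(**kwargs) -> TreatmentDesign:
    design = TreatmentDesign(**kwargs)
    design.clonal_sd_table = {g: 0.0 for g in design.clonal_sd_table}
    return design


class TestSampleCloneParams:
    def test_zero_variance_gives_identical_clones(self):
        design = zero_sd_design()
        group = TreatmentGroup.ancestor("S_marcescens")
        clones = sample_clone_params(design, group, seed=5)
        assert len(clones) == design.n_clones
        assert all(c == group_mean_params(design, group) for c in clones)

    def test_same_seed_reproduces_exactly(self):
        design = TreatmentDesign()
        group = TreatmentGroup("N_capsulatum", "large", "co", 13)
        a = sample_clone_params(design, group, seed=42)
        b = sample_clone_params(design, group, seed=42)
        assert a == b
        c = sample_clone_params(design, group, seed=43)
        assert a != c

    def test_lognormal_draws_are_mean_preserving(self):
        # ancestral S. marcescens r_max should average to the printed
        # 0.418 1/h within Monte-Carlo error at n = 1000
        design = TreatmentDesign(n_clones=19)
        group = TreatmentGroup.ancestor("S_marcescens")
        draws = []
        for rep in range(53):  # 53*19 > 1000 clones
            draws += [c.r_max for c in sample_clone_params(design, group, seed=rep)]
        draws = np.asarray(draws[:1000])
        sigma = 0.10
        se = 0.418 * np.sqrt(np.exp(sigma**2) - 1.0) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.418) < 4 * se

    def test_unknown_group_rejected(self):
        design = TreatmentDesign()
        with pytest.raises(ConfigError):
            sample_clone_params(design, TreatmentGroup("E_coli", "large", "mono", 1), 0)

    def test_negative_sigma_rejected(self):
        design = TreatmentDesign()
        group = TreatmentGroup.ancestor("S_marcescens")
        design.clonal_sd_table[group] = -0.1
        with pytest.raises(ValidationError):
            sample_clone_params(design, group, 0)

    def test_treatment_effects_shift_group_means(self):
        design = TreatmentDesign()
        anc = group_mean_params(design, TreatmentGroup.ancestor("S_marcescens"))
        evo = group_mean_params(design, TreatmentGroup("S_marcescens", "large", "mono", 13))
        assert evo.death_rate == pytest.approx(anc.death_rate * 0.5)
        assert evo.r_max < anc.r_max


class TestGenerateOdCurve:
    def test_no_death_no_decline(self, short_assay):
        params = dataclasses.replace(ANCESTOR_PARAMS["S_marcescens"], death_rate=0.0)
        curve = generate_od_curve(params, short_assay, seed=0)
        assert np.all(np.diff(curve.od) >= -1e-9)

    def test_sample_grid_matches_config(self, short_assay):
        curve = generate_od_curve(ANCESTOR_PARAMS["S_marcescens"], short_assay, 0)
        assert curve.times.size == int(48 * 60 / 5) + 1
        assert curve.sample_interval_min == pytest.approx(5.0)

    def test_mortality_matches_exponential_decay_closed_form(
        self, week_assay_noiseless
    ):
        # after growth ceases at t_c, live biomass decays as exp(-d*(t-t_c))
        # and proportional OD mortality is (1-phi)*(1-exp(-d*dt)); the
        # extractor's end biomass averages the last 12 samples, so the
        # closed form is averaged over those sample times too
        assay = week_assay_noiseless
        params = ANCESTOR_PARAMS["S_marcescens"]
        curve = generate_od_curve(params, assay, seed=0)
        t_c = curve.meta["growth_cessation_h"]
        assert t_c is not None and t_c < assay.duration_h
        phi = assay.dead_cell_opacity
        d = params.death_rate
        tail = curve.times[-12:] - t_c
        end_frac = np.mean(np.exp(-d * tail) + phi * (1.0 - np.exp(-d * tail)))
        expected_prop = 1.0 - end_frac
        mort = mortality(curve)
        assert mort.proportional_mortality == pytest.approx(expected_prop, rel=1e-3)
        mx = curve.meta["peak_od_true"]
        assert yield_max(curve).yield_od == pytest.approx(mx, rel=1e-3)
        assert mort.total_mortality == pytest.approx(expected_prop * mx, rel=2e-3)

    def test_final_od_below_peak_when_dying(self, week_assay_noiseless):
        curve = generate_od_curve(
            ANCESTOR_PARAMS["S_marcescens"], week_assay_noiseless, 0
        )
        corrected = curve.od - curve.blank_od
        assert corrected[-1] < corrected.max()

    def test_saturated_monod_limit_recovers_rmax(self, short_assay):
        # K_s << R0: pre-exhaustion growth is exponential at r_max
        params = dataclasses.replace(
            ANCESTOR_PARAMS["S_marcescens"], K_s=1e-4, death_rate=0.0
        )
        assay = dataclasses.replace(short_assay, dead_cell_opacity=1.0)
        curve = generate_od_curve(params, assay, seed=0)
        fit = max_growth_rate(curve)
        assert fit.rate == pytest.approx(params.r_max, rel=2e-3)

    def test_noiseless_curve_has_interior_peak_when_dying(self, week_assay_noiseless):
        for species in ("S_marcescens", "N_capsulatum"):
            curve = generate_od_curve(
                ANCESTOR_PARAMS[species], week_assay_noiseless, 0
            )
            peak_idx = int(np.argmax(curve.od))
            assert 0 < peak_idx < curve.od.size - 1

    def test_deterministic_under_seed(self, short_assay):
        assay = dataclasses.replace(short_assay, od_noise_sd=0.01)
        a = generate_od_curve(ANCESTOR_PARAMS["N_capsulatum"], assay, 9)
        b = generate_od_curve(ANCESTOR_PARAMS["N_capsulatum"], assay, 9)
        assert np.array_equal(a.od, b.od)


class TestBiofilmSignal:
    def test_zero_mean_gives_zero(self):
        params = dataclasses.replace(ANCESTOR_PARAMS["S_marcescens"], biofilm_mu=0.0)
        assert generate_biofilm_signal(params, seed=0) == 0.0

    def test_zero_noise_gives_mean_exactly(self):
        params = ANCESTOR_PARAMS["S_marcescens"]
        assert generate_biofilm_signal(params, seed=0, noise_sd=0.0) == params.biofilm_mu

    def test_sample_mean_within_three_se(self):
        params = ANCESTOR_PARAMS["S_marcescens"]
        noise_sd = 0.1
        draws = np.array(
            [generate_biofilm_signal(params, seed=i, noise_sd=noise_sd) for i in range(10_000)]
        )
        se = params.biofilm_mu * np.sqrt(np.exp(noise_sd**2) - 1.0) / 100.0
        assert abs(draws.mean() - params.biofilm_mu) < 3 * se
        assert np.all(draws > 0)


@pytest.fixture(scope="module")
def small_dataset():
    assay = AssayConfig(duration_h=24.0, od_noise_sd=0.0)
    design = TreatmentDesign(n_clones=6)
    return generate_experiment(design, assay, seed=77), design


class TestGenerateExperiment:
    def test_factorial_population_count(self, small_dataset):
        dataset, design = small_dataset
        meta = dataset.metadata()
        evolved = meta[meta.week != 0]
        pops = evolved.groupby(["species", "pulse", "diversity", "week", "replicate"])
        assert pops.ngroups == 2 * 2 * 2 * 2 * 3
        ancestors = meta[meta.week == 0]
        assert ancestors.groupby("species").ngroups == 2

    def test_ancestor_clone_set_size(self, small_dataset):
        dataset, design = small_dataset
        meta = dataset.metadata()
        per_anc = meta[meta.week == 0].groupby("species").size()
        assert (per_anc == design.n_clones).all()

    def test_dataset_identical_across_runs(self):
        assay = AssayConfig(duration_h=6.0)
        design = TreatmentDesign(
            species_set=("S_marcescens",), pulses=("large",), diversities=("mono",),
            weeks=(1,), n_replicates=1, n_clones=6,
        )
        a = generate_experiment(design, assay, seed=3)
        b = generate_experiment(design, assay, seed=3)
        assert a.od_long().equals(b.od_long())
        assert a.biofilm_table().equals(b.biofilm_table())

    def test_long_table_schema(self, small_dataset):
        dataset, _ = small_dataset
        long = dataset.od_long()
        assert list(long.columns) == [
            "species", "pulse", "diversity", "week", "replicate", "clone",
            "time_h", "od",
        ]


class TestClonalSdContract:
    def test_doubling_sigma_doubles_extracted_trait_sd(self):
        # generator-level contract on noiseless curves: the clone spread of
        # the extracted growth rate scales with the parameter sigma
        assay = AssayConfig(duration_h=48.0, od_noise_sd=0.0)
        medians = {}
        for sigma in (0.15, 0.30):
            design = TreatmentDesign(
                species_set=("N_capsulatum",), n_clones=10,
            )
            design.clonal_sd_table = {g: {"r_max": sigma} for g in design.clonal_sd_table}
            group = TreatmentGroup("N_capsulatum", "large", "mono", 1)
            sds = []
            for pop in range(12):
                clones = sample_clone_params(design, group, seed=1000 + pop)
                rates = [
                    extract_traits(
                        generate_od_curve(cp, assay, seed=2000 + 17 * pop + i)
                    ).max_growth_rate
                    for i, cp in enumerate(clones)
                ]
                sds.append(np.std(rates, ddof=1))
            medians[sigma] = float(np.median(sds))
        ratio = medians[0.30] / medians[0.15]
        assert 1.6 < ratio < 2.4
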