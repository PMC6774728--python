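"""Forward simulators: branching expansion, clonal interference, chemostat,
Pool-seq observation and assay generation."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from coevopool import (
    SimConfig,
    SweepEvent,
    sample_poolseq,
    simulate_chemostat,
    simulate_clonal_interference,
    simulate_coevolution_experiment,
    simulate_infection_assay,
    simulate_neutral_expansion,
    staircase_resistance,
)
from coevopool.filtering import derive_frequencies


class TestNeutralExpansion:
    def test_no_mutation_no_variation(self, small_config):
        cfg = dataclasses.replace(small_config, per_division_mutation_rate=0.0)
        res = simulate_neutral_expansion(cfg)
        assert res.vafs.size == 0
        assert res.final_size > 0

    def test_fixed_seed_reproducible(self, small_config):
        a = simulate_neutral_expansion(small_config)
        b = simulate_neutral_expansion(small_config)
        assert np.array_equal(a.vafs, b.vafs)
        assert np.array_equal(a.positions, b.positions)

    def test_extinction_is_reported_not_raised(self):
        cfg = SimConfig(offspring_survival_rate=0.02, n_generations=30, seed=0)
        statuses = {simulate_neutral_expansion(
            SimConfig(offspring_survival_rate=0.02, n_generations=30,
                      seed=s)).status for s in range(30)}
        assert "extinct" in statuses

    def test_vaf_spectrum_matches_power_law_shape(self):
        # binned variant counts follow c*(1/a - 1/b) (the density of the
        # cumulative law M(f) = (mu/beta)(1/f - 1/fmax)); compared over
        # 100 seeds at 3 standard errors of the per-seed mean
        edges = np.array([0.05, 0.08, 0.12, 0.18, 0.27, 0.40])
        per_seed = []
        for seed in range(100):
            cfg = SimConfig(seed=seed, n_generations=18,
                            per_division_mutation_rate=3.0)
            res = simulate_neutral_expansion(cfg)
            if res.extinct:
                continue
            h, _ = np.histogram(res.vafs, bins=edges)
            per_seed.append(h)
        per_seed = np.array(per_seed)
        mean = per_seed.mean(axis=0)
        se = per_seed.std(axis=0, ddof=1) / np.sqrt(len(per_seed))
        shape = 1 / edges[:-1] - 1 / edges[1:]
        scale = (mean * shape / se**2).sum() / (shape**2 / se**2).sum()
        assert np.all(np.abs(mean - scale * shape) < 3 * se)

    def test_lineages_inherit_parent_mutations(self, small_config):
        res = simulate_neutral_expansion(small_config, track_history=True)
        assert np.all(res.mutation_positions >= 1)
        assert np.all(res.mutation_positions <= small_config.genome_length)
        assert np.all(res.final_counts >= 0)
        # a child's subtree count is included in its parent's
        for i in range(1, min(res.parent.size, 200)):
            assert res.subtree_counts[res.parent[i]] >= res.subtree_counts[i]


class TestClonalInterference:
    def test_single_neutral_cohort_reduces_to_expansion(self, small_config):
        rng_a = small_config.rng("x")
        rng_b = small_config.rng("x")
        a = simulate_clonal_interference(small_config, n_cohorts=1,
                                         selection_coefficients=(0.0,), rng=rng_a)
        b = simulate_neutral_expansion(small_config, rng=rng_b)
        assert np.array_equal(a.vafs, b.vafs)

    def test_equal_cohorts_give_bimodal_vafs(self, small_config):
        res = simulate_clonal_interference(small_config,
                                           selection_coefficients=(0.31, 0.30),
                                           rng=small_config.rng("ci"))
        w = np.sort(res.cohort_fractions)
        assert w[0] == pytest.approx(0.5, abs=0.02)
        # hitchhiker atoms sit at both cohort frequencies
        for frac in res.cohort_fractions:
            assert (np.abs(res.vafs - frac) < 1e-12).sum() >= 5

    def test_distinct_positive_s_required(self, small_config):
        with pytest.raises(ValueError):
            simulate_clonal_interference(small_config,
                                         selection_coefficients=(0.3, 0.3))

    def test_fixing_cohort_warns(self, small_config):
        with pytest.warns(UserWarning, match="fixed"):
            simulate_clonal_interference(small_config,
                                         selection_coefficients=(5.0, 0.01),
                                         selection_generations=10)


class TestChemostat:
    def test_no_virus_reaches_carrying_capacity(self):
        cfg = SimConfig(virus_inoculum=0, total_days=60)
        res = simulate_chemostat(cfg)
        K = cfg.carrying_capacity
        equil = K * (1 - cfg.dilution_rate / cfg.host_growth_rate)
        tail = res.popsize.host.iloc[-10:]
        assert np.allclose(tail, equil, rtol=0.02)

    def test_logistic_fixed_point_without_dilution(self):
        cfg = SimConfig(virus_inoculum=0, dilution_rate=0.0, total_days=60)
        res = simulate_chemostat(cfg)
        assert res.popsize.host.iloc[-1] == pytest.approx(cfg.carrying_capacity,
                                                          rel=1e-3)

    def test_predator_prey_cycles_without_resistance(self):
        res = simulate_chemostat(SimConfig(total_days=100))
        h = np.log10(np.maximum(res.popsize.host.to_numpy(), 1.0))
        after = h[13:]
        # at least two local maxima and an excursion of >= 2 orders
        peaks = sum(1 for i in range(1, len(after) - 1)
                    if after[i] > after[i - 1] and after[i] >= after[i + 1])
        assert peaks >= 2
        assert h.max() - h.min() >= 2.0

    def test_abundances_stay_nonnegative(self):
        res = simulate_chemostat(SimConfig(total_days=80, sweep_schedule=[
            SweepEvent(16, 0.9, "resistance"), SweepEvent(40, 0.9, "infectivity")]))
        assert (res.popsize.host >= 0).all()
        assert (res.popsize.virus >= 0).all()

    def test_large_step_blowup_names_the_parameter(self):
        cfg = SimConfig(step_days=3.0, host_growth_rate=5.0,
                        adsorption_rate=1e-5, burst_size=500, total_days=60)
        with pytest.raises(ValueError, match="step_days"):
            simulate_chemostat(cfg)


class TestSamplePoolseq:
    def test_no_error_no_variant_means_pure_reference(self):
        cfg = SimConfig(sequencing_error_rate=0.0, coverage_mean=50)
        freqs = pd.DataFrame(np.zeros((20, 2)), columns=[0, 1])
        table = sample_poolseq(freqs, cfg, n_background=0, rng=cfg.rng("t"))
        for i in range(table.n_sites):
            col = "ATCG".index(table.ref[i])
            assert table.counts[i, :, col].sum() == table.counts[i].sum()

    def test_observed_frequency_is_unbiased(self):
        cfg = SimConfig(coverage_mean=100, sequencing_error_rate=0.0)
        n = 1000
        freqs = pd.DataFrame(np.full((n, 1), 0.3), columns=[0])
        table = sample_poolseq(freqs, cfg, n_background=0, rng=cfg.rng("t"))
        traj = derive_frequencies(table)
        obs = traj.freqs.to_numpy().ravel()
        se = np.sqrt(0.3 * 0.7 / 100 / n)
        assert abs(np.nanmean(obs) - 0.3) < 4 * se

    def test_coverage_follows_poisson_moments(self):
        cfg = SimConfig(coverage_mean=1000)
        freqs = pd.DataFrame(np.zeros((2000, 1)), columns=[0])
        table = sample_poolseq(freqs, cfg, n_background=0, rng=cfg.rng("t"))
        cov = table.coverage()[:, 0]
        assert cov.mean() == pytest.approx(1000, rel=0.01)
        assert cov.var(ddof=1) == pytest.approx(1000, rel=0.15)

    def test_missing_timepoint_emits_zero_coverage(self):
        cfg = SimConfig()
        freqs = pd.DataFrame([[0.2, np.nan]], columns=[0, 1])
        table = sample_poolseq(freqs, cfg, n_background=0, rng=cfg.rng("t"))
        assert table.counts[0, 1].sum() == 0


class TestInfectionAssayGenerator:
    def test_noise_free_susceptible_grows_below_control(self):
        rel = staircase_resistance([0], [0], [], [])   # susceptible
        df = simulate_infection_assay(rel, noise_sd=0.0,
                                      rng=np.random.default_rng(0))
        exposed = df[~df.is_control].growth_rate
        control = df[df.is_control].growth_rate
        assert exposed.max() < control.min()

    def test_comparison_count_matches_design(self):
        rel = staircase_resistance(list(range(12)), list(range(11)), [5], [])
        df = simulate_infection_assay(rel, n_clones=10,
                                      rng=np.random.default_rng(0))
        cells = df[~df.is_control].groupby(["clone", "virus_day"]).ngroups
        assert cells == 10 * 12 * 11


class TestCoevolutionScenario:
    def test_run_is_internally_consistent(self):
        run = simulate_coevolution_experiment(seed=5)
        assert run.sync.timepoints == run.truth["sample_days"]
        fs = run.truth["f_sweep"]
        fix = run.truth["sweep_fixation_day"]
        assert fix is not None and fs[fix] >= 0.95
        assert run.truth["sweep_start_day"] < fix
        # frequencies at day 0 are ancestral (isogenic start)
        assert np.nanmax(run.true_freqs[0].to_numpy()) == 0.0

    def test_seed_changes_data_deterministically(self):
        a = simulate_coevolution_experiment(seed=5)
        b = simulate_coevolution_experiment(seed=5)
        c = simulate_coevolution_experiment(seed=6)
        assert np.array_equal(a.sync.counts, b.sync.counts)
        assert not np.array_equal(a.sync.counts, c.sync.counts)
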