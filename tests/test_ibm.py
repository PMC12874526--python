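"""Population engine: initialization, migration, the daily loop, and
Monte Carlo summaries."""

from dataclasses import replace

import numpy as np
import pytest

from whiteflysim.deb import FEMALE, Stage
from whiteflysim.exposure import ApplicationEvent
from whiteflysim.ibm import (InitialGroup, Population,
                             ScenarioConfig, efficacy, efficacy_map,
                             initialize_population, migration_step,
                             monte_carlo, simulate, NYMPH_STAGES)
from whiteflysim.plant import PlantState


def flat_scenario(T=28.0, horizon=15, **kw):
    base = dict(horizon=horizon, temps=tuple([T] * horizon),
                initial_population=(InitialGroup(Stage.N2, 20),
                                    InitialGroup(Stage.ADULT, 2, sex=FEMALE)),
                seed=5, substeps=8, n_reps=10)
    base.update(kw)
    return ScenarioConfig(**base)


class TestInitialization:
    def test_synchronized_composition(self, params, rng):
        cfg = flat_scenario(initial_population=(
            InitialGroup(Stage.N2, 100),
            InitialGroup(Stage.ADULT, 2, sex=FEMALE)))
        pop = initialize_population(cfg, rng, params.deb)
        counts = pop.count_stages()
        assert counts[int(Stage.N2)] == 100
        assert counts[int(Stage.ADULT)] == 2
        assert counts.sum() == 102

    def test_heterogeneous_lengths_recovered(self, params, rng):
        cfg = flat_scenario(initial_population=(
            InitialGroup(Stage.N2, 100, length_mean=0.030,
                         length_sd=0.002),))
        pop = initialize_population(cfg, rng, params.deb)
        L = pop.L[:pop.n]
        assert abs(L.mean() - 0.030) < 3 * 0.002 / np.sqrt(100)
        lo, hi = params.deb.instar_lengths[0], params.deb.instar_lengths[1]
        assert np.all((L >= lo) & (L < hi))

    def test_zero_counts_empty_population(self, params, rng):
        cfg = flat_scenario(initial_population=())
        pop = initialize_population(cfg, rng, params.deb)
        assert pop.n == 0

    def test_maturity_consistent_with_stage(self, params, rng):
        cfg = flat_scenario(initial_population=(
            InitialGroup(Stage.N1, 30), InitialGroup(Stage.N3, 30)))
        pop = initialize_population(cfg, rng, params.deb)
        E_H = pop.E_H[:pop.n]
        assert np.all((E_H >= params.deb.E_Hb) & (E_H < params.deb.E_Hp))

    def test_out_of_bounds_length_rejected(self, params, rng):
        cfg = flat_scenario(initial_population=(
            InitialGroup(Stage.N2, 10, length_mean=0.10,
                         length_sd=1e-6),))
        with pytest.raises(ValueError):
            initialize_population(cfg, rng, params.deb)


class TestMigration:
    def _adult_pop(self, params, rng, n=50):
        cfg = flat_scenario(initial_population=(
            InitialGroup(Stage.ADULT, n, sex=FEMALE),))
        return initialize_population(cfg, rng, params.deb)

    def test_no_migration_no_change(self, params, rng):
        pop = self._adult_pop(params, rng)
        cfg = flat_scenario(immigration=0.0, emigration_rate=0.0)
        plant = PlantState(leaf_area=100.0, nodes=5.0)
        n_imm, n_em = migration_step(pop, cfg, plant, 0, rng, params.deb)
        assert (n_imm, n_em) == (0, 0)
        assert pop.count_stages().sum() == 50

    def test_full_emigration_empties_adults(self, params, rng):
        pop = self._adult_pop(params, rng)
        cfg = flat_scenario(emigration_rate=1.0)
        plant = PlantState(leaf_area=100.0, nodes=5.0)
        migration_step(pop, cfg, plant, 0, rng, params.deb)
        assert pop.count_stages()[int(Stage.ADULT)] == 0

    def test_node_trigger_removes_95_percent(self, params, rng):
        """Above 22 mainstem nodes the triggered fraction (0.95)
        replaces the daily emigration rate."""
        removed = 0
        total = 0
        for _ in range(60):
            pop = self._adult_pop(params, rng)
            cfg = flat_scenario(emigration_rate=0.1)
            plant = PlantState(leaf_area=100.0, nodes=23.0)
            _, n_em = migration_step(pop, cfg, plant, 0, rng, params.deb)
            removed += n_em
            total += 50
        frac = removed / total
        # binomial(3000, 0.95): 4 sd ~ 0.016
        assert abs(frac - 0.95) < 0.02

    def test_immigrants_are_clean_adults(self, params, rng):
        pop = Population()
        cfg = flat_scenario(immigration=40.0)
        plant = PlantState(leaf_area=100.0, nodes=5.0)
        n_imm, _ = migration_step(pop, cfg, plant, 0, rng, params.deb)
        assert n_imm > 0 and pop.n == n_imm
        assert np.all(pop.stage[:pop.n] == int(Stage.ADULT))
        assert np.all(pop.D[:pop.n] == 0.0)
        assert np.all(pop.sex[:pop.n] == FEMALE)


class TestSimulate:
    def test_adults_start_laying_within_days(self, params):
        cfg = flat_scenario(T=30.0, horizon=8, initial_population=(
            InitialGroup(Stage.ADULT, 2, sex=FEMALE),))
        traj = simulate(cfg, 3, params)
        assert traj.counts[5:, int(Stage.EGG)].max() > 0

    def test_identical_seeds_bit_identical(self, params):
        cfg = flat_scenario(applications=(ApplicationEvent(0, 12.0),))
        t1 = simulate(cfg, 42, params)
        t2 = simulate(cfg, 42, params)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        np.testing.assert_array_equal(t1.leaf_area, t2.leaf_area)

    def test_treated_dominated_by_control_in_paired_reps(self, params):
        """At 12 g a.i./ha the treated total at day 20 is <= the paired
        control total in at least 95 of 100 replicates."""
        cfg_c = flat_scenario(T=30.0, horizon=20, initial_population=(
            InitialGroup(Stage.N2, 100),
            InitialGroup(Stage.ADULT, 2, sex=FEMALE)))
        cfg_t = replace(cfg_c, applications=(ApplicationEvent(0, 12.0),))
        wins = 0
        for rep in range(100):
            seed = np.random.SeedSequence((7, rep))
            c = simulate(cfg_c, seed, params)
            t = simulate(cfg_t, np.random.SeedSequence((7, rep)), params)
            wins += t.totals[20] <= c.totals[20]
        assert wins >= 95

    def test_no_hazard_population_never_shrinks(self, params):
        deb0 = replace(params.deb, h_b_nymph=0.0, h_a=0.0,
                       starvation_hazard=0.0)
        p0 = replace(params, deb=deb0)
        cfg = flat_scenario(T=28.0, horizon=25)
        traj = simulate(cfg, 11, p0)
        assert np.all(np.diff(traj.totals) >= 0)

    def test_chemistry_free_arms_identical_with_and_without_tktd(self, params):
        """With zero applications the damage module is inert: replacing
        the TKTD block leaves trajectories bit-identical at equal seed."""
        alt = replace(params, tktd=replace(params.tktd, b_h=99.0, c_s=99.0,
                                           k_d=3.0))
        cfg = flat_scenario()
        t1 = simulate(cfg, 9, params)
        t2 = simulate(cfg, 9, alt)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_temps_shorter_than_horizon_rejected(self, params):
        cfg = flat_scenario(temps=(28.0,) * 5)
        with pytest.raises(ValueError, match="shorter"):
            simulate(cfg, 1, params)


class TestMonteCarlo:
    def test_single_rep_median_is_the_trajectory(self, params):
        cfg = flat_scenario(horizon=10, seed=21)
        out = monte_carlo(cfg, 1, params, keep_trajectories=True)
        traj = out["trajectories"][0]
        np.testing.assert_array_equal(out["counts_median"],
                                      traj.counts.astype(float))

    def test_quantile_ordering(self, params):
        cfg = flat_scenario(horizon=12, seed=2)
        out = monte_carlo(cfg, 15, params)
        assert np.all(out["counts_lo"] <= out["counts_median"] + 1e-12)
        assert np.all(out["counts_median"] <= out["counts_hi"] + 1e-12)

    def test_empty_population_all_quantiles_zero(self, params):
        cfg = flat_scenario(initial_population=(), horizon=8)
        out = monte_carlo(cfg, 5, params)
        assert np.all(out["counts_hi"] == 0.0)
        assert np.all(out["totals_hi"] == 0.0)


class TestEfficacy:
    @pytest.mark.parametrize("treated, control, expected",
                             [(100, 100, 0.0), (0, 100, 100.0),
                              (50, 200, 75.0)])
    def test_abbott_arithmetic(self, treated, control, expected):
        assert efficacy(treated, control) == pytest.approx(expected)

    def test_zero_control_is_missing_not_an_error(self):
        out = efficacy(np.array([5.0, 0.0]), np.array([0.0, 0.0]))
        assert np.all(np.isnan(out))

    def test_untreated_vs_untreated_median_near_zero(self, params):
        cfg = flat_scenario(T=28.0, horizon=14, initial_population=(
            InitialGroup(Stage.N2, 50),
            InitialGroup(Stage.ADULT, 4, sex=FEMALE)))
        a = monte_carlo(cfg, 100, params)
        b = monte_carlo(replace(cfg, seed=777), 100, params)
        eff = efficacy(b["totals_median"][14], a["totals_median"][14])
        assert abs(eff) < 5.0


class TestEfficacyMap:
    def test_zero_rate_map_is_near_zero(self, params):
        cfg = flat_scenario(T=28.0, horizon=10, n_reps=10)
        grid = efficacy_map(cfg, [28.0], [4], params, rate=0.0,
                            evaluation_lag=6, scope="total", n_reps=10)
        assert abs(grid[0, 0]) < 8.0

    def test_single_cell_matches_plain_two_application_run(self, params):
        cfg = flat_scenario(T=30.0, horizon=15, n_reps=8, seed=31)
        lag, day2 = 8, 6
        grid = efficacy_map(cfg, [30.0], [day2], params, rate=12.0,
                            evaluation_lag=lag, scope="nymphs", n_reps=8)
        horizon = day2 + lag + 1
        temps = tuple([30.0] * horizon)
        ctrl = monte_carlo(replace(cfg, horizon=horizon, temps=temps,
                                   applications=()), 8, params)
        trt = monte_carlo(replace(cfg, horizon=horizon, temps=temps,
                                  applications=(ApplicationEvent(0, 12.0),
                                                ApplicationEvent(day2, 12.0))),
                          8, params)
        idx = [int(s) for s in NYMPH_STAGES]
        expected = efficacy(trt["counts_median"][day2 + lag, idx].sum(),
                            ctrl["counts_median"][day2 + lag, idx].sum())
        assert grid[0, 0] == pytest.approx(expected, abs=1e-9)


class TestDoseResponse:
    def test_median_nymph_efficacy_monotone_in_rate(self, params):
        """Across three application rates the seed-averaged median
        nymph efficacy never decreases with dose (100 reps per arm)."""
        cfg = flat_scenario(T=28.0, horizon=16, seed=61,
                            initial_population=(
                                InitialGroup(Stage.N2, 60),
                                InitialGroup(Stage.ADULT, 4, sex=FEMALE)))
        idx = [int(s) for s in NYMPH_STAGES]
        control = monte_carlo(cfg, 100, params)
        c = control["counts_median"][16, idx].sum()
        effs = []
        for rate in (3.0, 12.0, 48.0):
            treated = monte_carlo(
                replace(cfg, applications=(ApplicationEvent(0, rate),)),
                100, params)
            effs.append(efficacy(treated["counts_median"][16, idx].sum(), c))
        assert effs[0] <= effs[1] + 1e-9 <= effs[2] + 2e-9


class TestConservation:
    def test_integer_bookkeeping_random_scenarios(self, params):
        """The in-loop audit (births/deaths/migration) passes on a batch
        of randomized small scenarios."""
        master = np.random.default_rng(99)
        for _ in range(60):
            horizon = int(master.integers(3, 10))
            cfg = ScenarioConfig(
                horizon=horizon,
                temps=tuple(master.uniform(16, 34, horizon)),
                applications=(ApplicationEvent(
                    int(master.integers(0, horizon)),
                    float(master.uniform(0, 24))),),
                initial_population=(
                    InitialGroup(Stage.EGG, int(master.integers(0, 20))),
                    InitialGroup(Stage.N2, int(master.integers(0, 20))),
                    InitialGroup(Stage.ADULT, int(master.integers(0, 6)),
                                 sex=FEMALE)),
                immigration=float(master.uniform(0, 3)),
                emigration_rate=float(master.uniform(0, 0.4)),
                seed=int(master.integers(0, 2**31)), substeps=4)
            simulate(cfg, cfg.seed, params)  # raises on any violation
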