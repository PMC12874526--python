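"""Individual-level DEB dynamics: growth, maturation, reproduction, aging."""

import numpy as np
import pytest
from scipy.optimize import brentq

from whiteflysim.deb import (FEMALE, Individual, Stage,
                             classify_stage, daily_death_probability,
                             deb_derivatives, derive_compound_params,
                             spawn_viable_eggs, step_individual)


def fresh_egg(deb, comp):
    e0 = comp.E_0 / (deb.E_m * deb.L_egg**3)
    return Individual(L=deb.L_egg, e=e0, E_H=0.0)


def fresh_adult(deb, comp, e=1.0):
    return Individual(L=comp.L_p, e=e, E_H=deb.E_Hp, stage=Stage.ADULT,
                      sex=FEMALE)


def run_to_adult(deb, c_T=1.0, substeps=24, max_days=120):
    comp = derive_compound_params(deb)
    ind = fresh_egg(deb, comp)
    stages = [ind.stage]
    while ind.stage != Stage.ADULT:
        ind = step_individual(ind, (1.0, c_T, 0.0), substeps=substeps,
                              params=deb)
        stages.append(ind.stage)
        if ind.age > max_days:
            raise AssertionError("no emergence within the time limit")
    return ind, stages


class TestCompoundDerivation:
    def test_egg_reserve_matches_f_at_birth(self, deb, comp):
        """E_0 is solved so the scaled reserve density is 1 at hatching."""
        from whiteflysim.deb import _integrate_reference

        e_b, L_b, _, t_b = _integrate_reference(deb, comp.E_0)
        assert e_b == pytest.approx(1.0, abs=1e-6)
        assert L_b == pytest.approx(comp.L_b, rel=1e-9)
        assert 0 < t_b < 30

    def test_lengths_ordered(self, deb, comp):
        assert deb.L_egg < comp.L_b < comp.L_p
        assert comp.s_M_max == pytest.approx(comp.L_p / comp.L_b)


class TestLifeCycle:
    def test_egg_hatches_at_maturity_threshold(self, deb, comp):
        ind = fresh_egg(deb, comp)
        while ind.stage == Stage.EGG:
            prev = ind
            ind = step_individual(ind, (1.0, 1.25, 0.0), substeps=24,
                                  params=deb)
            assert ind.age < 40
        assert prev.E_H < deb.E_Hb <= ind.E_H
        assert ind.stage == Stage.N1

    def test_stage_sequence_monotone(self, deb):
        _, stages = run_to_adult(deb)
        codes = [int(s) for s in stages]
        assert codes == sorted(codes)
        assert set(stages) == set(Stage)

    def test_development_accelerates_with_temperature(self, deb, params):
        from whiteflysim.temperature import arrhenius_factor

        times = []
        for T in (20.0, 25.0, 30.0):
            c_T = arrhenius_factor(T, params.whitefly_resp)
            ind, _ = run_to_adult(deb, c_T=c_T, substeps=12)
            times.append(ind.age)
        assert times[0] > times[1] > times[2]

    def test_maturity_never_decreases(self, deb, comp):
        ind = fresh_egg(deb, comp)
        last = 0.0
        for _ in range(40):
            ind = step_individual(ind, (1.0, 1.0, 0.0), substeps=12,
                                  params=deb)
            assert ind.E_H >= last - 1e-12
            last = ind.E_H


class TestDerivatives:
    def test_adult_growth_is_exactly_zero(self, deb, comp):
        rates = deb_derivatives(1.0, comp.L_p, deb.E_Hp, 0.0, 0.0, 0.0,
                                feeding=True, adult=True, f=1.0, c_T=1.0,
                                params=deb, comp=comp)
        assert float(rates["dL"]) == 0.0

    def test_reserve_relaxes_to_functional_response(self, deb, comp):
        """e drifts monotonically toward f and is stationary at e = f."""
        ind = fresh_adult(deb, comp, e=0.5)
        values = [ind.e]
        for _ in range(30):
            ind = step_individual(ind, (1.0, 1.0, 0.0), substeps=24,
                                  params=deb)
            values.append(ind.e)
        assert np.all(np.diff(values) > 0)
        assert values[-1] == pytest.approx(1.0, abs=1e-3)
        rates = deb_derivatives(1.0, comp.L_p, deb.E_Hp, 0.0, 0.0, 0.0,
                                feeding=True, adult=True, f=1.0, c_T=1.0,
                                params=deb, comp=comp)
        assert float(rates["de"]) == pytest.approx(0.0, abs=1e-12)

    def test_adult_reserve_relaxation_is_analytic_exponential(self, deb, comp):
        """At fixed adult length, e(t) = f + (e0-f) exp(-v_T t / L)."""
        e0, t_days = 0.4, 3.0
        ind = fresh_adult(deb, comp, e=e0)
        for _ in range(int(t_days)):
            ind = step_individual(ind, (1.0, 1.0, 0.0), substeps=24,
                                  params=deb)
        rate = deb.v * comp.s_M_max / comp.L_p
        expected = 1.0 + (e0 - 1.0) * np.exp(-rate * t_days)
        assert ind.e == pytest.approx(expected, abs=1e-4)

    def test_growth_equilibrium_matches_root_finder(self, deb, comp):
        """Integrating the growth equation (acceleration capped) converges
        to the fixed point found independently by a root-finder, which in
        turn equals kappa*s_M*p_Am/p_M."""

        def dLdt(L):
            return float(deb_derivatives(
                1.0, L, deb.E_Hb, 0.0, 0.0, 0.0, feeding=True, adult=False,
                f=1.0, c_T=1.0, params=deb, comp=comp)["dL"])

        def growth_drive(L):
            # e - L/(L_m s_M): sign of growth at e = 1, from the balance
            # of mobilization against maintenance at the capped
            # acceleration
            s_M = min(max(L / comp.L_b, 1.0), comp.s_M_max)
            return 1.0 - L / (deb.L_m * s_M)

        L_root = brentq(growth_drive, comp.L_p * 1.01,
                        deb.L_m * comp.s_M_max * 2)
        assert L_root == pytest.approx(deb.L_m * comp.s_M_max, rel=1e-9)
        L, h = comp.L_b, 0.05
        for _ in range(40000):
            L = L + dLdt(L) * h
        assert L == pytest.approx(L_root, rel=0.01)

    def test_energy_balance_kappa_rule(self, deb, comp):
        """kappa p_C = p_S + p_G and (1-kappa) p_C = p_J + maturation for a
        non-starving juvenile (algebraic identity of the budget)."""
        L = 0.5 * (comp.L_b + comp.L_p)
        E_H = 0.5 * (deb.E_Hb + deb.E_Hp)
        r = deb_derivatives(1.0, L, E_H, 0.0, 0.0, 0.0, feeding=True,
                            adult=False, f=1.0, c_T=1.0, params=deb,
                            comp=comp)
        assert not bool(r["starving"])
        p_C, p_S, p_G, p_J = (float(r[k]) for k in
                              ("p_C", "p_S", "p_G", "p_J"))
        assert deb.kappa * p_C == pytest.approx(p_S + p_G, rel=1e-9)
        assert (1 - deb.kappa) * p_C == pytest.approx(
            p_J + float(r["dE_H"]), rel=1e-9)

    def test_zero_temperature_correction_freezes_state(self, deb, comp):
        ind = fresh_adult(deb, comp, e=0.7)
        ind2 = step_individual(ind, (1.0, 0.0, 5.0), substeps=12, params=deb)
        for name in ("e", "L", "E_H", "E_R", "q", "h_age", "D"):
            assert getattr(ind2, name) == getattr(ind, name)
        assert ind2.age == ind.age + 1


class TestNumerics:
    def test_substep_convergence_on_juvenile_run(self, deb, comp):
        """Doubling substeps moves the 30-day length by < 0.1%."""
        results = {}
        for substeps in (24, 48):
            ind = Individual(L=comp.L_b, e=1.0, E_H=deb.E_Hb,
                             stage=Stage.N1)
            for _ in range(30):
                ind = step_individual(ind, (1.0, 0.8, 0.0),
                                      substeps=substeps, params=deb)
            results[substeps] = ind.L
        assert abs(results[48] - results[24]) / results[24] < 1e-3

    def test_aging_hazard_matches_weibull_closed_form(self, deb, comp):
        """With s_G ~ 0 and constant adult conditions the aging hazard is
        h(t) = h_a (e v_T/L) t^2 / 2 (Weibull limit)."""
        from dataclasses import replace as drep

        p = drep(deb, s_G=0.0)
        ind = fresh_adult(p, comp)
        t = 12
        for _ in range(t):
            ind = step_individual(ind, (1.0, 1.0, 0.0), substeps=24,
                                  params=p)
        a = p.v * comp.s_M_max / comp.L_p
        assert ind.h_age == pytest.approx(0.5 * p.h_a * a * t**2, rel=0.02)


class TestStageClassification:
    def test_zero_maturity_is_egg(self, deb):
        assert classify_stage(0.0, deb.L_egg, deb, Stage.EGG) == Stage.EGG

    def test_puberty_is_adult_regardless_of_length(self, deb):
        assert classify_stage(deb.E_Hp, 0.001, deb, Stage.EGG) == Stage.ADULT
        assert classify_stage(deb.E_Hp * 2, 1.0, deb, Stage.EGG) == Stage.ADULT

    def test_threshold_length_belongs_to_later_instar(self, deb):
        E_H = 0.5 * (deb.E_Hb + deb.E_Hp)
        lo, mid, hi = deb.instar_lengths
        assert classify_stage(E_H, lo, deb, Stage.EGG) == Stage.N2
        assert classify_stage(E_H, mid, deb, Stage.EGG) == Stage.N3
        assert classify_stage(E_H, hi, deb, Stage.EGG) == Stage.PSEUDOPUPA

    def test_never_moves_backward(self, deb):
        E_H = 0.5 * (deb.E_Hb + deb.E_Hp)
        assert classify_stage(E_H, 0.027, deb, Stage.N3) == Stage.N3


class TestMortality:
    def test_zero_hazard_zero_probability(self, deb, comp):
        nymph = Individual(L=0.03, e=1.0, E_H=deb.E_Hb * 2, stage=Stage.N2)
        from dataclasses import replace as drep

        p0 = drep(deb, h_b_nymph=0.0)
        assert daily_death_probability(nymph, 0.0, 1.0, p0) == 0.0

    def test_log2_hazard_gives_half(self, deb, comp):
        adult = fresh_adult(deb, comp)
        adult.h_age = np.log(2.0)
        assert daily_death_probability(adult, 0.0, 1.0, deb) == \
            pytest.approx(0.5, abs=1e-12)

    def test_background_hazard_log_linearity(self, deb):
        from dataclasses import replace as drep

        nymph = Individual(L=0.03, e=1.0, E_H=deb.E_Hb * 2, stage=Stage.N2)
        p1 = daily_death_probability(nymph, 0.0, 1.0, deb)
        p2 = daily_death_probability(
            nymph, 0.0, 1.0, drep(deb, h_b_nymph=2 * deb.h_b_nymph))
        assert -np.log(1 - p2) == pytest.approx(-2 * np.log(1 - p1),
                                                rel=1e-12)


class TestReproduction:
    def test_no_stress_expectation(self, deb, comp):
        adult = fresh_adult(deb, comp)
        adult.E_R = 10 * comp.E_0
        n, updated = spawn_viable_eggs(adult, 0.0, 0.0, 1.0, None,
                                       params=deb)
        expected = deb.kap_R * adult.E_R / comp.E_0
        assert n == int(expected)
        assert updated.E_R == 0.0

    def test_infinite_embryo_hazard_kills_all_eggs(self, deb, comp):
        adult = fresh_adult(deb, comp)
        adult.E_R = 10 * comp.E_0
        n, _ = spawn_viable_eggs(adult, 0.0, 1e9, 1.0, None, params=deb)
        assert n == 0

    def test_insufficient_buffer_accrues(self, deb, comp):
        adult = fresh_adult(deb, comp)
        adult.E_R = 0.1 * comp.E_0
        n, updated = spawn_viable_eggs(adult, 0.0, 0.0, 1.0, None,
                                       params=deb)
        assert n == 0 and updated.E_R == adult.E_R

    def test_doubled_cost_halves_egg_output(self, deb, comp):
        """s_repro = 1 halves cumulative viable eggs at equal buffer
        accrual (brute-force multi-day buffer simulation)."""
        accrual = 0.6  # J/day into the buffer
        totals = {}
        for s_repro in (0.0, 1.0):
            adult = fresh_adult(deb, comp)
            total = 0.0
            for _ in range(40):
                adult.E_R += accrual
                n, adult = spawn_viable_eggs(adult, s_repro, 0.0, 1.0, None,
                                             params=deb)
                total += n
            totals[s_repro] = total
        assert totals[1.0] == pytest.approx(totals[0.0] / 2.0, rel=0.05)

    def test_poisson_draw_matches_expectation(self, deb, comp, rng):
        adult = fresh_adult(deb, comp)
        adult.E_R = 20 * comp.E_0
        mean = deb.kap_R * adult.E_R / comp.E_0
        draws = []
        for _ in range(400):
            a = fresh_adult(deb, comp)
            a.E_R = 20 * comp.E_0
            n, _ = spawn_viable_eggs(a, 0.0, 0.0, 1.0, rng, params=deb)
            draws.append(n)
        assert np.mean(draws) == pytest.approx(mean, rel=0.1)
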