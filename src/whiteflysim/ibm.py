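"""Individual-based population engine for *Bemisia tabaci*.

Runs the daily loop over all individuals on a single host plant:
temperature correction, exposure and damage dynamics, DEB state
updates with stage transitions, stochastic mortality, reproduction
(viable eggs only), adult immigration/emigration, and plant growth.
Population state is stored as flat numpy arrays (one slot per
individual, structure-of-arrays) so the whole population advances
through the vectorized DEB kernel in one call per substep.

Stochasticity enters through probabilistic mortality, Poisson
offspring and immigration numbers, binomial emigration, sex
assignment, and the initial population composition; everything flows
from one master seed, so trajectories are bit-identical across runs
for equal (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .deb import (FEMALE, MALE, CompoundParams, DEBParams, Stage,
                  classify_stage_array, derive_compound_params,
                  integrate_states)
from .exposure import ApplicationEvent, ExposureProfile, build_exposure_profile
from .plant import PlantParams, PlantState, step_plant
from .temperature import TemperatureResponse, arrhenius_factor
from .tktd import TKTDParams

__all__ = [
    "InitialGroup",
    "ModelParams",
    "ScenarioConfig",
    "PopulationTrajectory",
    "Population",
    "initialize_population",
    "migration_step",
    "simulate",
    "monte_carlo",
    "efficacy",
    "efficacy_map",
    "NYMPH_STAGES",
]

#: stages counted as 'nymphs' in efficacy scopes (sessile immatures
#: scored on leaf discs: instars plus pseudopupa, excluding eggs)
NYMPH_STAGES = (Stage.N1, Stage.N2, Stage.N3, Stage.PSEUDOPUPA)


@dataclass(frozen=True)
class InitialGroup:
    """One homogeneous block of the initial population.

    ``length_mean``/``length_sd`` describe the structural-length
    distribution (cm); with ``length_mean=None`` a stage-typical
    default is used (mid-instar for nymphs, hatchling/ultimate sizes
    for the boundary stages).
    """

    stage: Stage
    count: int
    length_mean: float | None = None
    length_sd: float = 0.0
    sex: int | None = None   # None -> Bernoulli(sex_ratio)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one simulation arm."""

    horizon: int
    temps: tuple                      # daily mean temperature, deg C
    applications: tuple = ()          # ApplicationEvent list; empty = control
    initial_population: tuple = ()    # InitialGroup list
    immigration: float | tuple = 0.0  # adults/day (scalar or per-day)
    emigration_rate: float = 0.0      # daily fraction of adults
    emigration_trigger_nodes: float = 22.0
    emigration_trigger_fraction: float = 0.95
    background_hazard_multiplier: float | tuple = 1.0
    n_reps: int = 100
    seed: int = 0
    substeps: int = 12
    f: float = 1.0                    # scaled functional response (ad libitum)
    immigrant_sex: int | None = FEMALE  # None -> Bernoulli(sex_ratio)

    def validate(self) -> list[str]:
        out = []
        if self.horizon < 1:
            out.append("horizon: must be >= 1 day")
        if len(self.temps) < self.horizon:
            out.append(f"temps: length {len(self.temps)} shorter than "
                       f"horizon {self.horizon}")
        for g in self.initial_population:
            if g.count < 0:
                out.append(f"initial_population: negative count for {g.stage}")
        for name in ("emigration_rate", "emigration_trigger_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                out.append(f"{name}: must lie in [0, 1]")
        imm = np.atleast_1d(np.asarray(self.immigration, dtype=float))
        if np.any(imm < 0):
            out.append("immigration: must be >= 0")
        if self.n_reps < 1:
            out.append("n_reps: must be >= 1")
        if self.substeps < 1:
            out.append("substeps: must be >= 1")
        if not 0.0 <= self.f <= 1.0:
            out.append("f: must lie in [0, 1]")
        return out

    def daily_immigration(self) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(self.immigration, dtype=float))
        if arr.size == 1:
            return np.full(self.horizon, float(arr[0]))
        if arr.size < self.horizon:
            raise ValueError("immigration series shorter than horizon")
        return arr[: self.horizon]

    def daily_hazard_multiplier(self) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(self.background_hazard_multiplier,
                                       dtype=float))
        if arr.size == 1:
            return np.full(self.horizon, float(arr[0]))
        if arr.size < self.horizon:
            raise ValueError("hazard multiplier series shorter than horizon")
        return arr[: self.horizon]


@dataclass
class PopulationTrajectory:
    """Daily per-stage integer counts plus environment state."""

    counts: np.ndarray        # (horizon+1, n_stages) incl. day 0
    totals: np.ndarray        # (horizon+1,)
    leaf_area: np.ndarray     # (horizon+1,) cm^2
    nodes: np.ndarray         # (horizon+1,)
    exposure: np.ndarray      # (horizon+1,) scaled concentration
    replicate: int
    seed: int

    def stage_counts(self, stages: Sequence[Stage]) -> np.ndarray:
        idx = [int(s) for s in stages]
        return self.counts[:, idx].sum(axis=1)


class Population:
    """Structure-of-arrays container for the living (and dead) slots."""

    _FIELDS = ("e", "L", "E_H", "E_R", "D", "q", "h_age", "age", "egg_frac")

    def __init__(self, capacity: int = 256):
        capacity = max(capacity, 16)
        for name in self._FIELDS:
            setattr(self, name, np.zeros(capacity))
        self.stage = np.zeros(capacity, dtype=np.int8)
        self.sex = np.zeros(capacity, dtype=np.int8)
        self.alive = np.zeros(capacity, dtype=bool)
        self.n = 0

    @property
    def capacity(self) -> int:
        return self.alive.shape[0]

    def _grow(self, needed: int) -> None:
        cap = self.capacity
        new_cap = cap
        while new_cap < needed:
            new_cap *= 2
        if new_cap == cap:
            return
        for name in self._FIELDS:
            arr = getattr(self, name)
            setattr(self, name, np.resize(arr, new_cap))
            getattr(self, name)[self.n:] = 0.0
        self.stage = np.resize(self.stage, new_cap)
        self.stage[self.n:] = 0
        self.sex = np.resize(self.sex, new_cap)
        self.sex[self.n:] = 0
        self.alive = np.resize(self.alive, new_cap)
        self.alive[self.n:] = False

    def compact(self) -> None:
        """Drop dead slots (deterministic, order-preserving)."""
        keep = self.alive[: self.n]
        m = int(keep.sum())
        for name in self._FIELDS:
            arr = getattr(self, name)
            arr[:m] = arr[: self.n][keep]
            arr[m:self.n] = 0.0
        self.stage[:m] = self.stage[: self.n][keep]
        self.sex[:m] = self.sex[: self.n][keep]
        self.alive[:m] = True
        self.alive[m:self.n] = False
        self.n = m

    def add(self, **fields) -> None:
        """Append individuals; fields are equal-length arrays."""
        k = len(np.atleast_1d(fields["L"]))
        if k == 0:
            return
        self._grow(self.n + k)
        sl = slice(self.n, self.n + k)
        for name in self._FIELDS:
            getattr(self, name)[sl] = fields.get(name, 0.0)
        self.stage[sl] = fields.get("stage", int(Stage.EGG))
        self.sex[sl] = fields.get("sex", FEMALE)
        self.alive[sl] = True
        self.n += k

    def count_stages(self) -> np.ndarray:
        """Living individuals per stage, length len(Stage)."""
        counts = np.zeros(len(Stage), dtype=np.int64)
        if self.n:
            live_stages = self.stage[: self.n][self.alive[: self.n]]
            got = np.bincount(live_stages, minlength=len(Stage))
            counts[: len(got)] = got[: len(Stage)]
        return counts


# ---------------------------------------------------------------------------
# initialization

def _stage_length_bounds(stage: Stage, params: DEBParams,
                         comp: CompoundParams) -> tuple[float, float]:
    lo_1, lo_2, lo_3 = params.instar_lengths
    return {
        Stage.EGG: (params.L_egg, comp.L_b),
        Stage.N1: (comp.L_b, lo_1),
        Stage.N2: (lo_1, lo_2),
        Stage.N3: (lo_2, lo_3),
        Stage.PSEUDOPUPA: (lo_3, comp.L_p),
        Stage.ADULT: (comp.L_p * 0.9, comp.L_p * 1.05),
    }[stage]


def _maturity_for_length(L, params: DEBParams, comp: CompoundParams):
    """Reconstruct a maturity level consistent with a juvenile length.

    Uses the f=1 reference relation: maturity grows monotonically with
    length between birth and puberty, interpolated on a cached grid.
    """
    table = _reference_L_EH_table(params)
    return np.interp(np.asarray(L, dtype=float), table[0], table[1])


_REF_TABLE_CACHE: dict = {}


def _reference_L_EH_table(params: DEBParams):
    key = params
    if key in _REF_TABLE_CACHE:
        return _REF_TABLE_CACHE[key]
    comp = derive_compound_params(params)
    # integrate the f=1 juvenile with the production kernel (single
    # individual, no chemistry) and tabulate (L, E_H)
    tk = TKTDParams()
    e = np.array([1.0]); L = np.array([comp.L_b])
    E_H = np.array([params.E_Hb]); E_R = np.array([0.0])
    q = np.array([0.0]); h_age = np.array([0.0]); D = np.array([0.0])
    stage = np.array([int(Stage.N1)], dtype=np.int8)
    Ls, EHs = [comp.L_b], [params.E_Hb]
    for _ in range(400):
        e, L, E_H, E_R, q, h_age, D, stage, _ = integrate_states(
            e, L, E_H, E_R, q, h_age, D, stage, f=1.0, c_T=1.0,
            C_imm=0.0, C_adult=0.0, dt=0.25, substeps=6, params=params,
            comp=comp, tktd_params=tk)
        Ls.append(float(L[0])); EHs.append(float(E_H[0]))
        if E_H[0] >= params.E_Hp:
            break
    table = (np.asarray(Ls), np.minimum(np.asarray(EHs), params.E_Hp))
    _REF_TABLE_CACHE[key] = table
    return table


def _adult_aging_state(params: DEBParams, comp: CompoundParams,
                       adult_age: float = 5.0) -> tuple[float, float]:
    """Aging states (q, h_age) of an adult ``adult_age`` days after
    emergence at reference temperature (closed form for small s_G)."""
    spec_mob = params.v * comp.s_M_max / comp.L_p  # e = 1
    q = params.h_a * spec_mob * adult_age
    h = 0.5 * params.h_a * spec_mob * adult_age**2
    return q, h


def _make_adults(k: int, params: DEBParams, comp: CompoundParams,
                 rng: np.random.Generator, sex, mid_age: bool = True) -> dict:
    q0, h0 = _adult_aging_state(params, comp) if mid_age else (0.0, 0.0)
    if sex is None:
        sexes = np.where(rng.random(k) < params.sex_ratio, FEMALE, MALE)
    else:
        sexes = np.full(k, sex, dtype=np.int8)
    return dict(e=np.ones(k), L=np.full(k, comp.L_p),
                E_H=np.full(k, params.E_Hp), E_R=np.zeros(k),
                D=np.zeros(k), q=np.full(k, q0), h_age=np.full(k, h0),
                age=np.full(k, comp.t_p + (5.0 if mid_age else 0.0)),
                stage=np.full(k, int(Stage.ADULT), dtype=np.int8),
                sex=sexes)


def initialize_population(config: ScenarioConfig, rng: np.random.Generator,
                          params: DEBParams) -> Population:
    """Create the starting population.

    Structural lengths are drawn from the group's normal distribution
    truncated to the stage's length bounds (resampling, with an error
    after persistent failure); reserve density starts at the scaled
    functional response and maturity is reconstructed from length via
    the f=1 reference relation, so intermediate states are internally
    consistent.  Sexes are Bernoulli(sex_ratio) unless pinned.
    """
    bad = config.validate()
    if bad:
        raise ValueError("invalid scenario: " + "; ".join(bad))
    comp = derive_compound_params(params)
    pop = Population(capacity=max(64, sum(g.count for g in
                                          config.initial_population) * 2))
    for group in config.initial_population:
        k = group.count
        if k == 0:
            continue
        stage = Stage(group.stage)
        if stage == Stage.ADULT:
            fields = _make_adults(k, params, comp, rng, group.sex)
            pop.add(**fields)
            continue
        lo, hi = _stage_length_bounds(stage, params, comp)
        if group.length_mean is None:
            L = np.full(k, 0.5 * (lo + hi))
        elif group.length_sd == 0.0:
            L = np.full(k, float(group.length_mean))
            if np.any((L < lo) | (L >= hi)) and stage != Stage.EGG:
                raise ValueError(
                    f"length {group.length_mean} outside {stage.name} bounds "
                    f"[{lo:.4f}, {hi:.4f})")
        else:
            L = np.empty(k)
            remaining = np.arange(k)
            for _attempt in range(200):
                draw = rng.normal(group.length_mean, group.length_sd,
                                  len(remaining))
                ok = (draw >= lo) & (draw < hi)
                L[remaining[ok]] = draw[ok]
                remaining = remaining[~ok]
                if len(remaining) == 0:
                    break
            else:
                raise ValueError(
                    f"could not draw lengths inside {stage.name} bounds "
                    f"[{lo:.4f}, {hi:.4f}) from N({group.length_mean}, "
                    f"{group.length_sd}^2)")
        if group.sex is None:
            sexes = np.where(rng.random(k) < params.sex_ratio, FEMALE, MALE)
        else:
            sexes = np.full(k, group.sex, dtype=np.int8)
        if stage == Stage.EGG:
            e0 = comp.E_0 / (params.E_m * params.L_egg**3)
            pop.add(e=np.full(k, e0), L=np.full(k, params.L_egg),
                    E_H=np.zeros(k), stage=np.full(k, int(Stage.EGG),
                                                   dtype=np.int8),
                    sex=sexes, age=np.zeros(k))
        else:
            E_H = _maturity_for_length(L, params, comp)
            pop.add(e=np.full(k, config.f), L=L, E_H=E_H,
                    stage=np.full(k, int(stage), dtype=np.int8),
                    sex=sexes, age=np.zeros(k))
    return pop


# ---------------------------------------------------------------------------
# daily processes

def migration_step(pop: Population, config: ScenarioConfig,
                   plant_state: PlantState, day: int,
                   rng: np.random.Generator, params: DEBParams,
                   immigration_today: float | None = None,
                   ) -> tuple[int, int]:
    """Adult immigration and emigration for one day.

    Immigrants are untreated adults (no damage) at ultimate size and
    mid-reproductive age, Poisson in number.  Each resident adult
    emigrates with the daily emigration fraction — or with the trigger
    fraction (default 0.95) once the plant exceeds the mainstem-node
    threshold (default 22).  Returns (n_immigrants, n_emigrants).
    """
    comp = derive_compound_params(params)
    if immigration_today is None:
        immigration_today = float(config.daily_immigration()[day])
    n_imm = int(rng.poisson(immigration_today)) if immigration_today > 0 else 0
    if n_imm:
        pop.add(**_make_adults(n_imm, params, comp, rng, config.immigrant_sex))
    if plant_state.nodes > config.emigration_trigger_nodes:
        p_leave = config.emigration_trigger_fraction
    else:
        p_leave = config.emigration_rate
    n_em = 0
    if p_leave > 0 and pop.n:
        adults = (pop.stage[: pop.n] == int(Stage.ADULT)) & pop.alive[: pop.n]
        idx = np.nonzero(adults)[0]
        if len(idx):
            leaving = rng.random(len(idx)) < p_leave
            pop.alive[idx[leaving]] = False
            n_em = int(leaving.sum())
    return n_imm, n_em


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all parameter blocks one simulation needs."""

    deb: DEBParams
    tktd: TKTDParams
    whitefly_resp: TemperatureResponse
    cotton_resp: TemperatureResponse
    plant: PlantParams
    k_dec_ref: float = 0.042
    #: apply the bioassay survival onset delay to immature uptake in
    #: the population model.  Off by default: the delay aggregates egg
    #: hatching and crawler settlement of treated eggs, which the IBM
    #: resolves mechanistically through its explicit egg stage, so the
    #: shift would wrongly shelter nymphs already settled and feeding
    #: at application time.
    apply_onset_delay_immatures: bool = False


def _immature_profile(profile: ExposureProfile, tau: float,
                      horizon: int) -> np.ndarray:
    """Exposure input for immature uptake: the profile shifted by the
    survival onset delay (linear interpolation on the daily grid)."""
    days = np.arange(horizon, dtype=float)
    return np.interp(days - tau, profile.days.astype(float), profile.C,
                     left=0.0, right=0.0)


def simulate(config: ScenarioConfig, rep_seed, params: ModelParams,
             ) -> PopulationTrajectory:
    """Run one replicate of the daily loop.

    Per day: (1) temperature correction, (2) exposure and damage
    update, (3) DEB update and stage transitions (inside one kernel
    call with (2)), (4) mortality draws, (5) reproduction — viable
    eggs enter the population, (6) migration, (7) plant growth,
    (8) recording.  Deterministic given (config, rep_seed).
    """
    bad = config.validate()
    if bad:
        raise ValueError("invalid scenario: " + "; ".join(bad))
    deb_p = params.deb
    comp = derive_compound_params(deb_p)
    if isinstance(rep_seed, np.random.SeedSequence):
        rng = np.random.Generator(np.random.PCG64(rep_seed))
        key = (rep_seed.spawn_key[-1] if rep_seed.spawn_key
               else rep_seed.entropy)
        seed_label = int(key) if isinstance(key, (int, np.integer)) else -1
    else:
        rng = np.random.Generator(np.random.PCG64(rep_seed))
        seed_label = int(rep_seed)

    horizon = config.horizon
    temps = np.asarray(config.temps, dtype=float)[:horizon]
    c_T_wf = np.asarray(
        arrhenius_factor(temps, params.whitefly_resp), dtype=float)
    profile = build_exposure_profile(config.applications, temps,
                                     params.k_dec_ref, params.cotton_resp)
    if params.apply_onset_delay_immatures:
        C_imm = _immature_profile(profile, params.tktd.tau_surv, horizon)
    else:
        C_imm = profile.C
    C_adult = profile.C
    immigration = config.daily_immigration()
    hazard_mult = config.daily_hazard_multiplier()

    pop = initialize_population(config, rng, deb_p)
    plant_state = PlantState(leaf_area=params.plant.leaf_area_0,
                             nodes=params.plant.nodes_0)

    n_stages = len(Stage)
    counts = np.zeros((horizon + 1, n_stages), dtype=np.int64)
    leaf = np.zeros(horizon + 1)
    nodes = np.zeros(horizon + 1)
    expo = np.zeros(horizon + 1)
    counts[0] = pop.count_stages()
    leaf[0], nodes[0] = plant_state.leaf_area, plant_state.nodes
    expo[0] = 0.0

    e0_egg = comp.E_0 / (deb_p.E_m * deb_p.L_egg**3)

    for day in range(horizon):
        c_T = float(c_T_wf[day])
        n = pop.n
        if n:
            sl = slice(0, n)
            (pop.e[sl], pop.L[sl], pop.E_H[sl], pop.E_R[sl], pop.q[sl],
             pop.h_age[sl], pop.D[sl], pop.stage[sl], starved) = \
                integrate_states(
                    pop.e[sl], pop.L[sl], pop.E_H[sl], pop.E_R[sl],
                    pop.q[sl], pop.h_age[sl], pop.D[sl], pop.stage[sl],
                    f=config.f, c_T=c_T, C_imm=float(C_imm[day]),
                    C_adult=float(C_adult[day]), dt=1.0,
                    substeps=config.substeps, params=deb_p, comp=comp,
                    tktd_params=params.tktd)
            pop.age[sl] += 1.0

            # (4) mortality: background + aging + toxicant hazards
            stage_arr = pop.stage[sl]
            alive = pop.alive[sl]
            immature = stage_arr < int(Stage.ADULT)
            excess = np.maximum(0.0, pop.D[sl] - params.tktd.z)
            # killing rate is a rate constant: temperature-corrected
            h_tox = np.where(immature, params.tktd.b_h * c_T * excess, 0.0)
            h_bg = np.where(immature,
                            deb_p.h_b_nymph * c_T * hazard_mult[day], 0.0)
            h_bg = np.where(immature & starved,
                            h_bg + deb_p.starvation_hazard * c_T, h_bg)
            h_aging = np.where(immature, 0.0, pop.h_age[sl])
            p_die = 1.0 - np.exp(-(h_bg + h_aging + h_tox))
            dying = alive & (rng.random(n) < p_die)
            pop.alive[sl][dying] = False
            n_deaths = int(dying.sum())

            # (5) reproduction by adult females
            females = (alive & ~dying & (stage_arr == int(Stage.ADULT))
                       & (pop.sex[sl] == FEMALE))
            n_births = 0
            if np.any(females):
                idx = np.nonzero(females)[0]
                s_sub = params.tktd.c_s * excess[idx]
                cost = comp.E_0 * (1.0 + s_sub) / deb_p.kap_R
                n_prod = pop.E_R[sl][idx] / cost
                spawning = n_prod >= 1.0
                mean_viable = np.where(spawning,
                                       n_prod * np.exp(-s_sub), 0.0)
                eggs = rng.poisson(mean_viable)
                pop.E_R[sl][idx[spawning]] = 0.0
                n_births = int(eggs.sum())
                if n_births:
                    sexes = np.where(rng.random(n_births) < deb_p.sex_ratio,
                                     FEMALE, MALE)
                    pop.add(e=np.full(n_births, e0_egg),
                            L=np.full(n_births, deb_p.L_egg),
                            E_H=np.zeros(n_births),
                            stage=np.full(n_births, int(Stage.EGG),
                                          dtype=np.int8),
                            sex=sexes, age=np.zeros(n_births))
        else:
            n_deaths = n_births = 0

        # (6) migration
        n_imm, n_em = migration_step(pop, config, plant_state, day, rng,
                                     deb_p, float(immigration[day]))

        # (7) plant growth
        plant_state = step_plant(plant_state, float(temps[day]),
                                 plant_resp=params.cotton_resp,
                                 params=params.plant)

        # (8) record + integer conservation audit
        day_counts = pop.count_stages()
        total_prev = int(counts[day].sum())
        total_now = int(day_counts.sum())
        if total_now != total_prev + n_births + n_imm - n_deaths - n_em:
            raise AssertionError(
                f"day {day}: population bookkeeping violated "
                f"({total_prev} + {n_births} births + {n_imm} immigrants "
                f"- {n_deaths} deaths - {n_em} emigrants != {total_now})")
        counts[day + 1] = day_counts
        leaf[day + 1] = plant_state.leaf_area
        nodes[day + 1] = plant_state.nodes
        expo[day + 1] = C_adult[day]

        # keep the array dense: drop dead slots when they dominate
        if pop.n > 512 and pop.alive[: pop.n].sum() < 0.5 * pop.n:
            pop.compact()

    totals = counts.sum(axis=1)
    return PopulationTrajectory(counts=counts, totals=totals, leaf_area=leaf,
                                nodes=nodes, exposure=expo,
                                replicate=0, seed=seed_label)


def monte_carlo(config: ScenarioConfig, n_reps: int | None = None,
                params: ModelParams | None = None,
                keep_trajectories: bool = False) -> dict:
    """Run independent replicates and summarize per-day quantiles.

    Replicate seeds are spawned from the master seed in ``config``.
    Returns a dict with per-day 2.5/50/97.5% quantiles of the
    per-stage counts (arrays of shape (horizon+1, n_stages)) and of
    the totals, plus the trajectories when requested.
    """
    if params is None:
        raise TypeError("params is required")
    if n_reps is None:
        n_reps = config.n_reps
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(n_reps)
    trajs = []
    all_counts = np.zeros((n_reps, config.horizon + 1, len(Stage)),
                          dtype=np.int64)
    for rep, child in enumerate(children):
        traj = simulate(config, child, params)
        traj.replicate = rep
        all_counts[rep] = traj.counts
        if keep_trajectories:
            trajs.append(traj)
    qs = np.quantile(all_counts, [0.025, 0.5, 0.975], axis=0)
    totals = all_counts.sum(axis=2)
    tq = np.quantile(totals, [0.025, 0.5, 0.975], axis=0)
    out = {
        "counts_lo": qs[0], "counts_median": qs[1], "counts_hi": qs[2],
        "totals_lo": tq[0], "totals_median": tq[1], "totals_hi": tq[2],
        "n_reps": n_reps,
    }
    if keep_trajectories:
        out["trajectories"] = trajs
    return out


def efficacy(treated_counts, control_counts):
    """Abbott-style efficacy in percent: (1 - treated/control) * 100.

    Elementwise; undefined where the control count is zero (NaN, never
    an exception, so batch evaluation survives empty controls).
    """
    treated = np.asarray(treated_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (1.0 - treated / control) * 100.0
    out = np.where(control > 0, out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def efficacy_map(base_config: ScenarioConfig, temperatures,
                 second_application_days, params: ModelParams,
                 rate: float = 12.0, water_volume: float = 300.0,
                 evaluation_lag: int = 14, scope: str = "nymphs",
                 n_reps: int | None = None,
                 first_application_day: int = 0) -> np.ndarray:
    """Median efficacy for a (temperature x second-application-day) grid.

    For each cell, a control and a two-application treatment arm run
    at constant temperature; efficacy is computed on the median counts
    of the chosen scope ('nymphs' or 'total') ``evaluation_lag`` days
    after the second application.  Returns an array of shape
    (len(temperatures), len(second_application_days)).
    """
    temperatures = list(temperatures)
    day2_list = [int(d) for d in second_application_days]
    if not temperatures or not day2_list:
        raise ValueError("temperature and day grids must be non-empty")
    if scope not in ("nymphs", "total"):
        raise ValueError("scope must be 'nymphs' or 'total'")
    n_reps = n_reps if n_reps is not None else base_config.n_reps
    horizon = max(day2_list) + evaluation_lag + 1
    out = np.full((len(temperatures), len(day2_list)), np.nan)
    for i, T in enumerate(temperatures):
        temps = tuple([float(T)] * horizon)
        control_cfg = replace(base_config, horizon=horizon, temps=temps,
                              applications=())
        control = monte_carlo(control_cfg, n_reps, params)
        for j, day2 in enumerate(day2_list):
            apps = (ApplicationEvent(day=first_application_day, rate=rate,
                                     water_volume=water_volume),
                    ApplicationEvent(day=day2, rate=rate,
                                     water_volume=water_volume))
            treated_cfg = replace(base_config, horizon=horizon, temps=temps,
                                  applications=apps)
            treated = monte_carlo(treated_cfg, n_reps, params)
            t_eval = day2 + evaluation_lag
            if scope == "nymphs":
                idx = [int(s) for s in NYMPH_STAGES]
                c = control["counts_median"][t_eval, idx].sum()
                t = treated["counts_median"][t_eval, idx].sum()
            else:
                c = control["totals_median"][t_eval]
                t = treated["totals_median"][t_eval]
            out[i, j] = efficacy(t, c)
    return out
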