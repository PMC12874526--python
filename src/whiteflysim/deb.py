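"""Per-individual dynamic energy budget (DEB) model for *Bemisia tabaci*.

Each whitefly is a DEB 'abp' individual: a standard-DEB energy budget
with metabolic acceleration between birth (egg hatching) and puberty
(adult emergence), after which growth ceases.  Assimilated energy
enters a reserve; mobilized reserve is split by the kappa rule between
soma (somatic maintenance + growth) and the maturity/reproduction
branch (maturity maintenance + maturation in immatures, reproduction
buffer in adult females).  Aging follows the standard DEB aging module
(damage-induced damage with Gompertz stress), and immatures carry an
additional background hazard.

State variables per individual: structural length ``L`` (cm), scaled
reserve density ``e`` (dimensionless), maturity ``E_H`` (J),
reproduction buffer ``E_R`` (J), aging acceleration ``q`` (1/d^2),
aging hazard ``h_age`` (1/d), plus scaled damage ``D`` from the
toxicant module, age, stage, sex, and an alive flag.

Eggs do not feed (they burn the maternal reserve ``E_0``), and neither
does the pseudopupa.  The initial egg reserve ``E_0`` is not a free
parameter: it is solved by bisection so that the scaled reserve
density equals the (maximal) functional response at hatching.

All rate constants are defined at the reference temperature of the
insect temperature response and are multiplied by the Arrhenius
factor ``c_T``; the aging acceleration ``h_a`` (1/d^2) scales with
``c_T`` squared.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from functools import lru_cache
from typing import NamedTuple

import numpy as np

__all__ = [
    "Stage",
    "DEBParams",
    "Individual",
    "CompoundParams",
    "derive_compound_params",
    "deb_derivatives",
    "step_individual",
    "classify_stage",
    "daily_death_probability",
    "spawn_viable_eggs",
]


class Stage(IntEnum):
    """Life stages; transitions only move forward.

    Hatching (EGG -> N1) happens when maturity reaches ``E_Hb``;
    emergence (-> ADULT) when it reaches ``E_Hp``.  The three nymphal
    instars and the pseudopupa are delimited by structural length.
    """

    EGG = 0
    N1 = 1
    N2 = 2
    N3 = 3
    PSEUDOPUPA = 4
    ADULT = 5


#: stages that ingest food (assimilation active)
FEEDING_STAGES = (Stage.N1, Stage.N2, Stage.N3, Stage.ADULT)

FEMALE = 0
MALE = 1


@dataclass(frozen=True)
class DEBParams:
    """Primary DEB 'abp' parameters at reference temperature.

    Energies in J, lengths in cm, times in days.
    """

    p_Am: float          # max surface-specific assimilation, J/(cm^2 d)
    v: float             # energy conductance, cm/d
    kappa: float         # allocation fraction to soma
    p_M: float           # volume-specific somatic maintenance, J/(cm^3 d)
    k_J: float           # maturity maintenance rate, 1/d
    E_G: float           # volume-specific cost of structure, J/cm^3
    E_Hb: float          # maturity at birth (hatching), J
    E_Hp: float          # maturity at puberty (emergence), J
    kap_R: float         # reproduction efficiency
    h_a: float           # Weibull aging acceleration, 1/d^2
    s_G: float           # Gompertz stress coefficient
    h_b_nymph: float     # background hazard for immatures, 1/d
    instar_lengths: tuple[float, float, float]  # N1|N2, N2|N3, N3|pseudopupa (cm)
    L_egg: float = 4e-3  # initial structural length of a freshly laid egg, cm
    sex_ratio: float = 0.5  # probability an egg is female
    starvation_hazard: float = 0.5  # extra hazard (1/d) for starving immatures

    def validate(self) -> list[str]:
        out = []
        for name in ("p_Am", "v", "p_M", "k_J", "E_G", "E_Hb", "E_Hp",
                     "kap_R", "h_a", "s_G", "h_b_nymph", "L_egg"):
            if getattr(self, name) < 0:
                out.append(f"{name}: must be >= 0")
        if not 0 < self.kappa < 1:
            out.append("kappa: must lie in (0, 1)")
        if self.E_Hb >= self.E_Hp:
            out.append("E_Hb: must be smaller than E_Hp")
        if list(self.instar_lengths) != sorted(self.instar_lengths):
            out.append("instar_lengths: must be strictly increasing")
        return out

    # -- frequently used compound quantities -------------------------
    @property
    def E_m(self) -> float:
        """Maximum reserve density, J/cm^3."""
        return self.p_Am / self.v

    @property
    def g(self) -> float:
        """Energy investment ratio."""
        return self.E_G * self.v / (self.kappa * self.p_Am)

    @property
    def L_m(self) -> float:
        """Maximum structural length without acceleration, cm."""
        return self.kappa * self.p_Am / self.p_M


@dataclass
class Individual:
    """One whitefly: DEB state plus damage, aging, and bookkeeping."""

    L: float             # structural length, cm
    e: float             # scaled reserve density
    E_H: float           # maturity, J
    E_R: float = 0.0     # reproduction buffer, J
    D: float = 0.0       # scaled damage, units of corrected application rate
    q: float = 0.0       # aging acceleration, 1/d^2
    h_age: float = 0.0   # aging hazard, 1/d
    age: float = 0.0     # days since egg deposition
    stage: Stage = Stage.EGG
    sex: int = FEMALE
    alive: bool = True
    egg_fraction: float = 0.0  # deterministic spawn carry-over accumulator


class CompoundParams(NamedTuple):
    """Quantities derived once from :class:`DEBParams` at f = 1."""

    E_0: float     # initial reserve energy in an egg, J
    L_b: float     # structural length at birth, cm
    L_p: float     # structural length at puberty, cm
    s_M_max: float  # maximum acceleration factor L_p / L_b
    t_b: float     # egg duration at reference temperature, d
    t_p: float     # age at emergence at reference temperature, d


def _acceleration(L, params: DEBParams, comp: CompoundParams):
    """Metabolic acceleration s_M, ramping from 1 at birth to its
    maximum at puberty (abp: frozen thereafter)."""
    return np.clip(np.asarray(L, dtype=float) / comp.L_b, 1.0, comp.s_M_max)


def deb_derivatives(e, L, E_H, E_R, q, h_age, *, feeding, adult, f, c_T,
                    params: DEBParams, comp: CompoundParams):
    """Instantaneous per-day rates of (e, L, E_H, E_R, q, h_age).

    Elementwise on arrays.  ``feeding`` and ``adult`` are boolean masks;
    non-feeding stages (egg, pseudopupa) run with f = 0.  Adults do not
    grow; their full mobilized flux net of both maintenances accrues to
    the reproduction buffer.  Also returns the mobilization flux and
    its uses so energy-balance checks can audit the kappa rule.

    Returns a dict with rate and flux arrays.
    """
    e = np.asarray(e, dtype=float)
    L = np.asarray(L, dtype=float)
    E_H = np.asarray(E_H, dtype=float)
    q = np.asarray(q, dtype=float)
    h_age = np.asarray(h_age, dtype=float)
    feeding = np.asarray(feeding, dtype=bool)
    adult = np.asarray(adult, dtype=bool)

    g = params.g
    s_M = _acceleration(L, params, comp)
    v_T = params.v * s_M * c_T            # accelerated, temperature-corrected
    f_eff = np.where(feeding, f, 0.0)

    de = (f_eff - e) * v_T / L

    # growth: dL/dt = v_T/(3(e+g)) * (e - L/(L_m s_M)); non-negative
    # (structure is not burned under starvation), zero in adults
    l_hat = L / (params.L_m * s_M)
    dL = v_T / (3.0 * (e + g)) * (e - l_hat)
    dL = np.where(adult | (dL < 0.0), 0.0, dL)
    r = 3.0 * dL / L                      # specific growth rate, 1/d

    # mobilization p_C = E (v_T/L - r) with E = E_m e L^3
    E = params.E_m * e * L**3
    p_C = E * (v_T / L - r)
    p_S = params.p_M * c_T * L**3         # somatic maintenance
    p_J = params.k_J * c_T * np.minimum(E_H, params.E_Hp)  # maturity maint.
    p_G = params.E_G * 3.0 * L**2 * dL    # growth investment

    # maturation / reproduction from the (1-kappa) branch; adults also
    # receive the somatic surplus since growth has ceased
    p_R = p_C - p_S - p_J - p_G           # what is left after all sinks
    dE_H = np.where(adult, 0.0, np.maximum(0.0, p_R))
    dE_R = np.where(adult, p_R, 0.0)

    # starving: kappa-branch cannot cover somatic maintenance
    starving = params.kappa * p_C < p_S

    # standard DEB aging, all rates temperature-corrected
    V_ratio = (L / (params.L_m * comp.s_M_max)) ** 3
    mob_specific = e * (v_T / L - r)
    dq = (q * V_ratio * params.s_G + params.h_a * c_T**2) * mob_specific - r * q
    dh = q - r * h_age

    return {
        "de": de, "dL": dL, "dE_H": dE_H, "dE_R": dE_R, "dq": dq, "dh": dh,
        "p_C": p_C, "p_S": p_S, "p_J": p_J, "p_G": p_G, "p_R": p_R,
        "starving": starving, "s_M": s_M,
    }


#: lookup tables indexed by Stage value
_FEEDING_LUT = np.zeros(len(Stage), dtype=bool)
for _s in FEEDING_STAGES:
    _FEEDING_LUT[int(_s)] = True


def classify_stage_array(E_H, L, params: DEBParams, prior):
    """Vectorized stage classification; never moves backward."""
    E_H = np.asarray(E_H, dtype=float)
    L = np.asarray(L, dtype=float)
    prior = np.asarray(prior, dtype=np.int8)
    thresholds = np.asarray(params.instar_lengths, dtype=float)
    nymph = np.int8(Stage.N1) + np.searchsorted(
        thresholds, L, side="right").astype(np.int8)
    stage = np.where(E_H < params.E_Hb, np.int8(Stage.EGG), nymph)
    stage = np.where(E_H >= params.E_Hp, np.int8(Stage.ADULT), stage)
    return np.maximum(stage, prior)


def integrate_states(e, L, E_H, E_R, q, h_age, D, stage, *, f, c_T,
                     C_imm, C_adult, dt, substeps, params: DEBParams,
                     comp: CompoundParams, tktd_params):
    """Advance DEB states and damage of a cohort by ``dt`` days.

    All state arguments are numpy arrays of equal length (``stage`` as
    integer codes); they are advanced in place semantics-free (new
    arrays returned).  Reserve density and damage use their exact
    within-substep exponential solutions; structure, maturity, the
    reproduction buffer, and the aging states use Heun's method.
    ``C_imm`` / ``C_adult`` are the damage-driving concentrations for
    immature and adult uptake (the immature one already carries the
    survival onset delay).  Returns the updated arrays, plus a boolean
    'starved' mask flagging individuals whose kappa-branch mobilization
    fell short of somatic maintenance at any substep.
    """
    from .tktd import update_damage

    e = np.array(e, dtype=float)
    L = np.array(L, dtype=float)
    E_H = np.array(E_H, dtype=float)
    E_R = np.array(E_R, dtype=float)
    q = np.array(q, dtype=float)
    h_age = np.array(h_age, dtype=float)
    D = np.array(D, dtype=float)
    stage = np.array(stage, dtype=np.int8)
    starved = np.zeros(e.shape, dtype=bool)

    exposed_lut = np.zeros(len(Stage), dtype=bool)
    for s in tktd_params.exposed_stages:
        exposed_lut[int(s)] = True

    h = dt / substeps
    for _ in range(substeps):
        feeding = _FEEDING_LUT[stage]
        adult = stage == np.int8(Stage.ADULT)
        s_M = np.clip(L / comp.L_b, 1.0, comp.s_M_max)
        v_T = params.v * s_M * c_T
        f_eff = np.where(feeding, f, 0.0)
        e = f_eff + (e - f_eff) * np.exp(-v_T * h / L)

        r1 = deb_derivatives(e, L, E_H, E_R, q, h_age, feeding=feeding,
                             adult=adult, f=f, c_T=c_T, params=params,
                             comp=comp)
        L1 = L + r1["dL"] * h
        EH1 = E_H + r1["dE_H"] * h
        ER1 = E_R + r1["dE_R"] * h
        q1 = q + r1["dq"] * h
        ha1 = h_age + r1["dh"] * h
        r2 = deb_derivatives(e, L1, EH1, ER1, q1, ha1, feeding=feeding,
                             adult=adult, f=f, c_T=c_T, params=params,
                             comp=comp)
        L = L + 0.5 * h * (r1["dL"] + r2["dL"])
        E_H = E_H + 0.5 * h * (r1["dE_H"] + r2["dE_H"])
        E_R = E_R + 0.5 * h * (r1["dE_R"] + r2["dE_R"])
        q = q + 0.5 * h * (r1["dq"] + r2["dq"])
        h_age = h_age + 0.5 * h * (r1["dh"] + r2["dh"])
        starved |= np.asarray(r1["starving"])

        exposed = exposed_lut[stage]
        C_drive = np.where(adult, C_adult, C_imm)
        D = update_damage(D, C_drive, tktd_params.k_d, c_T, exposed, h)
        stage = classify_stage_array(E_H, L, params, stage)
    return e, L, E_H, E_R, q, h_age, D, stage, starved


def classify_stage(E_H, L, params: DEBParams, prior: Stage) -> Stage:
    """Stage from maturity and length; never moves backward.

    Egg below ``E_Hb``, adult at or above ``E_Hp``; in between the
    nymphal instars and the pseudopupa are delimited by structural
    length with a half-open [low, high) convention (a length exactly
    at a threshold belongs to the later instar).
    """
    if E_H >= params.E_Hp:
        return Stage.ADULT
    if E_H < params.E_Hb:
        stage = Stage.EGG
    else:
        lo, mid, hi = params.instar_lengths
        if L < lo:
            stage = Stage.N1
        elif L < mid:
            stage = Stage.N2
        elif L < hi:
            stage = Stage.N3
        else:
            stage = Stage.PSEUDOPUPA
    return max(stage, prior)


def step_individual(ind: Individual, env, dt: float = 1.0,
                    substeps: int = 24, params: DEBParams | None = None,
                    tktd_params=None) -> Individual:
    """Advance one individual by ``dt`` days (deterministic).

    ``env`` is a tuple ``(f, c_T, C_eff)`` of functional response,
    temperature correction, and effective exposure concentration
    driving damage uptake (pass 0 for unexposed conditions; the same
    concentration is used whether the individual is immature or
    adult).  Thin wrapper around the vectorized population kernel, so
    single-individual and population trajectories are bit-identical.
    """
    from .tktd import TKTDParams

    if params is None:
        raise TypeError("params is required")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    comp = derive_compound_params(params)
    f, c_T, C_eff = env
    if tktd_params is None:
        tktd_params = TKTDParams()

    arrays = [np.array([x], dtype=float) for x in
              (ind.e, ind.L, ind.E_H, ind.E_R, ind.q, ind.h_age, ind.D)]
    stage_arr = np.array([int(ind.stage)], dtype=np.int8)
    e, L, E_H, E_R, q, h_age, D, stage_arr, _ = integrate_states(
        *arrays, stage_arr, f=f, c_T=c_T, C_imm=C_eff, C_adult=C_eff,
        dt=dt, substeps=substeps, params=params, comp=comp,
        tktd_params=tktd_params)
    for name, value in (("e", e), ("L", L), ("E_H", E_H), ("E_R", E_R),
                        ("q", q), ("h_age", h_age), ("D", D)):
        if not np.isfinite(value[0]):
            raise FloatingPointError(
                f"non-finite state variable {name!r} after step")
    return replace(ind, e=float(e[0]), L=float(L[0]), E_H=float(E_H[0]),
                   E_R=float(E_R[0]), q=float(q[0]), h_age=float(h_age[0]),
                   D=float(D[0]), age=ind.age + dt,
                   stage=Stage(int(stage_arr[0])))


def daily_death_probability(ind: Individual, h_tox: float, c_T: float,
                            params: DEBParams, starving: bool = False) -> float:
    """Probability of dying within one day.

    Immatures: temperature-corrected background hazard (plus a
    starvation hazard when flagged); adults: aging hazard.  The
    toxicant hazard adds on top.  p = 1 - exp(-h_total * 1 d).
    """
    if ind.stage is Stage.ADULT:
        h_bg = ind.h_age
    else:
        h_bg = params.h_b_nymph * c_T
        if starving:
            h_bg = h_bg + params.starvation_hazard * c_T
    h_total = h_bg + h_tox
    return float(1.0 - np.exp(-h_total * 1.0))


def spawn_viable_eggs(adult: Individual, s_repro: float, s_embryo: float,
                      c_T: float, rng: np.random.Generator | None,
                      params: DEBParams,
                      embryo_mapping: str = "exponential") -> tuple[int, Individual]:
    """Convert the reproduction buffer into viable eggs.

    The energetic cost of one egg is ``E_0' = E_0 (1 + s_repro)`` —
    the 'increased reproduction costs' mode of action inflates the
    per-egg cost — paid from the buffer at efficiency ``kap_R``.  Each
    produced egg is viable with probability ``exp(-s_embryo)`` (the
    'hazard to embryos' mode of action; ``1/(1+s)`` available as an
    alternative mapping).  The realized viable count is Poisson with
    that mean; the buffer is debited for *all* eggs produced, viable
    or not.  With ``rng=None`` a deterministic carry-over accumulator
    replaces the Poisson draw (for tests and expectation checks).

    Returns ``(viable_egg_count, updated_individual)``.
    """
    if adult.stage is not Stage.ADULT or adult.sex != FEMALE or not adult.alive:
        return 0, adult
    comp = derive_compound_params(params)
    cost_per_egg = comp.E_0 * (1.0 + s_repro) / params.kap_R
    n_produced = adult.E_R / cost_per_egg
    if n_produced < 1.0:
        return 0, adult  # buffer keeps accruing
    if embryo_mapping == "exponential":
        viability = float(np.exp(-s_embryo))
    elif embryo_mapping == "hyperbolic":
        viability = 1.0 / (1.0 + s_embryo)
    else:
        raise ValueError(f"unknown embryo_mapping {embryo_mapping!r}")
    mean_viable = n_produced * viability
    if rng is None:
        total = mean_viable + adult.egg_fraction
        n_viable = int(total)
        frac = total - n_viable
    else:
        n_viable = int(rng.poisson(mean_viable))
        frac = adult.egg_fraction
    updated = replace(adult, E_R=0.0, egg_fraction=frac)
    return n_viable, updated


class _EggExhausted(RuntimeError):
    """Raised when an egg runs out of reserve before hatching."""


def _integrate_reference(params: DEBParams, E_0: float, dt: float = 2e-3,
                         until: str = "birth"):
    """Integrate the f = 1, c_T = 1 reference trajectory of an egg
    (and optionally the juvenile) with RK4 on (e, L, E_H).

    Acceleration needs L_b, which is only known at birth, so the egg
    phase runs unaccelerated (s_M = 1, exact for L <= L_b) and the
    juvenile phase uses s_M = L/L_b uncapped (exact until puberty).
    Returns (e, L, E_H, t) at the requested event.
    """
    g = params.g
    E_m = params.E_m

    def rhs(y, L_b):
        e, L, E_H = y
        s_M = 1.0 if L_b is None else max(1.0, L / L_b)
        v_T = params.v * s_M
        f = 0.0 if L_b is None else 1.0
        de = (f - e) * v_T / L
        dL = max(0.0, v_T / (3.0 * (e + g)) * (e - L / (params.L_m * s_M)))
        r = 3.0 * dL / L
        p_C = E_m * e * L**3 * (v_T / L - r)
        dE_H = max(0.0, p_C - params.p_M * L**3 - params.k_J * E_H
                   - params.E_G * 3.0 * L**2 * dL)
        return np.array([de, dL, dE_H])

    def rk4(y, L_b):
        k1 = rhs(y, L_b)
        k2 = rhs(y + 0.5 * dt * k1, L_b)
        k3 = rhs(y + 0.5 * dt * k2, L_b)
        k4 = rhs(y + dt * k3, L_b)
        return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    L0 = params.L_egg
    y = np.array([E_0 / (E_m * L0**3), L0, 0.0])
    t = 0.0
    # egg phase; an exhausted reserve (e << 1) means E_0 was too small
    while y[2] < params.E_Hb:
        y = rk4(y, None)
        t += dt
        if y[0] < 0.05 or t > 200.0:
            raise _EggExhausted(t)
    if until == "birth":
        return y[0], y[1], y[2], t
    L_b = y[1]
    while y[2] < params.E_Hp:
        y = rk4(y, L_b)
        t += dt
        if t > 500.0:
            raise RuntimeError("juvenile did not reach E_Hp within 500 d")
    return y[0], y[1], y[2], t


@lru_cache(maxsize=8)
def derive_compound_params(params: DEBParams) -> CompoundParams:
    """Solve E_0 (bisection: scaled reserve density equals 1 at
    hatching under f = 1) and the birth/puberty lengths and times."""

    def e_at_birth(E_0):
        try:
            e_b, _, _, _ = _integrate_reference(params, E_0)
        except _EggExhausted:
            return -1.0  # reserve ran out: E_0 too small
        return e_b - 1.0

    lo = params.E_m * params.L_egg**3 * 2.0
    hi = params.E_m * params.L_m**3
    while e_at_birth(hi) < 0:
        hi *= 4.0
        if hi > 1e6:
            raise RuntimeError("failed to bracket E_0")
    while e_at_birth(lo) > 0:
        lo *= 0.5
        if lo < 1e-12:
            raise RuntimeError("failed to bracket E_0")
    from scipy.optimize import brentq

    E_0 = brentq(e_at_birth, lo, hi, xtol=1e-10, rtol=1e-9)
    _, L_b, _, t_b = _integrate_reference(params, E_0, until="birth")
    _, L_p, _, t_p = _integrate_reference(params, E_0, until="puberty")
    return CompoundParams(E_0=float(E_0), L_b=float(L_b), L_p=float(L_p),
                          s_M_max=float(L_p / L_b), t_b=float(t_b),
                          t_p=float(t_p))
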