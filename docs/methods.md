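# Methods

This note documents the model equations, the meaning and provenance of
the shipped default parameters, the numerical scheme, what the
synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## 1. Temperature correction

Every rate constant in the model is defined at a reference temperature
and multiplied by a five-parameter Arrhenius factor

```
c_T(T) = exp(T_A/T_ref − T_A/T) · s(T_ref)/s(T)
s(T)   = 1 + exp(T_AL/T − T_AL/T_L) + exp(T_AH/T_H − T_AH/T)
```

with the lower/upper boundary terms dropped according to the response
mode. The normalization by `s(T_ref)` makes `c_T(T_ref) = 1` exact by
construction. Public interfaces take °C; Kelvin is internal.

Two responses ship:

* **whitefly** (both boundaries): `T_ref = 296.15 K` (23 °C, the
  greenhouse bioassay temperature, so trial-scale rate constants apply
  at face value), `T_A = 9500 K`, `T_L = 286.15 K`, `T_AL = 35000 K`,
  `T_H = 309.15 K`, `T_AH = 100000 K`. These are calibrated defaults
  chosen to reproduce the published thermal biology of *B. tabaci*:
  egg-to-adult ≈ 25 d at 23 °C, ≈ 20 d at 25 °C, ≈ 12 d at 30 °C,
  fastest development near 33–34 °C, steep decline above 35 °C.
* **cotton** (upper boundary only): `T_ref = 291.794 K`,
  `T_A = 23161.4 K`, `T_H = 302.745 K`, `T_AH = 100000 K`. Solved so
  that (i) the temperature-corrected leaf-area growth rate peaks at
  exactly 28.5 °C on a 0.1 °C grid, (ii) the exposure half-life at
  23 °C is 5.14 d (within the "approximately 5.5 d" band), and
  (iii) the minimum half-life is 1.61 d (within the "approximately
  1.5 d" band). The three anchors jointly demand a ~3.2–3.7-fold rate
  rise over only 5.5 °C, which this functional family can only deliver
  with a steep flank on both sides of the optimum; among the exactly
  solving parameter sets we ship the flattest-topped one (smallest
  `T_AH` that still brackets), which keeps the half-life at 30 °C at
  2.2 d. A flatter curve with a ~1.5 d half-life at 30 °C is not
  attainable in this family together with the 23 °C anchor; this is a
  known limitation of the shipped response above ~31 °C, where both
  plant growth and residue decay are likely understated.

## 2. The DEB 'abp' individual

States: structural length `L` (cm), scaled reserve density `e`,
maturity `E_H` (J), reproduction buffer `E_R` (J), aging states
`(q, h_age)`, scaled damage `D`, age, stage, sex.

Dynamics (all rates × `c_T`; `s_M = clip(L/L_b, 1, L_p/L_b)` is the
metabolic acceleration, frozen at its maximum after emergence):

* reserve: `de/dt = (f − e)·v·s_M/L`, with `f = 0` for the two
  non-feeding stages (egg, pseudopupa);
* growth: `dL/dt = v·s_M/(3(e+g))·(e − L/(L_m·s_M))`, clamped at zero
  (structure is never burned) and identically zero in adults;
* mobilization `p_C = E·(v·s_M/L − r)` with `E = E_m e L³` and
  `r = 3 dL/dt / L`; somatic maintenance `p_M L³` and growth
  `E_G dV/dt` are paid from the κ branch (the clamped-growth residual
  formulation keeps the kappa rule an exact identity when growth is
  interior);
* maturation: `dE_H/dt = (1−κ)p_C − k_J E_H` in immatures, clamped at
  zero (maturity never regresses); adults instead accrue
  `dE_R/dt = p_C − p_M L³ − k_J E_Hp` (growth has ceased, so the
  somatic surplus joins the reproduction flux);
* aging: the standard DEB aging module,
  `dq/dt = (q (V/V_m) s_G + c_T² h_a) e (v·s_M·c_T/L − r) − r q`,
  `dh/dt = q − r h`; `h_a` carries units d⁻² and therefore scales with
  `c_T²`.

Stages: egg below `E_Hb`; adult at or above `E_Hp`; between them three
nymphal instars and the pseudopupa delimited by structural length with
a half-open `[low, high)` convention. Transitions never move
backward. Hatching coincides with birth and adult emergence with
puberty.

The egg's initial reserve `E_0` is solved at import time by bisection
so that `e = 1` at hatching under `f = 1` (RK4 reference integration
at dt = 0.002 d); the same integration provides the birth and puberty
lengths `L_b`, `L_p` that anchor the acceleration factor. Because the
pseudopupa does not feed, the actual emergence length under the
stage-gated model (~0.051 cm) sits slightly below the `f = 1`
reference `L_p` (~0.052 cm); `E_Hp` was placed so that emergence
occurs ~2.5–3 d into the pseudopupa with ample reserve margin, making
emergence robust (temperature scales all rates equally, so the
e-versus-E_H path is temperature-invariant).

Mortality: immatures carry a background hazard `h_b_nymph·c_T`
(optionally multiplied by a piecewise daily factor) plus the toxicant
hazard and, when the κ branch cannot cover somatic maintenance, a
starvation hazard; adults die by aging (`h_age`). Daily death
probability is `1 − exp(−h_total)`.

Reproduction: each day a female's buffer converts to eggs at cost
`E_0(1+s_repro)/kap_R` per egg; the expected viable count is the
production times `exp(−s_embryo)` and the realized count is Poisson
(a deterministic carry-over accumulator is available for tests). The
buffer is debited for all eggs produced, viable or not. Sex is
Bernoulli(0.5) at egg creation.

### Default DEB parameters (calibrated)

`p_Am = 100 J cm⁻² d⁻¹`, `v = 0.007 cm d⁻¹`, `κ = 0.6`,
`p_M = 600 J cm⁻³ d⁻¹`, `k_J = 0.002 d⁻¹`, `E_G = 4400 J cm⁻³`,
`E_Hb = 0.03 J`, `E_Hp = 0.70 J`, `kap_R = 0.95`, `h_a = 2·10⁻³ d⁻²`,
`s_G = 10⁻⁴`, `h_b_nymph = 0.01 d⁻¹`, instar boundaries
`(0.026, 0.033, 0.045) cm`, `L_egg = 0.004 cm`.

These are calibrated defaults, tuned once to the published
life-history scale of *B. tabaci* on cotton and then frozen: egg
≈ 8 d and egg-to-adult ≈ 23 d at 23 °C (≈ 12 d at 30 °C); hatchling
structural length 0.0195 cm, emergence at ≈ 0.051 cm; instar
durations of roughly 4–5 d (N1), 4 d (N2), 4–5 d (N3) and ≈ 3 d
pseudopupa at 23 °C; ≈ 3 eggs female⁻¹ d⁻¹ at 23 °C rising to ≈ 6 at
30 °C; median adult lifespan ≈ 18 d at 23 °C, ≈ 9 d at 30 °C. The
energy scale (`p_Am`) is arbitrary — only ratios enter the dynamics —
and `E_0 ≈ 0.18 J` follows from the bisection.

## 3. Reduced TKTD module

One damage compartment in units of the corrected application rate:
`dD/dt = k_d·c_T·(C_eff − D)` while exposed, pure repair
`−k_d·c_T·D` otherwise. Effects are linear with a shared threshold:
lethal hazard `b_h·(D−z)⁺` (a rate, temperature-corrected) and the two
numerically identical sublethal stresses `c_s·(D−z)⁺` routed to
'increased reproduction costs' and 'hazard to embryos'. Exposed
stages: N1, N2, adults; eggs, N3, and pseudopupae do not feed on
treated sap. Damage persists across molts.

Defaults (calibrated, at 23 °C): `k_d = 0.6 d⁻¹`, `z = 2.5`,
`b_h = 0.15 (damage·d)⁻¹`, `c_s = 1.0 damage⁻¹`; onset delays
`τ_surv = 3.7 d`, `τ_fec = 0.6 d`, `τ_fert = 0.3 d`. The effect
parameters were chosen so that (i) the two lowest bioassay rates (1.5
and 3 g a.i./ha) sit below the effect threshold while 6–24 g a.i./ha
produce graded, identifiable survival curves at the 5/7/17-day
assessments; (ii) a single 12 g a.i./ha application against a
synchronized young population at 30 °C reduces the total population
about fourfold by day 20; and (iii) a second application after the
egg bank has hatched (day 12) outperforms an early one (day 6) in
nymph-scope efficacy — the demographic signature of an
egg-insensitive compound.

Delays are pure time shifts of the exposure input
(`C_eff(t) = C(t−τ)·1[t ≥ τ]`), not extra compartments. In the
**bioassay forward models** `τ_surv` applies to the treated-egg
cohorts (it aggregates residual egg development and crawler
settlement) and `τ_fec`/`τ_fert` to the caged adults (settlement in
the cage). In the **population model** no immature onset delay is
applied by default (`ModelParams.apply_onset_delay_immatures=False`):
the IBM resolves egg development explicitly, so the dominant component
of the delay is already mechanistic, and shifting the profile would
wrongly shelter nymphs that were settled and feeding at application
time. The switch restores the literal shift if wanted. Adults in the
field are assumed settled (no delay). Adults accumulate damage but
suffer only the sublethal modes of action; the lethal pathway applies
to immatures, where it was measured.

The embryo-hazard viability mapping is `exp(−s)` (a survival-fraction
reading of 'hazard to embryos'); `1/(1+s)` is available behind the
`embryo_mapping` argument.

## 4. Exposure

Each application contributes `rate × min(V, 300)/300` (water-volume
correction, linear to saturation at 300 L/ha) on its day —
start-of-day convention, full deposit before any decay — and decays by
`exp(−k_dec·c_T_plant(T_day))` per day with `k_dec = 0.042 d⁻¹` at the
plant reference temperature. Contributions add across events. The
laboratory cuticle-penetration model `P(t) = P_max(V)(1−e^{−k_up t})`
with `k_up = 0.25 h⁻¹` (95% of plateau at 12 h) and
`P_max(300) = 0.31` reproduces the saturation test; the IBM uses only
the water-volume factor, the absolute penetrated fraction being
test-specific.

## 5. Host plant

Logistic leaf-area growth (`r_leaf = 0.018 d⁻¹` at reference,
maximum 12000 cm², seedling 60 cm²) and linear mainstem-node accrual
(`r_node = 0.034 d⁻¹`, seedling 2 nodes), both temperature-corrected
by the cotton response; the within-step logistic update is exact, so
results are invariant to splitting a day. Densities divide stage
counts by leaf area on a 3.88 cm² leaf-disc basis; adult densities use
a 20-disc default leaf area. Once nodes exceed 22, a 0.95 triggered
emigration fraction replaces the daily adult emigration rate,
emulating whitefly departure from maturing cotton. Plant parameters
are calibrated defaults reproducing seasonal canopy scale (~60 d to 22
nodes at the growth optimum).

## 6. The population engine

Population state is a structure of arrays; the whole population passes
through one vectorized kernel per substep. Daily order: temperature
correction → damage + DEB update with stage transitions (one kernel
call) → mortality draws → reproduction (viable eggs join the
population) → migration → plant growth → recording. Each day asserts
exact integer conservation
(`pop(t+1) = pop(t) + births + immigrants − deaths − emigrants`).

Initial populations are built from `(stage, count, length mean ± sd)`
groups: lengths are drawn from the normal truncated to the stage's
length bounds, and maturity is reconstructed from length via the
`f = 1` reference relation so intermediate states are consistent.
Immigrants are untreated females at ultimate size and mid-reproductive
age (aging states from the small-`s_G` closed form at five adult
days). All randomness flows from one master seed through
`SeedSequence`-spawned per-replicate streams; trajectories are
bit-identical for equal (config, seed). Monte Carlo summaries report
per-day 2.5/50/97.5% quantiles per stage; efficacy is
`(1 − treated/control)·100`, computed canonically on median counts
(per-replicate efficacies are available from the kept trajectories).

## 7. Numerics

Within each daily step the kernel takes `substeps` (default 12)
sub-steps: scaled reserve density and damage are updated with their
exact within-substep exponential solutions (hence the damage
discretization is error-free for constant daily concentration, and
adult reserve relaxation is exact at fixed length), while `L`, `E_H`,
`E_R`, `q`, `h_age` use Heun's method. Doubling the substeps moves a
30-day juvenile trajectory by < 0.1% in length. The egg phase is the
stiffest regime (relaxation rate `v·c_T/L`); the default initial egg
length of 0.004 cm keeps that rate below ~5 d⁻¹ so daily substepping
resolves it, and hatch timing at 8–24 substeps agrees to within one
day of the fine-step reference. Stage classification runs every
substep; ties at instar boundaries go to the later instar.

## 8. Bioassay forward models, likelihoods, and fitting

Trial 1 (survival): eggs treated at rates (24, 6, 3, 1.5, 0) g/ha,
cohorts of 40 × 3 replicates, assessed 5/7/17 d post-treatment at
23 °C. The damage pulse after the shifted onset has the closed form
`D(u) = C₀ k_d/(k_d−k_dec)(e^{−k_dec u} − e^{−k_d u})`; the hazard
integral is accumulated on a 0.01-d grid. The likelihood is
multinomial over interval deaths plus final survivors.

Trials 2/3 (fecundity/fertility): five females per cage for 24 h at
cohort offsets 0–3 d, against rate (Trial 2: 24/12/6/3/0 g/ha, fresh
residue) or residue age (Trial 3: 24 g/ha aged 1/7/9/14/21 d). Within
the caging window each sublethal pathway builds damage after its own
settlement delay; eggs laid follow `∫ 1/(1+s_fec) du` and the hatched
fraction is the laying-weighted mean of `exp(−s_fert)`. Egg counts
are Poisson (control fecundity 8 eggs female⁻¹ d⁻¹, a known design
constant), hatches binomial (control hatch 0.9). Background hazard is
treated as known (the DEB default), not fitted.

`fit_tktd` estimates (k_d, z, b_h, c_s, k_dec_ref, τ_surv, τ_fec,
τ_fert) simultaneously under the sharing constraints by multi-start
Nelder-Mead (Latin-hypercube starts over bounds, log transforms for
positive parameters, soft bound penalties), followed by a Powell
ridge-polish and a final simplex restart from the incumbent.

**Identifiability.** On synthetic data at shipped defaults with
cohort sizes ×5 and 20 starts, `k_d`, `z`, `k_dec_ref` are recovered
within ~±20% and the delays within ~±0.15 d across generator seeds.
The sublethal strength `c_s` rides a likelihood ridge with `τ_fert`
once `exp(−s)` saturates near zero in the high-damage cells, and is
the least identified quantity: point estimates can wander far along
the ridge at negligible likelihood cost. Interpreting fitted `c_s`
therefore requires profile likelihoods or informative marginal-dose
cells; the recovery test pins it only at a fixed generator seed.

## 9. What the synthetic generator does and does not emulate

`generate_synthetic_bioassay` draws observation noise (multinomial
deaths, Poisson eggs, binomial hatches) around the model's own
predicted means for the three trial designs. It emulates sampling
noise at the published design sizes, but not: between-replicate
overdispersion, cage or leaf effects, observer error in hatch
scoring, dose-preparation error, or any model misspecification.
Passing parameter-recovery tests therefore demonstrates estimator
correctness and design identifiability under the assumed error model,
not robustness of the trial designs to real-world noise.
Equivalently, the population-scenario checks (fourfold knockdown,
second-application timing) validate internal consistency of the
calibrated parameter set, not field transferability — the model
ignores density dependence, resistance, parasitism/predation beyond a
constant background hazard, spatial structure beyond one plant, and
within-day temperature variation (daily means only).

## 10. Open choices made

* Starvation: adults pay maintenance shortfalls from `E_R`; starving
  immatures get an extra hazard (0.5 d⁻¹, temperature-corrected).
  Under ad-libitum scenarios (`f = 1`) this matters only transiently
  for pseudopupae.
* Maturity maintenance is never diverted; maturation simply stalls
  when the (1−κ) branch cannot cover it.
* Males occupy counts and die by the same hazards; they have no other
  role. Immigrants default to all females (scenario egg-layers),
  switchable.
* Nymph scope for efficacy counts N1–N3 plus pseudopupa (all sessile
  immatures scored on leaf discs), excluding eggs.
* Trial-1 cohorts are treated as independent multinomials; the
  replicate structure carries no random effect.
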