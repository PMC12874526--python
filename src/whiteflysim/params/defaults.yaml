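# Shipped default parameters for the Bemisia tabaci DEB-TKTD-IBM.
#
# Temperatures in K inside the temperature blocks; energies in J,
# lengths in cm, rates per day, application rates in g a.i./ha.
#
# DEB and plant growth values are calibrated defaults: they were tuned
# once so that the model reproduces published B. tabaci life-history
# scales (egg ~7-9 d and egg-to-adult ~20-25 d at 23-25 C, fastest
# development near 33 C, hatchling structural length ~0.02 cm, adult
# ~0.05 cm, fecundity of a few eggs per female-day) and the reported
# exposure behaviour of spidoxamat in cotton (decay 0.042 /d at
# reference temperature, effective half-life ~5.5 d at 23 C with a
# minimum of ~1.5 d at the 28.5 C leaf-growth optimum).

temperature:
  whitefly:
    T_ref: 296.15        # 23 C, the greenhouse trial temperature
    T_A: 9500.0
    T_L: 286.15          # 13 C
    T_AL: 35000.0
    T_H: 309.15          # 36 C
    T_AH: 100000.0
    mode: both_boundaries
  cotton:
    T_ref: 291.7944      # 18.64 C; leaf growth peaks at 28.5 C
    T_A: 23161.37
    T_H: 302.7452
    T_AH: 100000.0
    mode: upper_only

deb:
  p_Am: 100.0            # J/(cm^2 d) surface-specific assimilation
  v: 0.007               # cm/d energy conductance
  kappa: 0.6             # allocation fraction to soma
  p_M: 600.0             # J/(cm^3 d) somatic maintenance
  k_J: 0.002             # 1/d maturity maintenance
  E_G: 4400.0            # J/cm^3 cost of structure
  E_Hb: 0.03             # J maturity at hatching
  E_Hp: 0.70             # J maturity at adult emergence
  kap_R: 0.95            # reproduction efficiency
  h_a: 0.002             # 1/d^2 Weibull aging acceleration
  s_G: 0.0001            # Gompertz stress coefficient
  h_b_nymph: 0.01        # 1/d background hazard, immature stages
  instar_lengths: [0.026, 0.033, 0.045]  # cm: N1|N2, N2|N3, N3|pseudopupa
  L_egg: 0.004           # cm initial egg structural length
  sex_ratio: 0.5
  starvation_hazard: 0.5 # 1/d extra hazard for starving immatures

tktd:
  k_d: 0.6               # 1/d dominant rate constant
  z: 2.5                 # damage threshold, corrected-rate units
  b_h: 0.15              # 1/(damage d) killing rate
  c_s: 1.0               # 1/damage sublethal effect strength
  tau_surv: 3.7          # d exposure onset delay, immature survival
  tau_fec: 0.6           # d onset delay, fecundity
  tau_fert: 0.3          # d onset delay, fertility
  exposed_stages: [N1, N2, ADULT]

exposure:
  k_dec_ref: 0.042       # 1/d decay at plant reference temperature
  V_sat: 300.0           # L/ha water volume at penetration saturation
  k_up: 0.25             # 1/h cuticle penetration rate (t95 = 12 h)
  P_max_at_sat: 0.31     # test-specific maximum penetrated fraction

plant:
  r_leaf: 0.018          # 1/d logistic leaf-area growth at T_ref
  leaf_area_max: 12000.0 # cm^2
  r_node: 0.034          # 1/d node appearance at T_ref
  leaf_area_0: 60.0      # cm^2 seedling
  nodes_0: 2.0

scenario:
  n_reps: 100
  substeps: 12
  disc_area_cm2: 3.88
  adult_leaf_multiplier: 20.0
  emigration_trigger_nodes: 22
  emigration_trigger_fraction: 0.95
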