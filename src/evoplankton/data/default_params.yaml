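# Default parameterization of the eco-evolutionary plankton column model.
#
# Allometric trait rules follow the general power-law form
#     log10(x) = a + b * log10(V)          (V = cell volume, um^3)
# Constants are drawn from the standard phytoplankton trait-allometry
# literature (Litchman et al. 2007; Menden-Deuer & Lessard 2000; Ward et
# al. 2012-style size-structured food webs) and are configuration data,
# not model code: every value here can be overridden from a user file.
allometry:
  # (a, b) pairs shared by all functional types unless overridden.
  rules:
    V_max: [-0.301, -0.15]        # mol N (mol C)^-1 d^-1
    K_N: [-0.770, 0.27]           # mmol N m^-3
    Q_min: [-1.398, 0.0]          # mol N (mol C)^-1
    Q_max: [-0.770, 0.0]          # mol N (mol C)^-1
    sinking: [-1.523, 0.17]       # m d^-1
    carbon_per_cell: [-13.745, 0.939]   # mmol C cell^-1
    mu_max: [0.0, -0.10]          # d^-1; intercept replaced per type below
  functional_types:
    Prochlorococcus:
      volume_range: [0.1, 1.0]
      mu_max_a: -0.187            # 10^a = 0.65 d^-1 at V = 1 um^3
      can_use_nitrate: false
    Synechococcus:
      volume_range: [0.5, 50.0]
      mu_max_a: -0.046            # 0.90 d^-1
      can_use_nitrate: true
    small-eukaryote:
      volume_range: [10.0, 1.0e+5]
      mu_max_a: 0.041             # 1.10 d^-1
      can_use_nitrate: true
    diatom:
      volume_range: [300.0, 1.0e+7]
      mu_max_a: 0.146             # 1.40 d^-1
      can_use_nitrate: true

foodweb:
  m: 0.05               # phytoplankton background mortality, d^-1 (size-independent)
  m_zoo: 0.05           # zooplankton closure mortality coefficient
  # linear | quadratic; quadratic (default) entrains the plankton cycles to
  # the annual forcing, a validity requirement of the invasion-trial method
  zoo_mortality: quadratic
  assimilation: 0.30    # fraction of ingested C and N assimilated by grazers
  k_A: 0.75             # grazing half-saturation on palatability-weighted prey, mmol C m^-3
  rho_opt: 1000.0       # optimal predator:prey volume ratio
  sigma: 0.60           # log-normal grazing-kernel width (ln-units)
  q_zoo: 0.15           # zooplankton reference N:C quota, mol N (mol C)^-1
  zoo_excretion: 0.5    # d^-1, relaxation of zoo N:C toward q_zoo (excess N -> NH4)
  # Nine grazers whose optimal prey volumes (volume/rho_opt) tile the full
  # phytoplankton size range 0.1 .. 1e7 um^3 in decade steps.
  zoo_volumes: [1.0e+2, 1.0e+3, 1.0e+4, 1.0e+5, 1.0e+6,
                1.0e+7, 1.0e+8, 1.0e+9, 1.0e+10]
  I_max_rule: [1.176, -0.15]   # max ingestion d^-1 vs body volume: 15 * V^-0.15
  # Remineralization chain (all first-order, d^-1)
  r_pon_small: 0.10     # small detritus N -> DON
  r_pon_large: 0.05     # large detritus N -> DON
  r_poc_small: 0.10     # small detritus C loss (implicit CO2)
  r_poc_large: 0.05
  r_don: 0.10           # DON -> NH4
  r_nitrif_nh4: 0.05    # NH4 -> NO2
  r_nitrif_no2: 0.10    # NO2 -> NO3
  large_detritus_volume: 1.0e+5   # losses from organisms above this volume -> large pool
  w_det_small: 1.0      # sinking of small detritus, m d^-1
  w_det_large: 10.0
  # Temperature and light limitation factors, both 1 at reference conditions
  T_ref: 10.0           # deg C
  eppley_k: 0.0639      # gamma_T = exp(k*(T - T_ref)); Q10 ~ 1.9
  I_k: 25.0             # W m^-2; gamma_I = 1 - exp(-I/I_k)
  theta_chl_n: 1.6      # mg Chl (mmol N)^-1, pigment synthesis ratio

column:
  n_levels: 35
  depth: 3275.0         # m
  dt: 0.05              # biological/transport time step, d
  k_water: 0.04         # background light attenuation, m^-1
  k_chl: 0.03           # self-shading, m^-1 (mg Chl m^-3)^-1
  stretch_min_dz: 5.0   # thickness of the surface level, m (geometric stretching)
  floor: 1.0e-15        # quasi-extinction/immigration floor, mmol C m^-3 per level

forcing:
  # Idealized high-latitude (Norwegian Sea-like) seasonal cycle, 365-d year.
  I_summer: 250.0       # surface irradiance extremes, W m^-2
  I_winter: 5.0
  day_solstice: 172
  T_surface_summer: 10.0  # deg C
  T_surface_winter: 3.0
  T_deep: 2.0
  day_T_peak: 232         # thermal lag behind the solstice
  thermocline_scale: 50.0 # m, e-folding of the seasonal surface layer
  mld_winter: 500.0       # deep convective mixing Dec-Mar
  mld_summer: 25.0
  day_mld_peak: 46        # mid-February
  kappa_mix: 1.0e+4       # mixed-layer diffusivity, m^2 d^-1 (~0.12 m^2 s^-1)
  kappa_bg: 0.5           # background diffusivity, m^2 d^-1
  mld_edge: 10.0          # m, smoothness of the mixed-layer base

initial:
  NO3: 12.0             # mmol N m^-3, winter water column
  NO2: 0.05
  NH4: 0.05
  DON: 0.5
  plankton_seed: 6.0e-9 # mmol C m^-3, uniform depth profile for every species

evolution:
  mutation_step: 0.10   # fractional cell-volume step of the two mutants
  eval_years: 1
  relax_years: 2
  mutant_scale: 1.0e-6  # mutant profiles = resident profiles times this factor

protocol:
  n_phyto_seed: 20
  n_zoo: 9
  phase1_years: 100
  phase2_years: 250
  ensemble_k: 24
  richness_threshold: 1.0e-3   # mmol C m^-2 column-integrated biomass
  n_size_classes: 100
  n_probes: 200
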