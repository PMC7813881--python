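# Example scenario configuration for `hepamet run --config ...`
# All lengths in micrometers, times in minutes unless noted.

domain:
  width: 5000.0        # 0.5 cm
  height: 5000.0
  thickness: 30.0      # thin-slab thickness; enters volume scalings only

tissue:
  cv_density: 2.0e-06       # central veins per um^2 (~800 um lobules)
  min_separation: 200.0     # merge CV pairs closer than this
  parenchyma_radius: 15.0
  spacing_factor: 0.95      # confluent spacing = 2 * radius * factor
  cv_exclusion_radius: 26.5 # keep agents off the vein lumen

transport:
  D: 1.0e+05          # oxygen diffusion coefficient, um^2/min
  decay: 0.01         # bulk decay, 1/min
  U_cell: 3.5         # per-cell uptake before volume scaling, 1/min
  S_cell: 0.0
  rho_star: 38.0
  sigma_H: 5.0        # hypoxic/necrotic threshold, mmHg
  sigma_cv: 38.0      # oxygen at the central vein
  sigma_pt: 60.0      # oxygen at the lobule boundary (portal proxy)
  profile: linear     # analytic profile shape: linear | exponential

mechanics:
  c_rep: 10.0         # repulsion strength, um/min
  c_adh: 0.4          # adhesion strength, um/min
  adh_multiplier: 1.25
  # the swept biomechanical triplet; grid values are
  # r_E in {0.05, 0.1, 0.2}, r_P in {0.0005, 0.001, 0.002},
  # d_max in {0.75, 1.5, 3}
  r_E: 0.1            # elastic response rate, 1/min
  r_P: 0.001          # plastic relaxation rate, 1/min
  d_max: 1.5          # max tolerated parenchyma deformation, um
  p_scale: null       # pressure normalization; calibrated automatically

phenotype:
  r01_max: 0.004604   # max Ki67- -> Ki67+ entry rate (1/(3.62 h)), 1/min
  T_K1: 780.0         # premitotic duration (13 h)
  T_K2: 150.0         # postmitotic duration (2.5 h)
  p1: 0.0             # pressure gate lower threshold
  p2: 1.0             # full cycle arrest at and above this pressure
  sigma_H: 5.0
  sigma_sat: 38.0     # proliferation saturates above this oxygen
  r_N_max: 0.002778   # max necrosis rate (1/(6 h)), 1/min
  T_apop: 516.0       # apoptotic shrink duration (8.6 h)
  T_lysis: 360.0      # necrotic shrink duration (6 h)
  tumor_radius: 8.4

seeding:
  mode: single        # single | disks
  diameters: []       # for disks: e.g. [250.0, 2000.0]
  centers: null       # null -> automatic non-overlapping layout

duration_days: 90.0
dx: 20.0              # oxygen voxel edge
dt_diff: 0.01
dt_mech: 0.1
dt_phen: 6.0
diffusion_substeps: null  # null -> dt_phen / dt_diff substeps
snapshot_interval: 360.0  # minutes between saved outputs (6 h)
burn_in_min: 60.0
seed: 0
events: []            # e.g. [{time_min: 129600, mechanics: {...}}]
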