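# 5 µm polystyrene beads in room-temperature water, 1 ml syringe,
# concentric 0.5 mm outlet at 10 µl/min — the study's default system.
particle:
  radius_um: 5.0
  density_g_cm3: 1.07
buffer:
  density_g_cm3: 0.997
  viscosity_mPa_s: 1.0
syringe:
  barrel_radius_mm: 2.3
  barrel_length_mm: 40.0
  outlet_radius_mm: 0.5
  outlet_length_mm: 5.0
  outlet_offset_mm: 0.0        # -(R_S - R_O) for a bottom-eccentric outlet
flow:
  rate_ul_min: 10.0
  backend: superposition       # or stokes_axisym (concentric only)
sim:
  n_particles: 2000
  dt_s: 0.05
  max_time_s: 1200
  seed: 0
  integrator: euler
analysis:
  lowpass_cutoff_hz: 100.0
  threshold_sigmas: 5.0
  min_separation_ms: 1.0
  bin_width_s: 1.0
  init_window_s: 20.0
  smooth_bins: 21
model:
  g_m_s2: 9.81
  # K_S: 0.52                  # uncomment for a point estimate
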