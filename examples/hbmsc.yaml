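# Human bone-marrow stromal cells (literature size/density) in PBS,
# 1 ml syringe — closed-form half-life prediction at the low-flow
# boundary (K_S = 0.4).
particle:
  radius_um: 10.3
  density_g_cm3: 1.062
buffer:
  density_g_cm3: 1.00
  viscosity_mPa_s: 1.0
syringe:
  barrel_radius_mm: 2.3
  barrel_length_mm: 40.0
  outlet_radius_mm: 0.5
model:
  K_S: 0.4
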