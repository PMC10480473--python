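# Non-living tissue (bacon) under a 20 mW, 130 GHz collimated beam focused to
# an effective ~2 cm spot.  The absorption coefficient of cured fat at
# 130 GHz is user-supplied (edit mu_a_per_cm below; the shipped value is a
# fat-like placeholder, not a measured datum).  No perfusion, no metabolic
# heat; room temperature 22.8 C on both the boundary and the blood record so
# the baseline is uniform.
name: bacon
stack:
  layers:
    - name: bacon
      thickness_mm: 5.0
      mu_a_per_cm: 10.0
      mu_s_prime_per_cm: 0.0
      g: 0.0
      n: 1.4
      perfused: false
      thermal: {rho_kg_m3: 950.0, c_p_j_kg_k: 2500.0, k_w_m_k: 0.2}
  blood:
    rho_kg_m3: 1060.0
    c_p_j_kg_k: 3600.0
    perfusion_rate_per_s: 0.0
    arterial_temp_c: 22.8
    metabolic_heat_w_m3: 0.0
source:
  power_w: 0.02
  waist_mm: 20.0
  profile: gaussian
  pulse: {duty_cycle: 1.0, frequency_hz: 1.0}
grid: {dr_mm: 1.0, dz_mm: 0.05, r_max_mm: 60.0}
thermal_boundary: {h_w_m2_k: 10.0, ambient_temp_c: 22.8}
run: {backend: diffusion, t_end_s: 200.0, dt_s: 1.0, snapshot_times_s: []}
optics:
  diffusion: {convention: standard_third, far_boundary: zero_fluence,
              source_scaling: beam_power, solver_tol: 1.0e-10}
  montecarlo: {n_photons: 200000, seed: 1, match_indices: true, ambient_n: 1.0}
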