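# 130 GHz (sub-THz, "6G band") exposure of three-layer skin.
# Scattering is negligible at these wavelengths; attenuation is pure water
# absorption.  Thermal values are the documented package defaults.
name: thz_130ghz
stack:
  layers:
    - name: epidermis
      thickness_mm: 0.2
      mu_a_per_cm: 50.0
      mu_s_prime_per_cm: 0.0
      g: 0.0
      n: 1.4
      perfused: false
      thermal: {rho_kg_m3: 1050.0, c_p_j_kg_k: 3600.0, k_w_m_k: 0.5}
    - name: dermis
      thickness_mm: 1.0
      mu_a_per_cm: 70.0
      mu_s_prime_per_cm: 0.0
      g: 0.0
      n: 1.4
      perfused: true
      thermal: {rho_kg_m3: 1050.0, c_p_j_kg_k: 3600.0, k_w_m_k: 0.5}
    - name: fat
      thickness_mm: 1.6
      mu_a_per_cm: 7.0
      mu_s_prime_per_cm: 0.0
      g: 0.0
      n: 1.4
      perfused: true
      thermal: {rho_kg_m3: 1050.0, c_p_j_kg_k: 3600.0, k_w_m_k: 0.5}
  blood:
    rho_kg_m3: 1060.0
    c_p_j_kg_k: 3600.0
    perfusion_rate_per_s: 1.0e-3
    arterial_temp_c: 37.0
    metabolic_heat_w_m3: 1000.0
source:
  power_w: 0.1
  waist_mm: 20.0
  profile: gaussian
  pulse: {duty_cycle: 1.0, frequency_hz: 1.0}
grid: {dr_mm: 0.5, dz_mm: 0.01, r_max_mm: 60.0}
thermal_boundary: {h_w_m2_k: 10.0, ambient_temp_c: 23.0}
run: {backend: diffusion, t_end_s: 300.0, dt_s: 1.0, snapshot_times_s: []}
optics:
  diffusion: {convention: standard_third, far_boundary: zero_fluence,
              source_scaling: beam_power, solver_tol: 1.0e-10}
  montecarlo: {n_photons: 200000, seed: 1, match_indices: true, ambient_n: 1.0}
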