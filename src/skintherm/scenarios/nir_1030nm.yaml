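# Near-infrared (1030 nm, 0.29 PHz) exposure: low absorption, strong forward
# scattering -- the "biological window".  The literature source for this
# band's skin coefficients is not reproduced here, so the values below are
# documented typical ones and are meant to be edited; tests on this scenario
# assert qualitative behaviour only.  The fat layer is extended to 2.8 mm so
# the field can be followed to 3 mm depth.
name: nir_1030nm
stack:
  layers:
    - name: epidermis
      thickness_mm: 0.2
      mu_a_per_cm: 1.0
      mu_s_prime_per_cm: 15.0
      g: 0.9
      n: 1.4
      perfused: false
      thermal: {rho_kg_m3: 1050.0, c_p_j_kg_k: 3600.0, k_w_m_k: 0.5}
    - name: dermis
      thickness_mm: 1.0
      mu_a_per_cm: 0.8
      mu_s_prime_per_cm: 12.0
      g: 0.9
      n: 1.4
      perfused: true
      thermal: {rho_kg_m3: 1050.0, c_p_j_kg_k: 3600.0, k_w_m_k: 0.5}
    - name: fat
      thickness_mm: 2.8
      mu_a_per_cm: 0.7
      mu_s_prime_per_cm: 10.0
      g: 0.9
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
  waist_mm: 5.0
  profile: gaussian
  pulse: {duty_cycle: 1.0, frequency_hz: 1.0}
grid: {dr_mm: 0.25, dz_mm: 0.05, r_max_mm: 15.0}
thermal_boundary: {h_w_m2_k: 10.0, ambient_temp_c: 23.0}
run: {backend: diffusion, t_end_s: 300.0, dt_s: 1.0, snapshot_times_s: []}
optics:
  diffusion: {convention: standard_third, far_boundary: zero_fluence,
              source_scaling: beam_power, solver_tol: 1.0e-10}
  montecarlo: {n_photons: 200000, seed: 1, match_indices: false, ambient_n: 1.0}
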