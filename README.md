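# skintherm

Coupled tissue-optics / bioheat simulator for electromagnetic exposure
dosimetry of layered human skin.

Emerging wireless bands above 100 GHz (and laboratory THz / near-infrared
sources) deposit their power in the first fraction of a millimetre of skin,
where water absorption is strong.  `skintherm` predicts the resulting
fluence distribution and transient temperature rise for a layered tissue
stack (epidermis / dermis / blood-infused fat by default) exposed to a
continuous or pulsed Gaussian beam.  It is written for dosimetry and
biophotonics work: exposure-limit studies, photothermal therapy planning
sanity checks, and cross-validation of light-transport approximations.

## Model

The domain is axisymmetric (r, z) with z = 0 at the air–tissue interface.
Three interchangeable optics backends compute the absorbed power density
Q(r, z) from per-layer optical properties (μa, μs′, g, n):

* **Beer–Lambert** — 1D layered attenuation
  I(z)/I₀ = exp(−Σ (μa+μs′)·Δz), the analytical reference;
* **diffusion approximation** — steady finite-volume solve of
  −∇·(D∇Φ) + μa Φ = 0 with Dirichlet Gaussian incidence
  Φ(r,0) = (2P/πw²)·exp(−2r²/w²), D = 1/(3(μa+μs′)) by default
  (the literal D = 1/(μa+μs′) convention is selectable);
* **Monte Carlo** — layered hop/drop/spin photon transport with photon
  weights, Henyey–Greenstein scattering, Fresnel interface handling and
  Russian roulette, scored on the same grid (numba-accelerated,
  bit-reproducible per seed).

The thermal stage integrates the Pennes bioheat equation

    ρc ∂T/∂t = ∇·(k∇T) + ρ_b c_b ω_b (T_b − T) + Q_met + Q(r,z)·s(t)

implicitly (backward Euler / Crank–Nicolson) with a convective boundary at
the skin surface, insulated far boundaries, and a square-wave pulse
schedule s(t) of arbitrary duty cycle and repetition frequency.
Temperature rises are reported against the no-source steady baseline.
Because the discrete system is linear, continuous-source plateaus are
computed exactly from the steady system; pulsed envelopes are refined by a
warm-started cycle integration.

## Worked example

```python
import skintherm as st

cfg  = st.scenario("thz_130ghz")          # 0.2/1/1.6 mm skin, mu_a 50/70/7 /cm
grid = cfg.make_grid()
field = st.solve_fluence(cfg.stack, cfg.source, grid, cfg.diffusion)
print(st.absorbed_fraction_by_layer(field, cfg.stack))
# {'epidermis': 0.8230600358507141, 'dermis': 0.17693897561782404,
#  'fat': 7.0977725751692e-07, 'escaped': 2.7875420506379575e-07}

for p in (0.01, 0.05, 0.1):               # W, 2 cm waist, continuous
    print(p, st.coupled_plateau_rise(cfg, power=p))
# 0.01 0.4377323318142547
# 0.05 2.188661659071271
# 0.1 4.377323318142542
```

The first block says 82.3% of the delivered 130 GHz beam power is absorbed
within the 0.2 mm epidermis (the fraction of power that never reaches the
dermis); the second shows the plateau maximum temperature rise scaling
exactly linearly with beam power (0.44 → 4.4 K from 10 → 100 mW) under the
documented default thermal set.  Absolute rises depend on the thermal
parameters (perfusion, convection); see `docs/methods.md`.

The same pipeline is scriptable from the shell:

```
skintherm run thz_130ghz --backend diffusion --out out/
skintherm compare-optics thz_1thz --out compare.csv
skintherm sweep duty thz_130ghz --values 0.25,0.5,1.0 --frequencies 1,10,100
```

`run` writes the fluence grid, the centerline profile, the max-rise time
series, optional snapshots and a JSON manifest (config hash, seed,
conservation diagnostics); rerunning the same config and seed reproduces
every numeric output byte for byte.

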