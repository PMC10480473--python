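# Methods

This note records the physical model, the numerical choices, the default
parameter set and the known limitations of `skintherm`.

## Geometry and units

The tissue is a stack of plane-parallel layers on an axisymmetric (r, z)
finite-volume grid; z = 0 is the air–tissue interface and increases into the
tissue.  The air above the skin is not meshed: optical incidence and
convective cooling enter as boundary conditions at z = 0.  Layer interfaces
use half-open [top, bottom) intervals, so a depth exactly on an interface
belongs to the layer below.  The axial grid snaps to layer interfaces
(each layer is divided into an integer number of cells, per-layer spacings
allowed), which keeps every cell inside exactly one material.

Internal units are SI throughout.  Scenario configs accept the units the
tissue-optics literature prints — cm⁻¹ for μa and μs′, mm for lengths,
°C for temperatures — and convert once on load; every config key carries a
unit suffix.  "Beam waist" w is the 1/e² intensity radius of the Gaussian
beam, giving on-axis peak irradiance 2P/(πw²); sources that quote a spot
diameter should halve it before entry.

## Optics backends

All three backends produce the absorbed power density Q(r, z) = μa·Φ that
drives the heat solver, and a normalized centerline profile for
cross-comparison.

**Beer–Lambert.**  I(z)/I₀ = exp(−Σ (μa+μs′)Δz) along z, scattering lumped
into absorption, as is conventional for 1D analytical comparisons.  No
specular correction at entry (consistent with the diffusion backend's
no-reflection assumption).  Cell deposition uses exact integrals: the
Gaussian is integrated analytically over each radial ring and the
transmitted fraction differenced across axial faces.

**Diffusion approximation.**  Steady −∇·(D∇Φ) + μaΦ = 0; the transient
1/v ∂Φ/∂t term of the P1 limit is dropped because photon transport
equilibrates in picoseconds while heating evolves over seconds.  Boundary
conditions: Dirichlet Φ(r,0) = incident irradiance at the surface, Neumann
symmetry at r = 0, zero-fluence (default) or Robin partial-current at the
bottom/outer boundaries, which should sit several penetration depths from
the beam (this emulates a semi-infinite surround).  D is cell-wise constant
with harmonic averaging on faces, so diffusive flux is continuous across
layer jumps.  The sparse 5-point system is solved directly; the assembled
operator is conservative, and the solver reports absorbed + escaped −
influx as a diagnostic (machine-precision zero).

Two D conventions are supported: the textbook `standard_third`,
D = 1/(3(μa+μs′)) (default), under which a homogeneous absorption-only
medium decays as exp(−√3 μa z); and `reciprocal`, D = 1/(μa+μs′), under
which the decay rate is exactly μa and the centerline coincides with
Beer–Lambert.  The absorbed-fraction figures this package is checked
against (≈82% epidermal absorption at 130 GHz, ≈99% at 1 THz) follow from
the standard convention.

**Source normalization.**  A Dirichlet surface value does not by itself fix
the delivered power: under the standard-D convention the diffusive influx
of a wide beam is ≈ P/√3.  Since the model neglects surface reflection, all
incident power physically enters the tissue, so by default the solved field
is rescaled so that absorbed + escaped power equals the beam power exactly
(`source_scaling: beam_power`); `dirichlet` retains the raw field.  The
choice does not affect normalized profiles or per-layer fractions, only the
absolute thermal forcing.  Per-layer absorbed fractions are reported
relative to delivered power, which is what per-layer absorption percentages
in this literature mean.

**Monte Carlo.**  MCML-style layered transport: photons launch at z = 0
collimated, radial position sampled from the Gaussian intensity; step
s = −ln U/(μa+μs) with μs = μs′/(1−g); at each interaction a fraction
μa/(μa+μs) of the weight is deposited in the local cell and the direction
is redrawn from the Henyey–Greenstein inverse CDF; unpolarized Fresnel
coefficients (with total internal reflection) act at the surface and at
index-mismatched internal interfaces.  After an interface event the
remaining step is resampled, which the memoryless exponential makes
statistically exact.  The bottom face of the stack is a domain truncation:
photons crossing it are tallied as transmitted without a Fresnel event.
Photons wandering radially outside the scored grid keep propagating; their
absorption still enters the global energy bookkeeping.

Russian roulette (threshold 10⁻⁴, survival 0.1) terminates low-weight
photons.  Roulette is unbiased only in expectation, so the kernel tracks the
net weight it creates/destroys; the per-run identity
`specular + diffuse + transmitted + absorbed = 1 + roulette_net` is then
exact to floating-point, and `|roulette_net|` is itself a diagnostic
(typically ≲10⁻³).  Runs are bit-reproducible for a fixed seed.  Standard
errors come from 16 photon batches: per-layer absorbed fractions and the
innermost-ring depth profile are accumulated per batch, and the profile
normalization error is propagated.  In `match_indices` mode every layer's
refractive index is overridden to the ambient value so MC shares the
diffusion model's no-reflection assumption — this is how cross-backend
centerline comparisons are run.

## Bioheat stage

Pennes' equation with conduction, a perfusion sink
ρ_b c_b ω_b (T_b − T) active in layers flagged `perfused`, metabolic heat
everywhere, and the optics-supplied source modulated by a unit square wave
s(t) (duty d, frequency f; s ≡ 1 for continuous exposure).  The advection
term ρc u·∇T of the general balance is carried with u = 0: bulk blood
motion is already represented by the perfusion sink and no tissue velocity
field is available.  Boundary conditions: convective flux at z = 0 through
a series conductance (half-cell conduction + film coefficient h), insulated
far boundaries at the padded extent.

Time integration is implicit (backward Euler default, Crank–Nicolson
optional); step maps are LU-factorized once per distinct dt.  Pulsed runs
subdivide the time grid at switching instants so s(t) is piecewise-constant
per step, and require dt ≤ (shorter of ON/OFF)/10.  Rises are always
reported against the no-source steady baseline field, since convection
makes the unexposed steady state non-uniform.

**Plateaus.**  The discrete system is linear and time-invariant, so the
asymptote of a continuous run is the solution of the steady system
K·ΔT = Q·V, which is solved directly (the transient solver is still used
for time histories, and a test confirms the transient approaches the steady
value).  For pulsed sources the long-time mean field is d × the continuous
steady rise; the per-cycle maximum envelope is obtained by warm-starting
the transient at that mean and marching whole cycles until consecutive
cycle maxima agree to 0.1%.  This reproduces the duty-cycle
proportionality (plateau ≈ d × continuous) and its frequency invariance
over 1–100 Hz (spread ~1%) at desk-scale cost; the small super-duty excess
at low frequency (~0.5% at 1 Hz, 1 W) is the physical half-ripple of the
surface temperature during the ON phase.

## Default parameters

Optical coefficients for the THz scenarios (130 GHz: μa = 50/70/7 cm⁻¹;
1 THz: 137/140/25 cm⁻¹; μs′ = 0) and the geometry (0.2 mm epidermis, 1 mm
dermis, 1.6 mm blood-infused fat) are the scenario definitions.  The
1030 nm scenario's source table is not public, so it ships documented
typical skin values (μa 1.0/0.8/0.7 cm⁻¹, μs′ 15/12/10 cm⁻¹, g = 0.9,
fat extended to 2.8 mm so the field can be followed to 3 mm); tests on it
assert qualitative behaviour only (subsurface MC fluence peak, near-zero
centerline by 3 mm on a linear scale).

Thermal values are rarely printed in the exposure literature; the package
defaults are standard soft-tissue numbers, stated here and overridable per
layer in every config:

| quantity | default | units |
|---|---|---|
| tissue k | 0.5 | W/(m·K) |
| tissue ρ | 1050 | kg/m³ |
| tissue c_p | 3600 | J/(kg·K) |
| blood ρ_b, c_b | 1060, 3600 | kg/m³, J/(kg·K) |
| perfusion ω_b | 1×10⁻³ (dermis/fat), 0 (epidermis) | s⁻¹ |
| arterial T_b | 37 | °C |
| metabolic Q_met | 1000 | W/m³ |
| convection h | 10 | W/(m²·K) |
| ambient | 23 | °C |

With this set the 130 GHz / 100 mW / 2 cm-waist scenario plateaus at
≈4.4 K.  Published figures for comparable exposures are ≈6 K; the ~25%
gap is within the spread attributable to the unpublished thermal
parameters (doubling ω_b or halving h moves the plateau by tens of
percent).  Power-linearity and duty-cycle ratios are independent of that
uncertainty and are held to ≤1% and ≤5% respectively by the tests.

## Numerical choices and degenerate inputs

* Grids: radial spacing uniform (required by MC scoring); axial spacing
  per layer.  The solvers reject grids narrower than 3 beam waists, grids
  that do not span the stack, and dz coarser than the thinnest layer.
  Diffusion absorbed fractions move by <0.5% under grid halving at the
  shipped scenario resolutions.
* The diffusion solve refuses media with μa + μs′ = 0 in any layer
  (D diverges); MC handles transparent layers by free flight.
* A steady baseline with no sink anywhere (h = 0, no perfusion, Q_met > 0)
  is reported as unbounded rather than solved.
* MC fluence is undefined in cells with μa = 0 (reported NaN); the
  absorbed power density q_abs remains defined.
* Pulsed transient grids drop near-duplicate step times (a pulse switch
  landing on a base step within floating-point noise) — distinct nearly
  equal steps would otherwise poison the LU cache.
* Synthetic stacks for property tests round their sampled values to six
  decimals in config units so YAML round-trips are bit-exact.

## What the packaged scenarios do and do not show

The fixtures emulate the study conditions of the THz/NIR exposure setting:
plane layers, properties uniform per layer, normal-incidence Gaussian
beams, continuous perfusion at a fixed rate.  They do not model curved or
heterogeneous anatomy, vasculature geometry, temperature-dependent
perfusion, thermal damage kinetics (CEM43/Arrhenius), frequency-dependent
dielectric models of water (absorption coefficients are inputs), or
microscale non-Fourier conduction.  Passing tests therefore validate the
solvers and their coupling under these idealized conditions, not the
biological response of real skin; absolute temperature predictions inherit
the thermal-parameter uncertainty described above.
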