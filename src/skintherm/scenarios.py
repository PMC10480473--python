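"""Packaged exposure scenarios, parametric sweep drivers and a synthetic
stack generator.

Four scenarios ship with the package: ``thz_130ghz`` and ``thz_1thz``
(absorption-dominated sub-THz/THz bands), ``nir_1030nm`` (scattering-
dominated near-infrared) and ``bacon`` (non-living tissue validation
geometry).  Each is a YAML file under ``skintherm/scenarios/`` readable with
:func:`skintherm.config.load_config`; :func:`scenario` loads one by name.

The sweep drivers reproduce the parametric studies of interest in exposure
dosimetry: plateau temperature rise versus source power (linear), versus
beam waist (sub-linear decrease) and versus pulse duty cycle
(frequency-invariant proportionality).  Plateaus are the steady limit of the
linear bioheat system; pulsed plateaus are the converged per-cycle maximum
envelope (see :mod:`skintherm.pennes`).
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd

from .beer_lambert import bl_absorbed_density
from .config import ScenarioConfig, load_config
from .diffusion import solve_fluence
from .domain import (
    BloodModel,
    Layer,
    OpticalProperties,
    PulseSchedule,
    SourceSpec,
    ThermalProperties,
    TissueStack,
    make_grid,
)
from .montecarlo import run_mc
from .pennes import pulsed_plateau_rise, solve_steady_rise

__all__ = [
    "SCENARIO_NAMES",
    "scenario",
    "compute_q_abs",
    "coupled_plateau_rise",
    "power_sweep",
    "waist_sweep",
    "duty_cycle_sweep",
    "synth_stack",
]

SCENARIO_NAMES = ("thz_130ghz", "thz_1thz", "nir_1030nm", "bacon")


def scenario(name: str) -> ScenarioConfig:
    """Load a packaged scenario by name."""
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario '{name}'; choose one of {SCENARIO_NAMES}"
        )
    text = resources.files(__package__).joinpath(
        f"scenarios/{name}.yaml"
    ).read_text()
    return load_config(text)


def compute_q_abs(cfg: ScenarioConfig, grid, backend: str | None = None,
                  seed: int | None = None) -> np.ndarray:
    """Absorbed power density (W/m^3) on ``grid`` from the selected backend."""
    backend = backend or cfg.backend
    if backend == "beer_lambert":
        return bl_absorbed_density(cfg.stack, cfg.source, grid)
    if backend == "diffusion":
        return solve_fluence(cfg.stack, cfg.source, grid, cfg.diffusion).q_abs
    if backend == "montecarlo":
        mc = cfg.montecarlo
        if seed is not None:
            mc = dataclasses.replace(mc, seed=seed)
        return run_mc(cfg.stack, cfg.source, grid, mc).q_abs()
    raise ValueError(f"unknown backend '{backend}'")


def _with_source(cfg: ScenarioConfig, power=None, waist=None,
                 pulse: PulseSchedule | None = None) -> ScenarioConfig:
    src = cfg.source
    src = SourceSpec(
        power=src.power if power is None else float(power),
        waist=src.waist if waist is None else float(waist),
        profile=src.profile,
        pulse=src.pulse if pulse is None else pulse,
    )
    return dataclasses.replace(cfg, source=src)


def coupled_plateau_rise(cfg: ScenarioConfig, power=None, waist=None,
                         pulse: PulseSchedule | None = None,
                         backend: str | None = None) -> float:
    """End-to-end plateau max temperature rise (K) for one source setting.

    Runs the optics backend for the (possibly overridden) source, feeds the
    absorbed power density into the bioheat solver and returns the plateau of
    the maximum rise over the domain.  The grid radial extent is widened when
    an overridden waist needs it.
    """
    cfg = _with_source(cfg, power=power, waist=waist, pulse=pulse)
    r_max = max(cfg.grid.r_max, 3.0 * cfg.source.waist)
    grid = make_grid(cfg.stack, dr=cfg.grid.dr, dz=cfg.grid.dz, r_max=r_max)
    q = compute_q_abs(cfg, grid, backend=backend)
    sched = cfg.source.pulse
    if sched.continuous:
        return float(np.max(solve_steady_rise(cfg.stack, grid, cfg.boundary, q)))
    return pulsed_plateau_rise(cfg.stack, grid, cfg.boundary, q, sched)


def power_sweep(cfg: ScenarioConfig, powers) -> pd.DataFrame:
    """Plateau rise for each beam power (one coupled run per row)."""
    rows = []
    for p in powers:
        if p <= 0:
            raise ValueError(f"powers must be > 0, got {p}")
        try:
            rise = coupled_plateau_rise(cfg, power=p)
        except Exception as exc:
            raise RuntimeError(f"power sweep failed at {p} W: {exc}") from exc
        rows.append({"power_w": float(p), "plateau_rise_k": rise})
    return pd.DataFrame(rows, columns=["power_w", "plateau_rise_k"])


def waist_sweep(cfg: ScenarioConfig, waists) -> pd.DataFrame:
    """Plateau rise for each beam waist at fixed power (input order kept)."""
    rows = []
    for w in waists:
        if w <= 0:
            raise ValueError(f"waists must be > 0, got {w}")
        try:
            rise = coupled_plateau_rise(cfg, waist=w)
        except Exception as exc:
            raise RuntimeError(f"waist sweep failed at {w} m: {exc}") from exc
        rows.append({"waist_m": float(w), "plateau_rise_k": rise})
    return pd.DataFrame(rows, columns=["waist_m", "plateau_rise_k"])


def duty_cycle_sweep(cfg: ScenarioConfig, duties, frequencies) -> pd.DataFrame:
    """Plateau envelope rise over a duty-cycle x pulse-frequency grid.

    The plateau scales with the duty cycle and is frequency-invariant; a
    duty of 1 reduces to the continuous run for any frequency.
    """
    rows = []
    for d in duties:
        for f in frequencies:
            sched = PulseSchedule(duty_cycle=float(d), frequency=float(f))
            try:
                rise = coupled_plateau_rise(cfg, pulse=sched)
            except Exception as exc:
                raise RuntimeError(
                    f"duty sweep failed at duty={d}, f={f} Hz: {exc}"
                ) from exc
            rows.append({"duty_cycle": float(d), "frequency_hz": float(f),
                         "plateau_rise_k": rise})
    return pd.DataFrame(rows, columns=["duty_cycle", "frequency_hz",
                                       "plateau_rise_k"])


def synth_stack(
    seed: int,
    n_layers: int = 3,
    mu_a_range_per_cm: tuple[float, float] = (1.0, 100.0),
    mu_s_prime_range_per_cm: tuple[float, float] = (0.0, 20.0),
    thickness_range_mm: tuple[float, float] = (0.1, 2.0),
    g_range: tuple[float, float] = (0.0, 0.95),
    n_range: tuple[float, float] = (1.33, 1.5),
) -> TissueStack:
    """Reproducible random layered medium for property tests.

    Sampled values are rounded to 6 decimals in config units so that a stack
    round-trips through the YAML config format bit-exactly.
    """
    for name, (lo, hi) in (
        ("mu_a_range_per_cm", mu_a_range_per_cm),
        ("mu_s_prime_range_per_cm", mu_s_prime_range_per_cm),
        ("thickness_range_mm", thickness_range_mm),
        ("g_range", g_range),
        ("n_range", n_range),
    ):
        if not (lo <= hi):
            raise ValueError(f"{name}: range must be ordered, got {(lo, hi)}")
        if lo < 0:
            raise ValueError(f"{name}: range must be non-negative")
    if thickness_range_mm[0] <= 0:
        raise ValueError("thickness_range_mm: thickness must be > 0")
    if g_range[1] >= 1.0:
        raise ValueError("g_range: anisotropy must stay below 1")
    if n_range[0] < 1.0:
        raise ValueError("n_range: refractive index must be >= 1")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")

    rng = np.random.default_rng(seed)

    def draw(lo, hi):
        return round(float(rng.uniform(lo, hi)), 6)

    layers = []
    for i in range(n_layers):
        layers.append(
            Layer(
                name=f"layer{i}",
                thickness=draw(*thickness_range_mm) * 1e-3,
                optical=OpticalProperties(
                    mu_a=draw(*mu_a_range_per_cm) * 100.0,
                    mu_s_reduced=draw(*mu_s_prime_range_per_cm) * 100.0,
                    g=draw(*g_range),
                    n=draw(*n_range),
                ),
                thermal=ThermalProperties(rho=1050.0, c_p=3600.0, k=0.5),
                perfused=(i > 0),
            )
        )
    return TissueStack(layers=tuple(layers), blood=BloodModel())
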