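"""Scenario configuration: YAML schema, loading and lossless saving.

Configs use the units of the tissue-optics literature (mm, cm^-1, degrees C,
mW-scale watts); every key carries its unit as a suffix.  Loading converts to
SI once; saving converts back.  Schema (all sections required except
``optics``):

.. code-block:: yaml

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
      montecarlo: {n_photons: 200000, seed: 1, match_indices: false,
                   ambient_n: 1.0}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .diffusion import DiffusionSettings
from .domain import (
    CM_INV,
    MM,
    BloodModel,
    PulseSchedule,
    SourceSpec,
    TissueStack,
    build_stack,
)
from .montecarlo import McSettings
from .pennes import ThermalBoundary, ThermalSettings

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "config_to_dict",
    "stack_to_records",
]

_BACKENDS = ("beer_lambert", "diffusion", "montecarlo")


class ConfigError(ValueError):
    """A scenario config is missing a key or carries an invalid value."""


@dataclass(frozen=True)
class GridSpec:
    dr: float  # m
    dz: float  # m (target; axial edges snap to layer interfaces)
    r_max: float  # m


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    stack: TissueStack
    source: SourceSpec
    grid: GridSpec
    boundary: ThermalBoundary
    thermal: ThermalSettings
    backend: str
    diffusion: DiffusionSettings = field(default_factory=DiffusionSettings)
    montecarlo: McSettings = field(default_factory=McSettings)

    def make_grid(self):
        from .domain import make_grid

        return make_grid(self.stack, dr=self.grid.dr, dz=self.grid.dz,
                         r_max=self.grid.r_max)


def _need(d: Mapping, key: str, where: str):
    try:
        return d[key]
    except (KeyError, TypeError):
        raise ConfigError(f"missing key '{where}.{key}'") from None


def load_config(src) -> ScenarioConfig:
    """Load a scenario from a YAML path, YAML text, or an already-parsed dict."""
    if isinstance(src, Mapping):
        doc = dict(src)
    else:
        text = str(src)
        if "\n" not in text:
            p = Path(text)
            if not p.exists():
                raise ConfigError(f"config file not found: {text}")
            text = p.read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigError("config must be a mapping of sections")

    name = str(doc.get("name", "scenario"))
    stack_sec = _need(doc, "stack", name)
    try:
        stack = build_stack(_need(stack_sec, "layers", "stack"),
                            blood=stack_sec.get("blood"))
    except ValueError as exc:
        raise ConfigError(f"stack: {exc}") from exc

    src_sec = _need(doc, "source", name)
    pulse_sec = src_sec.get("pulse") or {}
    try:
        pulse = PulseSchedule(
            duty_cycle=float(pulse_sec.get("duty_cycle", 1.0)),
            frequency=float(pulse_sec.get("frequency_hz", 1.0)),
        )
        source = SourceSpec(
            power=float(_need(src_sec, "power_w", "source")),
            waist=float(_need(src_sec, "waist_mm", "source")) * MM,
            profile=str(src_sec.get("profile", "gaussian")),
            pulse=pulse,
        )
    except ValueError as exc:
        raise ConfigError(f"source: {exc}") from exc

    grid_sec = _need(doc, "grid", name)
    dz_raw = _need(grid_sec, "dz_mm", "grid")
    dz = ({k: float(v) * MM for k, v in dz_raw.items()}
          if isinstance(dz_raw, Mapping) else float(dz_raw) * MM)
    grid = GridSpec(
        dr=float(_need(grid_sec, "dr_mm", "grid")) * MM,
        dz=dz,
        r_max=float(_need(grid_sec, "r_max_mm", "grid")) * MM,
    )

    tb = doc.get("thermal_boundary", {})
    boundary = ThermalBoundary(
        h=float(tb.get("h_w_m2_k", 10.0)),
        T_ambient=float(tb.get("ambient_temp_c", 23.0)) + 273.15,
    )

    run = doc.get("run", {})
    backend = str(run.get("backend", "diffusion"))
    if backend not in _BACKENDS:
        raise ConfigError(f"run.backend must be one of {_BACKENDS}, got '{backend}'")
    thermal = ThermalSettings(
        dt=float(run.get("dt_s", 1.0)),
        t_end=float(run.get("t_end_s", 300.0)),
        scheme=str(run.get("scheme", "backward_euler")),
        snapshot_times=tuple(float(x) for x in run.get("snapshot_times_s", [])),
    )

    opt = doc.get("optics", {})
    dsec = opt.get("diffusion", {})
    diffusion = DiffusionSettings(
        diffusion_convention=str(dsec.get("convention", "standard_third")),
        far_boundary=str(dsec.get("far_boundary", "zero_fluence")),
        source_scaling=str(dsec.get("source_scaling", "beam_power")),
        solver_tol=float(dsec.get("solver_tol", 1e-10)),
    )
    msec = opt.get("montecarlo", {})
    montecarlo = McSettings(
        n_photons=int(msec.get("n_photons", 100_000)),
        seed=int(msec.get("seed", 1)),
        roulette_threshold=float(msec.get("roulette_threshold", 1e-4)),
        roulette_survival=float(msec.get("roulette_survival", 0.1)),
        ambient_n=float(msec.get("ambient_n", 1.0)),
        match_indices=bool(msec.get("match_indices", False)),
    )

    return ScenarioConfig(
        name=name, stack=stack, source=source, grid=grid, boundary=boundary,
        thermal=thermal, backend=backend, diffusion=diffusion,
        montecarlo=montecarlo,
    )


def stack_to_records(stack: TissueStack) -> dict:
    """Back-convert a stack to the config-unit mapping (inverse of build_stack)."""
    layers = []
    for la in stack.layers:
        layers.append(
            {
                "name": la.name,
                "thickness_mm": la.thickness / MM,
                "mu_a_per_cm": la.optical.mu_a / CM_INV,
                "mu_s_prime_per_cm": la.optical.mu_s_reduced / CM_INV,
                "g": la.optical.g,
                "n": la.optical.n,
                "perfused": la.perfused,
                "thermal": {
                    "rho_kg_m3": la.thermal.rho,
                    "c_p_j_kg_k": la.thermal.c_p,
                    "k_w_m_k": la.thermal.k,
                },
            }
        )
    b = stack.blood
    return {
        "layers": layers,
        "blood": {
            "rho_kg_m3": b.rho_b,
            "c_p_j_kg_k": b.c_pb,
            "perfusion_rate_per_s": b.omega_b,
            "arterial_temp_c": b.T_b - 273.15,
            "metabolic_heat_w_m3": b.q_met,
        },
    }


def config_to_dict(cfg: ScenarioConfig) -> dict:
    dz = cfg.grid.dz
    dz_out = ({k: v / MM for k, v in dz.items()} if isinstance(dz, Mapping)
              else dz / MM)
    return {
        "name": cfg.name,
        "stack": stack_to_records(cfg.stack),
        "source": {
            "power_w": cfg.source.power,
            "waist_mm": cfg.source.waist / MM,
            "profile": cfg.source.profile,
            "pulse": {
                "duty_cycle": cfg.source.pulse.duty_cycle,
                "frequency_hz": cfg.source.pulse.frequency,
            },
        },
        "grid": {"dr_mm": cfg.grid.dr / MM, "dz_mm": dz_out,
                 "r_max_mm": cfg.grid.r_max / MM},
        "thermal_boundary": {
            "h_w_m2_k": cfg.boundary.h,
            "ambient_temp_c": cfg.boundary.T_ambient - 273.15,
        },
        "run": {
            "backend": cfg.backend,
            "t_end_s": cfg.thermal.t_end,
            "dt_s": cfg.thermal.dt,
            "scheme": cfg.thermal.scheme,
            "snapshot_times_s": list(cfg.thermal.snapshot_times),
        },
        "optics": {
            "diffusion": {
                "convention": cfg.diffusion.diffusion_convention,
                "far_boundary": cfg.diffusion.far_boundary,
                "source_scaling": cfg.diffusion.source_scaling,
                "solver_tol": cfg.diffusion.solver_tol,
            },
            "montecarlo": {
                "n_photons": cfg.montecarlo.n_photons,
                "seed": cfg.montecarlo.seed,
                "roulette_threshold": cfg.montecarlo.roulette_threshold,
                "roulette_survival": cfg.montecarlo.roulette_survival,
                "ambient_n": cfg.montecarlo.ambient_n,
                "match_indices": cfg.montecarlo.match_indices,
            },
        },
    }


def save_config(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
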