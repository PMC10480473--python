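"""Layered axisymmetric tissue domain: materials, sources and grids.

All quantities are stored in SI units (m, s, K, W).  Absorption and reduced
scattering coefficients are quoted in cm^-1 in the literature and in the
scenario configs; :func:`build_stack` converts them once at the boundary.

The geometry is a stack of plane-parallel layers with ``z = 0`` at the
air-tissue interface and z increasing into the tissue.  Both the optics and
the thermal solvers share the same axisymmetric (r, z) finite-volume grid,
:class:`AxiGrid`, whose axial edges snap to the layer interfaces so that every
cell lies wholly inside one layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "OpticalProperties",
    "ThermalProperties",
    "BloodModel",
    "Layer",
    "TissueStack",
    "PulseSchedule",
    "SourceSpec",
    "AxiGrid",
    "build_stack",
    "layer_at",
    "make_grid",
    "CM_INV",
    "MM",
]

#: multiply a cm^-1 coefficient by this to get m^-1
CM_INV = 100.0
#: multiply a mm length by this to get m
MM = 1e-3


class ValidationError(ValueError):
    """A field of a domain object violates its physical invariant."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class OpticalProperties:
    """Per-layer optical coefficients.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, m^-1.
    mu_s_reduced : float
        Reduced scattering coefficient mu_s' = mu_s (1 - g), m^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection), in [0, 1).  Only the Monte Carlo backend uses it.
    n : float
        Refractive index, >= 1.  Only the Monte Carlo backend uses it.
    """

    mu_a: float
    mu_s_reduced: float = 0.0
    g: float = 0.0
    n: float = 1.4

    def __post_init__(self) -> None:
        _require(self.mu_a >= 0, "mu_a", "absorption coefficient must be >= 0")
        _require(self.mu_s_reduced >= 0, "mu_s_reduced", "reduced scattering must be >= 0")
        _require(0.0 <= self.g < 1.0, "g", "anisotropy must lie in [0, 1)")
        _require(self.n >= 1.0, "n", "refractive index must be >= 1")

    @property
    def mu_s(self) -> float:
        """Unreduced scattering coefficient mu_s' / (1 - g), m^-1."""
        return self.mu_s_reduced / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, m^-1 (MC step length)."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class ThermalProperties:
    """Density (kg/m^3), specific heat (J/kg/K) and conductivity (W/m/K)."""

    rho: float
    c_p: float
    k: float

    def __post_init__(self) -> None:
        _require(self.rho > 0, "rho", "density must be > 0")
        _require(self.c_p > 0, "c_p", "specific heat must be > 0")
        _require(self.k > 0, "k", "thermal conductivity must be > 0")


@dataclass(frozen=True)
class BloodModel:
    """Arterial blood pool entering the Pennes perfusion term.

    The perfusion heat sink rho_b * c_pb * omega_b * (T_b - T) acts in every
    layer flagged ``perfused``; Q_met is the metabolic volumetric heat applied
    throughout the tissue.
    """

    rho_b: float = 1060.0
    c_pb: float = 3600.0
    omega_b: float = 1.0e-3
    T_b: float = 310.15
    q_met: float = 1000.0

    def __post_init__(self) -> None:
        _require(self.rho_b > 0, "rho_b", "blood density must be > 0")
        _require(self.c_pb > 0, "c_pb", "blood specific heat must be > 0")
        _require(self.omega_b >= 0, "omega_b", "perfusion rate must be >= 0")
        _require(self.q_met >= 0, "q_met", "metabolic heat must be >= 0")


@dataclass(frozen=True)
class Layer:
    name: str
    thickness: float  # m
    optical: OpticalProperties
    thermal: ThermalProperties
    perfused: bool = False

    def __post_init__(self) -> None:
        _require(self.thickness > 0, "thickness", f"layer '{self.name}' must have thickness > 0")


# documented default thermal set for soft tissue (the source papers in this
# problem area rarely print these; values are standard literature skin values)
DEFAULT_THERMAL = ThermalProperties(rho=1050.0, c_p=3600.0, k=0.5)


@dataclass(frozen=True)
class TissueStack:
    """Ordered layers, top to bottom, plus the blood model.

    Interface depths are half-open: a depth exactly on an interface belongs to
    the layer *below* it.
    """

    layers: tuple[Layer, ...]
    blood: BloodModel = field(default_factory=BloodModel)

    def __post_init__(self) -> None:
        _require(len(self.layers) >= 1, "layers", "stack needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def interfaces(self) -> np.ndarray:
        """Cumulative interface depths, m: [0, d1, d1+d2, ...]."""
        return np.concatenate([[0.0], np.cumsum([la.thickness for la in self.layers])])

    @property
    def total_depth(self) -> float:
        return float(self.interfaces[-1])

    def layer_names(self) -> list[str]:
        return [la.name for la in self.layers]

    def layer_index_of(self, name: str) -> int:
        for i, la in enumerate(self.layers):
            if la.name == name:
                return i
        raise KeyError(f"no layer named '{name}'; layers are {self.layer_names()}")


@dataclass(frozen=True)
class PulseSchedule:
    """Square-wave source modulation.

    duty_cycle = 1 means continuous exposure; otherwise the source is ON for
    ``duty_cycle / frequency`` seconds at the start of every period.
    """

    duty_cycle: float = 1.0
    frequency: float = 1.0

    def __post_init__(self) -> None:
        _require(0.0 < self.duty_cycle <= 1.0, "duty_cycle", "must lie in (0, 1]")
        _require(self.frequency > 0, "frequency", "pulse repetition rate must be > 0")

    @property
    def continuous(self) -> bool:
        return self.duty_cycle >= 1.0


@dataclass(frozen=True)
class SourceSpec:
    """Gaussian beam: total power P (W) and 1/e^2 intensity radius w (m).

    On-axis peak irradiance is 2 P / (pi w^2).
    """

    power: float
    waist: float
    profile: str = "gaussian"
    pulse: PulseSchedule = field(default_factory=PulseSchedule)

    def __post_init__(self) -> None:
        _require(self.power >= 0, "power", "beam power must be >= 0")
        _require(self.waist > 0, "waist", "beam waist must be > 0")
        _require(self.profile == "gaussian", "profile", "only 'gaussian' is supported")

    def surface_irradiance(self, r: np.ndarray) -> np.ndarray:
        """Incident irradiance profile I(r) = 2P/(pi w^2) exp(-2 r^2 / w^2)."""
        peak = 2.0 * self.power / (math.pi * self.waist**2)
        return peak * np.exp(-2.0 * np.asarray(r) ** 2 / self.waist**2)


@dataclass(frozen=True)
class AxiGrid:
    """Axisymmetric finite-volume grid shared by optics and thermal solvers.

    Cells are indexed ``[j, i]`` = (axial, radial).  ``layer_index[j]`` maps
    each axial row of cells to its tissue layer (layers are plane-parallel, so
    the assignment depends on z only).
    """

    r_edges: np.ndarray  # (nr+1,), m, starting at 0
    z_edges: np.ndarray  # (nz+1,), m, starting at 0
    layer_index: np.ndarray  # (nz,), int

    def __post_init__(self) -> None:
        r = np.asarray(self.r_edges, dtype=float)
        z = np.asarray(self.z_edges, dtype=float)
        _require(r[0] == 0.0, "r_edges", "radial edges must start at r = 0")
        _require(np.all(np.diff(r) > 0), "r_edges", "edges must be strictly increasing")
        _require(np.all(np.diff(z) > 0), "z_edges", "edges must be strictly increasing")
        object.__setattr__(self, "r_edges", r)
        object.__setattr__(self, "z_edges", z)
        object.__setattr__(self, "layer_index", np.asarray(self.layer_index, dtype=np.int64))

    @property
    def nr(self) -> int:
        return len(self.r_edges) - 1

    @property
    def nz(self) -> int:
        return len(self.z_edges) - 1

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    @property
    def ring_areas(self) -> np.ndarray:
        """Annular cross-section area of each radial ring, m^2; shape (nr,)."""
        return math.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)

    @property
    def cell_volumes(self) -> np.ndarray:
        """Cell volumes, m^3; shape (nz, nr)."""
        return np.outer(self.dz, self.ring_areas)

    @property
    def r_max(self) -> float:
        return float(self.r_edges[-1])

    @property
    def z_max(self) -> float:
        return float(self.z_edges[-1])


# ---------------------------------------------------------------------------
# constructors


def _layer_from_record(rec: Mapping, idx: int) -> Layer:
    """Build a Layer from a config-unit record (mm, cm^-1)."""
    name = str(rec.get("name", f"layer{idx}"))
    try:
        thickness = float(rec["thickness_mm"]) * MM
    except KeyError as exc:
        raise ValidationError(f"layer '{name}': missing key {exc}") from None
    optical = OpticalProperties(
        mu_a=float(rec.get("mu_a_per_cm", 0.0)) * CM_INV,
        mu_s_reduced=float(rec.get("mu_s_prime_per_cm", 0.0)) * CM_INV,
        g=float(rec.get("g", 0.0)),
        n=float(rec.get("n", 1.4)),
    )
    th = rec.get("thermal", {})
    thermal = ThermalProperties(
        rho=float(th.get("rho_kg_m3", DEFAULT_THERMAL.rho)),
        c_p=float(th.get("c_p_j_kg_k", DEFAULT_THERMAL.c_p)),
        k=float(th.get("k_w_m_k", DEFAULT_THERMAL.k)),
    )
    return Layer(name=name, thickness=thickness, optical=optical,
                 thermal=thermal, perfused=bool(rec.get("perfused", False)))


def build_stack(layer_specs: Sequence[Mapping], blood: BloodModel | Mapping | None = None) -> TissueStack:
    """Build a validated :class:`TissueStack` from config-unit records.

    Each record carries ``thickness_mm``, ``mu_a_per_cm``, ``mu_s_prime_per_cm``,
    ``g``, ``n``, an optional ``thermal`` sub-record and a ``perfused`` flag;
    coefficients are converted to SI here, once.
    """
    if not layer_specs:
        raise ValidationError("layer_specs: at least one layer is required")
    layers = [_layer_from_record(rec, i) for i, rec in enumerate(layer_specs)]
    if blood is None:
        blood = BloodModel()
    elif isinstance(blood, Mapping):
        blood = BloodModel(
            rho_b=float(blood.get("rho_kg_m3", 1060.0)),
            c_pb=float(blood.get("c_p_j_kg_k", 3600.0)),
            omega_b=float(blood.get("perfusion_rate_per_s", 1.0e-3)),
            T_b=float(blood.get("arterial_temp_c", 37.0)) + 273.15,
            q_met=float(blood.get("metabolic_heat_w_m3", 1000.0)),
        )
    return TissueStack(layers=tuple(layers), blood=blood)


def layer_at(stack: TissueStack, z: float) -> Layer:
    """Layer containing depth ``z`` (half-open [top, bottom) intervals).

    A depth exactly on an interface belongs to the layer below it.
    """
    depth = stack.total_depth
    if not (0.0 <= z < depth):
        raise ValueError(f"depth z={z!r} m outside the stack [0, {depth}) m")
    iface = stack.interfaces
    idx = int(np.searchsorted(iface, z, side="right")) - 1
    return stack.layers[idx]


def make_grid(
    stack: TissueStack,
    dr: float,
    dz: float | Mapping[str, float],
    r_max: float,
) -> AxiGrid:
    """Discretize the stack on an axisymmetric grid.

    ``dz`` is a target axial spacing (scalar, or per-layer-name mapping); each
    layer is subdivided into ``ceil(thickness/dz)`` equal cells, so the axial
    edges snap exactly to the layer interfaces.  ``dr`` is the uniform radial
    spacing; the radial extent is rounded up to a whole number of cells.
    """
    if dr <= 0:
        raise ValidationError("dr: radial spacing must be > 0")
    if r_max <= 0:
        raise ValidationError("r_max: radial extent must be > 0")

    nr = int(math.ceil(r_max / dr - 1e-9))
    r_edges = np.arange(nr + 1, dtype=float) * dr

    z_edges = [0.0]
    layer_index: list[int] = []
    for li, layer in enumerate(stack.layers):
        dz_l = float(dz[layer.name]) if isinstance(dz, Mapping) else float(dz)
        if dz_l <= 0:
            raise ValidationError("dz: axial spacing must be > 0")
        if dz_l > layer.thickness * (1 + 1e-9):
            raise ValidationError(
                f"dz: spacing {dz_l} m exceeds the thickness of layer "
                f"'{layer.name}' ({layer.thickness} m); refine dz"
            )
        ncell = int(math.ceil(layer.thickness / dz_l - 1e-9))
        top = z_edges[-1]
        sub = top + layer.thickness * np.arange(1, ncell + 1) / ncell
        z_edges.extend(sub.tolist())
        layer_index.extend([li] * ncell)
        z_edges[-1] = top + layer.thickness  # exact interface snap

    grid = AxiGrid(r_edges=r_edges, z_edges=np.asarray(z_edges),
                   layer_index=np.asarray(layer_index))
    return grid


def cell_property(grid: AxiGrid, stack: TissueStack, getter) -> np.ndarray:
    """Per-axial-row material property broadcast helper; shape (nz,)."""
    vals = np.array([getter(stack.layers[li]) for li in grid.layer_index], dtype=float)
    return vals
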