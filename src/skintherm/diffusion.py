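"""Steady-state diffusion-approximation optics on the axisymmetric grid.

Solves  -div(D grad Phi) + mu_a Phi = 0  in cylindrical (r, z) with a
Dirichlet Gaussian-beam condition at the tissue surface,

    Phi(r, 0) = (2 P / pi w^2) exp(-2 r^2 / w^2),

Neumann symmetry at r = 0 and zero-fluence (or Robin partial-current) far
boundaries.  The transient 1/v dPhi/dt term of the radiative-transfer
diffusion limit is dropped: photon transport equilibrates on picoseconds
while the thermal problem evolves on seconds, so only the stationary field
matters for heating.

Two conventions for the diffusion coefficient are supported:

``standard_third``
    D = 1/(3 (mu_a + mu_s')), the textbook P1 value; in a homogeneous
    absorption-only medium the centerline decays like exp(-sqrt(3) mu_a z).
``reciprocal``
    D = 1/(mu_a + mu_s'); then the homogeneous decay is exactly
    exp(-mu_a z), i.e. it coincides with Beer-Lambert when mu_s' = 0.

Because a Dirichlet surface value does not by itself fix the power delivered
into the tissue, the solved field is by default rescaled so that absorbed +
escaped power equals the beam power P (``source_scaling='beam_power'``): the
model neglects surface reflection, so all incident power enters the medium.
``source_scaling='dirichlet'`` keeps the raw Dirichlet-normalized field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .beer_lambert import AxialProfile
from .domain import AxiGrid, SourceSpec, TissueStack

__all__ = [
    "DiffusionSettings",
    "FluenceField",
    "diffusion_coefficients",
    "solve_fluence",
    "absorbed_fraction_by_layer",
    "centerline_profile",
]


@dataclass(frozen=True)
class DiffusionSettings:
    """Numerical controls for the steady diffusion solve.

    ``v`` (wave speed, m/s) is retained for documentation only: the steady
    solve never uses it.
    """

    diffusion_convention: str = "standard_third"
    far_boundary: str = "zero_fluence"
    source_scaling: str = "beam_power"
    solver_tol: float = 1e-10
    v: float = 2.998e8

    def __post_init__(self) -> None:
        if self.diffusion_convention not in ("standard_third", "reciprocal"):
            raise ValueError(
                "diffusion_convention must be 'standard_third' or 'reciprocal'"
            )
        if self.far_boundary not in ("zero_fluence", "robin"):
            raise ValueError("far_boundary must be 'zero_fluence' or 'robin'")
        if self.source_scaling not in ("beam_power", "dirichlet"):
            raise ValueError("source_scaling must be 'beam_power' or 'dirichlet'")
        if self.solver_tol <= 0:
            raise ValueError("solver_tol must be > 0")


@dataclass(frozen=True)
class FluenceField:
    """Fluence rate Phi(r, z) and the derived absorbed power density.

    ``phi`` and ``q_abs`` have shape (nz, nr); ``q_abs = mu_a * phi`` cell by
    cell.  ``delivered_power`` is the power entering through the top boundary
    (equal to total absorbed + escaped by discrete conservation), and
    ``escaped_fraction`` the share of it leaving through the far boundaries.
    """

    grid: AxiGrid
    phi: np.ndarray
    q_abs: np.ndarray
    escaped_fraction: float
    delivered_power: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def absorbed_power(self) -> float:
        return float(np.sum(self.q_abs * self.grid.cell_volumes))

    def to_csv(self, path) -> None:
        import pandas as pd

        r = np.broadcast_to(self.grid.r_centers, self.phi.shape)
        z = np.broadcast_to(self.grid.z_centers[:, None], self.phi.shape)
        pd.DataFrame(
            {
                "r_m": r.ravel(),
                "z_m": z.ravel(),
                "phi_w_m2": self.phi.ravel(),
                "q_abs_w_m3": self.q_abs.ravel(),
            }
        ).to_csv(path, index=False)


def diffusion_coefficients(stack: TissueStack, convention: str) -> np.ndarray:
    """Per-layer diffusion coefficient D (m) under the chosen convention."""
    mu_tr = np.array(
        [la.optical.mu_a + la.optical.mu_s_reduced for la in stack.layers]
    )
    if np.any(mu_tr <= 0):
        raise ValueError(
            "diffusion requires mu_a + mu_s' > 0 in every layer (D would diverge)"
        )
    if convention == "standard_third":
        return 1.0 / (3.0 * mu_tr)
    return 1.0 / mu_tr


def _assemble(
    grid: AxiGrid,
    D_row: np.ndarray,
    mua_row: np.ndarray,
    surface_phi: np.ndarray,
    far_boundary: str,
):
    """Assemble the finite-volume operator A and right-hand side b.

    Flux between neighbouring cells uses a harmonic (series-resistance)
    transmissibility T = area / (d1/D1 + d2/D2); the Dirichlet surface and
    zero-fluence far boundaries connect through half-cell resistances.
    Returns (A, b, top_T) with top_T the per-column conductance to the
    surface value (needed for the influx diagnostic).
    """
    nr, nz = grid.nr, grid.nz
    n = nr * nz
    dz = grid.dz
    dr = np.diff(grid.r_edges)
    ring = grid.ring_areas
    vol = grid.cell_volumes
    idx = np.arange(n).reshape(nz, nr)

    rows_l: list[np.ndarray] = []
    cols_l: list[np.ndarray] = []
    vals_l: list[np.ndarray] = []

    def add(r, c, v):
        rows_l.append(np.asarray(r).ravel())
        cols_l.append(np.asarray(c).ravel())
        vals_l.append(np.asarray(v).ravel())

    diag = (mua_row[:, None] * vol).ravel()  # absorption sink
    b = np.zeros((nz, nr))

    # radial internal faces (between columns i and i+1), shape (nz, nr-1)
    face_area_r = 2.0 * math.pi * np.outer(dz, grid.r_edges[1:-1])
    half = 0.5 * (dr[:-1] + dr[1:])  # same D either side of a radial face
    T_r = face_area_r * D_row[:, None] / half
    a, c = idx[:, :-1], idx[:, 1:]
    add(a, c, -T_r)
    add(c, a, -T_r)
    add(a, a, T_r)
    add(c, c, T_r)

    # axial internal faces (between rows j and j+1), shape (nz-1, nr)
    resist = 0.5 * dz[:-1] / D_row[:-1] + 0.5 * dz[1:] / D_row[1:]
    T_z = ring[None, :] / resist[:, None]
    a, c = idx[:-1, :], idx[1:, :]
    add(a, c, -T_z)
    add(c, a, -T_z)
    add(a, a, T_z)
    add(c, c, T_z)

    # top Dirichlet boundary (j = 0)
    top_T = ring * D_row[0] / (0.5 * dz[0])
    add(idx[0, :], idx[0, :], top_T)
    b[0, :] = top_T * surface_phi

    # far boundaries: bottom (j = nz-1) and outer radius (i = nr-1)
    bot_half = 0.5 * dz[-1] / D_row[-1]
    out_area = 2.0 * math.pi * grid.r_edges[-1] * dz
    out_half = 0.5 * dr[-1] / D_row
    extra = 0.0 if far_boundary == "zero_fluence" else 2.0  # Robin: -D dPhi/dn = Phi/2
    bot_T = ring / (bot_half + extra)
    out_T = out_area / (out_half + extra)
    add(idx[-1, :], idx[-1, :], bot_T)
    add(idx[:, -1], idx[:, -1], out_T)

    A = sp.coo_matrix(
        (np.concatenate(vals_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n, n),
    ).tocsr()
    A = A + sp.diags(diag)
    return A, b.ravel(), top_T, bot_T, out_T


def solve_fluence(
    stack: TissueStack,
    source: SourceSpec,
    grid: AxiGrid,
    settings: DiffusionSettings | None = None,
) -> FluenceField:
    """Solve the steady diffusion equation for the fluence rate field.

    Raises if the grid does not span the stack, if the radial extent is less
    than three beam waists (the far boundary would clip the beam), or if the
    linear solve fails to reach ``solver_tol``.
    """
    settings = settings or DiffusionSettings()
    if not math.isclose(grid.z_max, stack.total_depth, rel_tol=1e-9):
        raise ValueError(
            f"grid depth {grid.z_max} m does not match stack depth "
            f"{stack.total_depth} m"
        )
    if grid.r_max < 3.0 * source.waist:
        raise ValueError(
            f"grid radial extent {grid.r_max} m < 3 x beam waist "
            f"{source.waist} m; widen r_max"
        )

    D_layer = diffusion_coefficients(stack, settings.diffusion_convention)
    D_row = D_layer[grid.layer_index]
    mua_row = np.array([la.optical.mu_a for la in stack.layers])[grid.layer_index]

    surface_phi = source.surface_irradiance(grid.r_centers)
    A, b, top_T, bot_T, out_T = _assemble(
        grid, D_row, mua_row, surface_phi, settings.far_boundary
    )

    phi = spla.spsolve(A.tocsc(), b)
    bnorm = np.linalg.norm(b)
    residual = np.linalg.norm(A @ phi - b) / bnorm if bnorm > 0 else 0.0
    if not np.isfinite(phi).all() or residual > max(settings.solver_tol, 1e-12) * 1e3:
        raise RuntimeError(
            f"diffusion solve did not converge (relative residual {residual:.3e})"
        )
    phi = phi.reshape(grid.nz, grid.nr)
    phi = np.maximum(phi, 0.0)  # clip FP noise; the continuous solution is >= 0

    vol = grid.cell_volumes
    absorbed = float(np.sum(mua_row[:, None] * phi * vol))
    influx = float(np.sum(top_T * (surface_phi - phi[0, :])))
    escaped = float(np.sum(bot_T * phi[-1, :]) + np.sum(out_T * phi[:, -1]))

    scale = 1.0
    if settings.source_scaling == "beam_power" and influx > 0:
        scale = source.power / influx
    phi = phi * scale
    delivered = influx * scale
    q_abs = mua_row[:, None] * phi
    escaped_frac = escaped / influx if influx > 0 else 0.0

    diag = {
        "residual": residual,
        "raw_influx_w": influx,
        "scale": scale,
        "absorbed_w": absorbed * scale,
        "escaped_w": escaped * scale,
        "conservation_defect": abs(influx - absorbed - escaped) / influx
        if influx > 0
        else 0.0,
        "convention": settings.diffusion_convention,
    }
    return FluenceField(
        grid=grid,
        phi=phi,
        q_abs=q_abs,
        escaped_fraction=escaped_frac,
        delivered_power=delivered,
        diagnostics=diag,
    )


def absorbed_fraction_by_layer(field: FluenceField, stack: TissueStack) -> dict[str, float]:
    """Per-layer share of the delivered power, plus the escaped share.

    Cylindrical-volume integral of q_abs over each layer divided by the power
    delivered through the surface; all fractions plus ``escaped`` sum to 1.
    """
    grid = field.grid
    if len(grid.layer_index) != grid.nz or grid.layer_index.max() >= len(stack.layers):
        raise ValueError("fluence grid is not aligned with this stack")
    vol = grid.cell_volumes
    per_cell = field.q_abs * vol
    out: dict[str, float] = {}
    for li, layer in enumerate(stack.layers):
        mask = grid.layer_index == li
        out[layer.name] = float(per_cell[mask, :].sum())
    total = field.delivered_power
    if total <= 0:
        return {**{k: 0.0 for k in out}, "escaped": 0.0}
    out = {k: v / total for k, v in out.items()}
    out["escaped"] = field.escaped_fraction
    return out


def centerline_profile(field: FluenceField) -> AxialProfile:
    """Phi(0, z) / Phi(0, 0): innermost-column fluence, normalized at the
    first tissue cell."""
    col = field.phi[:, 0]
    if col[0] <= 0:
        raise ValueError("surface fluence is zero; nothing to normalize")
    return AxialProfile(z=field.grid.z_centers, value=col / col[0])
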