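"""Transient Pennes bioheat solver on the axisymmetric grid.

The temperature field obeys

    rho c_p dT/dt = div(k grad T) + rho_b c_pb omega_b (T_b - T) + Q_met + Q(t)

with the perfusion sink active only in layers flagged ``perfused`` and the
electromagnetic heat source Q = q_abs * s(t), where q_abs comes from any
optics backend and s(t) is the unit square wave of the pulse schedule
(s = 1 for a continuous source).  The advection term rho c_p u . grad T of
the general heat balance is carried with u = 0: bulk blood motion is already
represented by the perfusion sink, and no velocity field is available for
tissue.

Boundary conditions: convective flux -k dT/dz = h (T - T_ambient) at the
skin surface z = 0; all far boundaries insulated (the padded domain stands in
for the infinite surroundings).  Because the discrete system is linear and
time-invariant, the plateau of the transient is the solution of the steady
system, which :func:`solve_steady_rise` computes directly; the implicit
transient solver (backward Euler default, Crank-Nicolson optional) is used
for time histories and pulsed envelopes.

Temperature rises are always reported relative to the no-source baseline
*field* (convection makes the unexposed steady state non-uniform), never
relative to a uniform 37 C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .domain import AxiGrid, PulseSchedule, TissueStack

__all__ = [
    "ThermalBoundary",
    "ThermalSettings",
    "TemperatureResult",
    "solve_baseline",
    "solve_steady_rise",
    "solve_transient",
    "pulse_signal",
    "steady_max_rise",
    "pulsed_plateau_rise",
]


@dataclass(frozen=True)
class ThermalBoundary:
    """Convective skin surface; insulated far boundaries."""

    h: float = 10.0  # W/(m^2 K)
    T_ambient: float = 296.15  # K
    outer: str = "insulated"

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("h: convection coefficient must be >= 0")
        if self.outer != "insulated":
            raise ValueError("outer boundary supports only 'insulated'")


@dataclass(frozen=True)
class ThermalSettings:
    """Time stepping controls for the transient solve."""

    dt: float = 1.0  # s
    t_end: float = 300.0  # s
    scheme: str = "backward_euler"
    advection_velocity: float = 0.0  # m/s; held at zero (see module docstring)
    snapshot_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.scheme not in ("backward_euler", "crank_nicolson"):
            raise ValueError("scheme must be 'backward_euler' or 'crank_nicolson'")
        if self.advection_velocity != 0.0:
            raise ValueError("advection velocity is fixed at zero in this model")


@dataclass(frozen=True)
class TemperatureResult:
    """Baseline field, transient max-rise series and snapshots."""

    baseline: np.ndarray  # (nz, nr), K
    t: np.ndarray  # (nt,), s
    T_max_rise: np.ndarray  # (nt,), K
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)
    schedule: PulseSchedule = field(default_factory=PulseSchedule)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t_s": self.t, "T_max_rise_K": self.T_max_rise}).to_csv(
            path, index=False
        )


def pulse_signal(schedule: PulseSchedule, t) -> np.ndarray | float:
    """Unit square wave: 1 while (t mod 1/f) < duty/f, else 0.

    A continuous schedule (duty = 1) returns 1 for every t >= 0.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    if schedule.continuous:
        out = np.ones_like(tt)
    else:
        period = 1.0 / schedule.frequency
        out = ((tt % period) < schedule.duty_cycle * period).astype(float)
    return out if out.ndim else float(out)


def _material_rows(stack: TissueStack, grid: AxiGrid):
    k_row = np.array([la.thermal.k for la in stack.layers])[grid.layer_index]
    rho_c = np.array([la.thermal.rho * la.thermal.c_p for la in stack.layers])[
        grid.layer_index
    ]
    blood = stack.blood
    perf = np.array(
        [blood.rho_b * blood.c_pb * blood.omega_b if la.perfused else 0.0
         for la in stack.layers]
    )[grid.layer_index]
    return k_row, rho_c, perf


def _assemble_thermal(stack: TissueStack, grid: AxiGrid, boundary: ThermalBoundary):
    """Build K (W/K), the constant source b0 (W), and the capacity diag (J/K).

    K collects conduction, the perfusion sink and the convective surface;
    b0 collects perfusion * T_b, metabolic heat and convection * T_ambient,
    so the steady baseline solves K T = b0 and the transient is
    M dT/dt = -K T + b0 + s(t) q V.
    """
    nr, nz = grid.nr, grid.nz
    n = nr * nz
    dz = grid.dz
    dr = np.diff(grid.r_edges)
    ring = grid.ring_areas
    vol = grid.cell_volumes
    idx = np.arange(n).reshape(nz, nr)
    k_row, rho_c, perf = _material_rows(stack, grid)

    rows_l, cols_l, vals_l = [], [], []

    def add(r, c, v):
        rows_l.append(np.asarray(r).ravel())
        cols_l.append(np.asarray(c).ravel())
        vals_l.append(np.asarray(v).ravel())

    # radial internal faces
    face_area_r = 2.0 * math.pi * np.outer(dz, grid.r_edges[1:-1])
    half = 0.5 * (dr[:-1] + dr[1:])
    T_r = face_area_r * k_row[:, None] / half
    a, c = idx[:, :-1], idx[:, 1:]
    add(a, c, -T_r)
    add(c, a, -T_r)
    add(a, a, T_r)
    add(c, c, T_r)

    # axial internal faces (harmonic conductivity across layer jumps)
    resist = 0.5 * dz[:-1] / k_row[:-1] + 0.5 * dz[1:] / k_row[1:]
    T_z = ring[None, :] / resist[:, None]
    a, c = idx[:-1, :], idx[1:, :]
    add(a, c, -T_z)
    add(c, a, -T_z)
    add(a, a, T_z)
    add(c, c, T_z)

    b0 = np.zeros((nz, nr))

    # convective top surface: series resistance of half-cell conduction + film
    if boundary.h > 0:
        U = 1.0 / (1.0 / boundary.h + 0.5 * dz[0] / k_row[0])
        add(idx[0, :], idx[0, :], U * ring)
        b0[0, :] += U * ring * boundary.T_ambient
    # bottom and outer radius insulated: nothing to add

    # perfusion sink and sources
    perf_cell = perf[:, None] * vol
    add(idx, idx, perf_cell)
    b0 += perf_cell * stack.blood.T_b
    b0 += stack.blood.q_met * vol

    K = sp.coo_matrix(
        (np.concatenate(vals_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n, n),
    ).tocsr()
    M_diag = (rho_c[:, None] * vol).ravel()
    return K, b0.ravel(), M_diag, perf


def solve_baseline(
    stack: TissueStack, grid: AxiGrid, boundary: ThermalBoundary
) -> np.ndarray:
    """Steady no-source temperature field (the rise reference), K.

    Raises if the steady state is unbounded (no convection and no perfusion
    anywhere while metabolic heat is generated).
    """
    K, b0, _, perf = _assemble_thermal(stack, grid, boundary)
    if boundary.h == 0.0 and np.all(perf == 0.0):
        if stack.blood.q_met > 0:
            raise ValueError(
                "unbounded steady state: metabolic heat with h = 0 and no "
                "perfusion has no sink; enable convection or perfusion"
            )
        # pure conduction with insulated boundaries: any constant solves it
        return np.full((grid.nz, grid.nr), stack.blood.T_b)
    T = spla.spsolve(K.tocsc(), b0)
    if not np.isfinite(T).all():
        raise RuntimeError("baseline solve produced non-finite temperatures")
    return T.reshape(grid.nz, grid.nr)


def solve_steady_rise(
    stack: TissueStack,
    grid: AxiGrid,
    boundary: ThermalBoundary,
    q_abs: np.ndarray,
) -> np.ndarray:
    """Steady temperature rise field for a continuous source, K.

    By linearity the rise decouples from the baseline: K dT = q_abs V.  This
    is the exact plateau of the transient solution.
    """
    K, _, _, perf = _assemble_thermal(stack, grid, boundary)
    if boundary.h == 0.0 and np.all(perf == 0.0) and np.any(q_abs > 0):
        raise ValueError("unbounded steady state: source with no heat sink")
    rhs = (np.asarray(q_abs) * grid.cell_volumes).ravel()
    dT = spla.spsolve(K.tocsc(), rhs)
    if not np.isfinite(dT).all():
        raise RuntimeError("steady rise solve produced non-finite temperatures")
    return dT.reshape(grid.nz, grid.nr)


def _time_grid(settings: ThermalSettings, schedule: PulseSchedule) -> np.ndarray:
    """Step times in (0, t_end], subdivided at pulse switching instants."""
    base = np.arange(settings.dt, settings.t_end + 0.5 * settings.dt, settings.dt)
    if len(base) == 0 or base[-1] < settings.t_end - 1e-12:
        base = np.append(base, settings.t_end)
    base[-1] = settings.t_end  # land exactly on t_end
    if schedule.continuous:
        return base
    period = 1.0 / schedule.frequency
    on = schedule.duty_cycle * period
    if settings.dt > on / 10.0 + 1e-12 or settings.dt > (period - on) / 10.0 + 1e-12:
        raise ValueError(
            f"dt = {settings.dt} s does not resolve the pulse: need "
            f"dt <= {min(on, period - on) / 10.0:.3g} s for duty "
            f"{schedule.duty_cycle} at {schedule.frequency} Hz"
        )
    switches = []
    k = 0
    while k * period < settings.t_end:
        for s in (k * period + on, (k + 1) * period):
            if 0.0 < s < settings.t_end:
                switches.append(s)
        k += 1
    t = np.unique(np.concatenate([base, np.asarray(switches)]))
    t = t[(t > 1e-15) & (t <= settings.t_end + 1e-12)]
    # drop near-duplicates (a switch landing on a base step within FP noise)
    keep = np.concatenate([[True], np.diff(t) > 1e-6 * settings.dt])
    t = t[keep]
    t[-1] = settings.t_end
    return t


def solve_transient(
    stack: TissueStack,
    grid: AxiGrid,
    boundary: ThermalBoundary,
    q_abs: np.ndarray,
    schedule: PulseSchedule | None = None,
    settings: ThermalSettings | None = None,
    T0: np.ndarray | None = None,
) -> TemperatureResult:
    """Implicit time integration of the bioheat equation from the baseline.

    The source is q_abs * s(t) with s the unit square wave of ``schedule``
    (piecewise-constant per step: the time grid is subdivided at switching
    instants).  ``T0`` overrides the initial field (used for warm-started
    pulsed envelopes); rises are still reported against the baseline.
    """
    schedule = schedule or PulseSchedule()
    settings = settings or ThermalSettings()
    q = np.asarray(q_abs, dtype=float)
    if q.shape != (grid.nz, grid.nr):
        raise ValueError(f"q_abs shape {q.shape} != grid shape {(grid.nz, grid.nr)}")

    K, b0, M_diag, _ = _assemble_thermal(stack, grid, boundary)
    baseline = solve_baseline(stack, grid, boundary)
    qv = (q * grid.cell_volumes).ravel()

    T = (baseline if T0 is None else np.asarray(T0, dtype=float)).ravel().copy()
    times = _time_grid(settings, schedule)
    n = len(T)
    M = sp.diags(M_diag)

    out_t = [0.0]
    out_rise = [float(np.max(T - baseline.ravel()))]
    snapshots: dict[float, np.ndarray] = {}
    snap_left = sorted(settings.snapshot_times)

    cn = settings.scheme == "crank_nicolson"
    factor_cache: dict[float, spla.SuperLU] = {}
    t_prev = 0.0
    for t_now in times:
        dt_k = t_now - t_prev
        key = dt_k
        if key not in factor_cache:
            A = (M / dt_k + (0.5 * K if cn else K)).tocsc()
            factor_cache[key] = spla.splu(A)
        lu = factor_cache[key]
        s_mid = float(pulse_signal(schedule, 0.5 * (t_prev + t_now)))
        rhs = M_diag / dt_k * T + b0 + s_mid * qv
        if cn:
            rhs = rhs - 0.5 * (K @ T)
        T = lu.solve(rhs)
        if not np.isfinite(T).all():
            raise RuntimeError(
                f"transient solve produced non-finite temperatures at t={t_now} s"
            )
        out_t.append(t_now)
        out_rise.append(float(np.max(T - baseline.ravel())))
        while snap_left and snap_left[0] <= t_now + 1e-12:
            snapshots[snap_left.pop(0)] = T.reshape(grid.nz, grid.nr).copy()
        t_prev = t_now

    return TemperatureResult(
        baseline=baseline,
        t=np.asarray(out_t),
        T_max_rise=np.asarray(out_rise),
        snapshots=snapshots,
        schedule=schedule,
    )


def steady_max_rise(result: TemperatureResult, tol: float = 1e-3) -> float:
    """Plateau max-rise of a transient run, K.

    For continuous runs the late-time slope of T_max_rise must be below
    ``tol`` (K/s); for pulsed runs the criterion applies to the per-cycle
    maximum envelope.  Raises if the run has not flattened.
    """
    t, rise = result.t, result.T_max_rise
    if len(t) < 3:
        raise ValueError("time series too short to assess a plateau")
    if result.schedule.continuous:
        i0 = np.searchsorted(t, 0.9 * t[-1])
        i0 = min(i0, len(t) - 2)
        slope = abs(rise[-1] - rise[i0]) / max(t[-1] - t[i0], 1e-30)
        if slope > tol:
            raise ValueError(
                f"not at plateau: late-time slope {slope:.3g} K/s > tol {tol}; "
                "increase t_end"
            )
        return float(rise[-1])
    period = 1.0 / result.schedule.frequency
    cyc = np.floor((t - 1e-12) / period).astype(int)
    n_cyc = cyc.max()
    if n_cyc < 2:
        raise ValueError("fewer than two full pulse cycles; increase t_end")
    last = np.max(rise[cyc == n_cyc - 1])
    prev = np.max(rise[cyc == n_cyc - 2])
    if abs(last - prev) / period > tol:
        raise ValueError(
            f"pulsed envelope not at plateau (cycle-max drift "
            f"{abs(last - prev) / period:.3g} K/s > tol {tol}); increase t_end"
        )
    return float(last)


def pulsed_plateau_rise(
    stack: TissueStack,
    grid: AxiGrid,
    boundary: ThermalBoundary,
    q_abs: np.ndarray,
    schedule: PulseSchedule,
    rel_tol: float = 1e-3,
    max_periods: int = 64,
) -> float:
    """Plateau of the per-cycle maximum rise for a pulsed source, K.

    Exploits linearity: the long-time mean field equals duty * the continuous
    steady rise, so the integration is warm-started there and marched whole
    cycles until consecutive cycle maxima agree to ``rel_tol``; only the
    periodic ripple needs to converge, not the slow thermal transient.
    Continuous schedules return the steady maximum directly.
    """
    steady = solve_steady_rise(stack, grid, boundary, q_abs)
    if schedule.continuous:
        return float(np.max(steady))
    baseline = solve_baseline(stack, grid, boundary)
    period = 1.0 / schedule.frequency
    on = schedule.duty_cycle * period
    dt = min(on, period - on) / 10.0
    T0 = baseline + schedule.duty_cycle * steady

    chunk = 4
    prev_max: float | None = None
    T_start = T0
    for _ in range(max_periods // chunk):
        settings = ThermalSettings(
            dt=dt, t_end=chunk * period, snapshot_times=(chunk * period,)
        )
        res = solve_transient(
            stack, grid, boundary, q_abs, schedule, settings, T0=T_start
        )
        cyc = np.floor((res.t - 1e-12) / period).astype(int)
        last_max = float(np.max(res.T_max_rise[cyc == chunk - 1]))
        if prev_max is not None and abs(last_max - prev_max) <= rel_tol * max(
            abs(last_max), 1e-30
        ):
            return last_max
        prev_max = last_max
        # continue from the final field (phase-aligned: whole periods)
        T_start = res.snapshots[chunk * period]
    raise RuntimeError(
        f"pulsed envelope did not stabilise within {max_periods} periods"
    )
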