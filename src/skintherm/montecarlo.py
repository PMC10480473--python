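"""Layered Monte Carlo photon transport (hop / drop / spin with weights).

Photons are launched at z = 0, collimated along +z, with radial position
sampled from the Gaussian intensity profile of the beam.  Inside a layer the
step length is s = -ln(U)/(mu_a + mu_s); at each interaction a fraction
mu_a/mu_t of the weight is deposited in the local (r, z) cell and the
direction is redrawn from the Henyey-Greenstein phase function.  Refractive
index mismatches at the top surface and between layers are handled with the
unpolarized Fresnel coefficients (total internal reflection included); the
bottom face of the stack is a domain truncation and photons crossing it are
tallied as transmitted without a Fresnel event.  Low-weight photons undergo
Russian roulette.  Runs are bit-reproducible for a fixed seed.

Scoring is axisymmetric: deposited weight is binned on the shared
:class:`~skintherm.domain.AxiGrid`; photons that wander radially outside the
grid keep propagating and their absorption still enters the global energy
bookkeeping (specular + diffuse reflection + transmission + absorption = 1).
Per-layer fractions and the innermost-ring depth profile are also accumulated
in photon batches, which provides standard errors without storing per-photon
histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .beer_lambert import AxialProfile
from .domain import AxiGrid, SourceSpec, TissueStack

__all__ = [
    "McSettings",
    "McTally",
    "run_mc",
    "sample_henyey_greenstein",
    "fresnel_reflectance",
    "mc_centerline_profile",
]

N_BATCHES = 16


@dataclass(frozen=True)
class McSettings:
    n_photons: int = 100_000
    seed: int = 1
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    ambient_n: float = 1.0
    #: override every layer's refractive index with ambient_n (matched-index
    #: comparison mode, mirroring the diffusion model's no-reflection
    #: assumption); None keeps the configured per-layer indices.
    match_indices: bool = False

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not (0.0 < self.roulette_survival < 1.0):
            raise ValueError("roulette_survival must lie in (0, 1)")
        if not (0.0 < self.roulette_threshold < 1.0):
            raise ValueError("roulette_threshold must lie in (0, 1)")
        if self.ambient_n < 1.0:
            raise ValueError("ambient_n must be >= 1")


@dataclass(frozen=True)
class McTally:
    """Absorbed-weight tallies and derived fluence on the grid."""

    grid: AxiGrid
    absorbed: np.ndarray  # (nz, nr) deposited weight (per launched photon)
    specular_reflected: float
    diffuse_reflected: float
    transmitted: float
    absorbed_total: float  # includes weight deposited radially outside the grid
    power: float  # beam power, W
    n_photons: int
    seed: int
    #: net weight created minus destroyed by Russian roulette; the exact
    #: per-run identity is spec + diff + trans + absorbed = 1 + roulette_net
    roulette_net: float = 0.0
    #: per-batch innermost-ring absorbed weight vs depth, (N_BATCHES, nz)
    ring0_batches: np.ndarray = field(repr=False, default=None)
    #: per-batch per-layer absorbed weight, (N_BATCHES, n_layers)
    layer_batches: np.ndarray = field(repr=False, default=None)
    mua_row: np.ndarray = field(repr=False, default=None)

    def fluence(self) -> np.ndarray:
        """Phi per cell, W/m^2: absorbed*P / (mu_a * V * N); NaN where mu_a=0."""
        vol = self.grid.cell_volumes
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = self.absorbed * self.power / (self.mua_row[:, None] * vol)
        phi[:, :] = np.where(self.mua_row[:, None] > 0, phi, np.nan)
        return phi

    def q_abs(self) -> np.ndarray:
        """Absorbed power density, W/m^3 (defined even where mu_a = 0)."""
        return self.absorbed * self.power / self.grid.cell_volumes

    def weight_fractions(self) -> dict[str, float]:
        return {
            "specular_reflected": self.specular_reflected,
            "diffuse_reflected": self.diffuse_reflected,
            "transmitted": self.transmitted,
            "absorbed_total": self.absorbed_total,
            "roulette_net": self.roulette_net,
        }

    def layer_fractions(self) -> np.ndarray:
        """Mean per-layer absorbed fraction over batches, (n_layers,)."""
        return self.layer_batches.sum(axis=0)

    def layer_fraction_stderr(self) -> np.ndarray:
        m = self.layer_batches * N_BATCHES  # per-batch fraction estimates
        return m.std(axis=0, ddof=1) / math.sqrt(N_BATCHES)


@njit(cache=True)
def _hg_cos(g: float, u: float) -> float:
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def _fresnel(n_i: float, n_t: float, cos_i: float) -> float:
    if n_i == n_t:
        return 0.0
    if cos_i > 1.0:
        cos_i = 1.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_i / n_t * sin_i
    if sin_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp)


def sample_henyey_greenstein(g: float, u: float) -> float:
    """Deflection cosine from the HG inverse CDF; isotropic for g = 0."""
    if not (0.0 <= g < 1.0):
        raise ValueError("anisotropy g must lie in [0, 1)")
    if not (0.0 <= u < 1.0):
        raise ValueError("uniform variate u must lie in [0, 1)")
    return _hg_cos(g, u)


def fresnel_reflectance(n_i: float, n_t: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance for incidence cosine ``cos_i``."""
    if n_i < 1.0 or n_t < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if not (0.0 <= cos_i <= 1.0):
        raise ValueError("cos_i must lie in [0, 1]")
    return _fresnel(n_i, n_t, cos_i)


@njit(cache=True)
def _kernel(
    seed,
    n_photons,
    z_bounds,
    mua,
    mus,
    g_arr,
    n_arr,
    ambient_n,
    waist,
    r_edges,
    z_edges,
    layer_of_zcell,
    w_threshold,
    w_survival,
    n_batches,
):
    np.random.seed(seed)
    n_layers = len(mua)
    nr = len(r_edges) - 1
    nz = len(z_edges) - 1
    dr = r_edges[1] - r_edges[0]
    r_max = r_edges[nr]
    depth = z_bounds[n_layers]

    absorbed = np.zeros((nz, nr))
    ring0 = np.zeros((n_batches, nz))
    layer_w = np.zeros((n_batches, n_layers))
    spec_r = 0.0
    diff_r = 0.0
    trans = 0.0
    abs_tot = 0.0
    roulette_net = 0.0  # weight created minus weight destroyed by roulette

    batch_size = (n_photons + n_batches - 1) // n_batches
    tiny = 1e-30

    for ph in range(n_photons):
        batch = min(ph // batch_size, n_batches - 1)
        # launch: collimated, Gaussian-intensity radial position
        u = np.random.random()
        r0 = waist * math.sqrt(-math.log(1.0 - u + tiny) / 2.0)
        phi0 = 2.0 * math.pi * np.random.random()
        x = r0 * math.cos(phi0)
        y = r0 * math.sin(phi0)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        lay = 0

        # specular reflection at the air-tissue surface
        if ambient_n != n_arr[0]:
            rsp = _fresnel(ambient_n, n_arr[0], 1.0)
            spec_r += rsp
            w -= rsp

        alive = True
        while alive:
            mut = mua[lay] + mus[lay]
            if mut <= tiny:
                # transparent layer: free flight; overshoot the boundary so
                # the interface branch below fires and changes layer
                if uz > tiny:
                    db = (z_bounds[lay + 1] - z) / uz
                elif uz < -tiny:
                    db = (z_bounds[lay] - z) / uz
                else:
                    trans += w  # grazing ray in a void layer: leaves sideways
                    break
                s = db * (1.0 + 1e-9) + 1e-15
            else:
                s = -math.log(np.random.random() + tiny) / mut

            # walk the step across as many interfaces as it spans
            while True:
                if uz > tiny:
                    db = (z_bounds[lay + 1] - z) / uz
                elif uz < -tiny:
                    db = (z_bounds[lay] - z) / uz
                else:
                    db = 1e30
                if s <= db:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    hit = False
                    break
                # move to the interface
                x += ux * db
                y += uy * db
                z += uz * db
                s = 0.0  # memoryless: resample in the next medium
                hit = True
                going_down = uz > 0.0
                if going_down:
                    if lay == n_layers - 1:
                        trans += w  # truncation face: matched exit
                        alive = False
                        break
                    n1 = n_arr[lay]
                    n2 = n_arr[lay + 1]
                else:
                    n1 = n_arr[lay]
                    n2 = ambient_n if lay == 0 else n_arr[lay - 1]
                cos_i = abs(uz)
                R = _fresnel(n1, n2, cos_i)
                if np.random.random() < R:
                    uz = -uz  # reflect
                else:
                    if not going_down and lay == 0:
                        diff_r += w  # escapes through the surface
                        alive = False
                        break
                    # refract into the neighbour layer
                    ratio = n1 / n2
                    sin_i2 = max(0.0, 1.0 - cos_i * cos_i)
                    sin_t2 = ratio * ratio * sin_i2
                    cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
                    ux *= ratio
                    uy *= ratio
                    uz = cos_t if going_down else -cos_t
                    lay = lay + 1 if going_down else lay - 1
                if alive and s == 0.0:
                    break  # resample step in the (possibly new) layer
            if not alive:
                break
            if hit:
                continue  # interface handled; draw a fresh step

            if mut <= tiny:
                continue  # crossed a transparent layer without interacting

            # drop
            dw = w * mua[lay] / mut
            if dw > 0.0:
                abs_tot += dw
                layer_w[batch, lay] += dw
                rr = math.sqrt(x * x + y * y)
                if rr < r_max and 0.0 <= z < depth:
                    ir = int(rr / dr)
                    if ir >= nr:
                        ir = nr - 1
                    iz = np.searchsorted(z_edges, z, side="right") - 1
                    if iz < 0:
                        iz = 0
                    elif iz >= nz:
                        iz = nz - 1
                    absorbed[iz, ir] += dw
                    if ir == 0:
                        ring0[batch, iz] += dw
            w -= dw
            if w <= tiny:
                break  # everything deposited (absorption-only media)

            # roulette; the net weight it creates/destroys is tracked so the
            # energy bookkeeping stays an exact per-run identity
            if w < w_threshold:
                if np.random.random() < w_survival:
                    roulette_net += w * (1.0 / w_survival - 1.0)
                    w /= w_survival
                else:
                    roulette_net -= w
                    break

            # spin
            ct = _hg_cos(g_arr[lay], np.random.random())
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            psi = 2.0 * math.pi * np.random.random()
            cp = math.cos(psi)
            sp = math.sin(psi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct * (1.0 if uz >= 0.0 else -1.0)
            else:
                denom = math.sqrt(1.0 - uz * uz)
                ux_n = st * (ux * uz * cp - uy * sp) / denom + ux * ct
                uy_n = st * (uy * uz * cp + ux * sp) / denom + uy * ct
                uz_n = -st * cp * denom + uz * ct
                ux, uy, uz = ux_n, uy_n, uz_n
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm

    inv = 1.0 / n_photons
    return (
        absorbed * inv,
        ring0 * inv,
        layer_w * inv,
        spec_r * inv,
        diff_r * inv,
        trans * inv,
        abs_tot * inv,
        roulette_net * inv,
    )


def run_mc(
    stack: TissueStack,
    source: SourceSpec,
    grid: AxiGrid,
    settings: McSettings | None = None,
) -> McTally:
    """Run the photon-transport simulation and tally absorbed weight.

    Deterministic for a fixed ``settings.seed``.  Radial cells must be
    uniform (they are whenever the grid comes from :func:`make_grid`).
    """
    settings = settings or McSettings()
    drs = np.diff(grid.r_edges)
    if not np.allclose(drs, drs[0]):
        raise ValueError("Monte Carlo scoring requires uniform radial spacing")
    if grid.r_max < 3.0 * source.waist:
        raise ValueError(
            f"grid radial extent {grid.r_max} m < 3 x beam waist {source.waist} m"
        )
    mua = np.array([la.optical.mu_a for la in stack.layers])
    mus = np.array([la.optical.mu_s for la in stack.layers])
    if np.all(mua + mus <= 0):
        raise ValueError("stack has no interaction anywhere (mu_a + mu_s = 0)")
    g_arr = np.array([la.optical.g for la in stack.layers])
    n_arr = np.array([la.optical.n for la in stack.layers])
    if settings.match_indices:
        n_arr = np.full_like(n_arr, settings.ambient_n)

    absorbed, ring0, layer_w, spec, diffr, trans, abstot, rnet = _kernel(
        settings.seed,
        settings.n_photons,
        stack.interfaces,
        mua,
        mus,
        g_arr,
        n_arr,
        settings.ambient_n,
        source.waist,
        grid.r_edges,
        grid.z_edges,
        grid.layer_index,
        settings.roulette_threshold,
        settings.roulette_survival,
        N_BATCHES,
    )
    mua_row = mua[grid.layer_index]
    return McTally(
        grid=grid,
        absorbed=absorbed,
        specular_reflected=float(spec),
        diffuse_reflected=float(diffr),
        transmitted=float(trans),
        absorbed_total=float(abstot),
        power=source.power,
        n_photons=settings.n_photons,
        seed=settings.seed,
        roulette_net=float(rnet),
        ring0_batches=ring0,
        layer_batches=layer_w,
        mua_row=mua_row,
    )


def mc_centerline_profile(tally: McTally) -> AxialProfile:
    """Innermost-ring fluence vs depth, normalized at the first tissue cell.

    Standard errors come from the photon-batch spread and are propagated
    through the normalization.
    """
    grid = tally.grid
    vol0 = grid.cell_volumes[:, 0]
    mua = tally.mua_row
    if np.any(mua <= 0):
        raise ValueError("centerline fluence undefined where mu_a = 0")
    batches = tally.ring0_batches * N_BATCHES / (mua[None, :] * vol0[None, :])
    mean = batches.mean(axis=0)
    stderr = batches.std(axis=0, ddof=1) / math.sqrt(N_BATCHES)
    if mean[0] <= 0:
        raise ValueError(
            "no absorbed weight in the innermost ring at the surface; "
            "use more photons or a wider dr"
        )
    norm = mean[0]
    value = mean / norm
    rel = np.sqrt(
        (stderr / np.maximum(mean, 1e-300)) ** 2 + (stderr[0] / norm) ** 2
    )
    return AxialProfile(z=grid.z_centers, value=value, stderr=value * rel)
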