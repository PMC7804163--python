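"""Monte Carlo photon transport in a semi-infinite turbid medium.

Photon-packet random walk (MCML-style) specialised to a single semi-infinite
homogeneous layer: specular deduction at launch, exponential step sampling,
Henyey-Greenstein scattering, unpolarised Fresnel reflection/escape at the top
boundary and Russian roulette termination.  Absorbed weight is scored on a
cylindrical (r, z) grid and converted to fluence; photon-hitting-density (PHD)
maps and the probed depth (depth of the PHD maximum midway between source and
detector fibers) are derived from the fluence maps.

All lengths are handled internally in mm; fiber positions and probed depths
cross the API in µm, matching probe datasheets.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ConfigError, NumericalError

__all__ = [
    "OpticalProperties",
    "GridSpec",
    "FluenceMap",
    "PHDMap",
    "ProbedDepthProfile",
    "simulate_fluence",
    "compute_phd",
    "probed_depth",
    "depth_profile",
]

logger = logging.getLogger(__name__)

#: Russian-roulette weight threshold and survival probability (MCML conventions)
WEIGHT_THRESHOLD = 1e-4
SURVIVAL_PROB = 0.1


@dataclass(frozen=True)
class OpticalProperties:
    """Scalar optical properties of the medium at one wavelength.

    mu_a and mu_s are in 1/mm; g is the scattering anisotropy factor;
    eta_rel / eta_out are the tissue and outer-medium refractive indices.
    """

    mu_a: float
    mu_s: float
    g: float = 0.9
    eta_rel: float = 1.4
    eta_out: float = 1.0

    def __post_init__(self):
        if self.mu_a < 0:
            raise ConfigError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s <= 0:
            raise ConfigError(f"mu_s must be > 0, got {self.mu_s}")
        if not -1 < self.g < 1:
            raise ConfigError(f"g must be in (-1, 1), got {self.g}")
        if self.eta_rel < 1 or self.eta_out < 1:
            raise ConfigError("refractive indices must be >= 1")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g) in 1/mm."""
        return self.mu_s * (1.0 - self.g)


@dataclass(frozen=True)
class GridSpec:
    """Cylindrical scoring grid: 50 µm bins over 5 mm x 5 mm by default."""

    dr_mm: float = 0.05
    dz_mm: float = 0.05
    nr: int = 100
    nz: int = 100

    def __post_init__(self):
        if self.dr_mm <= 0 or self.dz_mm <= 0 or self.nr < 1 or self.nz < 1:
            raise ConfigError("invalid grid specification")

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr_mm

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz_mm


@njit(cache=True, fastmath=True)
def _fresnel(ct_i, n_i, n_t):
    """Unpolarised Fresnel reflectance for internal incidence cosine ct_i."""
    if ct_i > 0.9999999:
        r = (n_i - n_t) / (n_i + n_t)
        return r * r
    st_i = math.sqrt(max(0.0, 1.0 - ct_i * ct_i))
    st_t = n_i / n_t * st_i
    if st_t >= 1.0:
        return 1.0  # total internal reflection
    ct_t = math.sqrt(1.0 - st_t * st_t)
    rs = (n_i * ct_i - n_t * ct_t) / (n_i * ct_i + n_t * ct_t)
    rp = (n_i * ct_t - n_t * ct_i) / (n_i * ct_t + n_t * ct_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _run_mc(mu_a, mu_s, g, n_rel, n_out, n_photons, dr, dz, nr, nz,
            w_min, p_surv, seed):
    """Core photon-packet loop.

    Returns the absorbed-weight grid A[nr, nz], the escaping-weight radial
    profile Rd[nr] and the bookkeeping vector
    [specular, diffuse_total, absorbed_in, absorbed_beyond, roulette_net]
    (all raw weights; the caller normalises by n_photons).
    """
    np.random.seed(seed)
    A = np.zeros((nr, nz))
    Rd = np.zeros(nr)
    book = np.zeros(5)
    mu_t = mu_a + mu_s
    r_sp = ((n_rel - n_out) / (n_rel + n_out)) ** 2

    for _ in range(n_photons):
        book[0] += r_sp
        w = 1.0 - r_sp
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        alive = True
        while alive:
            xi = np.random.random()
            if xi < 1e-300:
                xi = 1e-300
            s = -math.log(xi) / mu_t
            # propagate, handling (possibly repeated) top-boundary hits
            while s > 0.0:
                if uz < 0.0:
                    db = -z / uz
                else:
                    db = 1e30
                if db <= s:
                    x += ux * db
                    y += uy * db
                    z = 0.0
                    s -= db
                    refl = _fresnel(-uz, n_rel, n_out)
                    if np.random.random() <= refl:
                        uz = -uz
                    else:
                        book[1] += w
                        rr = math.sqrt(x * x + y * y)
                        ir = int(rr / dr)
                        if ir < nr:
                            Rd[ir] += w
                        alive = False
                        s = 0.0
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    s = 0.0
            if not alive:
                break

            # absorb
            dw = w * mu_a / mu_t
            if dw > 0.0:
                rr = math.sqrt(x * x + y * y)
                ir = int(rr / dr)
                iz = int(z / dz)
                if ir < nr and iz < nz:
                    A[ir, iz] += dw
                    book[2] += dw
                else:
                    book[3] += dw
                w -= dw

            # Henyey-Greenstein scatter
            xi = np.random.random()
            if abs(g) > 1e-6:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                ct = 2.0 * xi - 1.0
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            st = math.sqrt(1.0 - ct * ct)
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz >= 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uz_n = -st * cp * den + uz * ct
                ux = ux_n
                uy = uy_n
                uz = uz_n

            # Russian roulette (expectation-neutral; net weight bookkept)
            if w < w_min:
                if np.random.random() < p_surv:
                    book[4] -= w * (1.0 / p_surv - 1.0)
                    w /= p_surv
                else:
                    book[4] += w
                    alive = False
    return A, Rd, book


@dataclass
class FluenceMap:
    """Cylindrical fluence grid plus energy bookkeeping for one simulation.

    ``fluence`` is absorbed weight / (bin volume * mu_a * n_photons) and is
    ``None`` when mu_a = 0 (no absorption scored); ``absorbed`` always holds
    the raw absorbed-weight grid.  ``diffuse_radial`` is the escaping weight
    per radial bin (per launched photon).
    """

    grid: GridSpec
    fluence: np.ndarray | None
    absorbed: np.ndarray
    diffuse_radial: np.ndarray
    n_photons: int
    bookkeeping: dict
    props: OpticalProperties
    seed: int

    @property
    def r_centers(self) -> np.ndarray:
        return self.grid.r_centers

    @property
    def z_centers(self) -> np.ndarray:
        return self.grid.z_centers

    def energy_balance(self) -> float:
        """Sum of all bookkeeping channels; equals 1 up to floating error."""
        b = self.bookkeeping
        return (b["specular"] + b["diffuse"] + b["absorbed_in"]
                + b["absorbed_beyond"] + b["roulette_net"])

    def radial_reflectance(self, rho_mm: float, window_mm: float = 0.1) -> float:
        """Diffuse reflectance per unit area (1/mm^2) near radius rho_mm.

        Averages escaping weight over the annular bins whose centers fall
        within ``window_mm`` of ``rho_mm``.
        """
        g = self.grid
        centers = g.r_centers
        mask = np.abs(centers - rho_mm) <= window_mm
        if not np.any(mask):
            raise NumericalError(f"radius {rho_mm} mm outside the scoring grid")
        edges = np.arange(g.nr + 1) * g.dr_mm
        areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        return float(self.diffuse_radial[mask].sum()
                     / (areas[mask].sum() * self.n_photons))


def simulate_fluence(props: OpticalProperties, n_photons: int,
                     grid: GridSpec = GridSpec(), seed: int = 0,
                     weight_threshold: float = WEIGHT_THRESHOLD,
                     survival_prob: float = SURVIVAL_PROB) -> FluenceMap:
    """Run the photon-packet walk and score fluence on the cylindrical grid."""
    n_photons = int(n_photons)
    if n_photons < 1000:
        raise ConfigError("n_photons must be >= 1000")
    seed = int(seed) % (2 ** 32)
    A, Rd, book = _run_mc(props.mu_a, props.mu_s, props.g, props.eta_rel,
                          props.eta_out, n_photons, grid.dr_mm, grid.dz_mm,
                          grid.nr, grid.nz, weight_threshold, survival_prob,
                          seed)
    bookkeeping = {
        "specular": book[0] / n_photons,
        "diffuse": book[1] / n_photons,
        "absorbed_in": book[2] / n_photons,
        "absorbed_beyond": book[3] / n_photons,
        "roulette_net": book[4] / n_photons,
    }
    if props.mu_a > 0:
        edges = np.arange(grid.nr + 1) * grid.dr_mm
        ring_areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        volumes = ring_areas[:, None] * grid.dz_mm
        fluence = A / (volumes * props.mu_a * n_photons)
    else:
        fluence = None
        logger.warning("mu_a = 0: absorbed-weight fluence map unavailable; "
                       "energy bookkeeping still returned")
    return FluenceMap(grid=grid, fluence=fluence, absorbed=A, diffuse_radial=Rd,
                      n_photons=n_photons, bookkeeping=bookkeeping, props=props,
                      seed=seed)


@dataclass
class PHDMap:
    """Cartesian photon-hitting-density map in the plane through both fibers."""

    values: np.ndarray  # shape (nx, nz)
    x_centers_mm: np.ndarray
    z_centers_mm: np.ndarray
    src_x_um: float
    det_x_um: float


def _interp_radial(values: np.ndarray, r_centers: np.ndarray,
                   rq: np.ndarray) -> np.ndarray:
    """Linear interpolation of a cylindrical map over radius, per z column.

    Radii below the first bin center clamp to the first bin; radii beyond the
    last bin center contribute 0.
    """
    nr = r_centers.shape[0]
    out = np.empty((rq.shape[0], values.shape[1]))
    idx = np.clip(np.searchsorted(r_centers, rq), 1, nr - 1)
    t = (rq - r_centers[idx - 1]) / (r_centers[idx] - r_centers[idx - 1])
    t = np.clip(t, 0.0, 1.0)
    out = values[idx - 1] * (1.0 - t)[:, None] + values[idx] * t[:, None]
    out[rq > r_centers[-1]] = 0.0
    return out


_beyond_grid_logged = False


def compute_phd(src_fluence: FluenceMap, det_fluence: FluenceMap,
                src_x_um: float, det_x_um: float,
                x_span_mm: float = 3.75) -> PHDMap:
    """Photon-hitting-density map: product of source and detector fluence.

    Evaluated on a Cartesian (x, z) grid in the plane through both fibers,
    spanning ``x_span_mm`` centered on the fiber midpoint at the fluence-grid
    resolution.  PHD(x, z) = Phi_src(|x - src_x|, z) * Phi_det(|x - det_x|, z)
    with linear interpolation of the cylindrical maps over radius.
    """
    global _beyond_grid_logged
    g = src_fluence.grid
    if det_fluence.grid != g:
        raise ConfigError("source and detector fluence maps use different grids")
    if src_fluence.fluence is None or det_fluence.fluence is None:
        raise NumericalError("PHD requires fluence maps (mu_a > 0)")
    src_mm = src_x_um / 1000.0
    det_mm = det_x_um / 1000.0
    if abs(det_mm - src_mm) > x_span_mm:
        raise ConfigError("fiber separation exceeds the PHD x-extent")
    mid = 0.5 * (src_mm + det_mm)
    nx = int(round(x_span_mm / g.dr_mm))
    x_centers = mid + (np.arange(nx) - (nx - 1) / 2.0) * g.dr_mm
    r_centers = g.r_centers
    r_src = np.abs(x_centers - src_mm)
    r_det = np.abs(x_centers - det_mm)
    if np.any(r_src > r_centers[-1]) or np.any(r_det > r_centers[-1]):
        if not _beyond_grid_logged:
            logger.info("some PHD nodes fall beyond the cylindrical grid; "
                        "their contribution is 0")
            _beyond_grid_logged = True
    phi_s = _interp_radial(src_fluence.fluence, r_centers, r_src)
    phi_d = _interp_radial(det_fluence.fluence, r_centers, r_det)
    return PHDMap(values=phi_s * phi_d, x_centers_mm=x_centers,
                  z_centers_mm=g.z_centers, src_x_um=float(src_x_um),
                  det_x_um=float(det_x_um))


def probed_depth(phd: PHDMap) -> float:
    """Depth (µm) of the PHD maximum in the column nearest the fiber midpoint.

    Ties resolve to the smallest depth; the depth is reported at the bin
    center.  Raises if the midpoint column is identically zero.
    """
    mid_mm = 0.5 * (phd.src_x_um + phd.det_x_um) / 1000.0
    icol = int(np.argmin(np.abs(phd.x_centers_mm - mid_mm)))
    col = phd.values[icol]
    if not np.any(col > 0):
        raise NumericalError("PHD midpoint column is identically zero")
    iz = int(np.argmax(col))  # first occurrence -> smallest z
    return float(phd.z_centers_mm[iz] * 1000.0)


@dataclass
class ProbedDepthProfile:
    """Probed depth per wavelength for one probe geometry."""

    wavelengths: np.ndarray
    depth_um: np.ndarray
    sdd_um: float
    n_photons: int
    seed: int

    @property
    def min_depth_um(self) -> float:
        return float(np.min(self.depth_um))

    @property
    def max_depth_um(self) -> float:
        return float(np.max(self.depth_um))


def depth_profile(wavelengths, props_by_wavelength, sdd_um: float,
                  n_photons: int = 100_000, seed: int = 0,
                  grid: GridSpec = GridSpec(),
                  x_span_mm: float = 3.75) -> ProbedDepthProfile:
    """Probed depth vs wavelength for one source-detector distance.

    Runs one fluence simulation per wavelength and reuses it for both source
    and detector fibers (reciprocity, identical fibers); fibers are placed
    symmetrically at +-sdd/2 about x = 0.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    props_by_wavelength = list(props_by_wavelength)
    if len(props_by_wavelength) != wavelengths.shape[0]:
        raise ConfigError("one OpticalProperties entry required per wavelength")
    depths = np.empty(wavelengths.shape[0])
    master = np.random.SeedSequence([int(seed), 0x5DD])
    child_seeds = [int(s.generate_state(1)[0]) for s in
                   master.spawn(len(props_by_wavelength))]
    for k, props in enumerate(props_by_wavelength):
        fmap = simulate_fluence(props, n_photons, grid=grid, seed=child_seeds[k])
        phd = compute_phd(fmap, fmap, -sdd_um / 2.0, sdd_um / 2.0,
                          x_span_mm=x_span_mm)
        depths[k] = probed_depth(phd)
    return ProbedDepthProfile(wavelengths=wavelengths, depth_um=depths,
                              sdd_um=float(sdd_um), n_photons=int(n_photons),
                              seed=int(seed))
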