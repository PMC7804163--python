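"""Synthetic diffuse-reflectance dataset generation.

Builds two-class (normal mucosa vs tumor) spectra with the statistical
structure the downstream analysis assumes: chromophore-driven absorption,
power-law scattering, a diffusion-theory forward model evaluated at the probe
source-detector distance, a smooth lamp x detector response, per-patient and
per-site variability and multiplicative detector noise.  The raw three-channel
bundles round-trip exactly through calibration, since the generator and the
preprocessing stage share the same instrument model.

The chromophore absorption bases are synthetic (sums of Gaussians plus an
exponential baseline); only the canonical band locations (hemoglobin near
420/540/580 nm, water near 970/1200/1450/1940 nm, lipid near 930/1210/1730 nm)
are fixed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Mapping

import numpy as np

from . import preprocess
from .errors import ConfigError
from .mcdepth import OpticalProperties
from .preprocess import SpectraDataset

__all__ = [
    "CHROMOPHORES",
    "ChromophoreModel",
    "ClassSpec",
    "RawChannel",
    "RawSpectrumBundle",
    "OpticalPropertySpectrum",
    "absorption_basis",
    "optical_properties",
    "diffusion_reflectance",
    "forward_reflectance",
    "generate_dataset",
    "interpolate_models",
    "default_class_specs",
    "default_vis_grid",
    "default_nir_grid",
    "deep_mixing_weight",
    "lamp_response",
    "DEFAULT_NORMAL_SUPERFICIAL",
    "DEFAULT_NORMAL_DEEP",
    "DEFAULT_TUMOR_SUPERFICIAL",
    "DEFAULT_TUMOR_DEEP",
]

logger = logging.getLogger(__name__)

CHROMOPHORES = ("oxyhemoglobin", "deoxyhemoglobin", "water", "lipid", "collagen")

WAVELENGTH_MIN = 350.0
WAVELENGTH_MAX = 1919.0


@dataclass(frozen=True)
class ChromophoreModel:
    """Tissue parameterisation: chromophore fractions + scattering power law.

    mu_s(lambda) = scattering_amplitude * (lambda / reference_wavelength) ** (-scattering_power)
    """

    concentrations: Mapping[str, float]
    scattering_amplitude: float  # 1/mm at the reference wavelength
    scattering_power: float
    reference_wavelength: float = 800.0

    def __post_init__(self):
        object.__setattr__(self, "concentrations", dict(self.concentrations))
        unknown = set(self.concentrations) - set(CHROMOPHORES)
        if unknown:
            raise ConfigError(f"unknown chromophores: {sorted(unknown)}")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ConfigError(f"negative concentration for {name}: {c}")
        water = self.concentrations.get("water", 0.0)
        lipid = self.concentrations.get("lipid", 0.0)
        if water + lipid > 1.0 + 1e-12:
            raise ConfigError("water + lipid fractions must not exceed 1")
        if self.scattering_amplitude <= 0:
            raise ConfigError("scattering amplitude must be > 0")
        if not (WAVELENGTH_MIN <= self.reference_wavelength <= WAVELENGTH_MAX):
            raise ConfigError("reference wavelength outside the simulated range")


@dataclass(frozen=True)
class ClassSpec:
    """Sampling specification for one tissue class.

    ``deep_model`` (optional) parameterises deeper tissue; the effective model
    at a given probe geometry mixes superficial and deep models with an
    SDD-dependent weight, so larger source-detector distances see more of the
    deep composition.
    """

    label: int
    chromophore_model: ChromophoreModel
    deep_model: ChromophoreModel | None = None
    per_site_jitter_sd: float = 0.0
    per_patient_sd: float = 0.0
    n_patients: int = 1
    sites_per_patient: int = 1

    def __post_init__(self):
        if self.label not in (-1, 1):
            raise ConfigError("class label must be -1 or +1")
        if self.per_site_jitter_sd < 0 or self.per_patient_sd < 0:
            raise ConfigError("relative SDs must be >= 0")
        if self.n_patients < 1 or self.sites_per_patient < 1:
            raise ConfigError("counts must be >= 1")


@dataclass
class RawChannel:
    """Raw detector counts for one spectrometer channel."""

    wavelengths: np.ndarray
    tissue: np.ndarray
    reference: np.ndarray
    background: np.ndarray


@dataclass
class RawSpectrumBundle:
    """Three-channel raw intensities for one measurement site (VIS + NIR)."""

    channels: dict  # {"VIS": RawChannel, "NIR": RawChannel}
    metadata: dict  # patient_id, site_id, label, sdd_um, seed


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def absorption_basis(wavelengths) -> dict[str, np.ndarray]:
    """Per-chromophore absorption spectra (1/mm per unit concentration).

    Deterministic synthetic bases with the canonical band structure; the grid
    must be monotone increasing within [350, 1919] nm.
    """
    lam = np.asarray(wavelengths, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise ConfigError("wavelength grid must be a non-empty 1-D array")
    if np.any(np.diff(lam) <= 0):
        raise ConfigError("wavelength grid must be strictly increasing")
    if lam[0] < WAVELENGTH_MIN or lam[-1] > WAVELENGTH_MAX:
        raise ConfigError(
            f"wavelength grid [{lam[0]:g}, {lam[-1]:g}] nm outside the "
            f"supported range [{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm"
        )
    g = _gauss
    return {
        "oxyhemoglobin": (30.0 * g(lam, 420, 12) + 4.0 * g(lam, 542, 17)
                          + 3.6 * g(lam, 577, 14) + 0.15 * g(lam, 900, 200)
                          + 0.05),
        "deoxyhemoglobin": (28.0 * g(lam, 430, 14) + 4.4 * g(lam, 555, 24)
                            + 1.0 * g(lam, 760, 32) + 0.15 * g(lam, 900, 200)
                            + 0.05),
        "water": (0.0045 * g(lam, 970, 45) + 0.10 * g(lam, 1190, 70)
                  + 2.2 * g(lam, 1450, 95) + 9.0 * g(lam, 1940, 110)),
        "lipid": (0.012 * g(lam, 930, 30) + 0.07 * g(lam, 1210, 55)
                  + 0.45 * g(lam, 1730, 80) + 0.03 * g(lam, 1400, 120)),
        # monotone decreasing baseline term
        "collagen": 0.6 * np.exp(-(lam - WAVELENGTH_MIN) / 280.0) + 0.01,
    }


@dataclass
class OpticalPropertySpectrum:
    """Per-wavelength absorption/scattering plus scalar g and indices."""

    wavelengths: np.ndarray
    mu_a: np.ndarray
    mu_s: np.ndarray
    g: float = 0.9
    eta_rel: float = 1.4
    eta_out: float = 1.0

    def at(self, wavelength: float) -> OpticalProperties:
        """Scalar optical properties at the grid point nearest ``wavelength``."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return OpticalProperties(mu_a=float(self.mu_a[i]), mu_s=float(self.mu_s[i]),
                                 g=self.g, eta_rel=self.eta_rel, eta_out=self.eta_out)

    @property
    def mu_s_prime(self) -> np.ndarray:
        return self.mu_s * (1.0 - self.g)


def optical_properties(model: ChromophoreModel, wavelengths,
                       g: float = 0.9, eta_rel: float = 1.4,
                       eta_out: float = 1.0) -> OpticalPropertySpectrum:
    """mu_a = sum_c concentration_c * basis_c; mu_s = a * (lambda/ref)^(-b)."""
    lam = np.asarray(wavelengths, dtype=float)
    basis = absorption_basis(lam)
    mu_a = np.zeros_like(lam)
    for name, conc in model.concentrations.items():
        mu_a += conc * basis[name]
    mu_s = model.scattering_amplitude * (lam / model.reference_wavelength) ** (
        -model.scattering_power)
    if np.any(mu_s <= 0):
        raise ConfigError("scattering model produced non-positive mu_s")
    return OpticalPropertySpectrum(lam, mu_a, mu_s, g=g, eta_rel=eta_rel,
                                   eta_out=eta_out)


# effective reflection coefficient polynomial in the relative refractive index
def _extrapolation_factor(n_rel: float) -> float:
    r_eff = -1.440 / n_rel ** 2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_eff) / (1.0 - r_eff)


@lru_cache(maxsize=None)
def _boundary_coefficients(n_rel: float, n_out: float = 1.0) -> tuple[float, float]:
    """Fluence and flux boundary coefficients from unpolarised Fresnel integrals.

    C_phi = 1/2 * int (1 - R_F) cos(t) sin(t) dt and
    C_j   = 3/2 * int (1 - R_F) cos^2(t) sin(t) dt over internal angles;
    (0.25, 0.5) for a matched boundary, ~(0.118, 0.306) at n_rel = 1.4.
    """
    theta = np.linspace(0.0, np.pi / 2.0, 4001)[1:]
    ct = np.cos(theta)
    st = np.sin(theta)
    stt = n_rel / n_out * st
    refl = np.ones_like(ct)
    ok = stt < 1.0
    ctt = np.sqrt(1.0 - stt[ok] ** 2)
    rs = (n_rel * ct[ok] - n_out * ctt) / (n_rel * ct[ok] + n_out * ctt)
    rp = (n_rel * ctt - n_out * ct[ok]) / (n_rel * ctt + n_out * ct[ok])
    refl[ok] = 0.5 * (rs ** 2 + rp ** 2)
    trans = 1.0 - refl
    c_phi = 0.5 * float(np.trapezoid(trans * ct * st, theta))
    c_j = 1.5 * float(np.trapezoid(trans * ct ** 2 * st, theta))
    return c_phi, c_j


def diffusion_reflectance(mu_a, mu_s_prime, rho_mm, n_rel: float = 1.4):
    """Steady-state diffusion-theory radially resolved diffuse reflectance.

    Extrapolated-boundary dipole for a pencil beam on a semi-infinite medium,
    in the hybrid fluence + flux form R = C_phi * phi(rho, 0) + C_j * j_z(rho, 0)
    (the flux-only dipole misses the boundary-fluence contribution and sits
    ~20% low for mismatched boundaries).  Returns reflectance per unit area
    (1/mm^2) at radius rho_mm; vectorised over mu_a / mu_s_prime.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_sp = np.asarray(mu_s_prime, dtype=float)
    mu_tr = mu_a + mu_sp
    D = 1.0 / (3.0 * mu_tr)
    mu_eff = np.sqrt(mu_a / D)
    z0 = 1.0 / mu_tr
    zb = 2.0 * _extrapolation_factor(n_rel) * D
    zp = z0 + 2.0 * zb
    r1 = np.hypot(z0, rho_mm)
    r2 = np.hypot(zp, rho_mm)
    phi = (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4.0 * np.pi * D)
    flux = (z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1 ** 2
            + zp * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2 ** 2
            ) / (4.0 * np.pi)
    c_phi, c_j = _boundary_coefficients(float(n_rel))
    return c_phi * phi + c_j * flux


_validity_warned = False


def forward_reflectance(props: OpticalPropertySpectrum, sdd_um: float) -> np.ndarray:
    """Forward reflectance spectrum at the given source-detector distance.

    Diffusion validity (mu_a <= mu_s') violations are logged once per call and
    the value is still returned.
    """
    if sdd_um <= 0:
        raise ConfigError("source-detector distance must be > 0")
    if np.any(props.mu_a < 0) or np.any(props.mu_s <= 0):
        raise ConfigError("optical properties must satisfy mu_a >= 0, mu_s > 0")
    mu_sp = props.mu_s_prime
    n_bad = int(np.sum(props.mu_a > mu_sp))
    if n_bad:
        global _validity_warned
        log = logger.debug if _validity_warned else logger.warning
        log("diffusion validity violated (mu_a > mu_s') at %d of %d "
            "wavelengths; values still returned", n_bad, props.mu_a.size)
        _validity_warned = True
    return diffusion_reflectance(props.mu_a, mu_sp, sdd_um / 1000.0,
                                 n_rel=props.eta_rel)


def interpolate_models(m0: ChromophoreModel, m1: ChromophoreModel,
                       t: float) -> ChromophoreModel:
    """Linear interpolation between two chromophore models (t=0 -> m0)."""
    names = set(m0.concentrations) | set(m1.concentrations)
    conc = {n: (1 - t) * m0.concentrations.get(n, 0.0)
            + t * m1.concentrations.get(n, 0.0) for n in names}
    return ChromophoreModel(
        concentrations=conc,
        scattering_amplitude=(1 - t) * m0.scattering_amplitude
        + t * m1.scattering_amplitude,
        scattering_power=(1 - t) * m0.scattering_power + t * m1.scattering_power,
        reference_wavelength=m0.reference_wavelength,
    )


DEFAULT_NORMAL_SUPERFICIAL = ChromophoreModel(
    {"oxyhemoglobin": 0.006, "deoxyhemoglobin": 0.003, "water": 0.65,
     "lipid": 0.06, "collagen": 0.20},
    scattering_amplitude=14.0, scattering_power=1.2)
DEFAULT_NORMAL_DEEP = ChromophoreModel(
    {"oxyhemoglobin": 0.005, "deoxyhemoglobin": 0.003, "water": 0.60,
     "lipid": 0.15, "collagen": 0.30},
    scattering_amplitude=16.0, scattering_power=1.0)
DEFAULT_TUMOR_SUPERFICIAL = ChromophoreModel(
    {"oxyhemoglobin": 0.010, "deoxyhemoglobin": 0.008, "water": 0.75,
     "lipid": 0.03, "collagen": 0.28},
    scattering_amplitude=12.0, scattering_power=1.0)
DEFAULT_TUMOR_DEEP = ChromophoreModel(
    {"oxyhemoglobin": 0.011, "deoxyhemoglobin": 0.009, "water": 0.78,
     "lipid": 0.05, "collagen": 0.36},
    scattering_amplitude=13.0, scattering_power=0.9)


def default_class_specs(contrast: float = 1.0, n_patients: int = 8,
                        sites_per_patient: int = 15,
                        per_site_jitter_sd: float = 0.08,
                        per_patient_sd: float = 0.12,
                        deep_only: bool = False) -> tuple[ClassSpec, ClassSpec]:
    """Normal/tumor class specs with a tunable concentration contrast.

    ``contrast`` linearly scales how far the tumor models sit from the normal
    models (0 -> identical classes).  With ``deep_only`` the tumor differs from
    normal tissue only in its deep model, so class contrast grows with SDD.
    """
    tum_sup = (DEFAULT_NORMAL_SUPERFICIAL if deep_only
               else interpolate_models(DEFAULT_NORMAL_SUPERFICIAL,
                                       DEFAULT_TUMOR_SUPERFICIAL, contrast))
    tum_deep = interpolate_models(DEFAULT_NORMAL_DEEP, DEFAULT_TUMOR_DEEP,
                                  contrast)
    normal = ClassSpec(label=-1, chromophore_model=DEFAULT_NORMAL_SUPERFICIAL,
                       deep_model=DEFAULT_NORMAL_DEEP,
                       per_site_jitter_sd=per_site_jitter_sd,
                       per_patient_sd=per_patient_sd, n_patients=n_patients,
                       sites_per_patient=sites_per_patient)
    tumor = replace(normal, label=+1, chromophore_model=tum_sup,
                    deep_model=tum_deep)
    return normal, tumor


def deep_mixing_weight(sdd_um: float) -> float:
    """Weight of the deep chromophore model; grows with source-detector distance."""
    return sdd_um / (sdd_um + 1800.0)


def default_vis_grid(step: float = 1.0) -> np.ndarray:
    n = int(np.ceil((1130.0 - WAVELENGTH_MIN) / step))
    return WAVELENGTH_MIN + step * np.arange(n + 1)


def default_nir_grid(step: float = 1.0) -> np.ndarray:
    n = int(np.ceil((WAVELENGTH_MAX - 1095.0) / step))
    return 1095.0 + step * np.arange(n + 1)


def lamp_response(wavelengths: np.ndarray, channel: str) -> np.ndarray:
    """Smooth positive lamp x detector response, identical for tissue and
    reference channels (cancels exactly under calibration)."""
    lam = np.asarray(wavelengths, dtype=float)
    if channel == "VIS":
        return 4000.0 * _gauss(lam, 730, 280) + 250.0
    if channel == "NIR":
        return 3500.0 * _gauss(lam, 1350, 330) + 200.0
    raise ConfigError(f"unknown channel {channel!r}")


_BG_LEVEL = {"VIS": 120.0, "NIR": 90.0}


def _jitter(rng: np.random.Generator, values: np.ndarray, sd: float) -> np.ndarray:
    """Multiplicative Gaussian jitter, clamped at zero."""
    mult = rng.normal(1.0, sd, size=values.shape)
    out = values * mult
    n_clamped = int(np.sum(out < 0))
    if n_clamped:
        logger.info("clamped %d negative jittered concentrations to 0", n_clamped)
        out = np.maximum(out, 0.0)
    return out


_WATER_IDX = CHROMOPHORES.index("water")
_LIPID_IDX = CHROMOPHORES.index("lipid")


def _cap_water_lipid(conc: np.ndarray) -> np.ndarray:
    """Rescale jittered water+lipid back under the volume-fraction cap."""
    total = conc[_WATER_IDX] + conc[_LIPID_IDX]
    if total > 1.0:
        logger.debug("rescaling water+lipid fraction %.3f to 1.0", total)
        conc = conc.copy()
        conc[_WATER_IDX] /= total
        conc[_LIPID_IDX] /= total
    return conc


def _effective_model(spec: ClassSpec, sdd_um: float) -> ChromophoreModel:
    if spec.deep_model is None:
        return spec.chromophore_model
    return interpolate_models(spec.chromophore_model, spec.deep_model,
                              deep_mixing_weight(sdd_um))


def generate_dataset(normal: ClassSpec, tumor: ClassSpec, sdd_um: float,
                     noise_sd: float = 0.0, seed: int = 0,
                     grid_step: float = 1.0,
                     return_bundles: bool = True
                     ) -> tuple[SpectraDataset, list[RawSpectrumBundle]]:
    """Generate a two-class synthetic dataset and its raw spectrum bundles.

    Per site: sample the patient-level effect, jitter concentrations, compute
    the forward reflectance, multiply by the lamp x detector response to obtain
    tissue counts, emit matching reference/background channels, and add
    multiplicative Gaussian noise of relative SD ``noise_sd``.  The returned
    :class:`SpectraDataset` holds the calibrated, merged spectra (the output of
    running the preprocessing stage on the bundles).  Fully reproducible for a
    given seed.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    vis_wl = default_vis_grid(grid_step)
    nir_wl = default_nir_grid(grid_step)
    s_vis = lamp_response(vis_wl, "VIS")
    s_nir = lamp_response(nir_wl, "NIR")

    rows: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[int] = []
    bundles: list[RawSpectrumBundle] = []
    merged_wl: np.ndarray | None = None

    for class_index, spec in enumerate((normal, tumor)):
        eff = _effective_model(spec, sdd_um)
        base_conc = np.array([eff.concentrations.get(c, 0.0) for c in CHROMOPHORES])
        base_scatter = np.array([eff.scattering_amplitude])
        for p in range(spec.n_patients):
            pat_conc = _jitter(rng, base_conc, spec.per_patient_sd)
            pat_scatter = _jitter(rng, base_scatter, spec.per_patient_sd)
            for s in range(spec.sites_per_patient):
                site_conc = _jitter(rng, pat_conc, spec.per_site_jitter_sd)
                site_scatter = _jitter(rng, pat_scatter, spec.per_site_jitter_sd)
                site_conc = _cap_water_lipid(site_conc)
                model = ChromophoreModel(
                    dict(zip(CHROMOPHORES, site_conc)),
                    scattering_amplitude=max(float(site_scatter[0]), 1e-6),
                    scattering_power=eff.scattering_power,
                    reference_wavelength=eff.reference_wavelength)
                channels = {}
                for name, wl, resp in (("VIS", vis_wl, s_vis),
                                       ("NIR", nir_wl, s_nir)):
                    props = optical_properties(model, wl)
                    refl = forward_reflectance(props, sdd_um)
                    bg = _BG_LEVEL[name] * (
                        1.0 + rng.normal(0.0, 0.1 * noise_sd, size=wl.shape))
                    reference = bg + resp
                    tissue = bg + refl * resp * (
                        1.0 + rng.normal(0.0, noise_sd, size=wl.shape))
                    channels[name] = RawChannel(wl, tissue, reference, bg)
                sample_id = class_index * 10_000_000 + p * 1000 + s
                bundle = RawSpectrumBundle(
                    channels=channels,
                    metadata={"patient_id": f"{'NT'[class_index]}{p:03d}",
                              "site_id": s, "label": spec.label,
                              "sdd_um": float(sdd_um), "seed": int(seed)})
                merged = preprocess.merge_bundle(bundle, grid_step=grid_step)
                merged_wl = merged.wavelengths
                rows.append(merged.reflectance)
                labels.append(spec.label)
                ids.append(sample_id)
                if return_bundles:
                    bundles.append(bundle)
    dataset = SpectraDataset(np.vstack(rows), np.array(labels), merged_wl,
                             sdd_um=float(sdd_um), ids=np.array(ids))
    return dataset, bundles
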