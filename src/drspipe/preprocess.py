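"""Raw-spectrum preprocessing: calibration, VIS/NIR merging, scaling, subsetting.

Turns three-channel raw intensities (tissue / reference / background) into a
single calibrated, merged and optionally min-max scaled reflectance matrix
ready for classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import CalibrationError, DataFormatError, MergeError, NumericalError

__all__ = [
    "CalibratedSpectrum",
    "MergedSpectrum",
    "FeatureScaler",
    "SpectraDataset",
    "calibrate",
    "calibrate_bundle",
    "merge_vis_nir",
    "merge_bundle",
    "scale_features",
    "subset_wavelengths",
    "DEFAULT_OVERLAP",
]

DEFAULT_OVERLAP = (1095.0, 1130.0)
#: number of evenly spaced cross-fade nodes inside the overlap (index i = 0..100)
N_OVERLAP_POINTS = 101


def _as_float_array(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise DataFormatError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class CalibratedSpectrum:
    """A single-channel reflectance spectrum (dimensionless ratio)."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    channel: str = "VIS"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.reflectance = _as_float_array(self.reflectance, "reflectance")
        if self.wavelengths.shape != self.reflectance.shape:
            raise DataFormatError(
                "wavelength grid and reflectance vector must have the same length"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise DataFormatError("calibrated reflectance contains non-finite values")


@dataclass
class MergedSpectrum:
    """A reflectance spectrum on the unified (VIS + NIR) wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.reflectance = _as_float_array(self.reflectance, "reflectance")
        if self.wavelengths.shape != self.reflectance.shape:
            raise DataFormatError("grid/reflectance length mismatch in merged spectrum")


def calibrate(tissue, reference, background, wavelengths, channel: str = "VIS",
              metadata: dict | None = None) -> CalibratedSpectrum:
    """Background-subtract and normalise a raw intensity spectrum.

    value(lambda) = (tissue - background) / (reference - background), with no
    clipping.  All four inputs must share one wavelength grid.  A non-positive
    denominator anywhere raises :class:`CalibrationError` naming the first
    offending wavelength.
    """
    wl = _as_float_array(wavelengths, "wavelengths")
    t = _as_float_array(tissue, "tissue")
    r = _as_float_array(reference, "reference")
    b = _as_float_array(background, "background")
    if not (t.shape == r.shape == b.shape == wl.shape):
        raise DataFormatError("tissue/reference/background/wavelengths lengths differ")
    denom = r - b
    bad = denom <= 0
    if np.any(bad):
        lam = wl[np.argmax(bad)]
        raise CalibrationError(
            f"reference - background is non-positive at {lam:g} nm"
        )
    refl = (t - b) / denom
    return CalibratedSpectrum(wl, refl, channel=channel, metadata=dict(metadata or {}))


def calibrate_bundle(bundle) -> tuple[CalibratedSpectrum, CalibratedSpectrum]:
    """Calibrate both channels of a raw spectrum bundle (VIS, NIR)."""
    out = []
    for name in ("VIS", "NIR"):
        ch = bundle.channels[name]
        out.append(
            calibrate(ch.tissue, ch.reference, ch.background, ch.wavelengths,
                      channel=name, metadata=dict(bundle.metadata))
        )
    return tuple(out)


def merge_vis_nir(vis: CalibratedSpectrum, nir: CalibratedSpectrum,
                  overlap: tuple[float, float] = DEFAULT_OVERLAP,
                  grid: np.ndarray | None = None,
                  grid_step: float | None = None) -> MergedSpectrum:
    """Merge VIS and NIR channels into one spectrum via an overlap cross-fade.

    Below the overlap the VIS values are used, above it the NIR values.  Inside
    the overlap both channels are linearly interpolated onto 101 evenly spaced
    points indexed i = 0..100 and combined as ((100 - i) * VIS + i * NIR) / 100,
    then re-interpolated onto the unified output grid.  The result is continuous
    at both overlap edges.
    """
    lo, hi = float(overlap[0]), float(overlap[1])
    if not (lo < hi):
        raise MergeError(f"invalid overlap bounds ({lo}, {hi})")
    for spec, name in ((vis, "VIS"), (nir, "NIR")):
        if spec.wavelengths[0] > lo or spec.wavelengths[-1] < hi:
            raise MergeError(
                f"{name} grid [{spec.wavelengths[0]:g}, {spec.wavelengths[-1]:g}] nm "
                f"does not cover the overlap [{lo:g}, {hi:g}] nm"
            )
    if grid is None:
        step = float(grid_step) if grid_step else float(np.median(np.diff(vis.wavelengths)))
        n = int(np.floor((nir.wavelengths[-1] - vis.wavelengths[0]) / step + 1e-9))
        grid = vis.wavelengths[0] + step * np.arange(n + 1)
    else:
        grid = _as_float_array(grid, "grid")

    xs = np.linspace(lo, hi, N_OVERLAP_POINTS)
    v = np.interp(xs, vis.wavelengths, vis.reflectance)
    nn = np.interp(xs, nir.wavelengths, nir.reflectance)
    i = np.arange(N_OVERLAP_POINTS, dtype=float)
    fade = ((100.0 - i) * v + i * nn) / 100.0

    out = np.empty_like(grid)
    below = grid < lo
    above = grid > hi
    mid = ~(below | above)
    out[below] = np.interp(grid[below], vis.wavelengths, vis.reflectance)
    out[above] = np.interp(grid[above], nir.wavelengths, nir.reflectance)
    out[mid] = np.interp(grid[mid], xs, fade)
    meta = dict(vis.metadata)
    meta.update(nir.metadata)
    return MergedSpectrum(grid, out, metadata=meta)


def merge_bundle(bundle, overlap=DEFAULT_OVERLAP, grid=None, grid_step=None) -> MergedSpectrum:
    """Calibrate then merge both channels of a raw bundle in one call."""
    vis, nir = calibrate_bundle(bundle)
    return merge_vis_nir(vis, nir, overlap=overlap, grid=grid, grid_step=grid_step)


@dataclass
class FeatureScaler:
    """Per-feature midrange/half-range ([-1, +1] min-max) scaling state."""

    offset: np.ndarray
    half_range: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, rows: np.ndarray) -> "FeatureScaler":
        rows = np.asarray(rows)
        if rows.size == 0:
            raise NumericalError("cannot fit feature scaling on an empty row set")
        sub = X[rows]
        mx = sub.max(axis=0)
        mn = sub.min(axis=0)
        return cls(offset=(mx + mn) / 2.0, half_range=(mx - mn) / 2.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = X - self.offset
        nz = self.half_range > 0
        out[:, nz] /= self.half_range[nz]
        out[:, ~nz] = 0.0
        return out

    def subset(self, cols: np.ndarray) -> "FeatureScaler":
        return FeatureScaler(self.offset[cols], self.half_range[cols])


@dataclass
class SpectraDataset:
    """n x m reflectance matrix with labels, wavelength grid and SDD tag.

    ``ids`` are stable per-sample identifiers used to key cross-validation
    splits so that results are invariant to row order.
    """

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray
    sdd_um: float = float("nan")
    ids: np.ndarray | None = None
    scaling: FeatureScaler | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y)
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        if self.ids is None:
            self.ids = np.arange(self.X.shape[0])
        else:
            self.ids = np.asarray(self.ids)
        if self.X.shape[0] != self.y.shape[0]:
            raise DataFormatError("number of rows of X must equal number of labels")
        if self.X.shape[1] != self.wavelengths.shape[0]:
            raise DataFormatError("number of columns of X must equal grid length")
        if self.ids.shape[0] != self.X.shape[0]:
            raise DataFormatError("ids length must equal number of rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def scaling_state(self) -> str:
        return "scaled" if self.scaling is not None else "raw"

    def select_rows(self, rows: np.ndarray) -> "SpectraDataset":
        rows = np.asarray(rows)
        return SpectraDataset(self.X[rows], self.y[rows], self.wavelengths,
                              sdd_um=self.sdd_um, ids=self.ids[rows],
                              scaling=self.scaling)


def scale_features(dataset: SpectraDataset, fit_rows: np.ndarray | None = None) -> SpectraDataset:
    """Center and scale every feature to [-1, +1] using fit_rows statistics.

    offset = (max + min) / 2 and half-range = (max - min) / 2 are computed on
    ``fit_rows`` only (default: all rows); every row of the dataset is mapped
    through (x - offset) / half-range without clipping, so held-out values may
    fall outside [-1, +1].  A zero half-range maps the feature to 0.
    """
    if fit_rows is None:
        fit_rows = np.arange(dataset.n_samples)
    scaler = FeatureScaler.fit(dataset.X, fit_rows)
    return replace(dataset, X=scaler.transform(dataset.X.copy()), scaling=scaler)


def subset_wavelengths(dataset: SpectraDataset,
                       ranges: Sequence) -> SpectraDataset:
    """Keep only the columns selected by intervals and/or discrete wavelengths.

    ``ranges`` items are either ``(lo, hi)`` closed intervals (keeps all grid
    columns with lo <= lambda <= hi) or scalars (keeps the single nearest grid
    column, ties broken towards the lower wavelength).  Column order is
    preserved and duplicates are removed.
    """
    wl = dataset.wavelengths
    selected: set[int] = set()
    for item in ranges:
        if np.isscalar(item) or isinstance(item, (int, float)):
            idx = int(np.argmin(np.abs(wl - float(item))))  # argmin -> lower-λ tie
            selected.add(idx)
        else:
            lo, hi = float(item[0]), float(item[1])
            idx = np.nonzero((wl >= lo) & (wl <= hi))[0]
            selected.update(int(i) for i in idx)
    if not selected:
        raise NumericalError(f"no wavelengths selected by ranges {list(ranges)!r}")
    cols = np.array(sorted(selected))
    scaling = dataset.scaling.subset(cols) if dataset.scaling is not None else None
    return SpectraDataset(dataset.X[:, cols], dataset.y, wl[cols],
                          sdd_um=dataset.sdd_um, ids=dataset.ids, scaling=scaling)


def parse_range_spec(text: str) -> list:
    """Parse a CLI range string like ``"400-440,540-580,625"`` into range items."""
    items: list = []
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        if "-" in tok[1:]:
            pos = tok.index("-", 1)
            items.append((float(tok[:pos]), float(tok[pos + 1:])))
        else:
            items.append(float(tok))
    if not items:
        raise DataFormatError(f"empty wavelength range specification: {text!r}")
    return items
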