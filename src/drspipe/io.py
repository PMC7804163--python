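"""Plain-text readers and writers for every pipeline artifact.

All formats are UTF-8 CSV with '.' decimal and comma separators, with JSON
sidecars for metadata.  Floats are written with 17 significant digits so that
write -> read round-trips are lossless and repeated writes are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .mcdepth import FluenceMap, ProbedDepthProfile
from .preprocess import SpectraDataset
from .synth import RawChannel, RawSpectrumBundle

__all__ = [
    "write_bundle", "read_bundle",
    "write_dataset", "read_dataset",
    "write_props", "read_props",
    "write_depth_profile", "read_depth_profile",
    "write_fluence_map",
    "write_results_table",
    "sha256_file",
]

_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FMT % x


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_channel_csv(path: Path, ch: RawChannel) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("wavelength_nm,tissue,reference,background\n")
        for wl, t, r, b in zip(ch.wavelengths, ch.tissue, ch.reference,
                               ch.background):
            fh.write(f"{_fmt(wl)},{_fmt(t)},{_fmt(r)},{_fmt(b)}\n")


def write_bundle(bundle: RawSpectrumBundle, directory, stem: str) -> list[Path]:
    """One CSV per channel plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, ch in bundle.channels.items():
        p = directory / f"{stem}_{name.lower()}.csv"
        _write_channel_csv(p, ch)
        paths.append(p)
    meta_path = directory / f"{stem}.json"
    meta_path.write_text(json.dumps(bundle.metadata, sort_keys=True, indent=1)
                         + "\n", encoding="utf-8")
    paths.append(meta_path)
    return paths


def _read_channel_csv(path: Path) -> RawChannel:
    df = _read_csv(path, required=("wavelength_nm", "tissue", "reference",
                                   "background"))
    wl = df["wavelength_nm"].to_numpy()
    _check_grid(wl, path)
    return RawChannel(wl, df["tissue"].to_numpy(), df["reference"].to_numpy(),
                      df["background"].to_numpy())


def read_bundle(directory, stem: str) -> RawSpectrumBundle:
    directory = Path(directory)
    channels = {}
    for name in ("VIS", "NIR"):
        p = directory / f"{stem}_{name.lower()}.csv"
        if not p.exists():
            raise DataFormatError(f"missing channel file {p}")
        channels[name] = _read_channel_csv(p)
    meta = json.loads((directory / f"{stem}.json").read_text(encoding="utf-8"))
    return RawSpectrumBundle(channels=channels, metadata=meta)


def _read_csv(path, required=()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    num = df.apply(pd.to_numeric, errors="coerce") if required else df
    if required:
        bad = num[list(required)].isna().any(axis=1)
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.argmax(bad.to_numpy())) + 2
            raise DataFormatError(f"{path}: non-numeric or missing value at "
                                  f"line {line}")
        df = num
    return df


def _check_grid(wl: np.ndarray, path) -> None:
    diffs = np.diff(wl)
    if np.any(~np.isfinite(wl)):
        line = int(np.argmax(~np.isfinite(wl))) + 2
        raise DataFormatError(f"{path}: non-finite wavelength at line {line}")
    if np.any(diffs <= 0):
        line = int(np.argmax(diffs <= 0)) + 3  # second row of the bad pair
        raise DataFormatError(f"{path}: wavelength grid not strictly "
                              f"increasing at line {line}")


def write_dataset(path, dataset: SpectraDataset) -> Path:
    """CSV matrix: first column label, remaining columns named by wavelength.

    The SDD tag and stable sample ids go into a ``<path>.meta.json`` sidecar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("label," + ",".join(_fmt(w) for w in dataset.wavelengths) + "\n")
        for yi, row in zip(dataset.y, dataset.X):
            fh.write(str(int(yi)) + "," + ",".join(_fmt(v) for v in row) + "\n")
    sidecar = {"sdd_um": None if np.isnan(dataset.sdd_um) else dataset.sdd_um,
               "ids": [int(i) for i in dataset.ids]}
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, sort_keys=True) + "\n", encoding="utf-8")
    return path


def read_dataset(path) -> SpectraDataset:
    path = Path(path)
    df = _read_csv(path)
    if df.columns[0] != "label":
        raise DataFormatError(f"{path}: first column must be 'label'")
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric wavelength column name: "
                              f"{exc}") from exc
    _check_grid(wl, path)
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        line = int(np.argmax(np.any(~np.isfinite(X), axis=1))) + 2
        raise DataFormatError(f"{path}: non-finite reflectance at line {line}")
    y = df["label"].to_numpy(dtype=int)
    sdd = float("nan")
    ids = None
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        if meta.get("sdd_um") is not None:
            sdd = float(meta["sdd_um"])
        if meta.get("ids") is not None:
            ids = np.array(meta["ids"])
    return SpectraDataset(X, y, wl, sdd_um=sdd, ids=ids)


def write_props(path, wavelengths, mu_a, mu_s) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("wavelength_nm,mu_a_per_mm,mu_s_per_mm\n")
        for wl, a, s in zip(wavelengths, mu_a, mu_s):
            fh.write(f"{_fmt(wl)},{_fmt(a)},{_fmt(s)}\n")
    return path


def read_props(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = _read_csv(path, required=("wavelength_nm", "mu_a_per_mm",
                                   "mu_s_per_mm"))
    wl = df["wavelength_nm"].to_numpy()
    _check_grid(wl, path)
    return wl, df["mu_a_per_mm"].to_numpy(), df["mu_s_per_mm"].to_numpy()


def write_depth_profile(path, profile: ProbedDepthProfile) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("wavelength_nm,depth_um\n")
        for wl, d in zip(profile.wavelengths, profile.depth_um):
            fh.write(f"{_fmt(wl)},{_fmt(d)}\n")
    header = {"sdd_um": profile.sdd_um, "n_photons": profile.n_photons,
              "seed": profile.seed, "min_depth_um": profile.min_depth_um,
              "max_depth_um": profile.max_depth_um}
    Path(str(path) + ".meta.json").write_text(
        json.dumps(header, sort_keys=True) + "\n", encoding="utf-8")
    return path


def read_depth_profile(path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path, required=("wavelength_nm", "depth_um"))
    return df["wavelength_nm"].to_numpy(), df["depth_um"].to_numpy()


def write_fluence_map(path, fmap: FluenceMap) -> Path:
    """Fluence matrix as CSV (rows r-bins, columns z-bins) + JSON header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = fmap.fluence if fmap.fluence is not None else fmap.absorbed
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in values:
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    header = {"dr_mm": fmap.grid.dr_mm, "dz_mm": fmap.grid.dz_mm,
              "nr": fmap.grid.nr, "nz": fmap.grid.nz,
              "n_photons": fmap.n_photons, "seed": fmap.seed,
              "mu_a": fmap.props.mu_a, "mu_s": fmap.props.mu_s,
              "g": fmap.props.g, "eta_rel": fmap.props.eta_rel,
              "eta_out": fmap.props.eta_out,
              "bookkeeping": fmap.bookkeeping,
              "kind": "fluence" if fmap.fluence is not None else "absorbed"}
    Path(str(path) + ".meta.json").write_text(
        json.dumps(header, sort_keys=True, indent=1) + "\n", encoding="utf-8")
    return path


def write_results_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, lineterminator="\n")
    return path
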