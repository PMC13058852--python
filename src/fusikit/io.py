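"""File formats, configuration and output manifests.

Conventions used by every reader and writer in the package:

* I/Q acquisitions live in an HDF5 container with datasets ``/iq/real`` and
  ``/iq/imag`` shaped ``(block, frame, z, x[, y])`` and root attributes
  ``f_pulse_Hz``, ``c_m_per_s``, ``f_iq_Hz``, ``voxel_size_mm``.
* Volumes (power Doppler, velocity, masks, seed maps) are NIfTI-1 with an
  isotropic voxel size in mm on a diagonal RAS-like affine; the time axis is
  last; voxel indexing is 0-based.
* Tables (QC metrics, confounds, scrub masks) are UTF-8 tab-separated files
  with a mandatory header row and ``n/a`` for missing values.
* Pipeline configuration is YAML (or JSON, a YAML subset); unspecified
  denoising fields resolve to the adaptive paradigm-1 defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .clutter import ClutterFilterSpec, PowerDopplerSeries
from .denoise import DenoiseStrategy
from .errors import ConfigurationError, InputError
from .qc import TemporalQC
from .velocity import IQBlock, VelocitySeries

__all__ = [
    "save_iq",
    "load_iq",
    "save_volume_series",
    "load_volume_series",
    "save_mask",
    "load_mask",
    "save_temporal_qc",
    "load_temporal_qc",
    "strategy_from_dict",
    "strategy_to_dict",
    "load_strategy",
    "save_strategy",
    "write_manifest",
]


# ---------------------------------------------------------------- HDF5 I/Q

def save_iq(path, blocks: list[IQBlock]) -> None:
    """Write an I/Q acquisition to the package's HDF5 container."""
    if not blocks:
        raise InputError("no blocks to save")
    first = blocks[0]
    data = np.stack([b.samples for b in blocks])
    with h5py.File(path, "w") as f:
        grp = f.create_group("iq")
        grp.create_dataset("real", data=data.real)
        grp.create_dataset("imag", data=data.imag)
        f.attrs["f_pulse_Hz"] = first.f_pulse_hz
        f.attrs["c_m_per_s"] = first.c_m_per_s
        f.attrs["f_iq_Hz"] = first.f_iq_hz
        f.attrs["voxel_size_mm"] = first.voxel_size_mm


def load_iq(path) -> list[IQBlock]:
    """Read an I/Q acquisition written by :func:`save_iq`."""
    with h5py.File(path, "r") as f:
        data = np.asarray(f["iq/real"]) + 1j * np.asarray(f["iq/imag"])
        attrs = dict(f.attrs)
    return [
        IQBlock(
            samples=data[b],
            f_pulse_hz=float(attrs["f_pulse_Hz"]),
            c_m_per_s=float(attrs["c_m_per_s"]),
            f_iq_hz=float(attrs["f_iq_Hz"]),
            voxel_size_mm=float(attrs["voxel_size_mm"]),
        )
        for b in range(data.shape[0])
    ]


# ---------------------------------------------------------------- NIfTI

def _affine(voxel_size_mm: float, ndim_space: int) -> np.ndarray:
    aff = np.eye(4)
    for i in range(min(ndim_space, 3)):
        aff[i, i] = voxel_size_mm
    return aff


def save_volume_series(path, series) -> None:
    """Write a PD or velocity series as 4D NIfTI (time last).

    The per-volume repetition time (s) is stored in the NIfTI header zooms.
    """
    vols = np.moveaxis(series.volumes, 0, -1)  # (…grid, time)
    while vols.ndim < 4:  # promote 2D grids to singleton 3rd axis
        vols = vols[..., np.newaxis, :] if vols.ndim == 3 else vols[np.newaxis]
    img = nib.Nifti1Image(np.asarray(vols, dtype=np.float32), _affine(series.voxel_size_mm, 3))
    zooms = list(img.header.get_zooms())
    zooms[3] = 1.0 / series.sampling_rate_hz
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_volume_series(path, kind: str = "pd"):
    """Read a 4D NIfTI into a :class:`PowerDopplerSeries` or :class:`VelocitySeries`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    vols = np.moveaxis(data, -1, 0)
    vols = np.squeeze(vols)
    if vols.ndim == 1:
        vols = vols[:, np.newaxis]
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    rate = 1.0 / tr if tr > 0 else 1.0
    voxel = float(img.header.get_zooms()[0])
    cls = PowerDopplerSeries if kind == "pd" else VelocitySeries
    return cls(volumes=vols, sampling_rate_hz=rate, voxel_size_mm=voxel)


def save_array_series(
    path, volumes: np.ndarray, sampling_rate_hz: float, voxel_size_mm: float
) -> None:
    """Write an arbitrary (time, *grid) array as 4D NIfTI (signed values allowed)."""

    class _Plain:
        pass

    series = _Plain()
    series.volumes = np.asarray(volumes, dtype=float)
    series.sampling_rate_hz = sampling_rate_hz
    series.voxel_size_mm = voxel_size_mm
    save_volume_series(path, series)


def save_volume(path, volume: np.ndarray, voxel_size_mm: float) -> None:
    """Write a single (possibly 2D) volume as NIfTI."""
    arr = np.asarray(volume, dtype=np.float32)
    while arr.ndim < 3:
        arr = arr[..., np.newaxis]
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size_mm, 3)), str(path))


def save_mask(path, mask: np.ndarray, voxel_size_mm: float) -> None:
    arr = np.asarray(mask, dtype=np.uint8)
    while arr.ndim < 3:
        arr = arr[..., np.newaxis]
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size_mm, 3)), str(path))


def load_mask(path) -> np.ndarray:
    return np.squeeze(np.asarray(nib.load(str(path)).dataobj)) > 0


# ---------------------------------------------------------------- TSV

def save_temporal_qc(path, tqc: TemporalQC) -> None:
    """QC table: frame, t_sec, rgs_pct, gv_mm_s, rdvars (missing as ``n/a``)."""
    df = pd.DataFrame(
        {
            "frame": np.arange(tqc.n_frames),
            "t_sec": tqc.frame_times_s,
            "rgs_pct": tqc.rgs_pct,
            "gv_mm_s": tqc.gv_mm_s,
            "rdvars": tqc.rdvars,
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def load_temporal_qc(path) -> TemporalQC:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    return TemporalQC(
        rgs_pct=df["rgs_pct"].to_numpy(float),
        gv_mm_s=df["gv_mm_s"].to_numpy(float),
        rdvars=df["rdvars"].to_numpy(float),
        frame_times_s=df["t_sec"].to_numpy(float),
    )


# ---------------------------------------------------------------- strategy config

def strategy_to_dict(strategy: DenoiseStrategy) -> dict:
    return {
        "clutter": {
            "method": strategy.clutter.method,
            "T": strategy.clutter.T,
            "use_brain_mask": strategy.clutter.use_brain_mask,
        },
        "scrub_metric": strategy.scrub_metric,
        "freq_filter": strategy.freq_filter,
        "confound_method": strategy.confound_method,
        "n_components": strategy.n_components,
        "smoothing_fwhm_mm": strategy.smoothing_fwhm_mm,
    }


def strategy_from_dict(cfg: dict | None) -> DenoiseStrategy:
    """Build a strategy from a (possibly partial) mapping.

    Unspecified fields default to the adaptive paradigm-1 strategy:
    constant-energy SVD₄₀ with brain mask, rDVARS scrubbing, 0.01 Hz
    high-pass, aCompCor.
    """
    cfg = dict(cfg or {})
    clutter_cfg = dict(cfg.pop("clutter", {}) or {})
    known_clutter = {"method", "T", "use_brain_mask", "hp_cutoff_hz", "hp_order"}
    unknown = set(clutter_cfg) - known_clutter
    if unknown:
        raise ConfigurationError("clutter", f"unknown fields {sorted(unknown)}")
    clutter = ClutterFilterSpec(
        method=clutter_cfg.get("method", "constant_energy"),
        T=clutter_cfg.get("T", 40),
        use_brain_mask=clutter_cfg.get("use_brain_mask", True),
        hp_cutoff_hz=clutter_cfg.get("hp_cutoff_hz", 20.0),
        hp_order=clutter_cfg.get("hp_order", 8),
    )
    known = {
        "scrub_metric", "freq_filter", "confound_method", "n_components",
        "smoothing_fwhm_mm",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ConfigurationError("strategy", f"unknown fields {sorted(unknown)}")
    return DenoiseStrategy(
        clutter=clutter,
        scrub_metric=cfg.get("scrub_metric", "rdvars"),
        freq_filter=cfg.get("freq_filter", "highpass"),
        confound_method=cfg.get("confound_method", "acompcor"),
        n_components=cfg.get("n_components", 5),
        smoothing_fwhm_mm=cfg.get("smoothing_fwhm_mm", 0.3),
    )


def load_strategy(path) -> DenoiseStrategy:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return strategy_from_dict(cfg)


def save_strategy(path, strategy: DenoiseStrategy) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(strategy_to_dict(strategy), f, sort_keys=False)


# ---------------------------------------------------------------- manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, files: list, extra: dict | None = None) -> Path:
    """List every written artifact with its checksum; returns the manifest path."""
    out_dir = Path(out_dir)
    entries = []
    for p in files:
        p = Path(p)
        if not p.exists():
            raise InputError(f"manifest lists a missing file: {p}")
        entries.append(
            {
                "path": str(p.relative_to(out_dir) if p.is_relative_to(out_dir) else p),
                "sha256": _sha256(p),
                "bytes": p.stat().st_size,
            }
        )
    manifest = {"artifacts": entries, **(extra or {})}
    path = out_dir / "manifest.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2)
    return path
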