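"""Spatial and temporal quality-control metrics for power Doppler acquisitions.

Three spatial maps summarise an acquisition: the temporal mean power Doppler
intensity, the temporal coefficient of variation (std/mean), and the temporal
mean absolute axial velocity. Three time series flag motion frames:

rGS
    relative global signal, ``100·(GS − D1)/D1`` where GS is the mean brain
    power Doppler per frame and D1 its first decile (a robust baseline);
GV
    global axial velocity — mean absolute axial velocity over brain voxels,
    a direct measure of tissue motion;
rDVARS
    the RMS frame-to-frame signal change (DVARS, backward differences)
    standardised by its expected null level. Under per-voxel AR(1) noise with
    coefficient ρ_v and standard deviation σ_v, the expected squared
    difference is ``μ0 = mean_v 2(1−ρ_v)σ_v²``; rDVARS = DVARS/√μ0 so its
    null baseline sits near 1. σ_v is estimated robustly as IQR/1.349.

All quantile computations use linear interpolation between order statistics
(numpy's default); rGS and rDVARS are invariant to positive rescaling of the
data, GV scales with velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clutter import PowerDopplerSeries
from .errors import DegenerateSignalError, InputError
from .velocity import VelocitySeries

__all__ = ["SpatialQC", "TemporalQC", "spatial_qc", "rgs", "gv", "rdvars", "temporal_qc"]


@dataclass
class SpatialQC:
    """Per-voxel temporal summaries of one acquisition."""

    mean_pd: np.ndarray
    cv: np.ndarray
    mean_velocity: np.ndarray

    def mean_pd_db(self) -> np.ndarray:
        """Mean power Doppler in dB relative to its maximum (display only)."""
        ref = float(np.max(self.mean_pd))
        if ref <= 0:
            return np.zeros_like(self.mean_pd)
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(np.where(self.mean_pd > 0, self.mean_pd, np.nan) / ref)


@dataclass
class TemporalQC:
    """Per-frame motion metrics; ``rdvars[0]`` is undefined (NaN)."""

    rgs_pct: np.ndarray
    gv_mm_s: np.ndarray
    rdvars: np.ndarray
    frame_times_s: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frame_times_s.size


def _flat_mask(mask: np.ndarray, n_voxels: int) -> np.ndarray:
    mask = np.asarray(mask).reshape(-1).astype(bool)
    if mask.size != n_voxels:
        raise InputError("brain mask size does not match the voxel grid")
    if not mask.any():
        raise InputError("brain mask is empty")
    return mask


def spatial_qc(pd: PowerDopplerSeries, vel: VelocitySeries) -> SpatialQC:
    """Temporal mean PD, temporal CV, and temporal mean velocity volumes."""
    if pd.n_frames != vel.n_frames or pd.grid_shape != vel.volumes.shape[1:]:
        raise InputError("power Doppler and velocity series must share frames and grid")
    mean_pd = pd.volumes.mean(axis=0)
    std_pd = pd.volumes.std(axis=0)  # population std
    cv = np.zeros_like(mean_pd)
    np.divide(std_pd, mean_pd, out=cv, where=mean_pd > 0)
    return SpatialQC(mean_pd=mean_pd, cv=cv, mean_velocity=vel.volumes.mean(axis=0))


def rgs(pd: PowerDopplerSeries, brain_mask: np.ndarray) -> np.ndarray:
    """Relative global signal per frame, percent above the first-decile baseline."""
    flat = pd.volumes.reshape(pd.n_frames, -1)
    mask = _flat_mask(brain_mask, flat.shape[1])
    gs = flat[:, mask].mean(axis=1)
    d1 = float(np.quantile(gs, 0.1))
    if d1 <= 0:
        raise DegenerateSignalError("first-decile baseline of the global signal is <= 0")
    return 100.0 * (gs - d1) / d1


def gv(vel: VelocitySeries, brain_mask: np.ndarray) -> np.ndarray:
    """Global axial velocity per frame: mean absolute velocity over brain voxels."""
    flat = vel.volumes.reshape(vel.n_frames, -1)
    mask = _flat_mask(brain_mask, flat.shape[1])
    return flat[:, mask].mean(axis=1)


def _lag1_autocorr(x: np.ndarray) -> np.ndarray:
    """Sample lag-1 Pearson autocorrelation per column of (time, voxels)."""
    xc = x - x.mean(axis=0)
    num = np.sum(xc[1:] * xc[:-1], axis=0)
    den = np.sum(xc * xc, axis=0)
    rho = np.zeros(x.shape[1])
    np.divide(num, den, out=rho, where=den > 0)
    return rho


def rdvars(pd: PowerDopplerSeries, brain_mask: np.ndarray) -> np.ndarray:
    """Standardised DVARS per frame; the first frame is NaN (backward difference).

    The AR(1) null level ``μ0 = mean_v 2(1−ρ_v)σ_v²`` uses the robust
    σ_v = IQR/1.349 and the per-voxel sample lag-1 autocorrelation clipped to
    [0, 0.99]. A constant acquisition returns all-zero rDVARS.
    """
    if pd.n_frames < 3:
        raise InputError("rDVARS needs at least 3 frames")
    flat = pd.volumes.reshape(pd.n_frames, -1)
    mask = _flat_mask(brain_mask, flat.shape[1])
    X = flat[:, mask]
    diffs = np.diff(X, axis=0)
    dvars = np.sqrt(np.mean(diffs**2, axis=1))

    iqr = np.quantile(X, 0.75, axis=0) - np.quantile(X, 0.25, axis=0)
    sigma = iqr / 1.349
    rho = np.clip(_lag1_autocorr(X), 0.0, 0.99)
    mu0 = float(np.mean(2.0 * (1.0 - rho) * sigma**2))

    out = np.full(pd.n_frames, np.nan)
    if mu0 <= 0:
        if np.allclose(dvars, 0.0):
            out[1:] = 0.0
            return out
        raise DegenerateSignalError("null DVARS level mu0 is not positive")
    out[1:] = dvars / np.sqrt(mu0)
    return out


def temporal_qc(
    pd: PowerDopplerSeries, vel: VelocitySeries, brain_mask: np.ndarray
) -> TemporalQC:
    """All three temporal QC series for one acquisition."""
    if pd.n_frames != vel.n_frames:
        raise InputError("power Doppler and velocity series must share frame count")
    return TemporalQC(
        rgs_pct=rgs(pd, brain_mask),
        gv_mm_s=gv(vel, brain_mask),
        rdvars=rdvars(pd, brain_mask),
        frame_times_s=np.asarray(pd.frame_times_s, dtype=float),
    )
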