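"""Axial tissue-velocity estimation from beamformed I/Q data.

The Kasai autocorrelation estimator recovers the mean axial velocity of
scatterers from the phase of the lag-1 temporal autocorrelation of the complex
beamformed signal ``IQ(x, z, t) = A e^{iφ}``: for adjacent frames,

    Δφ = arg(IQ(t+1) · IQ*(t)),      v_z = Δφ · c · f_IQ / (4π · f_pulse),

where ``c`` is the speed of sound, ``f_IQ`` the compound frame rate, and
``f_pulse`` the transmit frequency. Taking ``arg`` of the complex product
(rather than differencing phases) avoids 2π wrap errors. Velocities are
reported in mm/s and bounded by the Nyquist velocity ``c·f_IQ/(4·f_pulse)``.

One absolute-velocity volume is produced per compound block by averaging
``|v_z|`` over the block's adjacent frame pairs, which places the velocity
series at the same sampling rate as the power Doppler series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import InputError, ParameterError

__all__ = [
    "IQBlock",
    "VelocitySeries",
    "kasai_axial_velocity",
    "block_absolute_velocity",
    "estimate_block_velocity",
    "doppler_frequency_to_velocity",
    "velocity_to_doppler_frequency",
]


@dataclass
class IQBlock:
    """One compound block of complex beamformed samples.

    ``samples`` is indexed ``(frame, *grid)`` where ``grid`` is the 2D or 3D
    voxel grid; the frame axis runs at ``f_iq_hz``.
    """

    samples: np.ndarray
    f_pulse_hz: float
    c_m_per_s: float = 1540.0
    f_iq_hz: float = 500.0
    voxel_size_mm: float = 0.1

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim < 2:
            raise InputError("samples must be (frame, *grid) with >=1 spatial axis")
        if self.block_len < 2:
            raise InputError("block must contain at least 2 frames")
        if self.f_pulse_hz <= 0:
            raise InputError("f_pulse_hz must be positive")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise InputError("samples contain non-finite values")

    @property
    def block_len(self) -> int:
        return self.samples.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.samples.shape[1:]

    @property
    def nyquist_velocity_mm_s(self) -> float:
        """Largest unambiguous axial speed, mm/s (phase shift of π per frame)."""
        return 1e3 * self.c_m_per_s * self.f_iq_hz / (4.0 * self.f_pulse_hz)

    def as_matrix(self) -> np.ndarray:
        """Block as a (time, voxels) matrix."""
        return self.samples.reshape(self.block_len, -1)


@dataclass
class VelocitySeries:
    """Absolute axial velocity volumes (mm/s), one per compound block."""

    volumes: np.ndarray  # (n_blocks, *grid), nonnegative
    sampling_rate_hz: float
    voxel_size_mm: float = 0.1
    frame_times_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(self.volumes < 0):
            raise InputError("absolute velocity volumes must be nonnegative")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.volumes.shape[0]) / self.sampling_rate_hz

    @property
    def n_frames(self) -> int:
        return self.volumes.shape[0]


def _filtfilt_complex(sos: np.ndarray, x: np.ndarray, axis: int) -> np.ndarray:
    # real-coefficient filter: real and imaginary parts filter independently
    return signal.sosfiltfilt(sos, x.real, axis=axis) + 1j * signal.sosfiltfilt(
        sos, x.imag, axis=axis
    )


def kasai_axial_velocity(
    block: IQBlock,
    lowpass_cutoff_hz: float | None = 30.0,
    lowpass_order: int = 6,
    median_kernel: int = 3,
) -> np.ndarray:
    """Per-frame-pair axial velocity volumes from one I/Q block.

    The I/Q signal is optionally low-pass filtered along time (zero-phase
    Butterworth, 30 Hz / order 6 by default) before phase estimation; each
    velocity volume is then smoothed with a spatial median filter
    (3×3×3 voxels; 3×3 for 2D grids). Pass ``lowpass_cutoff_hz=None`` or
    ``median_kernel=1`` to disable either step.

    Returns
    -------
    ndarray, shape (block_len - 1, *grid)
        Signed axial velocity in mm/s; ``arg`` lies in (−π, π] so values are
        bounded by the Nyquist velocity.
    """
    iq = block.samples
    if lowpass_cutoff_hz is not None:
        if lowpass_cutoff_hz >= block.f_iq_hz / 2:
            raise ParameterError("lowpass cutoff must be below Nyquist")
        sos = signal.butter(
            lowpass_order, lowpass_cutoff_hz, btype="low", fs=block.f_iq_hz, output="sos"
        )
        iq = _filtfilt_complex(sos, iq, axis=0)

    dphi = np.angle(iq[1:] * np.conj(iq[:-1]))  # (-pi, pi]
    v_mm_s = dphi * (1e3 * block.c_m_per_s * block.f_iq_hz) / (4.0 * np.pi * block.f_pulse_hz)

    if median_kernel and median_kernel > 1:
        size = (1,) + (median_kernel,) * (v_mm_s.ndim - 1)
        v_mm_s = ndimage.median_filter(v_mm_s, size=size, mode="nearest")
    return v_mm_s


def block_absolute_velocity(velocity_frames: np.ndarray) -> np.ndarray:
    """One absolute-velocity volume: mean of |v_z| over the block's frame pairs."""
    velocity_frames = np.asarray(velocity_frames, dtype=float)
    if velocity_frames.ndim < 2 or velocity_frames.shape[0] < 1:
        raise InputError("need at least one velocity frame")
    return np.mean(np.abs(velocity_frames), axis=0)


def estimate_block_velocity(
    block: IQBlock,
    lowpass_cutoff_hz: float | None = 30.0,
    lowpass_order: int = 6,
    median_kernel: int = 3,
) -> np.ndarray:
    """Absolute axial velocity volume (mm/s) for one compound block."""
    return block_absolute_velocity(
        kasai_axial_velocity(block, lowpass_cutoff_hz, lowpass_order, median_kernel)
    )


def doppler_frequency_to_velocity(
    f_doppler_hz: float, f_pulse_hz: float, c_m_per_s: float = 1540.0
) -> float:
    """Axial speed (mm/s) whose round-trip Doppler shift equals ``f_doppler_hz``.

    ``v = f_d · c / (2 · f_pulse)``; e.g. a 20 Hz wall-filter cutoff at
    15.625 MHz and 1540 m/s maps to ≈ 0.99 mm/s.
    """
    if f_pulse_hz <= 0:
        raise ParameterError("f_pulse_hz must be positive")
    return 1e3 * f_doppler_hz * c_m_per_s / (2.0 * f_pulse_hz)


def velocity_to_doppler_frequency(
    v_mm_s: float, f_pulse_hz: float, c_m_per_s: float = 1540.0
) -> float:
    """Round-trip Doppler shift (Hz) of an axial speed given in mm/s."""
    return 2.0 * f_pulse_hz * (v_mm_s * 1e-3) / c_m_per_s
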