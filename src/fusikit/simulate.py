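"""Synthetic fUSI acquisitions with known ground truth.

Two generators make every pipeline stage testable without real data:

:func:`simulate_iq`
    complex beamformed I/Q blocks built from three components. *Clutter*: a
    low-rank (rank 3–5) sum of smooth complex spatial patterns times smooth
    temporal envelopes, scaled so its mean energy exceeds the blood energy by
    a configurable factor (≫1, mirroring the premise of SVD clutter
    filtering). During a motion event the clutter acquires a per-frame axial
    phase ramp ``exp(i·4π·f_pulse·v·t/(c·f_IQ))`` (so the Kasai estimator
    reads the injected tissue velocity), its energy is multiplied by a surge
    factor, and a broadband decorrelated clutter term is added — nonrigid
    tissue motion spreads clutter energy across many temporal eigenvectors,
    which is what defeats fixed-rank filters. *Blood*: per-voxel random
    scatterer phase advancing at a Doppler shift drawn from ±[2, 10] mm/s
    (above the ≈1 mm/s wall-filter cutoff), amplitude modulated by a slow
    per-voxel CBV signal carrying bilateral network structure. *Noise*:
    complex white noise.

:func:`simulate_power_doppler`
    power-Doppler-level series ``baseline × (1 + network signals + AR(1)
    noise)`` with multiplicative surges (e.g. ×2–×5, i.e. +100–400 %) at
    motion events.

Both draw every component from independent substreams of one root seed, so
adding a component never perturbs the others, and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .clutter import PowerDopplerSeries
from .errors import ConfigurationError
from .velocity import IQBlock, VelocitySeries

__all__ = [
    "MotionEvent",
    "SimConfig",
    "GroundTruth",
    "default_masks",
    "default_networks",
    "simulate_iq",
    "iter_iq_blocks",
    "ground_truth",
    "simulate_power_doppler",
    "simulate_velocity",
]


@dataclass(frozen=True)
class MotionEvent:
    """One transient motion event: affected block, tissue velocity, energy surge."""

    block: int
    velocity_mm_s: float = 0.05
    surge: float = 10.0


@dataclass
class SimConfig:
    """Parameters of a synthetic acquisition.

    ``clutter_energy`` is the clutter-to-blood energy ratio (dimensionless,
    ≫1; in vivo values are not reported, 100 is this package's modeling
    choice). ``network_rois`` lists voxel-index sets sharing a common slow CBV
    signal; consecutive pairs (0,1), (2,3), … share one latent each, emulating
    bilateral homotopic networks. ``ar1_rho`` shapes the power-Doppler-level
    temporal noise; ``surge`` factors multiply clutter energy (I/Q level) or
    PD intensity (PD level) during events.
    """

    grid_shape: tuple = (24, 24)
    voxel_size_mm: float = 0.1
    f_pulse_hz: float = 15.625e6
    c_m_per_s: float = 1540.0
    f_iq_hz: float = 500.0
    block_len: int = 200
    n_blocks: int = 50
    clutter_energy: float = 100.0
    motion_events: tuple = ()
    network_rois: tuple | None = None
    ar1_rho: float = 0.3
    rng_seed: int = 0
    # secondary knobs (defaults are the package's stated study conditions)
    clutter_rank: int = 4
    blood_velocity_range_mm_s: tuple = (2.0, 10.0)
    noise_energy_frac: float = 0.1
    motion_broadband_frac: float = 0.5
    network_amplitude: float = 0.08
    voxel_cbv_amplitude: float = 0.02
    pd_noise_std: float = 0.05
    inter_block_delay_s: float = 0.0

    def __post_init__(self):
        if self.block_len < 2:
            raise ConfigurationError("block_len", "must be >= 2")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks", "must be >= 1")
        if self.clutter_energy <= 1:
            raise ConfigurationError("clutter_energy", "must be > 1")
        if not (0 <= self.ar1_rho < 1):
            raise ConfigurationError("ar1_rho", "must be in [0, 1)")
        if not (3 <= self.clutter_rank <= 5):
            raise ConfigurationError("clutter_rank", "must be in [3, 5]")
        events = tuple(
            e if isinstance(e, MotionEvent) else MotionEvent(*e)
            for e in self.motion_events
        )
        for e in events:
            if not (0 <= e.block < self.n_blocks):
                raise ConfigurationError(
                    "motion_events", f"event block {e.block} outside [0, {self.n_blocks})"
                )
            if e.surge <= 0:
                raise ConfigurationError("motion_events", "surge factor must be > 0")
        self.motion_events = events
        if self.network_rois is None:
            self.network_rois = default_networks(self.grid_shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def pd_rate_hz(self) -> float:
        return 1.0 / (self.block_len / self.f_iq_hz + self.inter_block_delay_s)

    @property
    def event_blocks(self) -> dict:
        return {e.block: e for e in self.motion_events}


@dataclass
class GroundTruth:
    """What the generator injected, for validating the pipeline against."""

    true_cbv: np.ndarray  # (n_blocks, *grid), relative units around 1
    true_axial_velocity: np.ndarray  # (n_blocks,), mm/s
    motion_mask: np.ndarray  # bool per block
    network_membership: np.ndarray  # (*grid,) int, -1 = background
    brain_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    wmcsf_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def default_masks(grid_shape: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical brain mask and a mid-depth band as the WM+CSF stand-in.

    The band covers roughly 15 % of brain voxels — the proportion an
    anatomical WM/CSF mask occupies in a mouse coronal slice — and carries
    artifact but no network signal, which is what anatomical CompCor exploits.
    """
    centers = [(n - 1) / 2.0 for n in grid_shape]
    semi = [0.48 * n for n in grid_shape]
    coords = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    ell = sum(((c - m) / s) ** 2 for c, m, s in zip(coords, centers, semi))
    brain = ell <= 1.0
    depth = coords[0] / max(grid_shape[0] - 1, 1)
    band = (depth >= 0.40) & (depth <= 0.48)
    wmcsf = brain & band
    return brain, wmcsf


# fractional (depth, lateral) positions of the six default network ROIs:
# three bilateral pairs — dorsal cortex, hippocampus-like, thalamus-like
NETWORK_SPOTS = (
    (0.18, 0.25), (0.18, 0.75),
    (0.62, 0.28), (0.62, 0.72),
    (0.80, 0.38), (0.80, 0.62),
)

NETWORK_NAMES = (
    "somatosensory_left", "somatosensory_right",
    "hippocampus_left", "hippocampus_right",
    "thalamus_left", "thalamus_right",
)


def network_centers(grid_shape: tuple) -> list[tuple]:
    """Voxel-index centers of the six default network ROIs."""
    nz, nx = grid_shape[0], grid_shape[1]
    centers = []
    for fz, fx in NETWORK_SPOTS:
        center = [fz * (nz - 1), fx * (nx - 1)]
        for n in grid_shape[2:]:
            center.append((n - 1) / 2.0)
        centers.append(tuple(center))
    return centers


def default_networks(grid_shape: tuple) -> tuple:
    """Six ROIs as three bilateral pairs (cortex, hippocampus, thalamus-like).

    Returned as flat voxel-index arrays; pairs (0,1), (2,3), (4,5) share a
    latent signal. Positions avoid the WM/CSF band of :func:`default_masks`.
    """
    nz, nx = grid_shape[0], grid_shape[1]
    spots = NETWORK_SPOTS
    coords = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    rois = []
    radius = max(2.0, 0.07 * min(nz, nx))
    for fz, fx in spots:
        cz, cx = fz * (nz - 1), fx * (nx - 1)
        d2 = (coords[0] - cz) ** 2 + (coords[1] - cx) ** 2
        for extra in coords[2:]:  # 3D grids: center the ROI in depth
            d2 = d2 + (extra - (extra.max() / 2.0)) ** 2
        rois.append(np.flatnonzero((d2 <= radius**2).reshape(-1)))
    return tuple(rois)


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=key)
    )


def _smooth_field(rng: np.random.Generator, grid_shape, sigma_vox: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma_vox, mode="wrap")
    return f / max(np.sqrt(np.sum(f**2)), 1e-30)


def _smooth_series(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    s = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma, mode="wrap")
    sd = s.std()
    return s / sd if sd > 0 else s


class _IQSimState:
    """Deterministic acquisition-level state; blocks are generated on demand."""

    def __init__(self, config: SimConfig):
        self.config = c = config
        ngrid, nvox = c.grid_shape, c.n_voxels

        # --- clutter: low-rank smooth patterns × smooth temporal envelopes
        rng_cl = _rng(c, 0)
        sigma_vox = max(2.0, 0.12 * min(ngrid))
        self.patterns = np.stack(
            [
                _smooth_field(rng_cl, ngrid, sigma_vox).reshape(-1)
                + 1j * 0.2 * _smooth_field(rng_cl, ngrid, sigma_vox).reshape(-1)
                for _ in range(c.clutter_rank)
            ],
            axis=1,
        )  # (voxels, rank)
        self.weights = 1.0 / (1.0 + 0.8 * np.arange(c.clutter_rank))
        n_total = c.n_blocks * c.block_len
        env_sigma = 0.5 * c.f_iq_hz  # ~0.5 s correlation time
        # ±5 % envelope modulation: quiet-period tissue echoes are nearly
        # stationary, and the Kasai noise floor scales inversely with clutter
        # amplitude, so the no-motion GV baseline stays flat
        self.envelopes = np.stack(
            [
                1.0 + 0.05 * _smooth_series(rng_cl, n_total, env_sigma)
                for _ in range(c.clutter_rank)
            ],
            axis=1,
        )  # (n_total, rank)

        # --- blood: Doppler shifts, phases, vascular density, slow CBV
        rng_bl = _rng(c, 1)
        lo, hi = c.blood_velocity_range_mm_s
        speeds = rng_bl.uniform(lo, hi, nvox) * rng_bl.choice([-1.0, 1.0], nvox)
        self.omega = (
            2.0 * np.pi * 2.0 * c.f_pulse_hz * (speeds * 1e-3) / c.c_m_per_s / c.f_iq_hz
        )  # rad per frame
        self.phi0 = rng_bl.uniform(0, 2 * np.pi, nvox)
        dens = ndimage.gaussian_filter(
            rng_bl.standard_normal(ngrid), max(1.5, 0.08 * min(ngrid)), mode="wrap"
        )
        self.density = (0.5 + np.abs(dens.reshape(-1)) / np.abs(dens).mean()).clip(0.2)

        # --- slow CBV with bilateral network structure
        rng_cbv = _rng(c, 2)
        membership = np.full(nvox, -1, dtype=int)
        for label, roi in enumerate(c.network_rois):
            membership[np.asarray(roi, dtype=int)] = label
        self.membership = membership
        n_latents = (len(c.network_rois) + 1) // 2
        # ~0.8 s smoothing: slow CBV fluctuations span ~0.01-0.2 Hz in awake
        # rodents, extending above the 0.1 Hz band-pass edge
        latent_sigma = max(1.0, 0.8 * c.pd_rate_hz)
        latents = np.stack(
            [_smooth_series(rng_cbv, c.n_blocks, latent_sigma) for _ in range(n_latents)],
            axis=1,
        )
        cbv = np.ones((c.n_blocks, nvox))
        for label, roi in enumerate(c.network_rois):
            cbv[:, np.asarray(roi, dtype=int)] += (
                c.network_amplitude * latents[:, label // 2][:, None]
            )
        if c.voxel_cbv_amplitude > 0:
            idio = ndimage.gaussian_filter1d(
                rng_cbv.standard_normal((c.n_blocks, nvox)), latent_sigma, axis=0,
                mode="wrap",
            )
            sd = idio.std(axis=0, keepdims=True)
            cbv += c.voxel_cbv_amplitude * idio / np.where(sd > 0, sd, 1.0)
        self.cbv = cbv.clip(0.1)

        # --- exact energy bookkeeping for the clutter-to-blood ratio
        blood_energy_per_block = np.sum(
            (self.density**2)[None, :] * self.cbv, axis=1
        )  # per frame, constant within a block
        self.mean_blood_energy = float(blood_energy_per_block.mean())
        cross = self.patterns.conj().T @ self.patterns  # (rank, rank) pattern Gram
        w_env = self.envelopes * self.weights[None, :]
        clut_energy = np.einsum("tr,rs,ts->t", w_env, cross.real, w_env)
        self.clutter_scale = np.sqrt(
            c.clutter_energy * self.mean_blood_energy / clut_energy.mean()
        )
        self.mean_clutter_energy = c.clutter_energy * self.mean_blood_energy
        self.noise_var = c.noise_energy_frac * self.mean_blood_energy / nvox

        self.events = c.event_blocks

    def block(self, b: int) -> np.ndarray:
        """Complex samples of block ``b``, shape (block_len, *grid)."""
        c = self.config
        t0 = b * c.block_len
        t_local = np.arange(c.block_len)
        t_global = t0 + t_local

        env = self.envelopes[t0 : t0 + c.block_len] * self.weights[None, :]
        clut = (env @ self.patterns.T) * self.clutter_scale  # (time, voxels)

        event = self.events.get(b)
        if event is not None:
            dphi = (
                4.0 * np.pi * c.f_pulse_hz * (event.velocity_mm_s * 1e-3)
                / (c.c_m_per_s * c.f_iq_hz)
            )
            clut = clut * (np.sqrt(event.surge) * np.exp(1j * dphi * t_local))[:, None]

        amp = self.density * np.sqrt(self.cbv[b])
        blood = amp[None, :] * np.exp(
            1j * (self.omega[None, :] * t_global[:, None] + self.phi0[None, :])
        )

        rng_b = _rng(c, 3, b)
        noise = np.sqrt(self.noise_var / 2.0) * (
            rng_b.standard_normal((c.block_len, c.n_voxels))
            + 1j * rng_b.standard_normal((c.block_len, c.n_voxels))
        )
        x = clut + blood + noise

        if event is not None and c.motion_broadband_frac > 0:
            g = rng_b.standard_normal((c.block_len, c.n_voxels)) + 1j * rng_b.standard_normal(
                (c.block_len, c.n_voxels)
            )
            target = (
                c.motion_broadband_frac
                * event.surge
                * self.mean_clutter_energy
                * c.block_len
            )
            x = x + g * np.sqrt(target / np.sum(np.abs(g) ** 2))
        return x.reshape(c.block_len, *c.grid_shape)

    def iq_block(self, b: int) -> IQBlock:
        c = self.config
        return IQBlock(
            samples=self.block(b),
            f_pulse_hz=c.f_pulse_hz,
            c_m_per_s=c.c_m_per_s,
            f_iq_hz=c.f_iq_hz,
            voxel_size_mm=c.voxel_size_mm,
        )


def ground_truth(config: SimConfig) -> GroundTruth:
    """Injected CBV, per-block tissue velocity, motion mask, and labels."""
    state = _IQSimState(config)
    c = config
    vel = np.zeros(c.n_blocks)
    motion = np.zeros(c.n_blocks, dtype=bool)
    for e in c.motion_events:
        vel[e.block] = abs(e.velocity_mm_s)
        motion[e.block] = True
    brain, wmcsf = default_masks(c.grid_shape)
    return GroundTruth(
        true_cbv=state.cbv.reshape(c.n_blocks, *c.grid_shape),
        true_axial_velocity=vel,
        motion_mask=motion,
        network_membership=state.membership.reshape(c.grid_shape),
        brain_mask=brain,
        wmcsf_mask=wmcsf,
    )


def iter_iq_blocks(config: SimConfig):
    """Stream the acquisition block by block (constant memory)."""
    state = _IQSimState(config)
    for b in range(config.n_blocks):
        yield state.iq_block(b)


def simulate_iq(config: SimConfig) -> tuple[list[IQBlock], GroundTruth]:
    """Full synthetic I/Q acquisition plus its ground truth."""
    return list(iter_iq_blocks(config)), ground_truth(config)


def simulate_power_doppler(config: SimConfig) -> tuple[PowerDopplerSeries, GroundTruth]:
    """Power-Doppler-level acquisition: baseline × (1 + networks + AR(1) noise).

    One frame per block at the power Doppler rate; motion events multiply the
    whole frame by their surge factor (a surge of 3 is +200 % over baseline).
    """
    gt = ground_truth(config)
    c = config
    rng = _rng(c, 4)
    base = ndimage.gaussian_filter(
        rng.standard_normal(c.grid_shape), max(1.5, 0.08 * min(c.grid_shape)), mode="wrap"
    )
    baseline = (1.0 + 0.5 * np.abs(base) / max(np.abs(base).mean(), 1e-30)).reshape(-1)

    signal_rel = gt.true_cbv.reshape(c.n_blocks, -1) - 1.0  # networks + idiosyncratic CBV

    noise = rng.standard_normal((c.n_blocks, c.n_voxels))
    if c.ar1_rho > 0:
        for t in range(1, c.n_blocks):
            noise[t] = c.ar1_rho * noise[t - 1] + np.sqrt(1 - c.ar1_rho**2) * noise[t]
    pd = baseline[None, :] * (1.0 + signal_rel + c.pd_noise_std * noise)

    for e in c.motion_events:
        pd[e.block] *= e.surge
    pd = pd.clip(0.0).reshape(c.n_blocks, *c.grid_shape)
    series = PowerDopplerSeries(
        volumes=pd, sampling_rate_hz=c.pd_rate_hz, voxel_size_mm=c.voxel_size_mm
    )
    return series, gt


def simulate_velocity(config: SimConfig, baseline_mm_s: float = 0.02) -> VelocitySeries:
    """Velocity series consistent with the configured motion events.

    Companion to :func:`simulate_power_doppler` for testing GV-based stages
    without an I/Q-level run: a quiet baseline plus the injected event
    velocities, with small smooth fluctuations.
    """
    c = config
    rng = _rng(c, 5)
    fluct = 1e-3 * _smooth_series(rng, c.n_blocks, max(2.0, c.pd_rate_hz))
    v = np.full(c.n_blocks, baseline_mm_s) + fluct
    for e in c.motion_events:
        v[e.block] += abs(e.velocity_mm_s)
    vols = np.abs(v)[:, None] * np.ones((1, c.n_voxels))
    jitter = 1e-4 * rng.standard_normal((c.n_blocks, c.n_voxels))
    vols = np.abs(vols + jitter).reshape(c.n_blocks, *c.grid_shape)
    return VelocitySeries(
        volumes=vols, sampling_rate_hz=c.pd_rate_hz, voxel_size_mm=c.voxel_size_mm
    )
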