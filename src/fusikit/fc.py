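"""Seed-based functional connectivity maps and their group aggregation.

A seed is a small sphere (0.3 mm radius by default) around a named anatomical
coordinate; its signal is the mean denoised power Doppler over the sphere's
voxels, and the seed map is the Pearson correlation of that signal with every
brain voxel. Maps are averaged across acquisitions in Fisher-z space
(``tanh(mean(atanh(r)))``) and thresholded by keeping the top fraction of
voxels by (absolute) correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, GeometryError, InputError, ParameterError

__all__ = [
    "SeedSpec",
    "SeedMap",
    "sphere_mask",
    "seed_signal",
    "seed_map",
    "average_maps_fisher",
    "threshold_top_fraction",
]

_FISHER_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """A named spherical seed region in the acquisition's mm space."""

    name: str
    center_mm: tuple
    radius_mm: float = 0.3

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ParameterError("seed radius must be positive")


@dataclass
class SeedMap:
    """Voxelwise Pearson correlation volume for one seed."""

    r: np.ndarray  # (*grid,) in [-1, 1]; 0 with flag at zero-variance voxels
    seed: SeedSpec
    n_frames: int
    zero_variance: np.ndarray | None = None  # bool, voxels where r was forced to 0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise InputError("correlations must lie in [-1, 1]")


def sphere_mask(
    grid_shape: tuple, voxel_size_mm: float, center_mm: tuple, radius_mm: float
) -> np.ndarray:
    """Boolean mask of voxels whose centers fall within the sphere.

    Voxel centers sit at ``index * voxel_size_mm``; membership is
    center-to-center distance <= radius.
    """
    coords = np.meshgrid(
        *[np.arange(n) * voxel_size_mm for n in grid_shape], indexing="ij"
    )
    center = np.asarray(center_mm, dtype=float)
    if center.size != len(grid_shape):
        raise GeometryError("seed center dimensionality does not match the grid")
    dist2 = sum((c - m) ** 2 for c, m in zip(coords, center))
    mask = dist2 <= radius_mm**2 + 1e-12
    if not mask.any():
        raise GeometryError(f"seed sphere at {tuple(center)} contains no voxel centers")
    return mask


def seed_signal(
    clean: np.ndarray, seed: SeedSpec, voxel_size_mm: float
) -> np.ndarray:
    """Per-frame mean signal over the seed sphere of a (time, *grid) series."""
    clean = np.asarray(clean, dtype=float)
    mask = sphere_mask(clean.shape[1:], voxel_size_mm, seed.center_mm, seed.radius_mm)
    return clean.reshape(clean.shape[0], -1)[:, mask.reshape(-1)].mean(axis=1)


def seed_map(
    clean: np.ndarray,
    seed: SeedSpec,
    voxel_size_mm: float,
    brain_mask: np.ndarray | None = None,
) -> SeedMap:
    """Pearson correlation of the seed signal with every (brain) voxel.

    Zero-variance voxels get r = 0 and are flagged, so downstream
    thresholding and Dice are defined everywhere; voxels outside the brain
    mask are also 0.
    """
    clean = np.asarray(clean, dtype=float)
    if clean.shape[0] < 3:
        raise InputError("need at least 3 frames for a correlation map")
    sig = seed_signal(clean, seed, voxel_size_mm)
    sig_c = sig - sig.mean()
    sig_norm = np.sqrt(np.sum(sig_c**2))
    if sig_norm == 0:
        raise DegenerateSignalError("seed signal is constant")

    flat = clean.reshape(clean.shape[0], -1)
    Xc = flat - flat.mean(axis=0)
    vox_norm = np.sqrt(np.sum(Xc**2, axis=0))
    zero_var = vox_norm == 0
    r = np.zeros(flat.shape[1])
    np.divide(Xc.T @ sig_c, vox_norm * sig_norm, out=r, where=~zero_var)
    np.clip(r, -1.0, 1.0, out=r)
    if brain_mask is not None:
        r[~np.asarray(brain_mask).reshape(-1).astype(bool)] = 0.0
    return SeedMap(
        r=r.reshape(clean.shape[1:]),
        seed=seed,
        n_frames=clean.shape[0],
        zero_variance=zero_var.reshape(clean.shape[1:]),
    )


def average_maps_fisher(maps: list[SeedMap]) -> SeedMap:
    """Fisher-z average of seed maps: ``tanh(mean(atanh(r)))`` per voxel.

    Correlations are clipped to ±(1 − 1e−7) before ``atanh`` so perfect
    correlations stay finite.
    """
    if not maps:
        raise InputError("cannot average an empty list of maps")
    shape = maps[0].r.shape
    for m in maps[1:]:
        if m.r.shape != shape or m.seed != maps[0].seed:
            raise InputError("maps must share grid and seed")
    z = np.mean(
        [np.arctanh(np.clip(m.r, -_FISHER_CLIP, _FISHER_CLIP)) for m in maps], axis=0
    )
    return SeedMap(
        r=np.tanh(z),
        seed=maps[0].seed,
        n_frames=int(np.mean([m.n_frames for m in maps])),
    )


def threshold_top_fraction(
    smap: SeedMap,
    brain_mask: np.ndarray,
    fraction: float = 0.10,
    by_absolute: bool = True,
) -> np.ndarray:
    """Binary volume of the top ``floor(fraction·N_brain)`` correlated voxels.

    Ranking is by |r| (default, as used by the FC-similarity benchmark) or by
    signed r; ties are broken by voxel linear index.
    """
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must be in (0, 1]")
    brain = np.asarray(brain_mask).reshape(-1).astype(bool)
    if brain.size != smap.r.size:
        raise InputError("brain mask size does not match the map")
    if not brain.any():
        raise InputError("brain mask is empty")
    idx = np.flatnonzero(brain)
    score = np.abs(smap.r.reshape(-1)[idx]) if by_absolute else smap.r.reshape(-1)[idx]
    n_keep = int(np.floor(fraction * idx.size))
    out = np.zeros(smap.r.size, dtype=bool)
    if n_keep > 0:
        order = np.lexsort((idx, -score))  # descending score, ties by linear index
        out[idx[order[:n_keep]]] = True
    return out.reshape(smap.r.shape)
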