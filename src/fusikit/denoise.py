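"""Core functional-connectivity denoising pipeline.

The pipeline applies, in this fixed order:

1. spatial Gaussian smoothing (0.3 mm FWHM by default);
2. scrubbing — frames flagged by one QC metric (rGS > 10 %, rDVARS > 2.0, or
   GV above its first-decile baseline + 0.01 mm/s) are replaced by the mean of
   the unflagged frames so the series stays regularly sampled for filtering;
3. zero-phase Butterworth frequency filtering (order 6), either a 0.01 Hz
   high-pass or a 0.01–0.1 Hz band-pass;
4. removal of the scrubbed frames entirely (acquisitions retaining < 5 min
   are rejected);
5. ordinary-least-squares confound regression, ``X ← X − C·β``.

Confound regressors are estimated from the *raw* power Doppler data, before
smoothing or any other step (thin anatomical masks would otherwise suffer
partial-volume mixing), and then undergo the same scrubbing/filtering/censoring
as the data. Six methods are supported: none, global brain signal, and four
CompCor variants (temporal, anatomical, random-mask, low-variance) taking the
first 5 principal components of the voxel series in the respective mask.

One rule is enforced a priori: constant-energy clutter filtering flattens the
global signal, so combining it with rGS-based scrubbing is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .clutter import ClutterFilterSpec, PowerDopplerSeries
from .errors import InputError, ParameterError, RejectedAcquisitionError, StrategyError
from .qc import TemporalQC

__all__ = [
    "DenoiseStrategy",
    "ScrubMask",
    "ConfoundSet",
    "gaussian_smooth",
    "detect_high_motion",
    "scrub_replace",
    "frequency_filter",
    "drop_scrubbed",
    "compute_confounds",
    "regress_confounds",
    "run_denoise",
]

SCRUB_METRICS = ("rgs", "rdvars", "gv", "none")
FREQ_FILTERS = ("highpass", "bandpass")
CONFOUND_METHODS = (
    "none",
    "global_signal",
    "tcompcor",
    "acompcor",
    "random_compcor",
    "lowvar_compcor",
)

RGS_THRESHOLD_PCT = 10.0
RDVARS_THRESHOLD = 2.0
GV_THRESHOLD_MM_S = 1e-2
MIN_RETAINED_SECONDS = 300.0


@dataclass
class DenoiseStrategy:
    """One point of the factorial denoising grid."""

    clutter: ClutterFilterSpec = field(default_factory=ClutterFilterSpec)
    scrub_metric: str = "none"
    freq_filter: str = "highpass"
    confound_method: str = "none"
    n_components: int = 5
    smoothing_fwhm_mm: float = 0.3
    filter_order: int = 6
    highpass_cutoff_hz: float = 0.01
    bandpass_cutoffs_hz: tuple = (0.01, 0.1)
    # False only when enumerating the raw factorial grid, whose size counts
    # the (ineffective) constant-energy × rGS pairs before their exclusion
    enforce_exclusions: bool = True

    def __post_init__(self):
        if self.scrub_metric not in SCRUB_METRICS:
            raise StrategyError(f"unknown scrub metric {self.scrub_metric!r}")
        if self.freq_filter not in FREQ_FILTERS:
            raise StrategyError(f"unknown frequency filter {self.freq_filter!r}")
        if self.confound_method not in CONFOUND_METHODS:
            raise StrategyError(f"unknown confound method {self.confound_method!r}")
        if (
            self.enforce_exclusions
            and self.clutter.method == "constant_energy"
            and self.scrub_metric == "rgs"
        ):
            raise StrategyError(
                "constant-energy clutter filtering flattens the global signal; "
                "rGS-based scrubbing is ineffective and this combination is excluded"
            )

    def label(self) -> str:
        return (
            f"{self.clutter.label()}|scrub={self.scrub_metric}"
            f"|{self.freq_filter}|{self.confound_method}"
        )


@dataclass
class ScrubMask:
    """Frames flagged as high motion, with the acquisition's frame period."""

    flagged: np.ndarray  # bool per frame
    frame_period_s: float

    def __post_init__(self):
        self.flagged = np.asarray(self.flagged, dtype=bool)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def retained_seconds(self) -> float:
        return float((self.flagged.size - self.n_flagged) * self.frame_period_s)

    @property
    def retained_fraction(self) -> float:
        return 1.0 - self.n_flagged / self.flagged.size


@dataclass
class ConfoundSet:
    """Nuisance regressors, (time × k); k=0 means no confound regression."""

    regressors: np.ndarray
    method: str
    source_mask: np.ndarray | None = None

    def __post_init__(self):
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise InputError("regressors must be a (time, k) matrix")
        if not np.all(np.isfinite(self.regressors)):
            raise InputError("confound regressors contain non-finite values")

    @property
    def k(self) -> int:
        return 0 if self.regressors.size == 0 else self.regressors.shape[1]


def gaussian_smooth(
    pd: PowerDopplerSeries, fwhm_mm: float = 0.3
) -> PowerDopplerSeries:
    """Per-frame spatial Gaussian smoothing; ``fwhm_mm=0`` is the identity."""
    if fwhm_mm < 0:
        raise ParameterError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return pd
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pd.voxel_size_mm
    sigma = (0.0,) + (sigma_vox,) * (pd.volumes.ndim - 1)
    smoothed = ndimage.gaussian_filter(pd.volumes, sigma=sigma, mode="nearest")
    return replace(pd, volumes=smoothed)


def detect_high_motion(tqc: TemporalQC, strategy: DenoiseStrategy) -> ScrubMask:
    """Flag frames whose chosen metric exceeds its strict threshold.

    Thresholds: rGS > 10 %; rDVARS > 2.0 (the undefined first sample is never
    flagged); GV > first decile + 0.01 mm/s. ``scrub_metric='none'`` flags
    nothing.
    """
    period = float(np.median(np.diff(tqc.frame_times_s)))
    metric = strategy.scrub_metric
    if metric == "none":
        flagged = np.zeros(tqc.n_frames, dtype=bool)
    elif metric == "rgs":
        if strategy.clutter.method == "constant_energy":
            raise StrategyError("rGS scrubbing is excluded with constant-energy filtering")
        flagged = tqc.rgs_pct > RGS_THRESHOLD_PCT
    elif metric == "rdvars":
        with np.errstate(invalid="ignore"):
            flagged = np.nan_to_num(tqc.rdvars, nan=0.0) > RDVARS_THRESHOLD
    else:  # gv
        baseline = float(np.quantile(tqc.gv_mm_s, 0.1))
        flagged = tqc.gv_mm_s > baseline + GV_THRESHOLD_MM_S
    return ScrubMask(flagged=flagged, frame_period_s=period)


def scrub_replace(series: np.ndarray, mask: ScrubMask) -> np.ndarray:
    """Replace flagged frames by the per-voxel mean over unflagged frames."""
    series = np.asarray(series, dtype=float)
    if mask.flagged.size != series.shape[0]:
        raise InputError("scrub mask length does not match the series")
    if not mask.flagged.any():
        return series.copy()
    keep = ~mask.flagged
    if not keep.any():
        raise RejectedAcquisitionError(0.0)
    out = series.copy()
    out[mask.flagged] = series[keep].mean(axis=0)
    return out


def frequency_filter(
    series: np.ndarray,
    sampling_rate_hz: float,
    kind: str = "highpass",
    cutoffs_hz=None,
    order: int = 6,
) -> np.ndarray:
    """Zero-phase Butterworth filtering along the time axis (axis 0).

    ``kind='highpass'`` uses a 0.01 Hz cutoff, ``kind='bandpass'`` 0.01–0.1 Hz,
    unless ``cutoffs_hz`` overrides them. Applied identically to data voxels
    and confound columns.
    """
    series = np.asarray(series, dtype=float)
    if kind == "highpass":
        cut = 0.01 if cutoffs_hz is None else float(np.atleast_1d(cutoffs_hz)[0])
        if cut >= sampling_rate_hz / 2:
            raise ParameterError("highpass cutoff must be below Nyquist")
        sos = signal.butter(order, cut, btype="high", fs=sampling_rate_hz, output="sos")
    elif kind == "bandpass":
        lo, hi = (0.01, 0.1) if cutoffs_hz is None else cutoffs_hz
        if hi >= sampling_rate_hz / 2:
            raise ParameterError("bandpass upper cutoff must be below Nyquist")
        sos = signal.butter(order, (lo, hi), btype="band", fs=sampling_rate_hz, output="sos")
    else:
        raise ParameterError(f"unknown filter kind {kind!r}")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if series.shape[0] <= padlen:
        raise InputError(
            f"series too short ({series.shape[0]} frames) for the filter's "
            f"edge padding ({padlen} frames)"
        )
    return signal.sosfiltfilt(sos, series, axis=0)


def drop_scrubbed(
    series: np.ndarray,
    mask: ScrubMask,
    min_retained_s: float = MIN_RETAINED_SECONDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Delete flagged frames entirely; reject if < 5 min of data survives.

    Returns the censored series and the map from retained index to original
    frame index.
    """
    series = np.asarray(series)
    if mask.flagged.size != series.shape[0]:
        raise InputError("scrub mask length does not match the series")
    if mask.retained_seconds < min_retained_s:
        raise RejectedAcquisitionError(mask.retained_seconds, min_retained_s)
    keep = np.flatnonzero(~mask.flagged)
    return series[keep], keep


def _principal_components(
    X: np.ndarray, n_components: int
) -> np.ndarray:
    """First temporal principal components of (time, voxels) data.

    Voxel series are mean-centred (no variance normalisation) before the SVD.
    Sign convention: each component is flipped so its largest-magnitude
    spatial loading is positive, making outputs deterministic.
    """
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, s.size)
    comps = U[:, :k] * s[:k]
    for j in range(k):
        lead = Vt[j, np.argmax(np.abs(Vt[j]))]
        if lead < 0:
            comps[:, j] = -comps[:, j]
    return comps


def compute_confounds(
    raw_pd: PowerDopplerSeries,
    method: str,
    brain_mask: np.ndarray,
    wmcsf_mask: np.ndarray | None = None,
    n_components: int = 5,
    rng: np.random.Generator | int | None = None,
    tcompcor_fraction: float = 0.05,
) -> ConfoundSet:
    """Nuisance regressors from raw (pre-denoising) power Doppler data.

    ``global_signal``: mean PD over brain voxels (k=1). CompCor variants take
    the first ``n_components`` principal components over a source mask:
    ``tcompcor`` the top 5 % highest-variance brain voxels, ``acompcor`` the
    white-matter + CSF mask, ``random_compcor`` a brain mask of the same
    cardinality drawn once from ``rng``, ``lowvar_compcor`` the same
    cardinality of lowest-variance brain voxels. Variance ties are broken by
    voxel linear index.
    """
    if method not in CONFOUND_METHODS:
        raise ParameterError(f"unknown confound method {method!r}")
    n_frames = raw_pd.n_frames
    flat = raw_pd.volumes.reshape(n_frames, -1)
    if method == "none":
        return ConfoundSet(regressors=np.empty((n_frames, 0)), method=method)

    brain = np.asarray(brain_mask).reshape(-1).astype(bool)
    if brain.size != flat.shape[1]:
        raise InputError("brain mask size does not match the voxel grid")
    if not brain.any():
        raise InputError("brain mask is empty")

    if method == "global_signal":
        gs = flat[:, brain].mean(axis=1)
        return ConfoundSet(regressors=gs[:, None], method=method, source_mask=brain)

    brain_idx = np.flatnonzero(brain)
    if method == "tcompcor":
        std = flat[:, brain_idx].std(axis=0)
        n_sel = max(int(np.floor(tcompcor_fraction * brain_idx.size)), n_components)
        order = np.lexsort((brain_idx, -std))  # desc std, ties by linear index
        sel = brain_idx[order[:n_sel]]
    else:
        if wmcsf_mask is None:
            raise InputError(f"{method} requires a white-matter+CSF mask")
        wmcsf = np.asarray(wmcsf_mask).reshape(-1).astype(bool)
        if wmcsf.size != flat.shape[1]:
            raise InputError("wm/csf mask size does not match the voxel grid")
        if not wmcsf.any():
            raise InputError("wm/csf mask is empty")
        card = int(wmcsf.sum())
        if method == "acompcor":
            sel = np.flatnonzero(wmcsf)
        elif method == "random_compcor":
            gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
            sel = np.sort(gen.choice(brain_idx, size=min(card, brain_idx.size), replace=False))
        else:  # lowvar_compcor
            std = flat[:, brain_idx].std(axis=0)
            order = np.lexsort((brain_idx, std))  # asc std, ties by linear index
            sel = brain_idx[order[:card]]
    if n_frames <= n_components:
        raise InputError("need more frames than components for CompCor")
    comps = _principal_components(flat[:, sel], n_components)
    mask_out = np.zeros(flat.shape[1], dtype=bool)
    mask_out[sel] = True
    return ConfoundSet(regressors=comps, method=method, source_mask=mask_out)


def regress_confounds(
    series: np.ndarray, confounds: ConfoundSet, add_intercept: bool = True
) -> np.ndarray:
    """OLS removal of confound contributions: ``X − C·β``.

    An intercept column is included in the fit by default (censoring leaves
    the filtered data not exactly zero-mean) and its fitted offset is removed
    along with the confounds. Rank-deficient confound matrices have dependent
    columns dropped with a warning. Residuals are orthogonal to every
    confound column.
    """
    series = np.asarray(series, dtype=float)
    if confounds.k == 0:
        return series.copy()
    C = confounds.regressors
    if C.shape[0] != series.shape[0]:
        raise InputError("confounds and series must share the time axis")
    if add_intercept:
        C = np.column_stack([np.ones(C.shape[0]), C])
    # drop linearly dependent columns via rank-revealing QR
    q, r, piv = _qr_pivot(C)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)))
    if rank < C.shape[1]:
        warnings.warn(
            f"confound matrix is rank deficient ({rank}/{C.shape[1]}); "
            "dropping dependent columns",
            stacklevel=2,
        )
        C = C[:, np.sort(piv[:rank])]
    beta, *_ = np.linalg.lstsq(C, series.reshape(series.shape[0], -1), rcond=None)
    resid = series.reshape(series.shape[0], -1) - C @ beta
    return resid.reshape(series.shape)


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(A, mode="economic", pivoting=True)
    return q, r, piv


def run_denoise(
    raw_pd: PowerDopplerSeries,
    strategy: DenoiseStrategy,
    tqc: TemporalQC,
    brain_mask: np.ndarray,
    wmcsf_mask: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    min_retained_s: float = MIN_RETAINED_SECONDS,
):
    """Run the full pipeline on one acquisition.

    Returns ``(clean, scrub_mask, kept_idx)`` where ``clean`` is the censored,
    denoised (time, *grid) array and ``kept_idx`` maps its frames back to the
    original acquisition. Confounds are estimated from ``raw_pd`` first, then
    the data are smoothed, scrub-replaced, frequency filtered, censored, and
    confound-regressed; the confounds follow the same scrubbing, filtering and
    censoring before the regression.
    """
    confounds = compute_confounds(
        raw_pd,
        strategy.confound_method,
        brain_mask,
        wmcsf_mask=wmcsf_mask,
        n_components=strategy.n_components,
        rng=rng,
    )
    smoothed = gaussian_smooth(raw_pd, strategy.smoothing_fwhm_mm)
    mask = detect_high_motion(tqc, strategy)

    data = scrub_replace(smoothed.volumes, mask)
    kind = strategy.freq_filter
    cutoffs = (
        strategy.highpass_cutoff_hz if kind == "highpass" else strategy.bandpass_cutoffs_hz
    )
    data = frequency_filter(
        data, raw_pd.sampling_rate_hz, kind, cutoffs, strategy.filter_order
    )
    data, kept_idx = drop_scrubbed(data, mask, min_retained_s)

    if confounds.k > 0:
        creg = scrub_replace(confounds.regressors, mask)
        creg = frequency_filter(
            creg, raw_pd.sampling_rate_hz, kind, cutoffs, strategy.filter_order
        )
        creg = creg[kept_idx]
        data = regress_confounds(
            data, ConfoundSet(regressors=creg, method=confounds.method)
        )
    return data, mask, kept_idx
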