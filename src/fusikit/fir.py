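"""Finite-impulse-response characterisation of the velocity → power Doppler coupling.

Motion artifacts are not instantaneous: a power Doppler surge can lag or lead
the tissue-velocity excursion that caused it. To measure the coupling, each
voxel's power Doppler series is modeled as a linear combination of all
delayed copies of the global axial velocity (GV) between −12 and +12 s, plus
an intercept and a linear drift. Subject-level betas are fitted by ordinary
least squares; a second-level one-sample test across subjects converts each
(voxel, lag) beta to a z-score, and ROI traces summarise z across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import qr

from .errors import InputError

__all__ = ["FIRDesign", "ResponseMap", "make_fir_design", "fit_fir_subject", "group_fir"]


@dataclass
class FIRDesign:
    """Design matrix of lagged GV copies plus intercept and linear drift.

    The column for lag +k holds ``gv(t − k)``: a positive lag means the
    power Doppler response *follows* the velocity excursion. Samples shifted
    from outside the record are zero-padded and the affected rows flagged.
    """

    matrix: np.ndarray  # (time, n_lags + 2); last two columns intercept, drift
    lags_sec: np.ndarray  # (n_lags,)
    lag_samples: np.ndarray  # (n_lags,) integer shifts
    edge_rows: np.ndarray  # bool (time,), rows touched by zero padding

    @property
    def n_lags(self) -> int:
        return self.lags_sec.size


def make_fir_design(
    gv: np.ndarray, sampling_rate_hz: float, max_lag_s: float = 12.0
) -> FIRDesign:
    """Build the lagged-GV design for one acquisition.

    The lag grid runs at the power Doppler rate, giving
    ``2·round(max_lag·fs) + 1`` columns (61 at 2.5 Hz).
    """
    gv = np.asarray(gv, dtype=float).reshape(-1)
    n = gv.size
    max_shift = int(round(max_lag_s * sampling_rate_hz))
    shifts = np.arange(-max_shift, max_shift + 1)
    if n <= 2 * max_shift + 3:
        raise InputError("series too short for the requested lag range")
    cols = np.zeros((n, shifts.size))
    edge = np.zeros(n, dtype=bool)
    for j, k in enumerate(shifts):
        if k >= 0:
            cols[k:, j] = gv[: n - k]
            edge[:k] = True
        else:
            cols[:k, j] = gv[-k:]
            edge[k:] = True
    t = np.arange(n, dtype=float)
    drift = np.column_stack([np.ones(n), (t - t.mean()) / n])
    return FIRDesign(
        matrix=np.column_stack([cols, drift]),
        lags_sec=shifts / sampling_rate_hz,
        lag_samples=shifts,
        edge_rows=edge,
    )


@dataclass
class ResponseMap:
    """Group-level FIR response: z-scores per (lag, voxel) and ROI traces."""

    z: np.ndarray  # (n_lags, *grid)
    lags_sec: np.ndarray
    roi_traces: dict  # name -> (n_lags,) mean z over the ROI


def fit_fir_subject(
    pd_volumes: np.ndarray, gv: np.ndarray, sampling_rate_hz: float,
    max_lag_s: float = 12.0,
) -> tuple[np.ndarray, FIRDesign]:
    """Voxelwise OLS betas of the lagged-GV model for one subject.

    Returns ``(betas, design)`` with ``betas`` of shape (n_lags, *grid); the
    intercept and drift coefficients are fitted but not returned. Collinear
    design columns are dropped with a warning (their betas read 0).
    """
    pd_volumes = np.asarray(pd_volumes, dtype=float)
    design = make_fir_design(gv, sampling_rate_hz, max_lag_s)
    D = design.matrix
    if D.shape[0] != pd_volumes.shape[0]:
        raise InputError("power Doppler series and GV must share the time axis")
    keep = np.arange(D.shape[1])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        warnings.warn(
            f"FIR design is rank deficient ({rank}/{D.shape[1]}); "
            "dropping collinear columns",
            stacklevel=2,
        )
        _, r, piv = qr(D, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        D = D[:, keep]
    Y = pd_volumes.reshape(pd_volumes.shape[0], -1)
    beta_kept, *_ = np.linalg.lstsq(D, Y, rcond=None)
    beta = np.zeros((design.matrix.shape[1], Y.shape[1]))
    beta[keep] = beta_kept
    return beta[: design.n_lags].reshape((design.n_lags,) + pd_volumes.shape[1:]), design


def group_fir(
    subject_betas, lags_sec: np.ndarray, rois: dict | None = None
) -> ResponseMap:
    """Second-level one-sample test of subject betas per (voxel, lag).

    The t statistic across subjects is converted to a z-score through the
    normal quantile of the t CDF (survival-function form, numerically stable
    in both tails). ROI traces are mean z over each ROI's voxels.
    """
    stack = np.stack([np.asarray(b, dtype=float) for b in subject_betas])
    n = stack.shape[0]
    if n < 2:
        raise InputError("group-level FIR needs at least 2 subjects")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), np.sign(mean) * np.inf)
    z = _t_to_z(t, df=n - 1)
    traces = {}
    if rois:
        zf = z.reshape(z.shape[0], -1)
        for name, mask in rois.items():
            flat = np.asarray(mask).reshape(-1).astype(bool)
            traces[name] = zf[:, flat].mean(axis=1)
    return ResponseMap(z=z, lags_sec=np.asarray(lags_sec), roi_traces=traces)


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to standard-normal quantiles, tail-stable."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    # work in the upper tail for positive t, lower tail for negative t
    z[pos] = stats.norm.isf(np.clip(stats.t.sf(t[pos], df), 1e-300, 1.0))
    z[~pos] = stats.norm.ppf(np.clip(stats.t.cdf(t[~pos], df), 1e-300, 1.0))
    return z
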