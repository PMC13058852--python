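"""Factorial strategy grid and the two benchmarking metrics.

The denoising design space is the product of clutter filter (3 methods ×
3 thresholds × 2 mask options), scrubbing metric (4), frequency filter (2)
and confound method (6): 864 combinations. Constant-energy clutter filtering
flattens the global signal, so its pairings with rGS scrubbing are excluded
a priori, leaving 792 strategies; dropping the scrubbing factor entirely
(as the motion-robustness metric does) leaves 216.

Two scores rank strategies:

motion robustness
    the mean squared difference between seed maps computed without scrubbing
    and with GV-based scrubbing — a strategy that already suppresses motion
    artifacts is insensitive to censoring, so smaller is better;
FC similarity
    the Dice overlap between each acquisition's top-10 %-|r| seed-map mask
    and the group-level mask obtained with the standard strategy (static
    SVD₆₀, rGS scrubbing, 0.01–0.1 Hz band-pass, global-signal regression).

Both metrics average within subject first, then across subjects, so subjects
with many acquisitions are not over-weighted; strategies that reject more
than a third of the subjects (the 5-minute retention rule) are flagged
invalid rather than silently dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .clutter import ClutterFilterSpec
from .denoise import CONFOUND_METHODS, FREQ_FILTERS, SCRUB_METRICS, DenoiseStrategy
from .errors import InputError
from .fc import SeedMap, threshold_top_fraction

__all__ = [
    "StrategyGrid",
    "BenchmarkRecord",
    "enumerate_strategies",
    "dice",
    "motion_robustness",
    "fc_similarity",
    "save_benchmark_report",
    "standard_strategy",
    "paradigm1_strategy",
    "paradigm2_strategy",
]


@dataclass
class StrategyGrid:
    """Factor levels of the benchmarked design space."""

    clutter_methods: tuple = ("static", "static_highpass", "constant_energy")
    thresholds: tuple = (20, 40, 60)
    mask_options: tuple = (False, True)
    scrub_options: tuple = SCRUB_METRICS
    freq_options: tuple = FREQ_FILTERS
    confound_options: tuple = CONFOUND_METHODS

    @property
    def full_size(self) -> int:
        return (
            len(self.clutter_methods)
            * len(self.thresholds)
            * len(self.mask_options)
            * len(self.scrub_options)
            * len(self.freq_options)
            * len(self.confound_options)
        )


@dataclass
class BenchmarkRecord:
    """Scores of one strategy on one dataset."""

    strategy: str
    mse_mean: float = np.nan
    mse_sd: float = np.nan
    dice_mean: float = np.nan
    dice_sd: float = np.nan
    retained_subject_fraction: float = 1.0
    tdof_pct: float = 100.0
    valid: bool = True

    def __post_init__(self):
        # strategies must keep at least two thirds of the subjects
        if self.retained_subject_fraction < 2.0 / 3.0:
            self.valid = False


def enumerate_strategies(
    grid: StrategyGrid | None = None, mode: str = "post_exclusion"
) -> list[DenoiseStrategy]:
    """All strategies of the grid, in deterministic lexicographic order.

    ``mode='full'`` includes the (ineffective) constant-energy × rGS pairs;
    ``'post_exclusion'`` removes them; ``'no_scrubbing'`` drops the scrubbing
    factor entirely, as the motion-robustness metric does.
    """
    grid = grid or StrategyGrid()
    if mode not in ("full", "post_exclusion", "no_scrubbing"):
        raise InputError(f"unknown enumeration mode {mode!r}")
    scrub_levels = ("none",) if mode == "no_scrubbing" else grid.scrub_options
    out = []
    for method, T, mask, scrub, freq, conf in itertools.product(
        grid.clutter_methods,
        grid.thresholds,
        grid.mask_options,
        scrub_levels,
        grid.freq_options,
        grid.confound_options,
    ):
        if mode != "full" and method == "constant_energy" and scrub == "rgs":
            continue
        out.append(
            DenoiseStrategy(
                clutter=ClutterFilterSpec(method=method, T=T, use_brain_mask=mask),
                scrub_metric=scrub,
                freq_filter=freq,
                confound_method=conf,
                enforce_exclusions=(mode != "full"),
            )
        )
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B|/(|A|+|B|)``; two empty masks count as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError("masks must share the same grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _map_array(maps, brain_mask: np.ndarray | None) -> np.ndarray:
    """Stack one acquisition's seed maps into (n_seeds, n_voxels_used)."""
    rows = []
    for m in maps:
        r = m.r if isinstance(m, SeedMap) else np.asarray(m, dtype=float)
        r = r.reshape(-1)
        if brain_mask is not None:
            r = r[np.asarray(brain_mask).reshape(-1).astype(bool)]
        rows.append(r)
    return np.stack(rows)


def _subject_average(values: np.ndarray, subject_ids) -> np.ndarray:
    subject_ids = np.asarray(subject_ids)
    return np.array(
        [values[subject_ids == s].mean() for s in np.unique(subject_ids)]
    )


def motion_robustness(
    maps_no_scrub,
    maps_gv_scrub,
    subject_ids,
    brain_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean and across-subject sd of the no-scrub vs GV-scrub map MSE.

    ``maps_no_scrub``/``maps_gv_scrub`` are paired per acquisition: each item
    holds that acquisition's seed maps (all seeds). The MSE is averaged over
    all (voxel, seed) pairs per acquisition, then within subject, then across
    subjects.
    """
    if len(maps_no_scrub) != len(maps_gv_scrub) or len(maps_no_scrub) == 0:
        raise InputError("need the same nonzero number of paired acquisitions")
    per_acq = []
    for a, b in zip(maps_no_scrub, maps_gv_scrub):
        ra, rb = _map_array(a, brain_mask), _map_array(b, brain_mask)
        if ra.shape != rb.shape:
            raise InputError("paired acquisitions have mismatched maps")
        per_acq.append(float(np.mean((ra - rb) ** 2)))
    per_subject = _subject_average(np.asarray(per_acq), subject_ids)
    sd = float(per_subject.std(ddof=1)) if per_subject.size > 1 else 0.0
    return float(per_subject.mean()), sd


def fc_similarity(
    subject_maps,
    subject_ids,
    ground_truth_maps,
    brain_mask: np.ndarray,
    fraction: float = 0.10,
) -> tuple[float, float]:
    """Mean and across-subject sd of the Dice overlap with group-level maps.

    Both each acquisition's maps and the ground-truth (standard-strategy
    group average) maps are thresholded at the top ``fraction`` of brain
    voxels by absolute correlation before the overlap is taken; Dice values
    are averaged over seeds per acquisition, then within subject, then across
    subjects.
    """
    if len(subject_maps) == 0:
        raise InputError("no acquisitions provided")
    gt_masks = [
        threshold_top_fraction(m, brain_mask, fraction, by_absolute=True)
        for m in ground_truth_maps
    ]
    per_acq = []
    for maps in subject_maps:
        if len(maps) != len(gt_masks):
            raise InputError("acquisition is missing seed maps present in ground truth")
        ds = [
            dice(threshold_top_fraction(m, brain_mask, fraction, by_absolute=True), g)
            for m, g in zip(maps, gt_masks)
        ]
        per_acq.append(float(np.mean(ds)))
    per_subject = _subject_average(np.asarray(per_acq), subject_ids)
    sd = float(per_subject.std(ddof=1)) if per_subject.size > 1 else 0.0
    return float(per_subject.mean()), sd


def save_benchmark_report(records: list[BenchmarkRecord], out_dir) -> dict:
    """Write a benchmark run as a flat TSV, a JSON summary, and a scatter plot.

    The scatter shows FC similarity (Dice) against motion robustness (MSE,
    log scale, smaller is better); invalid records (too many rejected
    subjects) are greyed out. Returns the paths written.
    """
    import json
    from pathlib import Path

    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([vars(r) for r in records])
    tsv = out_dir / "benchmark.tsv"
    df.to_csv(tsv, sep="\t", index=False, na_rep="n/a")

    valid = df[df["valid"]]
    summary = {
        "n_strategies": len(df),
        "n_valid": int(df["valid"].sum()),
        "best_mse": (
            valid.loc[valid["mse_mean"].idxmin(), "strategy"] if len(valid) else None
        ),
        "best_dice": (
            valid.loc[valid["dice_mean"].idxmax(), "strategy"] if len(valid) else None
        ),
    }
    js = out_dir / "benchmark_summary.json"
    with open(js, "w") as f:
        json.dump(summary, f, indent=2)

    paths = {"tsv": tsv, "json": js}
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for ok, sub in df.groupby("valid"):
            ax.scatter(
                sub["mse_mean"], sub["dice_mean"],
                c="tab:blue" if ok else "0.7", s=18,
                label="valid" if ok else "rejected >1/3 subjects",
            )
        ax.set_xscale("log")
        ax.set_xlabel("motion robustness (MSE, lower is better)")
        ax.set_ylabel("FC similarity (Dice)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        png = out_dir / "benchmark_scatter.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        paths["scatter"] = png
    except ImportError:  # plotting backend unavailable; tables still written
        pass
    return paths


def standard_strategy(**overrides) -> DenoiseStrategy:
    """The field's common default: static SVD₆₀, rGS scrubbing, band-pass, GSR."""
    kw = dict(
        clutter=ClutterFilterSpec(method="static", T=60, use_brain_mask=False),
        scrub_metric="rgs",
        freq_filter="bandpass",
        confound_method="global_signal",
    )
    kw.update(overrides)
    return DenoiseStrategy(**kw)


def paradigm1_strategy(**overrides) -> DenoiseStrategy:
    """Adaptive paradigm: constant-energy SVD₄₀ + brain mask, rDVARS scrubbing,
    0.01 Hz high-pass, aCompCor."""
    kw = dict(
        clutter=ClutterFilterSpec(method="constant_energy", T=40, use_brain_mask=True),
        scrub_metric="rdvars",
        freq_filter="highpass",
        confound_method="acompcor",
    )
    kw.update(overrides)
    return DenoiseStrategy(**kw)


def paradigm2_strategy(**overrides) -> DenoiseStrategy:
    """Static paradigm: static SVD₆₀ + high-pass + brain mask, rDVARS scrubbing,
    0.01 Hz high-pass, aCompCor."""
    kw = dict(
        clutter=ClutterFilterSpec(method="static_highpass", T=60, use_brain_mask=True),
        scrub_metric="rdvars",
        freq_filter="highpass",
        confound_method="acompcor",
    )
    kw.update(overrides)
    return DenoiseStrategy(**kw)
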