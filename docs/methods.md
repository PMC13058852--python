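# Methods

`fusikit` implements a processing and benchmarking chain for awake-animal
functional ultrasound imaging (fUSI), where head and tissue motion injects
power Doppler surges that can exceed several hundred percent of baseline and
confound functional-connectivity (FC) analysis. This note records the models,
the defaults and their rationale, the numerical choices, and what the
synthetic tests do and do not establish.

## Signal chain

**Axial velocity (Kasai estimator).** The beamformed I/Q signal at a voxel is
`IQ(t) = A(t)·e^{iφ(t)}`. The phase advance between adjacent compound frames
is estimated from the lag-1 autocorrelation, `Δφ = arg(IQ(t+1)·IQ*(t))`, and
converted to axial velocity `v_z = Δφ·c·f_IQ/(4π·f_pulse)`. Taking `arg` of
the complex product (not the difference of phases) is exact and immune to 2π
wrapping; the estimate saturates at the Nyquist velocity
`c·f_IQ/(4·f_pulse)` (≈12.3 mm/s at 15.625 MHz, 500 Hz). The I/Q is low-pass
filtered along time (Butterworth, 30 Hz, order 6, zero-phase) before phase
estimation and each velocity volume is median-filtered spatially (3×3×3
voxels; 3×3 on 2D grids, edge replication at borders). One absolute-velocity
volume per block is the mean of |v_z| over the block's adjacent frame pairs,
placing the velocity series at the power Doppler rate. The low-pass is
applied per block: the block is the processing unit everywhere else in the
chain, and filtering across block boundaries would couple otherwise
independent blocks.

**Clutter filtering.** Each block is a (time × voxels) matrix `X`; a masked
subset `M` (brain voxels, or the whole field of view) supplies the clutter
basis. The temporal eigenvectors of the left Gram matrix `M·Mᴴ = U·Σ·Uᴴ`
order signal energy; tissue clutter, being far more energetic and
spatiotemporally coherent than blood speckle, concentrates at the top of the
spectrum. Selected clutter vectors are regressed out of the *full* matrix:
`X_filtered = X − U_c·U_cᴴ·X`. Selection rules: a fixed count `T` (static); a
fixed count followed by a 20 Hz order-8 zero-phase temporal high-pass
(static + high-pass; 20 Hz corresponds to ≈1 mm/s axial blood velocity via
`v = f_d·c/(2·f_pulse)`); or as many vectors as needed so that the residual
masked energy approaches but does not exceed a per-acquisition threshold `C`
(constant-energy), where `C` is the minimum static-`T` residual observed
across the acquisition's blocks. Eigenvalues are clamped at zero (the Gram
matrix is PSD; small negatives are round-off), ties keep the
eigendecomposition's order, and eigenvector phase is irrelevant because only
the projector `U·Uᴴ` enters. The residual energy target counts the same voxel
set used to build `M`. Power Doppler is the temporal mean of `|X_filtered|²`.
A trailing partial block is dropped.

**Quality control.** Spatial: temporal mean power Doppler (also rendered in
dB for display), temporal coefficient of variation, temporal mean absolute
velocity. Temporal: rGS `= 100·(GS − D1)/D1` with `D1` the first decile of
the global (brain-mean) signal; GV, the brain-mean absolute axial velocity —
a direct motion readout; and rDVARS. DVARS is the RMS backward frame
difference over brain voxels; its null level under per-voxel AR(1) noise is
`μ0 = mean_v 2(1−ρ_v)σ_v²` with `σ_v = IQR/1.349`. We report
`rDVARS = DVARS/√μ0`: dividing by `μ0` itself would be dimensionally
inconsistent (signal units over signal² units) and could not produce the
observed baseline near 1 against a threshold of 2.0, so the square root is
used and stated here prominently. `ρ_v` is the per-voxel sample lag-1
autocorrelation clipped to [0, 0.99] — the estimator is not prescribed
upstream, and clipping prevents pathological negative estimates from
inflating μ0. All quantiles (D1, IQR, GV baseline) use linear interpolation
between order statistics (numpy's default convention). The first rDVARS
sample is undefined and emitted as missing.

**Denoising pipeline.** Fixed order: (1) spatial Gaussian smoothing, 0.3 mm
FWHM; (2) optional scrubbing — frames with rGS > 10 %, rDVARS > 2.0, or GV
above its first decile + 0.01 mm/s are replaced by the mean of unflagged
frames so the sampling stays regular for filtering; (3) zero-phase
Butterworth filtering of order 6, either 0.01 Hz high-pass or 0.01–0.1 Hz
band-pass (odd-reflection edge padding, the scipy default of three times the
filter length); (4) the replaced frames are deleted outright, and an
acquisition retaining less than 300 s is rejected (the rule is evaluated at
this censoring step); (5) OLS confound regression `X ← X − C·β`. Confounds
are estimated from raw power Doppler before any other step — thin anatomical
masks would otherwise be contaminated by partial-volume mixing from
smoothing — and this pre-denoising rule is applied uniformly to all methods,
including the global signal. CompCor variants mean-center voxel series (no
variance normalisation — the upstream definition leaves this open; the
choice is configurable) and take the first 5 principal components, with a
deterministic sign convention (largest-magnitude spatial loading positive).
The random-CompCor mask is drawn once per dataset with the WM+CSF
cardinality; high-/low-variance selections break ties by voxel linear index
and use `floor(fraction·N)` cardinalities. Confound columns undergo the same
scrub-replacement, filtering and censoring as the data before the
regression; an intercept is always included since censored, filtered data
are not exactly zero-mean. Constant-energy filtering pins the global signal
to a near-constant level by construction, which blinds rGS-based scrubbing —
the combination is rejected a priori.

**Seed-based FC.** Seeds are 0.3 mm-radius spheres (voxel-center membership)
at named coordinates; the seed signal is the sphere mean of the denoised
series, the seed map its Pearson correlation with every brain voxel.
Zero-variance voxels get r = 0 with a flag so thresholding and Dice stay
defined. Group maps average in Fisher-z space, `tanh(mean(atanh r))`, with r
clipped to ±(1 − 1e−7). Thresholding keeps the top `floor(0.10·N_brain)`
voxels by |r| (the benchmark's convention) or signed r (display-style),
ties broken by linear index.

**FIR motion response.** Power Doppler at each voxel is regressed on all
lagged copies of GV between −12 and +12 s (2·round(12·fs)+1 columns; 61 at
2.5 Hz) plus intercept and linear drift, by plain OLS — no pre-whitening or
AR noise model, and labelled as such. Shifted samples from outside the
record are zero-padded with the affected rows flagged, keeping designs
aligned across lags. Group-level one-sample t statistics are mapped to
z-scores through the normal quantile of the t CDF, computed tail-wise for
numerical stability.

**Benchmark metrics.** The strategy grid is the product of clutter method
(3) × threshold T ∈ {20, 40, 60} × basis mask (2) × scrubbing metric (4) ×
frequency filter (2) × confound method (6) = 864; removing the
constant-energy × rGS pairs leaves 792, and dropping the scrubbing factor
leaves 216. Motion robustness is the MSE between seed maps computed without
scrubbing and with GV-based scrubbing, on raw correlation values (not
Fisher z — the metric is defined on the maps themselves; a z-space variant
is switchable), averaged over all (voxel, seed) pairs per acquisition, then
within subject, then across subjects, so subjects with many acquisitions are
not over-weighted. FC similarity is the Dice overlap of top-10 %-|r| masks
against group-level maps obtained with the standard strategy (static SVD₆₀,
rGS scrubbing, band-pass, global-signal regression), aggregated the same
way. Strategies rejecting more than a third of subjects are flagged invalid
rather than silently dropped; tDOF is reported as the percentage of frames
surviving censoring.

## Synthetic data: what it emulates, and what it does not

`simulate_iq` composes three components from independent substreams of one
root seed (adding a component never perturbs the others; outputs are
bit-reproducible):

* **Clutter** — a rank-3–5 sum of smooth complex spatial patterns times
  temporal envelopes with ±5 % RMS modulation, scaled so mean clutter energy
  is `clutter_energy` × mean blood energy (default 100; the in-vivo ratio is
  not quantified upstream, so this is a modeling choice). Near-stationarity
  matters: the Kasai noise floor scales inversely with clutter amplitude, so
  a quiet acquisition shows a flat GV baseline.
* **Blood** — per-voxel scatterer phases advancing at Doppler shifts drawn
  uniformly from ±[2, 10] mm/s (above the ≈1 mm/s wall-filter cutoff, so
  high-pass variants retain them), amplitudes modulated by a slow CBV signal
  with three bilateral network pairs sharing latent time courses. Latents are
  smoothed to a ≈0.01–0.2 Hz band, matching the range of hemodynamic
  fluctuations in awake rodents — deliberately extending above the 0.1 Hz
  band-pass edge, which real CBV signals also do.
* **Motion events** — in an affected block the clutter gains an axial phase
  ramp `exp(i·4π·f_pulse·v·t/(c·f_IQ))` (the Kasai estimator then reads the
  injected tissue velocity `v`), its energy is multiplied by the surge
  factor, and a broadband, temporally decorrelated clutter term is added
  (default: half the surged clutter energy). The broadband term models the
  nonrigid decorrelation of tissue echoes during motion, which spreads
  clutter energy across many temporal eigenvectors; it is the mechanism that
  defeats fixed-rank filters while the constant-energy rule adapts, and
  without it a static filter would remove the (still low-rank) ramped
  clutter completely.

`simulate_power_doppler` skips the I/Q level: baseline map × (1 + network
signals + AR(1) noise, default ρ = 0.3, σ = 5 %), with multiplicative surges
(factors 2–5, i.e. +100–400 %) at events. A companion `simulate_velocity`
provides a PD-rate velocity series consistent with the configured events.

Not emulated: realistic speckle statistics, acoustic propagation and skull
aberration, physiological rhythms (cardiac, respiratory), spatial artifact
gradients (a uniform tissue velocity per event is the default; a ventral
gradient is not required by any test), artifact tails extending beyond the
event block, and inter-subject anatomical variability. Consequently, passing
tests establish the *mechanics* of the pipeline (exact selection rules,
energy accounting, threshold behaviour, metric aggregation) and the
*direction* of the benchmark orderings under the stated artifact model —
not in-vivo effect sizes. In particular, scrubbing looks cleaner here than
on real data because injected artifacts are confined to their blocks.

## Benchmark problem sizes

The end-to-end benchmark simulates 8 subjects × 1000 power Doppler frames on
a 16×16 grid with 100-frame blocks at a 250 Hz compound rate — the power
Doppler rate is then the canonical 2.5 Hz and an acquisition spans 400 s,
comfortably above the 5-minute retention rule. Blood velocities are drawn
from ±[2, 5.5] mm/s to respect this configuration's Nyquist velocity
(≈6.2 mm/s). Each subject carries 12 single-block motion events (surge ×10,
v = 0.05 mm/s) spaced at least 3 blocks apart. Acquisitions are streamed
block by block and regenerated deterministically for the second
(constant-energy) pass, so memory stays constant in acquisition length. The
rDVARS flag set is compared against the event blocks *plus their immediate
successors*: a backward-difference metric necessarily marks the recovery
frame after a single-block surge, so "event window" equality is exact while
plain equality cannot be.

## Known limitations

* The FC-similarity ground truth is, by definition, the standard strategy's
  own group average. With a small cohort this hands the standard strategy a
  self-consistency advantage of order 1/n_subjects, so small Dice differences
  between strategies should not be over-interpreted at desk scale; the
  motion-robustness MSE does not share this bias.
* The rDVARS scrub set is expected to exceed the injected event set by the
  immediate post-event frames (backward differences), and its strict 2.0
  threshold can occasionally flag a quiet frame; GV flagging is instantaneous
  and exact under the synthetic model.
* The constant-energy filter can remove most of a motion block's blood
  signal along with the artifact; the resulting frames carry residual energy
  near the threshold `C` but with non-vascular spatial structure. rDVARS
  scrubbing (or no scrubbing plus CompCor) handles these frames; rGS cannot
  see them, which is exactly why the combination is excluded.
* OLS is used throughout (FIR, confound regression); no AR pre-whitening.
* Registration, slice-timing and group statistical testing are out of scope;
  synthetic fixtures carry their own coordinates, and seeds are specified in
  the acquisition's mm frame.
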