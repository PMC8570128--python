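# Methods

This note documents the models, algorithms, defaults and design
decisions behind `crterp`, and what the synthetic-data experiments do
and do not establish.

## Conventions

Internal amplitude unit is µV. Sample 0 of an epoch is stimulus onset;
epoch windows are half-open `[start, end)` in ms, so −50…550 ms at
512 Hz gives `round(0.6 × 512) = 307` samples; all sample indices are
0-based. Electrode positions are stored on the unit sphere. In the
packaged Biosemi-128 layout the site C21 is relabelled **Fz** (its
10-20 equivalent), so the 16-channel fronto-central ROI carries its
conventional names.

## Task sequencing

The CRT generator is a randomized greedy scheduler with retry. Each
picture contributes a consecutive run (New, Rep1–Rep3, optionally
Rep4); its N-back re-appearance must fall 9–15 intervening items after
the run ends. At every step the scheduler chooses among: starting the
next run (only if no pending N-back window would close mid-run),
emitting an eligible N-back (weighted by urgency), or inserting a catch
trial (only after Rep3/Rep4/N-back, and forced when eligible slots run
low). Dead ends — rare — trigger a re-draw with a fresh sub-seed.

Two structural decisions:

* **Blocks are self-contained.** Pictures are split into disjoint
  per-block sets, so every N-back must land inside its own block.
* **The unrepeated pictures close each block.** A block in which every
  picture receives an N-back is infeasible at lag 9–15 (the last
  N-backs cannot accumulate nine intervening items, because catch
  trials may not follow catch trials). The six unrepeated pictures
  (three per block) are therefore the last ones introduced; their runs
  are exactly the filler the block tail needs. Totals are preserved:
  66 N-back = 72 − 6.

Lag is counted as trials strictly between a picture's last consecutive
repetition and its N-back trial. `validate_sequence` re-derives every
invariant from the trial list and reports violations; the generator
rejects its own output if validation fails.

## Synthetic data

`simulate_erp_dataset` builds each subject × condition average ERP as a
schedule of scalp topographies: for every scheduled window, amplitude ×
subject gain × unit-norm template, cross-faded linearly over 10 ms
where two windows share a boundary, plus sensor noise. The pre-stimulus
baseline is signal-free.

* **Templates** are scalp patterns of random dipoles inside the head
  (average-referenced, unit L2 norm), rejection-sampled to pairwise
  |r| < 0.5. Amplitudes are on the GFP scale: amplitude *a* gives
  GFP = a/√128, so the default 4–5 µV amplitudes produce group-level
  GFPs of ≈ 0.35–0.44 µV against 1 µV single-subject noise — effects
  that need the 20-subject design to reach significance, which is the
  regime the statistics are meant for.
* **Subject variability** is a log-normal scalar gain (σ = 0.2) plus
  independent noise; the simplest structure that makes a
  repeated-measures analysis meaningful.
* **Noise** is Gaussian, spatially white by default (an exponential
  spatially-correlated mode is available) and **band-limited to
  1–30 Hz** with the variance renormalized to `noise_sd` per sample.
  The generator emulates *preprocessed* subject-average ERPs, which
  have passed a 1–30 Hz filter; broadband white noise would
  misrepresent their temporal smoothness and makes the 15-consecutive-
  sample cluster criterion unattainable at any realistic amplitude.
  Noise is generated with 1 s of padding and cropped, so filter edge
  transients do not inflate epoch-edge variance.
* The default **study-like ground truth** tiles the whole post-stimulus
  epoch: a shared perceptual map at 0–145 ms, condition-specific maps
  at 145–300 ms (New and N-back share a map that Rep3 does not), a
  shared map at 300–405 ms, a late 405–470 ms map stronger for N-back,
  and the perceptual map again at 470–550 ms. Real ERPs carry
  topographies throughout; an unscheduled dead span would feed pure
  noise maps to the segmentation.
* `tiling_ground_truth` is the clean template-recovery configuration:
  k maps at equal standard amplitude tiling the epoch, identical across
  conditions.
* `source_ground_truth` plants forward projections of single lead-field
  nodes, with conditions differing in **which node is active**, not in
  gain (see Source estimation for why).
* Blink artifacts are frontal-weighted raised-cosine transients
  (300 ms default) at Poisson times and/or centered in chosen trials;
  the ground-truth list of contaminated trials is returned.

What the generator does **not** model: realistic head geometry and
anatomy, muscle/line-noise artifacts, trial-to-trial latency jitter,
1/f background spectra, or condition differences in latency. Passing
tests therefore demonstrate the correctness and calibration of the
analysis chain under its stated assumptions, not performance on any
particular real dataset.

## Preprocessing

Fixed order: epoch → reject → interpolate → filter → re-reference →
smooth → average.

* Rejection is strict: an epoch is dropped iff any |sample| exceeds
  100 µV (a 100.0 µV sample is retained); the first violating
  (trial, channel, sample) is logged.
* Spherical-spline interpolation uses the classical g-function
  g(x) = (1/4π) Σₙ (2n+1)/(n(n+1))ᵐ Pₙ(x) with m = 4, 50 terms, and
  1e-5 Tikhonov regularization, with the usual zero-sum constraint. A
  degree-1 field is reconstructed to < 1 % of its range (tested).
* Filtering is a cascade of second-order Butterworth high-pass (1 Hz)
  and low-pass (30 Hz) sections applied forward–backward
  (`sosfiltfilt`). Zero-phase filtering was chosen because latency
  claims depend on undistorted timing; the price is a squared magnitude
  response (−24 dB/octave effective), so a 50 Hz sinusoid passes at
  10.7 %, not the single-pass 33 %.
* The instantaneous spatial filter is a row-normalized Gaussian
  neighbor average (σ defaults to the median nearest-neighbor
  distance); it is linear, purely spatial, and leaves constant maps
  unchanged.
* Cells with zero accepted epochs are flagged and become NaN; the
  statistics layer refuses incomplete designs by name.

## Mass-univariate statistics

The pointwise one-way repeated-measures ANOVA is computed from sums of
squares, fully vectorized over (channel, time); the Greenhouse–Geisser
epsilon comes from the double-centered condition covariance and is
applied whenever more than two conditions are present. The
implementation is cross-checked against `pingouin.rm_anova` (F, ε, and
corrected p) in the test suite. Under a true null the GG-corrected test
is slightly conservative (observed pointwise rate ≈ 0.0038 at
α = 0.005) because ε̂ < 1 even under sphericity; the exact-df F test is
calibrated to within sampling error. Both rates are reported by the
acceptance script.

**Adjacency.** "Neighboring electrodes" is defined by chord distance ≤
d × the median nearest-neighbor distance. The default is d = 2.0: on
geodesic montages such as the Biosemi-128 the second neighbor ring sits
at ≈ 1.9 × the nearest-neighbor distance, so smaller multipliers leave
a graph (mean degree ≈ 2.4) on which 10-electrode clusters cannot
exist; at 2.0 the mean degree is ≈ 6.7. A convex-hull (Delaunay) rule
is available.

**Cluster criterion.** The filter implements a threshold-extent rule,
not a permutation cluster-mass test: per sample, suprathreshold
(p < α) electrodes are grouped into connected components and components
below the electrode minimum are discarded (the per-slice reading of
"minimum 10 neighboring electrodes" — the stricter of the two
readings); surviving slices at consecutive samples sharing an electrode
are chained, and chains shorter than the duration minimum are
discarded. On small instances the filter is verified identical to an
independent exhaustive enumerator. The criterion is monotone: relaxing
α or either minimum never removes a retained cluster.

## Microstates

Segmentation is the modified K-means of topographic analysis: time
points are assigned to the template of maximal spatial correlation
(signed by default — evoked data have meaningful polarity; a
polarity-invariant mode with |r| assignment and eigenvector updates is
available), templates are re-estimated as normalized sums of assigned
maps (inherently GFP-weighted), and the best of `n_restarts` random
restarts by total GEV wins. Labels are defined wherever GFP > 0; empty
clusters are re-seeded and counted. Segmentation operates on the
post-stimulus group-average maps of all conditions concatenated.

**Meta-criterion.** The number of maps is the floor-median of four
per-k criteria: the predictive-residual cross-validation criterion
(argmin), the Krzanowski–Lai index (argmax, with ratios excluded when
the dispersion drop in the denominator is < 5 % of the largest drop —
otherwise the flattened tail of W(k) produces spurious spikes), and
chord-distance elbows on the total-GEV and dispersion curves (the k
farthest above/below the line joining the curve's endpoints).
Absolute-curvature elbows were rejected during development: on convex
curves they systematically vote for the first bend regardless of where
the true elbow lies.

**Fitting and GEV.** Back-fitting labels each time point of an
individual ERP with the best-correlated template;
GEV_k = Σ_{t∈k} (GFP(t)·r_k(t))² / Σ_t GFP(t)². The implementation is
verified against a scalar per-timepoint summation to 1e-12, and
Σ_k GEV_k equals the segmentation's total GEV exactly. The Map ×
Condition rmANOVA on GEV uses `pingouin.rm_anova` (two-way within-
subject, GG-corrected) with per-map paired post hocs. Fitting windows
are configuration, defaulting to 145–300, 295–405 and 405–470 ms.

## Head model and source estimation

**Forward model.** Three concentric spherical shells (brain/skull/scalp
radii 87/92/100 mm, conductivities 0.33/0.0042/0.33 S/m). The dipole
potential is computed per spherical-harmonic degree by solving the
radial boundary-value problem (continuity of potential and radial
current at the interfaces, insulating scalp) as a 5×5 linear system,
summed to degree 60. With equal conductivities this reduces exactly to
the analytic homogeneous-sphere series, which is the model's anchor
test. Source nodes lie on concentric shells (default 200 nodes, a
miniature stand-in for production-scale grids — the operator algebra is
model-agnostic, so a realistic lead field can be dropped in). Sources
are scalar with radial orientation; a node at the exact center has no
preferred direction and gets zero gain. Gain is µV per 10 nA·m.

**Inverse operator.** The local-autoregressive prior is W = I − C with
C_ij = d_ij⁻ᵉˣᵖ / (1 + Σ_k d_ik⁻ᵉˣᵖ) over neighbours within `radius`
(default 2.2 × median node spacing; distances in mm; exponent 2, the
electromagnetic falloff argument). Then K = M Gᵀ(G M Gᵀ + λI)⁻¹ with
M = (WᵀW)⁻¹. This weight construction has two useful consequences: a
node with no neighbours keeps an identity prior row (minimum-norm
fallback), and as the exponent grows the coupling vanishes so K
converges to the plain minimum-norm operator — asserted numerically to
1e-8. The prior additionally carries 1/‖g_i‖ depth weighting (exponent
1 by default, 0 disables): without it, deep-shell point sources
systematically mislocalize to superficial nodes. λ is chosen by
generalized cross-validation on the data over a log grid, or fixed
relative to the mean eigenvalue of G M Gᵀ.

**Standardization.** Two standardizations are provided and serve the
same goal — removing the leakage/depth bias of the linear estimate:

* `standardize_sources` z-scores each node's time series (over the
  epoch, or over a baseline period). Epoch-wide z-scoring makes each
  trace scale-free: it cancels purely multiplicative condition
  differences, and strong activity in one window depresses the trace
  elsewhere, which can create counter-window artifacts in window
  contrasts. These properties are inherent to the method, not bugs.
* Resolution-based spatial standardization divides node i by
  √(K C Kᵀ)_ii with C = G M Gᵀ + λI. It is linear (preserves gain
  contrasts, creates no time-axis interactions) and makes noiseless
  point sources peak exactly at the true node (all 200 nodes in the
  packaged model). The condition-contrast pipeline uses this one.

Window condition tests average (standardized) node activity in the
windows of interest (defaults 145–205, 210–300, 405–470 ms), run paired
t-tests per node and condition pair, and Bonferroni-correct over nodes
within each (window, pair) — the most conservative reading of the
correction scope that the per-window reporting supports.

The end-to-end dissociation experiment plants condition differences as
*which node is active* (an early node shared by New and N-back versus a
different node for Rep3; a late node for N-back only), mirroring
region-presence contrasts; at 20 subjects and default noise the chain
reports significant nodes near the planted sources in the matching
windows, and nothing in the crossed window/contrast combinations, in
≥ 90 % of seeds.

## Problem sizes and reproducibility

The validation suite uses 20 subjects, 128 channels and 307 samples
throughout — the design size of the paradigm. The recovery and
calibration experiments run 20 seeds (segmentation with 20 restarts per
k) and 200 null simulations; the toy source grid has 200 nodes. All
randomness flows through explicit integer seeds via
`numpy.random.default_rng`; CLI runs are byte-reproducible from
(config, seed), and each stage logs its config digest and seed to the
run manifest.

## Known limitations

* The "instantaneous spatial filter" is implemented as Gaussian
  neighbor smoothing; the original toolbox operator is not public, so
  equivalence cannot be claimed.
* Visual-inspection artifact rejection cannot be automated; only the
  ±100 µV rule is implemented, with an injectable manual-exclusion
  list.
* EDF writing is a minimal 16-bit implementation (one sample per data
  record, a `Status` code channel for events, exact sampling rate in
  the reserved header field); BrainVision is read-only.
* The spherical head model has no anatomy: source reports use node
  indices and coordinates, never region names.
* The behavioral layer is descriptive (accuracy/RT rmANOVA); no
  response-process model is fitted.
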