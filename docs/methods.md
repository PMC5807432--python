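# Methods

This note documents the models, numerical choices and limitations of
`meglock`. Nothing stated here is an empirical claim beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Experimental design modeled

The package targets event-related MEG studies with a 2×2 within-subject
design — gaze ∈ {averted, direct} × exposure duration ∈ {brief, long} — and
analyses performed on source-localized region-of-interest (ROI) time
courses rather than sensors. The canonical ROI set is bilateral V1, FFA,
pSTS, PAC and OFC. Epochs run from −500 ms to +1440 ms around stimulus
onset for the time-frequency branch, and −200 ms to +1300 ms (low-passed at
40 Hz) for the evoked time-course branch. Forward/inverse modeling, head
geometry and sensor-space processing are out of scope: the unit of data is
the per-trial, sign-preserving ROI time course (or vertex array, for label
extraction).

## Synthetic cohorts

`meglock.synth` generates cohorts whose only departures from pure noise are
explicitly injected and therefore known:

* **Bursts** (`BurstSpec`): a tapered cosine at frequency `f` added to one
  ROI inside a time window. On trials matching the burst's condition
  selector the trial phase is drawn from a von Mises distribution
  (concentration κ, mean μ); on all other trials the phase is uniform. The
  oscillation is therefore present — with matched amplitude and power — in
  *every* trial, and conditions differ only in phase consistency. This
  isolates the quantity the PLF measures and prevents power confounds.
  κ = 0 reduces to uniform phases (chance-level locking, `E[PLF²] = 1/N`);
  κ → ∞ approaches identical phases (PLF → 1).
* **Couplings** (`CouplingSpec`): the same carrier added to two ROIs, the
  second with a lag drawn from a von Mises distribution around a fixed
  `phase_lag` on matching trials and uniform otherwise, producing a PLV
  contrast without any PLF contrast.
* **Evoked component**: one smooth post-stimulus transient identical on
  every trial, so evoked phase locking exists in all conditions alike.
* **Noise**: white Gaussian plus 1/f^e colored noise (default e = 1,
  both unit SD), synthesized by spectral shaping; resting MEG background is
  approximately 1/f. Units are arbitrary source units throughout;
  peak-to-peak rejection thresholds are therefore config-relative.

Tapering uses a Tukey (α = 0.5) window over the burst interval to limit
spectral splatter outside the injected band and window.

Seeding is counter-based: subject `i` of a cohort uses the stream
`SeedSequence(master_seed, spawn_key=(i,))`, so cohorts are bit-reproducible
and independent of execution order.

**Default scale.** The desk-scale default is 12 subjects, 64 trials per
condition, 300 Hz sampling — the design shape of a 60-subject study sampled
at 600.615 Hz, reduced so that full simulation studies complete in minutes;
the full scale is one config away. Because no per-condition effect sizes in
phase-locking units are available from the literature the generator
emulates, the default κ values (κ = 8 for strongly locked injections, κ ≈ 4–6
for moderate ones, κ = 0 for null) are calibration choices fixed once, not
empirical estimates.

**What the generator does not emulate**: trial-to-trial amplitude
variability, inter-subject anatomical/functional variability beyond
independent noise, cross-frequency structure, artifacts with realistic MEG
topographies, and autocorrelated inter-trial dependencies. Passing tests
show the estimators and inference behave correctly under the stated
generative model; they do not certify performance under every real-data
pathology.

## Preprocessing

* **Trial rejection** drops any epoch whose peak-to-peak amplitude (max −
  min within the epoch) exceeds its signal's threshold; peak-to-peak is the
  MEG convention behind published fT/cm limits. Rejection is idempotent.
* **Channel screening**: a signal that would on its own reject ≥ 20% of
  epochs is excluded from analysis instead, preventing one bad channel from
  discarding the recording. If every signal is flagged the subject is an
  error, not an empty dataset.
* **Trial balance** across the four conditions is checked with paired
  t-tests on surviving counts across subjects (the test family is a
  package choice; identical counts give p = 1, a constant nonzero
  difference p = 0).
* **Low-pass** is a 4th-order Butterworth applied forward–backward
  (zero-phase), since phase distortion would corrupt latency claims; only
  the 40 Hz cutoff is externally prescribed.
* **Baseline noise normalization** divides each ROI's evoked response by
  its pre-stimulus (−200–0 ms) standard deviation — a diagonal
  approximation of dSPM-style noise normalization (the full version uses
  the sensor noise covariance through the inverse operator, which is out of
  scope here). Zero baseline variance raises an error naming the ROI
  rather than returning infinities.

## Wavelet family

`n_cycles = f/7` exactly, Gaussian envelope with `σ_t = n_cycles/(2πf)`,
which is frequency-independent: `σ_t = 1/(14π) s ≈ 22.7 ms`. This constant
time window is the point of the f/7 rule — uniform temporal resolution —
at the cost of a wide, constant spectral bandwidth (`σ_f = 7 Hz`), so
narrow-band effects visibly leak into neighboring frequencies and the two
analysis bands are not sharply separated. Kernels span ±5σ_t and are
L2-normalized (phase, the quantity of interest, is normalization-free).

Two deliberate choices:

* **No zero-mean correction.** At 8 Hz the kernel holds only 8/7 cycles and
  a textbook Morlet correction term would be non-negligible; the family is
  nevertheless implemented exactly as specified, and the resulting DC
  leakage at low frequencies is accepted and documented.
* **Edge trimming, not padding.** Samples within half a kernel of either
  epoch edge are dropped; phase estimates over zero-padding are biased, and
  the wide −500…+1440 ms epoch exists precisely to absorb the edges. With
  the constant-window family the trim is identical at every frequency.

The grid is integer Hz from 8 to 30 (23 frequencies; the step is a package
choice). Band ownership of the shared printed endpoint: 13 Hz belongs to
α (8–13 Hz); β is 13 < f ≤ 30 Hz.

Cross-validation: the implementation's phases agree with MNE-Python's
Morlet convolution (same cycles, no zero-mean) to ~1e−7 rad in tests.

## Phase-locking estimators

PLF and PLV are the magnitude of the across-trials circular mean of unit
phasors (of phases, resp. phase differences), computed from the ROI-label-
averaged signal's wavelet coefficients — one time course per ROI per trial,
not vertex-pairwise. No small-sample bias correction (e.g. PPC) is applied:
trial counts are balanced by design and verified; the chance level 1/√N is
identical across conditions and cancels in paired contrasts. Time-frequency
points where any trial has a zero-magnitude coefficient have no defined
angle; they are masked (NaN + mask bit), never silently zeroed.

## Cluster-mass permutation inference

* Pointwise one-sample t on per-subject condition differences, df = N−1
  (59 for a 60-subject cohort). Zero-variance points get t = 0 to avoid
  NaN/infinite clusters on degenerate inputs.
* Cluster-forming threshold: two-tailed Student critical t at α = 0.05
  (t ≈ 2.001 at df = 59).
* Clusters: maximal connected components of {t > +thr} and {t < −thr}
  separately; 2D contiguity defaults to 4-neighbor (the conservative
  reading of "contiguous time-frequency points"), 8-neighbor by flag.
* Per-subject 2D maps are smoothed with a discrete 5×5 Gaussian, σ = 2
  pixels, unit-sum kernel, reflect borders, *before* statistics; t-maps are
  never smoothed. "Kernel size 5" is read as a 5×5 window, the only reading
  consistent with a named discrete image filter.
* Null distribution: per permutation, the maximum |cluster mass| over the
  whole map, pooling positive and negative tails into one null (whether the
  original analyses pooled or kept per-sign nulls is not documented; the
  pooled-|mass| rule is this package's choice and matches the two-tailed
  framing). Permutations are sign flips of subject difference maps; for
  paired condition maps this is identical to the constrained label shuffle
  in which each subject's two maps may swap conditions but never share one.
  α- and β-band submaps are tested separately, each against its own null.
* Monte Carlo p = (number of null maxima strictly larger than the observed
  |mass|) / n_permutations — k/n with strict "larger" and no +1 correction,
  so the smallest attainable p is exactly 0; the (k+1)/(n+1) estimator is
  available by flag. Near-equality within a 1e−9 relative tolerance counts
  as a tie (not larger), which makes exhaustive enumeration exactly match
  brute-force exact permutation p-values despite floating-point roundoff.
* `exhaustive=True` enumerates all 2^n sign patterns (n ≤ 20) and then
  equals the exact permutation test.
* Default 5000 permutations, explicit seed, deterministic results;
  per-test seeds inside the pipeline are derived from the base seed by a
  fixed stride so that reruns are byte-identical.

## Functional labels

The label is the connected component containing the activation peak within
{mask vertices with activation ≥ 60% of the peak}; "neighboring vertices"
is read as requiring contiguity with the peak, so disconnected
suprathreshold islands are excluded. Peak ties break to the lowest vertex
index (deterministic). The activation used for growth should be the
across-condition average of the noise-normalized evoked magnitude, keeping
the label independent of trial type. Label time courses are sign-aligned
averages: each vertex is flipped when its pooled inner product with the
peak vertex's series is negative — a simplification of orientation-aware
extraction that prevents dipole-orientation flips across a sulcal wall from
cancelling the mean while preserving signal sign.

## Problem sizes used in validation

The simulation studies in the test suite use the desk-scale profile: type-I
calibration runs 200 null cohorts of 12 subjects × 64 trials/condition with
500 permutations each (the observed any-cluster-significant rate must fall
in the 95% binomial band around 0.05, ≈ 0.02–0.09); effect recovery runs 50
seeded cohorts per statistic (PLF and PLV) with a κ = 8 vs κ = 0 β-band
injection at 350–550 ms and 200 permutations, requiring a significant
cluster with time centroid inside the window in ≥ 90% of runs. These sizes
were chosen so the whole suite runs in minutes on one CPU while preserving
the design shape of the full-scale study.

## Known limitations

* The simplified baseline normalization is not dSPM; absolute normalized
  amplitudes are not comparable to dSPM values, though contrasts and
  cluster inference are unaffected by the per-ROI scale.
* The exact Gaussian-envelope convention and frequency step of the original
  analyses this mirrors are not published; `σ_t = n_cycles/(2πf)` and 1 Hz
  steps would need revisiting for exact script-level replication.
* With few subjects (df ≤ 5) the cluster-forming threshold is large and the
  permutation null is coarse (2^n patterns exist); exhaustive mode is
  recommended below ~10 subjects.
* The strict k/n Monte Carlo rule reports p = 0 when no permutation beats
  the observed cluster; readers who need strictly positive p-values should
  enable the (k+1)/(n+1) flag.
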