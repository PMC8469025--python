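# Methods

This note documents the models, algorithms and numerical choices behind
`gcimstools`, and what its synthetic-data tests do and do not demonstrate
about real GC-IMS data.

## Data model

A sample is an intensity grid over (retention time, seconds) × (drift
time, milliseconds), rows = retention, columns = drift, both axes strictly
increasing. A two-class dataset is an ordered list of such matrices with
labels; the first sample is the alignment reference by default. All
indices are 0-based; windows on sampled grids are half-open `[lo, hi)` for
cropping and inclusive for analysis windows (documented per function).

## Pre-processing pipeline

Six steps, drift axis before retention axis:

1. **Savitzky–Golay smoothing of each drift spectrum** (window n, degree
   d; edges by polynomial fit on shrunken windows via `mode="interp"`).
   Filter strength can be chosen by the apex-loss rule
   (`select_sg_params`): the strongest filter that reduces the reference's
   global maximum by at most 1%. Instrument-scale data typically admit
   n ≈ 19–27 at d = 2; the narrower synthetic peaks select n = 5 (drift)
   and n = 9 (retention), which the shipped synthetic configs fix, the
   same way one would fix them after inspecting a reference measurement.
2. **Psalsa baseline removal per spectrum.** Psalsa is an asymmetric
   Whittaker smoother: minimize Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with weights
   p·exp(−(yᵢ−zᵢ)/k) where the signal exceeds the baseline and 1−p
   elsewhere, iterated until the baseline moves less than `tol` (10⁻⁶ of
   the signal range) or 50 iterations (then a logged warning; the last
   iterate is returned). The pentadiagonal system is solved with a banded
   Cholesky factorization. λ, p, k are scale-dependent: λ controls the
   baseline's stiffness (characteristic length ≈ λ^¼ samples), k is in
   intensity units (peaks a few k above the baseline are effectively
   ignored), p ≪ 1 makes the fit hug the lower envelope. Signals are not
   rescaled before fitting, so configs must carry values appropriate to
   their units.
3. **Multiplicative drift alignment.** The RIP position is measured per
   sample as the mean drift position of the per-spectrum global maximum
   inside a quiet retention window (no analytes eluting), refined to
   sub-sample precision with a three-point parabola; each sample's drift
   axis is then scaled by (reference RIP)/(own RIP) and re-interpolated
   onto the common grid (linear, edge-clamped). Only a multiplicative
   correction is applied — no reduced-mobility calibration.
4. **Savitzky–Golay smoothing of each retention chromatogram.**
5. **Psalsa baseline removal per chromatogram.** With a stiff retention
   λ the RIP's charge-depletion dips survive as negative excursions of
   the corrected RIP chromatogram — the expected signature of this step —
   rather than being swallowed by a compliant baseline. Sign is never
   clipped.
6. **COW retention alignment.** The total ion chromatogram (TIC, row sums)
   of each sample is warped onto the reference TIC by
   correlation-optimized warping: the reference is divided into
   ⌊N/I⌋ segments (default I = 25); each internal sample boundary may
   move by up to the slack t (default 10 samples, segment lengths within
   I ± t); a dynamic program maximizes the summed per-segment Pearson
   correlation of linearly resampled segments and is exact (it matches
   exhaustive enumeration). The resulting piecewise-linear warp is applied
   to every drift column. (I, t) can be optimized per dataset by
   maximizing the mean warped correlation over a grid, ties to the
   smaller segment then smaller slack.

### COW numerical choices

Two refinements, both optional and off in the literal configuration:

* **Feature weighting** (`segment_weights="sd"`, the default): each
  segment's correlation is weighted by the reference segment's standard
  deviation. Pearson correlation is scale-free, so on sparse
  chromatograms a near-flat segment can buy as much objective by chasing
  residual structure as a peaked segment loses through a misplaced shared
  boundary; weighting by feature content makes peak-bearing segments
  steer the warp. `"uniform"` restores the equal-weight objective.
* **Segment overlap** (`segment_overlap`, default 0): the correlation of
  each candidate segment is evaluated on a window extended by a few
  samples on both sides, so a peak lying exactly on a segment boundary —
  where each adjacent segment sees only a shift-insensitive flank —
  still informs that boundary's placement. The synthetic configs use 5.

* **Alignment TIC window** (`tic_drift_window`, default full axis): the
  drift range the alignment TIC is summed over. In charge-conserving IMS
  the RIP loses what the analytes gain, so a full-axis sum can nearly
  cancel; summing over the analyte region restores alignment features.
  The TIC may also be smoothed before COW (`cow_tic_smooth`), which never
  touches the matrix itself.

### Known limitations of TIC-based retention alignment

With the defaults the pipeline recovers planted misalignments (drift
scale ±2%, smooth retention warps up to 8 samples on a 600-point axis) to
within one grid index at every planted apex — on *clean* data. Two
identifiability limits are worth knowing:

* At low TIC signal-to-noise (around 10–15 per TIC point), noise shifts
  boundary placements by up to ~3 samples near segments whose only
  features are peak flanks; this is a property of single-pass COW, not of
  the implementation (the noiseless pipeline recovers all apexes to
  ≤ 0.5 samples).
* Co-eluting peaks form one composite TIC feature; if their relative
  amplitudes differ between samples (e.g. class markers), the correlation
  optimum genuinely moves by a few samples. Retention alignment from a 1D
  projection cannot resolve this.

Neither limit materially affects downstream classification (peak matching
tolerates a few indices of jitter by construction), but apex-exactness
claims are scoped to clean, non-co-eluting data.

## Feature extraction

The RIC is built per sample as max(RIP) − RIP, with RIP(t_r) the maximum
intensity inside a drift window containing the reactant-ion ridge. Method
1 integrates it with the trapezoidal rule; method 2 uses the whole trace;
method 3 unfolds the matrix row-major (cell (i,j) at flat index
i·n_drift + j, so VIP vectors refold exactly).

The peak-table pipeline:

* **Detection** is the union of (a) a maxima-filter detector — cells equal
  to the local maximum of a (2·3+1)×(2·5+1) neighborhood and above a
  noise floor — and (b) strict 8-neighbor local maxima, on an optionally
  3×3 median-filtered copy; intensities are read from the unfiltered
  matrix. Maxima within the min-separation margin of the grid edge are
  discarded (their neighborhood is truncated, and smoothing/baseline edge
  artifacts concentrate there). The default floor is median + 2 robust
  SDs — deliberately permissive, so that a thin tail of noise maxima
  survives for the next step to key on. The RIP drift region is excluded
  from peak picking in the shipped configs so the table contains analyte
  ions only.
* **Intensity filter**: sort detections ascending by intensity; the
  largest first difference marks where peak intensities depart clearly
  from noise (index i*); detections with rank ≥ ⌈0.8·i*⌉ are retained. A
  near-constant list (spread ≤ 5% of its maximum) has no departure point
  and is kept whole.
* **Clustering**: single-linkage connected components, linkable iff
  Euclidean index distance ≤ 12 AND |Δt_r| ≤ 6 AND |Δt_d| ≤ 15; the
  representative is the geometric median restricted to members (the
  medoid), ties to higher intensity then lower (t_r, t_d) — always a real
  detected position. The partition is independent of input order.
* **Matching**: per-sample representatives are pooled and re-clustered
  with the same caps; the dataset-level medoid defines a peak-table
  column (columns sorted by position).
* **Readout**: a sample that contributed a detected peak to a cluster
  gets its maximum intensity within ±(5, 10) indices of the
  representative; otherwise the intensity at the representative cell is
  used and the cell flagged as a fallback. The table never has empty
  cells; the fallback fraction is reported. Detection defaults to
  per-sample mode; detection on the average matrix is available
  (`mode="average"`), at the price of a meaningless fallback flag.

Apex intensity (not volume integration) is used throughout; deconvolution
of co-eluting ions is out of scope.

## Modeling

* **Split**: Kennard–Stone max-min selection, 66% calibration. The
  modeling chain stratifies by class (max-min within each class, merged):
  on strongly separated classes plain max-min can sweep nearly all of the
  more dispersed class into calibration and leave a single-class
  validation set. The plain splitter is available and tested against a
  brute-force oracle.
* **Scaling**: autoscaling with calibration statistics only; constant
  features map to 0 and are flagged.
* **Outlier screen**: a simplified robust PCA — median/MAD
  standardization, SVD, chi-square cutoff (quantile 0.975) on the robust
  score distance, and a chi-square-calibrated cutoff on the squared
  orthogonal distance. Advisory only: flagged samples are reported, never
  removed.
* **PLS-DA**: NIPALS PLS1 on the centered 0/1 class code with per-component
  deflation; class calls threshold the predicted code at 0.5. Requested
  complexity beyond the data rank truncates with a warning. Coefficients
  agree with an independent PLS implementation to 10⁻⁸ in tests.
* **Complexity selection**: bootstrap resamples of the calibration rows
  (default 200; 50 in the reduced-size study configs); one maximal-rank
  model per resample, evaluated out-of-bag at every truncation; the LV
  count with the best mean out-of-bag classification rate wins, ties to
  the simpler model. Degenerate resamples (a missing class, empty
  out-of-bag set) are redrawn and logged.
* **VIP**: VIP_j = sqrt(p · Σ_a SSY_a w²_aj / Σ_a SSY_a) with unit-norm
  weight vectors and SSY_a = q_a²·t_aᵀt_a; mean squared VIP is exactly 1,
  hence the conventional VIP > 1 influence threshold.
* **Uncertainty**: classification rate with an exact Clopper–Pearson 95%
  interval; empirical (Mann–Whitney) AUC with a binormal interval — fit a
  Gaussian per class, AUC = Φ((μ₁−μ₀)/√(σ₀²+σ₁²)), delta-method standard
  error mapped through Φ and clipped to [0, 1].
* **Permutation test**: p = (1 + #{permuted CR ≥ observed}) / (n_perm+1),
  default 1000 permutations. The split is held fixed and labels permuted
  across all samples; by default the model is refitted at the selected
  complexity (`reselect_lv=True` reruns the bootstrap selection inside
  every permutation — statistically stricter and proportionally slower).
* **VIP concordance**: VIPs are binarized at 1 and compared per peak
  across strategies. A peak maps to the full-matrix VIP as the maximum
  within the ±(5, 10) assignment window around its representative cell,
  and to the RIC VIP at its retention index (co-eluting ions inherit the
  value owned by the most intense ion at that retention time).

## Synthetic data

The generator emulates a two-class volatolomics study: a RIP ridge
(Gaussian in drift) whose amplitude at each retention time is depleted by
max(1 − α·S(t_r), floor) with S the summed analyte elution profile
(charge conservation); analyte peaks Gaussian in retention ×
exponentially-modified-Gaussian in drift (tailing); a baseline of
exponential drift decay plus slow linear retention drift; i.i.d. Gaussian
noise; and per-sample misalignment — a multiplicative drift scale and a
smooth, monotone, endpoint-fixed retention warp built from a cumulative
smooth perturbation. The reference sample is rendered unwarped. Marker
peaks multiply their class-1 amplitude by the effect factor; all other
peaks are exchangeable between classes (verified by a t-test calibration
test at effect 1.0).

Peaks are placed on a jittered lattice that guarantees separations beyond
the clustering caps, keeps apexes clear of the RIP region and the grid
edges, and can optionally forbid co-elution (`unique_tr`) for
alignment-exactness studies. Defaults: 600×200 grid (retention 1 s/row,
drift 5–15 ms at 0.05 ms), RIP at 6.4 ms, 30-peak catalog with 15 markers
at effect 2.0, amplitudes 150–400 over noise σ 15 (SNR 10 at the weakest
peak), ±2% drift jitter, 8-sample warps.

**What passing tests show — and don't.** The synthetic data are separable
Gaussian-shaped peaks with stationary noise and exactly multiplicative
drift misalignment. Real GC-IMS data add proton-affinity-dependent
sensitivities, monomer/dimer ions, nonlinear drift distortions,
temperature-dependent tailing and correlated detector noise. Passing the
recovery tests shows the algorithms are implemented correctly and behave
as designed in their intended regime; it does not certify performance on
any particular instrument's data, for which the scale-dependent
parameters (Psalsa λ/p/k, noise floor, SG windows) must be re-chosen.

## Problem sizes

Test and acceptance runs use reduced grids chosen to exercise every code
path at desk scale: 600×200 for pre-processing recovery (12 samples) and
peak fidelity, 300×120 with 26+27 samples for the end-to-end study (25
peaks, 15 markers), bootstrap count 50, maximum 6 latent variables, 99
permutations, 10 replicate seeds. Production-scale matrices (thousands of
retention points) run through the identical code; only memory and time
grow.
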