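# Methods

## The phantom and its motion

The simulated object is a 30 mm diameter sphere fixed inside a cylindrical
water body (default radius 100 mm), with sphere:background intensity ratio
1.5 — the contrast a gadolinium-filled insert shows against water on
T1-weighted imaging, chosen to mimic lesion-to-liver contrast. The sphere
translates rigidly along the superior–inferior axis following a surrogate
trace; all positions are in mm relative to the rest center, and voxel
centers sit at `(i + 0.5)·voxel − extent/2`, so grids are symmetric about
the rest position.

Voxelized rendering uses exact inside/outside classification plus
deterministic 5³ sub-voxel sampling for voxels straddling the sphere
surface. This meets a 1% sphere-volume integral check on anisotropic grids;
a signed-distance ramp was rejected because its curvature bias scales with
voxel size squared and is harder to bound.

## Waveforms

* **Sinusoids**: peak-to-peak displacements of 6 and 10 mm (the clinical
  thresholds for ITV expansion and breath-hold selection) at 2.4, 4 and 12 s
  periods. "Displacement" is peak-to-peak throughout: a 10 mm waveform moves
  the sphere ±5 mm.
* **Patient-like traces** are built cycle-by-cycle from a warped raised
  cosine (faster inhale, flattened end-exhale rest). Regular traces jitter
  period and amplitude by ~3–4%; semiregular traces add a slow sinusoidal
  drift plus AR(1) wander in amplitude with stable periods; irregular traces
  draw heavy period/amplitude jitter (~22–25% CV) plus 2.5–3.2× sharp-inhale
  spikes and one multi-second pause. Regularity classification uses
  coefficient-of-variation thresholds on per-cycle excursion and period
  (regular: both < 0.10; irregular: either > 0.25 or any cycle exceeding
  twice the median excursion; otherwise semiregular; fewer than three cycles
  is unknown). The generator's distributions were chosen so each class
  satisfies its own definition across seeds — that is a consistency
  requirement, not a fit to data.
* **Amplitude programming** uses the mean of per-cycle peak-to-trough
  excursions (peak minus the mean of its bounding troughs), not the global
  maximum: a single 3× cough would otherwise compress the entire trace into
  the lower bins. Scaling a mean-centered trace to a target mean excursion
  is exactly linear, which the property tests exploit.
* Cycle detection is `scipy.signal.find_peaks` with prominence ≥ 20% of the
  global excursion and ≥ 1 s separation — enough to reject cardiac-scale
  ripple while resolving 2.4 s breathing. Traces shorter than an acquisition
  loop end-to-start, as the phantom software replays its input.

## Binning

Amplitude bins (MR) are equal-width over the 1st–99th percentile range of
the trace, outliers clamped to the extreme bins; inhale and exhale samples
mix within a bin (no hysteresis handling, matching the vendor scheme).
Phase bins (CT) assign each sample its elapsed fraction between consecutive
end-inhale peaks, with bin 0 centered on the peak (window ±1/(2n) of phase)
so the extreme bins of both modes are directly comparable; leading/trailing
partial cycles extrapolate with the adjacent period. For a sinusoid these
choices have closed forms used as oracles: the top of 10 amplitude bins
holds 20.48% of samples with centroid 0.9324·A; the extreme phase bin's
mean position is A·sin(π/10)/(π/10) = 0.9836·A.

## MR forward model

The acquisition model is 2.5-D. For each reconstructed slice, the in-plane
object at spoke time t is a set of disks: the static body cylinder plus the
sphere's cross-section at its current position. Their radial k-space is
analytic (`F(k) = r·J1(2πrk)/k`), so each golden-angle spoke (111.246°
increments, continuous across bins) samples the true time-resolved
transform — there is no inverse crime of simulating from a voxelized image.

* **Coronal** orientation puts SI motion in-plane: a phase ramp
  `exp(−2πi·k·a(t)·cosθ)` shifts the sphere along the spoke's cos component.
  Slice (AP) partial volume enters via 3-point Gauss quadrature of the
  cross-section radius over the slab — adequate because the central slices
  vary smoothly.
* **Axial** orientation puts SI motion through-plane: each SI slice sees a
  disk whose radius depends on the slab-to-sphere offset. The slab average
  is precomputed as a dense lookup table over that offset (0.2 mm steps,
  33-point integration), because the pole transition where the sphere enters
  a slab is discontinuous and coarse quadrature biases the through-plane
  edge by over a millimeter.
* Spokes are spread over time at one shot per TR×partitions (default 24
  partitions, TR 4.03 ms). Reported scan time is modeled as
  TR × views × partitions; vendor timing includes factors this model does
  not represent, so no claim is attached to absolute scan times.
* **Reconstruction** is standard Kaiser–Bessel regridding: ramp (|k|)
  density compensation with the angular density π/n applied per bin, width-4
  kernel (Beatty β) on a 1.5× oversampled grid, inverse FFT, analytic
  deapodization, magnitude image. Absolute intensity scale is preserved
  (verified against the analytic static phantom at 5% relative RMS in the
  FOV core); no vendor reconstruction is imitated.
* **Noise** is complex Gaussian per k-space sample, seed-controlled, scaled
  relative to the body's DC signal. The default (1e-4) places the thermal
  floor at the level of the reconstruction's own streak/ringing floor
  (background SNR ≈ 100). A lower SNR target (~30) was considered and
  rejected: it produces ~0.6 mm edge jitter, which would swamp the
  sub-millimeter binning effects this phantom exists to resolve; real
  displacement measurements average over structured edges, not single
  background pixels, so edge-level precision is the meaningful anchor.

## CT model

Each phase volume is a snapshot render at that bin's occupancy-weighted
mean sphere position on an axial grid (1 mm in-plane, 2.5 mm slices)
reconstructed at a half-thickness interval (1.25 mm), the usual overlapping
reconstruction; at the native interval the sphere edge quantizes to
half-voxel positions and the extreme-phase displacement collapses to
exactly the programmed amplitude. Flat traces raise a no-cycle error (phase
is undefined without cycles). Optional sorting-artifact emulation assigns
each slab an independently sampled breathing cycle, imitating the
incomplete/duplicate stitching irregular breathing causes; it is off by
default because no quantitative target constrains it.

## Displacement measurement

The profile line is fixed at the rest-center coordinates for every bin
(matching the same-coordinate-line procedure used on scanner data), sampled
along SI at the voxel pitch with linear interpolation, over ±45 mm — long
enough to hold the sphere plus clinical motion with background on both
sides, short enough that the background tails sample water inside the
insert rather than air outside it. The half level is baseline-corrected
(background + half the excess), where background is the median of the outer
20% of samples: with 1.5:1 contrast a raw max/2 level (0.75 of background)
would never cross the profile. Edges are the outermost half-level crossings
enclosing the global peak, interpolated linearly; multiple disjoint
plateaus raise an ambiguity error rather than guessing. The summary
displacement is the mean of the absolute superior and inferior edge shifts
(configurable to sup/inf/max, since published workflows do not state the
combination rule); it is symmetric under swapping inhale and exhale.

## Statistics

Welch's ANOVA and Games–Howell are direct implementations of the textbook
formulas on top of scipy's F and studentized-range distributions,
cross-checked against pingouin in the tests. η² uses the classical
between/total sum-of-squares decomposition (the convention when reported
beside Welch's F); Cohen's f = √(η²/(1−η²)). Replicate scans are treated as
independent measurements. Note Welch's F equals classical ANOVA exactly
only in the two-group equal-variance, equal-n limiting case (the correction
term vanishes); for k > 2 they agree only asymptotically.

The mixed model is `displacement ~ C(protocol)` with a random intercept per
waveform, fit by REML (statsmodels), Wald 95% CIs (±1.96·SE). The
programmed mean amplitude can enter as a pseudo-condition
(`waveform_mean`), so its fixed effect reports how far the reference
protocol sits from the programmed motion. A singular or failed fit falls
back to a per-waveform paired summary and is flagged. The random-effects
structure (intercept only) is an assumption; slopes were not identifiable
in designs this size.

## Organ displacement arithmetic

All table cells use exact decimal half-up rounding at one decimal, which
binary floats cannot reproduce (4.85 → 4.9, 4.05 → 4.1). Difference tables
are computed from the rounded per-direction means — the only rule exactly
consistent with the published summaries. Several printed summary cells are
inconsistent with their own printed per-patient inputs (they evidently came
from unrounded sources); the rebuild flags these instead of matching them.
Kidney values are averages of left and right kidneys, so kidney per-patient
Euclidean norms are averages of two norms and are carried as data, not
recomputed. The box-ROI translation estimator maximizes zero-normalized
cross-correlation over integer shifts with per-axis quadratic sub-voxel
refinement.

## Problem sizes and desk-scale choices

The default matrix is 128 over the 450 mm FOV (3.5 mm in-plane) with 3000
spokes and the clinical baseline protocol otherwise (3 mm slices, TR
4.03 ms); a full 256 matrix is available via `AcquisitionParams`. Coronal
sets reconstruct 3 slices and axial sets every SI slice covering the sphere
plus motion plus margin. One exception: the coronal-sharper-than-axial edge
comparison is run at matrix 128 over a 192 mm FOV (1.5 mm in-plane, body
radius 80 mm), because the mechanism lives in the ratio of in-plane
resolution (1.5 mm class) to slice thickness (3 mm); at 3.5 mm pixels the
ratio inverts and both orientations blur alike. Sweep and comparison
drivers default to 4 and 2 replicates per condition respectively.

## What the synthetic data does and does not show

The generator emulates the geometry, contrast, binning, undersampling and
orientation physics of the real experiment, so passing tests demonstrate
that the measurement chain (binning → reconstruction → FWHM displacement →
statistics) behaves as the underlying theory predicts. It does not emulate
scanner-specific navigator extraction, manual bin-quality resorting, coil
sensitivity, B0/B1 or fat-saturation effects, deformable or multi-axis
motion, or true CT projection physics — so absolute agreement with any
particular scanner's numbers is out of scope. Two known model-specific
behaviors: measured background SNR is artifact-dominated rather than
thermal-noise-dominated; and for irregular traces with large sharp-inhale
spikes the amplitude extreme bins legitimately track the spike excursions,
which real systems partially suppress through navigator processing and
manual bin curation, so simulated irregular-trace MR displacements can
exceed the programmed mean amplitude by more than scanner studies report.

## Numerical notes

Edge cases are explicit errors, not silent defaults: constant traces cannot
be amplitude-binned (no navigator signal) and have no phase; profiles
without a half-level crossing or with multiple plateaus raise; zero
within-group variance rejects the heteroscedastic ANOVA; flat ROIs reject
registration. A motionless trace in `simulate_mr` interleaves spokes
round-robin across bins (there is no navigator signal to sort by), which is
what makes the static identity tests meaningful. Seeds propagate from a
master seed through a stable CRC32 hash of (condition, replicate), keeping
every scan independent yet byte-reproducible.
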