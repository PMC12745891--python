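# motion4d

A digital respiratory-motion phantom for assessing 4D-MRI and 4D-CT
protocols used in abdominal radiotherapy motion management.

Free breathing moves abdominal tumors (liver, pancreas, kidneys) mostly
along the superior–inferior (SI) axis, and treatment planning needs a
motion-resolved image to size the internal target volume. 4D-CT sorts
projections by respiratory *phase*; radial stack-of-stars 4D-MRI
(golden-angle radial in-plane sampling, Cartesian slice encoding) sorts
spokes by surrogate *amplitude* into motion-averaged bins. Whether an MR
protocol measures the same displacement as CT — and how that depends on the
number of radial views, the number of respiratory bins, slice thickness and
acquisition orientation — is the question this package makes testable
without a scanner.

`motion4d` simulates a 30 mm contrast sphere (1.5× background signal) inside
a water-filled insert, driven along SI by sinusoidal or patient-like
breathing traces, and reconstructs:

* **4D-MR**: an analytic 2.5-D stack-of-stars forward model — per-slice 2-D
  radial k-space of the sphere's disk cross-section at each golden-angle
  spoke's instantaneous position, amplitude-binned via the surrogate trace,
  reconstructed by Kaiser–Bessel regridding with ramp density compensation.
  This reproduces the artifact classes that matter: streaking that grows as
  spokes-per-bin shrink, motion-averaged edges within bins, slice-thickness
  partial volume, and in-plane (coronal) vs through-plane (axial) rendering
  of SI motion.
* **4D-CT**: phase-binned snapshots rendered at each phase bin's
  occupancy-weighted mean sphere position.

Displacement is measured exactly as done on scanner data: a fixed-coordinate
SI line profile through the sphere center on the central coronal plane, with
the superior and inferior sphere edges located at the full width at half
maximum (half level = background + half the excess, edges interpolated
linearly between samples) and compared between the maximum-inhale and
maximum-exhale bins.

The statistics layer mirrors the study designs: Welch's heteroscedastic
ANOVA with Games–Howell post-hoc tests and η²/Cohen's f
(f = √(η²/(1−η²))) for parameter sweeps, and a linear mixed-effects model
(fixed effect per protocol, random intercept per waveform, REML) for
patient-waveform protocol comparisons. A small `organ_motion` module
reproduces the in-vivo arithmetic for box-ROI organ translations: Euclidean
norms, per-direction means with exact decimal half-up rounding, and
CT-minus-MR difference tables.

## Worked example

Measure the displacement a coronal 10-bin protocol reports for a 10 mm
peak-to-peak, 4 s sinusoid, and compare with 10-phase CT:

```python
from motion4d import (AcquisitionParams, PhantomSpec, generate_sinusoid,
                      simulate_mr, simulate_ct, measure_extreme_displacement)

trace = generate_sinusoid(pp_mm=10, period_s=4, duration_s=60)
phantom = PhantomSpec()  # 30 mm sphere, 1.5x contrast

mr = simulate_mr(trace, AcquisitionParams(orientation="coronal", n_bins=10, seed=1), phantom)
ct = simulate_ct(trace, phantom, n_phases=10)
print(f"MR coronal 10-bin: {measure_extreme_displacement(mr).displacement:.2f} mm")
print(f"CT 10-phase:       {measure_extreme_displacement(ct).displacement:.2f} mm")
```

```
MR coronal 10-bin: 9.49 mm
CT 10-phase:       9.98 mm
```

Both protocols undershoot the programmed 10 mm because binning averages
positions within each respiratory state: the top amplitude bin of a
sinusoid spans amplitudes ≥ 0.8·A, whose median position is 0.949·A, so the
edge-based MR measurement converges to ≈ 9.49 mm; the extreme phase bin
averages to 0.984·A, giving CT ≈ 9.84 mm (the measured 9.98 includes the
sub-voxel edge discretization of the CT grid). Fewer bins average more:
with 4 bins the same scan measures ≈ 8.3 mm, which is the mechanism behind
the bin-number accuracy trend.

## Analysis scripts

The study designs run as numbered drivers that write tables and figures
under `results/`:

```bash
python analysis/01_waveform_library.py     # build + classify the waveform library
python analysis/02_parameter_sweep.py      # one-at-a-time sweep + Welch/Games-Howell
python analysis/03_protocol_comparison.py  # axial MR vs coronal MR vs CT + LMM
python analysis/04_organ_tables.py         # in-vivo organ displacement tables
```

The same operations are available as a CLI
(`motion4d simulate|measure|sweep|compare|stats|organ-tables`).

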