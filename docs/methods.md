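# Methods

This note documents the models, conventions and open design choices behind
the package, in the spirit of a methods appendix: what is computed, under
which assumptions, and what a green test does and does not establish.

## Forward model

The photon transport that generates channel sensitivity profiles is the
continuous-wave diffusion approximation in a semi-infinite homogeneous
medium, not Monte-Carlo transport through the layered volume.  The fluence
from a surface optode is modelled by an isotropic point source at depth
`z0 = 1/μs'` with an extrapolated-boundary image source
(`zb = 2D(1+R_eff)/(1−R_eff)`, `R_eff = 0.493` for tissue/air,
`D = 1/3(μa+μs')`, `μ_eff = √(μa/D)`), and the Born/Rytov sensitivity of a
source–detector pair to a local absorption change is the adjoint product
`S(r) = G(s,r) G(r,d) / G(s,d)`, clipped at zero, zeroed outside the head,
and normalized so that the in-head sum equals the channel's mean photon
pathlength `−∂ ln G_sd/∂μa` (≈ DPF × separation).  The layered head enters
through volume-averaged optical coefficients.  This keeps the spatial
structure the downstream stages rely on — banana-shaped channel
sensitivity, monotone depth decay, exact source–detector reciprocity — and
is deterministic and fast; it does *not* reproduce layer-specific effects
such as CSF light piping.  A vectorized photon-random-walk oracle in the
test suite checks rank agreement (Spearman ≥ 0.9) on a homogeneous toy
head.  Tissue optical coefficients (μa, μs' per tissue at 690/830 nm) and
the base-e extinction table (ε in mm⁻¹µM⁻¹, converted from the standard
base-10 cm⁻¹M⁻¹ compilation values) are bundled fixtures from the standard
literature.

The 10/05-style scalp layout is generated deterministically (Vogel spiral on
the phantom's scalp face, 311 named positions with 63 flagged as the
EEG-reserved 10/10 subset); real digitized coordinates are out of scope, but
the counts — and therefore the 248-candidate enumeration — are exact.

## Montage optimization

Binary variables place a source or detector on each candidate; channel
indicator variables are linearized with `y ≤ s_i`, `y ≤ d_j`; exact count
constraints and `s_i + d_i ≤ 1` (no co-location) complete the MILP, solved
by HiGHS branch and bound to zero gap.  Source–detector admissibility is a
separation window, default 15–45 mm (the standard adult range; the
miniature test phantom uses 4–14 mm).  The target and contralateral VOI
enter the objective with equal weight (configurable).  Counts are equality
constraints (the acquisition hardware counts).  A free hemisphere split is
the default; a per-side quota mode places half the sources and detectors on
each side.  On the miniature phantom the free split degenerates into
cross-head channels (every source paired with every detector across the
midline) — geometrically impossible on a real head — so the simulation
harness uses the per-side mode with same-side channels.  Ties between
optimal placements are broken by the solver; the exhaustive oracle breaks
them lexicographically, so equivalence tests compare objective values, not
placements.

## Preprocessing

Order: bad-channel rejection → spline motion correction → band-pass → OD
conversion.  Bad channels are an automated proxy for manual inspection:
flagged when the cardiac-band (0.8–1.5 Hz) Welch-power fraction falls below
a threshold (default 0.02) at either wavelength, or on flatline.  Motion
correction subtracts, inside each marked segment only, a near-interpolating
cubic smoothing spline (penalty bandwidth half a sample) and re-levels the
segment onto a linear join between its flanking samples — marked artifact
content, steps and spikes included, is effectively replaced by a smooth
bridge, and the signal outside segments is untouched.  The band-pass is a
zero-phase 4th-order Butterworth (SOS, forward–backward), 0.005–0.3 Hz.
Because the high-pass removes the DC that the full-run-mean OD baseline
needs, the filter acts on the fluctuation about the run mean and the mean
itself serves as the baseline: `ΔOD = −ln((Ī + filtered)/Ī)`; for
fluctuations a few percent of the mean this is equivalent to filtering the
OD directly.  Natural log is paired with base-e extinction coefficients —
only the pairing matters.

## Events and epochs

Epochs span −20…+40 s around each marker (covering every response bound in
the cohort table) with no per-epoch baseline subtraction (the OD baseline is
the full-run mean; responses may precede markers by ~10 s, which a pre-event
baseline would distort).  Events whose window overlaps a motion artifact
longer than 5 s are discarded.  Control markers are drawn uniformly from
admissible time — at least `guard` (default 60 s) from every IED, clear of
long artifacts, admitting a full window — with a minimum mutual spacing.

## Reconstruction

The inverse is plain minimum norm (`R = I`; no depth weighting) with
`W = Jᵀ(JJᵀ + λC)⁻¹`, `C` diagonal and estimated from pre-event samples of
the averaged epoch.  λ is the noise/source variance ratio from a
two-hyperparameter EM (ReML): with the whitened Jacobian's SVD, both
variance updates are closed-form per iteration; stopping at relative change
< 1e-6 or 50 iterations (the honest `converged` flag matters — EM approaches
a zero-noise boundary sublinearly).  The operator is tuned once on the IED
average and frozen for every single-event reconstruction, so single-event
images are comparable.  The field of view is the minimal set of gray voxels
holding 90 % of the channel-summed sensitivity ("cumulative" reading; a
"count" mode keeping the most sensitive 90 % of voxels is also provided).
Concentrations are in µM under a unit partial-volume convention.

## Cluster statistics

One-sample two-sided t-tests against zero at every voxel–time point
(α = 5 %), on HbO only, at 2 mm and 2 samples s⁻¹ (block means in space,
block-mean decimation in time — safe because the signal is band-limited far
below the decimated Nyquist).  Spatio-temporal connectivity is the 4-D
cross-shaped structuring element: spatial 6-neighbors at the same sample,
or the same voxel at consecutive samples; no diagonals, no minimum extent.
Cluster strength is Σ|t|.  The permutation null pools IED and control
responses, redraws pseudo-IED sets of the original IED count without
replacement, and records the maximum cluster strength per permutation
(the family-wise-error–controlling max statistic; an "all clusters" mode
records every strength).  p-values follow `(1+b)/(1+m)` and can never be
exactly zero.  The stage is modality-agnostic: any event × voxel × time
array (e.g. BOLD epochs) can be fed in, densely or as FOV-voxel lists.

Response summaries operationalize the reported timing fields: onset = first
time inside any significant cluster interval, end = last, peak = time of
max |HbO| in between, duration = end − onset.  `trace_support` provides
5 %-of-peak threshold crossings of a trace, and `fit_response_params`
estimates (onset, time-to-peak, duration, amplitude) by least-squares
fitting the generator's waveform family *passed through the analysis band*
to an observed trace — see "known limitations" for why the raw crossings
are biased.

## Synthetic world

The response waveform is a constrained gamma-family lobe
`g(u) = u^α e^{α(1−u)}` whose shape exponent and time scaling are solved so
that the 5 %-of-peak support is exactly `[onset, onset+duration]` and the
peak sits exactly at `onset + time_to_peak` (time-reversed for peaks in the
second half of the support; an optional opposite-signed second lobe fills
the tail for biphasic shapes; inverted polarity flips both chromophores;
HbR = −HbO/3 by default).  All cohort morphologies — monophasic increase,
increase-then-decrease, decrease-then-increase, late peaks — are
expressible and tested.

Defaults are the stated study world: onset −5 s, time-to-peak 8 s, duration
22 s, lateral gains (1.0, 0.5), 60 events.  The amplitude convention sets
the best channel's single-event ΔOD peak to 0.5 × the noise sd *within the
analysis band* (≈0.003 OD for the default mix), giving realistic ~1.5 mOD
interictal responses; the broadband sd (≈0.015 OD, cardiac-dominated) would
give seizure-scale responses whose energy corrupts the global-mean baseline.
Noise defaults (ΔOD units): cardiac 1.1 Hz amp 0.02, respiration 0.25 Hz
amp 0.003, Mayer 0.1 Hz amp 0.003 (per-channel random phase, 2 % frequency
jitter), 1/f with sd 0.002, white sd 0.002, optional step/spike motion
artifacts with annotations.  One master seed fans out to independent
substreams per component.  Simulated intensities are `I₀ e^{−ΔOD}`; a
noise-free simulation round-trips through OD conversion to 1e-10 (up to the
common full-run-mean constant).

The simulation studies use 4 h runs (realistic recording length) with IED
refractory and control spacing equal to the 60 s epoch length, so epochs do
not overlap and the event-axis t statistics see independent samples; the
control guard of 60 s also exceeds window end + response end, keeping
control windows response-free.  Denser, overlapping event trains are the
documented failure mode of the method (responses covering most of the run
leave no baseline to contrast against), not a target of the green tests.

What the green tests establish: exact cohort arithmetic; provably optimal
montages on the phantom; conservative family-wise error (≤ 5 %) of the full
pipeline on 200 null datasets; ≥ 80 % detection and lateralization with
median onset/duration errors within ±1 s / ±20 % over 50 evoked replicates.
What they do not: performance on real anatomy, real optode coupling, real
physiological covariance between channels, or overlapping-response regimes.

## Known limitations and numerical notes

- **Band-limited timing observability.**  The 0.005 Hz high-pass must
  balance DC, so any slow bump acquires flanking compensation lobes: a 22 s
  response reads ~17 s between its filtered 5 %-of-peak crossings and its
  onset moves from −5 to ~−3.7 s, *noise-free and at any filter order*.
  Threshold-based timing on filtered traces is therefore biased; the
  recovery analyses fit the waveform family through the band instead.
- The EM/ReML fit is degenerate when `JJᵀ ∝ I` (source and noise variances
  are then non-identifiable and only their sum is constrained); real
  Jacobians have strongly varied spectra, where the ratio is identified.
- filtfilt edge transients at the extreme low cutoff are visible within
  ~1/f_lo of the run edges; epochs are windowed away from edges.
- The brute-force montage oracle refuses search spaces above 10⁶
  placements; the MILP has no such limit.
- Cluster p-values are permutation-resolution limited (≥ 1/(n_perm+1)).
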