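# Methods

## Scope and dimensionality

The pipeline is a 2D single-slice simulation of a transmission-source
attenuation-correction (AC) study: every computation that matters for the
comparison — line integrals, Poisson counting, OSEM reconstruction of μ and
activity, ROI statistics — is representative in 2D, at a fraction of the
cost of a volumetric simulation.  The grid is 128 × 128 at 2.1 mm pixels,
the in-plane resolution of the transmission-system μ-map being emulated;
the pseudo-CT is rendered at 2× finer spacing (1.05 mm) and down-sampled,
because a real CT always arrives at higher resolution than the PET grid.

## Phantom

A piglet-like transaxial slice: an elliptical soft-tissue body
(95 × 75 mm semi-axes), three cortical-bone structures modelled as 6 mm
thick shells (outer radius 12 mm) — a vertebral body and two limb bones —
an air-filled trachea, and a coil hardware ring (radius 124 mm, 5 mm,
0.110 cm⁻¹) outside the body.  Tissue LACs are literature-typical 511 keV
values (air 0, soft tissue 0.096 cm⁻¹, cortical bone 0.151 cm⁻¹); they are
fields of `PhantomSpec`, not code constants, because the emulated study
reports none.  Pseudo-CT values: air −1000 HU, soft 40 HU, bone 1000 HU.

The activity distribution is ¹⁸F-NaF-like: low soft-tissue background
(2 kBq/ml), diffuse skeletal uptake (15 kBq/ml in cortical bone), two focal
hot lesions (60 kBq/ml, radius 7 mm) centred on the limb bones, and nothing
in air.  Two geometric choices are deliberate calibrations of the study
conditions rather than anatomy:

* The trachea radius (18 mm) is oversized so that a single slice contains
  the 198 pixels the cold ROI requires.  A side effect is that the
  trachea-fill error of the Dixon surrogate is relatively larger than in a
  3D anatomy.
* The 6 mm cortical shells put roughly 10–15 mm of bone on a typical ray
  through a hot lesion, so the bone-free Dixon map underestimates the hot
  ROIs by ≈4–5% — the error regime reported for bone-avid tracers — rather
  than being masked by the trachea-fill compensation.

Degraded MR surrogates: the Dixon-like map replaces bone and internal air
by soft tissue (optionally eroding the body contour by a pixel-coverage
disk, emulating tissue-as-air at the boundary; off by default); the
UTE-like map is a three-class (air/soft/bone) map with the trachea dilated
by 2 px, a seeded 30% bone↔soft swap in a 2 px band around bone interfaces,
and a 5 mm soft-tissue patch mis-labelled air.  With every degradation
switched off the UTE surrogate reproduces the true three-class map
bit-exactly.

## Projector

Parallel-beam, 180 angles on [0, π), 192 radial bins at 2.1 mm.  Joseph-style
ray tracing (unit steps along the dominant axis, linear interpolation across
it) materialised once per (geometry, grid) as a sparse matrix; forward and
back projection share it, so the adjoint identity holds to round-off and the
OSEM sensitivity terms are consistent by construction.  Line integrals are
in image-unit × cm, so μ sinograms exponentiate directly to attenuation
factors.  Accuracy on an anti-aliased disc: central chord within 0.5%,
rotational asymmetry ≈0.15% RMS.

## Acquisition model

The transmission source is a point orbiting at the ring radius (250 mm); a
frame integrates one orbit sampled at 60 stops.  At each stop, only radial
bins within 8 bins of the source's projected position s = R·cos(φ−θ) are
accepted.  The per-bin duty cycle w (fraction of stops in-window) modulates
the transmission rate *and* the accepted emission contamination — windowing
is what makes post-injection transmission viable.  60 stops (not fewer) are
needed so the union of windows covers every radial bin; with ≤36 stops and
this window width the orbit leaves permanent gaps near the sinogram centre.

Expectations per bin:

* blank: ε·A_blank·T_blank·w·exp(−∫μ_hw) — the coil hardware is mounted
  during the blank, which is exactly why the blank/transmission ratio
  cancels it and the hardware μ-map must be added to all μ-maps afterwards;
* transmission frame: ε·A_tx·T_frame·w·exp(−∫(μ_body+μ_hw)) plus windowed
  contamination κ·(∫activity)·exp(−∫μ_total)·w·T_frame;
* emission-only frame and the 30 min emission scan: the unwindowed
  contamination rate.

All counts are Poisson draws from per-purpose generators spawned from one
master seed; a `noiseless` switch returns expectations.  Source decay
within the session is off by default (12 min ≪ the 109.8 min half-life);
an optional switch decays the source per frame and decay-corrects the
separation.  Dead time, randoms from the source, and scatter as distinct
physics are out of scope — the contamination term stands in for all
emission-derived background, matching the operational treatment of the
emulated protocol.

Scanner calibration constants: ε = 0.5 counts·s⁻¹·MBq⁻¹ per in-window bin
and κ = 0.2 counts·s⁻¹ per (kBq/ml·cm) per bin.  These place the session at
≈2.5 × 10⁸ blank counts, ≈5 × 10⁷ net transmission counts and ≈5 × 10⁷
emission counts — a genuinely high-count transmission regime in which
method bias, not transmission Poisson noise, dominates the comparison;
at two orders of magnitude fewer counts the μ-map becomes
variance-dominated (the test suite checks that its bias falls
monotonically with counts).  Contamination runs at ≈1/6 of the
transmission signal.

## Separation and μ-map reconstruction

The contamination rate per bin is the mean over emission-only frames
divided by their duration; each transmission frame is subtracted by
rate × duty × frame duration, then frames are summed and clamped at zero.
Bins never in-window, with under one scaled blank count, or under one net
transmission count are flagged *missing*, not zeroed, and are excluded from
both the OSEM numerator and sensitivity (no imputation).

p = ln(B_scaled/T_net) (clamped ≥ 0) is reconstructed with multiplicative
OSEM treating p as the data term — the "reconstruct the blank/transmission
ratio" formulation; a transmission-ML (MLTR) formulation is a deliberate
non-goal.  Defaults: 9 angle-interleaved subsets × 6 iterations, 4 mm FWHM
Gaussian post-smoothing, non-negativity on.  (9 subsets, not 8: the subset
count must divide the 180 angles.)  A noiseless water-disc study recovers
the configured water LAC to <0.1% in the disc interior; the high-count
stochastic default stays within 5%.

## μ-map variants

* `TRUE` — ground truth.
* `TX` — the transmission reconstruction above (body only, hardware
  cancelled by the blank).
* `REF` — reference scanner stand-in: the ground-truth map blurred to
  5.15 mm FWHM (mass-conserving Gaussian).  Blurring the truth (default)
  isolates AC-method error from transmission noise; a `transmission` mode
  blurs the TX reconstruction instead for a fidelity-style reference.
* `CT` — bilinear HU→LAC: μ = μ_w·(HU+1000)/1000 up to 50 HU, then a bone
  slope chosen so 1000 HU maps to 1.06 × the cortical-bone LAC.  The +6%
  bone bias reproduces the known dense-bone overestimation of bilinear
  scaling; it is a config value.  The finer CT grid is block-averaged
  (mass-conserving) onto the PET grid.
* `DIXON`, `UTE` — the phantom surrogates.

The hardware component is added voxelwise to every map exactly once
(a provenance flag makes double-merging an error).

## Activity reconstruction and evaluation

AW-OSEM with attenuation factors inside the system model (preserving
Poisson statistics), 9 subsets × 4 iterations by default (clinical-like,
deliberately not converged); a convergence mode (1 subset, ≥50 iterations)
serves the oracle tests.  The calibration constant and duration are part of
the model, so the image is in kBq/ml directly.  With one subset the Poisson
log-likelihood is non-decreasing and total modelled counts match measured
counts after every iteration (both asserted numerically).

ROIs are placed algorithmically because manual placement is not
reproducible: hot ROIs grow to exactly 27 connected pixels around each of
the two strongest local maxima of the *reference* reconstruction (greedy
highest-neighbour growth, ties broken in row/column order); the cold ROI is
the 198 trachea pixels nearest the trachea centroid.  ROI statistics are
the arithmetic mean and the population SD; relative differences to the
reference are rounded half-away-from-zero to integer percent (the rounding
rule under which the published comparison table's printed percentages are
exactly reproduced from its printed means).

## Numerical choices and degenerate inputs

Missing sinogram bins carry NaN plus a validity mask; OSEM updates guard
zero forward projections (ε = 10⁻¹²) and leave pixels with zero sensitivity
untouched; counts sinograms reject negative values; uniform activity images
are rejected at ROI placement (no two distinct maxima); up-sampling and
non-integer resampling factors are rejected; overlapping phantom structures
raise a geometry error rather than rendering ambiguous labels.

## Known limitations

* 2D single slice; volumetric partial-volume and axial-scatter effects are
  absent, and the cold-ROI percentages (tiny reference denominator,
  ≈0.5 kBq/ml) are only qualitatively comparable to an in-vivo study.
* The parallel-beam abstraction ignores cylindrical-PET line-of-response
  geometry, detector blur and depth of interaction.
* Scatter and randoms are not modelled as physics; consequently the
  "reduce scatter and randoms" role of windowing appears only as
  contamination suppression.
* The synthetic phantom is geometric, not anatomical: passing tests show
  the pipeline reproduces the *error structure* of the AC methods (signs
  and magnitudes of hot/cold ROI biases) under controlled conditions, not
  that it predicts in-vivo values for a specific animal.
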