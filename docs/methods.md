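# Methods

## Scope and model

`onhpulse` quantifies two physiological signals from fundus reflectance
image sequences at 570 nm:

1. **ONH vascular pulsation.** Cardiac blood-volume changes modulate the
   light absorbed by hemoglobin, so the mean reflectance of vascular
   pixels oscillates at the pulse frequency. The per-region waveform is
   modeled as a single sinusoid, `y(t) = A sin(Bt + C) + D`, after linear
   detrending and five-point smoothing. PA = A is the pulsation amplitude
   in arbitrary intensity units; PF = B·60/2π converts the angular
   frequency (rad/s) to beats per minute. A single harmonic is an
   intentional simplification: the waveform's dicrotic structure is out of
   scope, and the model's R² doubles as the quality-control statistic.
2. **Flicker-induced vasodilation.** Diffuse 10 Hz flicker raises retinal
   neural activity and dilates vessels (functional hyperemia). Diameters
   are measured as the full width at half maximum (FWHM) of intensity
   profiles perpendicular to vessel centerlines; dilation is the ratio of
   the during-flicker to pre-flicker diameter per vessel class (D_A_R,
   D_V_R).

Both analyses share the vessel segmentation (multiscale Frangi
vesselness) and the two-region decomposition of the ONH field: RV, the
segmented dominant vasculature, and ONH_T, the interior of an
observer-drawn ONH polygon minus a dilated copy of the vessel mask.

## Pipeline stages and the choices behind them

**Registration.** Translation-only, by normalized 2-D cross-correlation.
The reference (first frame by default — reproducible and almost always
usable) is inset by the maximum search shift and matched inside each
frame, so every candidate offset correlates against genuine frame
content; matching a full padded frame instead was found to bias peaks by
one pixel at large shifts, because reference structure then correlates
against constant pad fill. Ties are broken toward the smallest shift
magnitude, then row-major order. Vacated border pixels are filled with
the frame median, which biases ROI means less than zero-fill. Sub-pixel
refinement by parabolic peak interpolation exists behind a flag but
frames are always moved by integer amounts, keeping registration exactly
invertible. Constant (zero-variance) frames cannot be correlated; they
pass through with zero shift and a warning record.

**Segmentation.** Vesselness per scale σ uses the σ²-normalized Hessian's
eigenvalues |λ₁| ≤ |λ₂|: `exp(−R_B²/2β²)·(1 − exp(−S²/2c²))` with
R_B = λ₁/λ₂ and S = √(λ₁²+λ₂²), zeroed where sign(λ₂) contradicts the
dark-on-bright polarity (blood absorbs at 570 nm), maximum over scales.
Defaults: scales {2, 3, 4, 6, 8} px spanning the radii of the dominant
vessels, β = 0.5, c = 15 on a 0–255 intensity scale, threshold 0.10,
minimum component area 60 px. A border band of 2σ per scale is zeroed:
Gaussian-derivative support crossing the image edge otherwise produces a
spurious ring of response that survives thresholding. All parameters are
configuration-exposed, as the segmentation of real data is operator-tuned.

**ROIs.** RV is the full segmented dominant vasculature in the field (a
clip-to-polygon option exists); ONH_T is the polygon interior minus the
vessel mask dilated by 2 px, which keeps partial-volume vessel-edge
pixels out of the tissue signal. Polygon rasterization includes boundary
pixels (a pixel belongs if its center lies inside or on the boundary);
self-intersecting polygons are rejected. `rv ∩ onht = ∅` and
`onht ⊆ polygon` are asserted on every construction.

**Waveform processing.** Detrending fits an ordinary least-squares line
and removes the slope while retaining the mean, so the offset D stays
interpretable as mean reflectance; PA and PF are invariant to this choice
(adding any affine function of time leaves them unchanged). The smoothing
window is centered and unweighted; a centered window is what makes the
removal of exactly (window−1)/2 points at each end natural, and a 72-point
acquisition (3 s at 24 Hz) yields 68 fitted points. Note the OLS slope of
a finite stretch of sinusoid is not zero (≈ −12·A·cosφ/(ωT²) in continuous
time), so detrending perturbs a pure sinusoid slightly; at the tolerances
of the recovery targets this is immaterial, and the attenuation closed
form is validated on the smooth→fit chain where it holds exactly.

**Sinusoid fitting.** Nonlinear least squares (Levenberg–Marquardt) with
a deterministic initialization: D₀ = mean, A₀ = √2·sd, B₀ from the
dominant nonzero discrete-Fourier frequency, C₀ the best of
{0, π/2, π, 3π/2} by initial residual. Because the problem is multimodal
in B, the fit restarts over a B₀ grid spanning ±50% in five steps and
keeps the lowest-cost solution (stopping early when the first start
already explains 99.9% of variance). Results are canonicalized to A ≥ 0,
B > 0, C ∈ [0, 2π). R² is computed against the smoothed data — the data
actually fitted — and is not clipped; zero-variance input yields a
degenerate fit with R² = NaN, which QC always excludes. A 3-point median
prefilter for motion spikes exists behind a flag (off by default; the
running mean already suppresses isolated spikes).

**Calipers.** Centerlines are the medial axis (EDT ridge) of the vessel
mask, split at branch points; each branch-free piece is reduced to its
longest path (double breadth-first sweep), which also prunes short spurs;
paths under 10 px are dropped, and a mask nowhere wider than 2 px yields
an empty result with a warning. Stations sit every 5 px of arc length;
the local tangent is the principal axis of a 7-point neighborhood; the
profile samples ±half_length px at 0.5-px steps by bilinear
interpolation (half_length defaults to twice the local medial-axis radius
plus 5 px). The FWHM baseline comes from the outer 20% of samples on each
side — robust to shading, unlike a global background; dips below 3× the
tail standard deviation, clipped dips, and profiles leaving the image are
rejected per station. For flicker pairs, centerlines and stations are
extracted once from the pre-flicker image and reused on the during image,
so the ratio isolates the caliber change rather than centerline
variability. Diameters average within a vessel first, then across vessels
of a class, weighting vessels equally regardless of station count.

**Statistics.** Pearson correlation, paired t, and one-way ANOVA are the
standard scipy implementations; the test suite checks them against
explicit sum-of-squares formulas. Degenerate paired comparisons follow
fixed conventions (identical vectors: t = 0, p = 1; constant nonzero
difference: infinite t with a warning). Subject-level QC excludes a
subject when either region's R² falls below the cutoff (default fixed
0.23; a lower-percentile mode with linear interpolation is provided). No
multiple-testing correction is applied; significance is read at p ≤ 0.05.
The percent-difference variability uses the pair mean as denominator (a
first-measurement denominator is available by flag). OPP is computed per
subject and then averaged for group tables.

## The phantom: what it emulates and what it does not

The generator renders dark vessels with Gaussian cross-sections whose
FWHM equals the nominal width — a smooth profile chosen to exercise the
sub-pixel FWHM logic — on a flat background (default canvas 256×256,
0–255-range float intensities, background 100 au). Overlapping vessels
combine darkest-wins. Dynamics: an additive sinusoid on vessel pixels
(and, optionally with independent amplitude and phase, on ONH-disc tissue
pixels — whether tissue pulses in phase with vessels is deliberately not
assumed), whole-frame linear drift, integer translation jitter with the
first frame unjittered (it defines the coordinate origin, so sidecar
masks align with the registered geometry) and vacated pixels filled at
the frame's current background, then i.i.d. Gaussian sensor noise. Two
truth masks are recorded: the FWHM band (distance ≤ width/2 — what a
correct segmentation should recover) and the modulation mask (distance ≤
width — every pixel carrying the sinusoid). The wider modulation band
ensures a correct segmentation sits inside fully modulated pixels, so the
recovered amplitude estimates A·(smoothing gain) rather than a
mask-dependent diluted value.

Cohort simulation draws per-subject parameters from the population the
analysis targets: heart rate uniform on 55–90 BPM with the generative
pulse frequency set equal to it (making PF~HR recovery testable by
construction), pulsation amplitude ~N(1.83, 1.15) au clipped to
[0.5, 5], age ~N(60, 12), MAP ~N(99.9, 13.5) mmHg, IOP ~N(14.5, 2.8)
mmHg, HbA1c 5.5±0.7% for non-diabetic and ≈7.3–7.4% for diabetic groups,
drift 0.3 au/s, jitter sd 1 px, noise 5% of the subject's modulation
amplitude, dilation factors ~N(1.03, 0.04)/N(1.04, 0.03) for
arteries/veins. Tissue modulation defaults to 0.6× the vessel amplitude
with independent phase.

The phantom does **not** emulate choroidal background texture, optical
blur, non-rigid or torsional eye movement, blink dropout, vessel-wall
reflexes, or waveform shape beyond a single harmonic. Passing the
recovery suites therefore demonstrates the correctness of the numerical
chain (registration, masking, averaging, detrending, smoothing, fitting,
calipers, statistics) under realistic noise, drift and jitter — not
robustness to every artifact of clinical acquisition.

## Numerical conventions and degenerate inputs

- Time is in seconds from the first frame, so B is rad/s and
  PF = B·60/2π.
- Phantom distance maps are exact point-to-segment distances within three
  widths of each vessel (a nearest-vertex KD-tree bound elsewhere), so
  rendered cross-sections match the analytic Gaussian to machine
  precision.
- Registration search range defaults to one-eighth of the frame size and
  must leave a usable template (`2·max_shift < min(shape) − 8`).
- Correlation ties are resolved deterministically (smallest magnitude,
  then row-major); report generation is deterministic for a fixed cohort
  table; all phantom randomness flows from named integer seeds.
- Empty masks, constant frames, self-intersecting polygons, clipped or
  flat profiles, zero-variance statistics inputs, and MAP ≤ IOP raise
  explicit errors or per-item rejections rather than propagating NaNs
  (degenerate fits are the exception: they carry R² = NaN and an
  `excluded` flag, matching how QC consumes them).

## Problem sizes used in validation

The recovery suites run 50 phantom videos of 72 frames at 256×256 for
pulse-parameter recovery; four flicker pairs across dilation factors
1.00–1.06; ten-frame stacks with shifts up to ±25 px for registration;
and 100 simulated eight-subject cohorts (waveform level) for the type-I
behavior of the RV vs ONH_T comparison. These sizes give binomial
headroom at the stated pass rates while keeping a desk-scale run of the
whole validation in a few minutes.

## Known limitations

- Translation-only registration: rotation and non-rigid motion are out of
  scope.
- The single-sinusoid model underfits waveforms with strong dicrotic
  structure; R²-based QC will exclude such subjects rather than model
  them.
- FWHM diameters are reported in pixels; absolute calibration to µm is a
  pass-through of the pixel pitch, never computed.
- Artery/vein labels are observer inputs (or phantom truth); no automatic
  classification is attempted.
- The Frangi threshold and min-area defaults were chosen on the phantom;
  real acquisitions will need operator tuning, as the protocol itself
  anticipates.
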