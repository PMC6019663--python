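# Methods

## Coordinates and calibration

All geometry is in physical units: origin at the top-left corner of the
ultrasound window, `x` lateral (cm), `y` depth (cm) increasing caudally.
Pixel data are converted once at ingest — from the DICOM ultrasound-region
`PhysicalDeltaX/Y` tags (cm) or `PixelSpacing` (mm, converted), or from a
YAML sidecar for TIFF/PNG stacks — and never guessed, since every reported
quantity is in cm/mm/cm².  Contour annotations are stored in cm so they
survive image resampling.

## The Area method

A contour is an ordered polyline `y(x)`, strictly monotone in `x` (the
diaphragm interface is a function graph in this view; self-crossing traces
are rejected).  With the transducer fixed during the breath, the window
borders are legitimate area limits: the supradiaphragmatic region is closed
by the two vertical borders above the contour end points and the top
border, counter-clockwise, and its area is the absolute shoelace area of
that polygon (computed with shapely).  The contour must reach both lateral
borders to within half a lateral pixel; otherwise it is an "open contour"
error and extrapolation must be applied first.

ΔA = area at maximal contraction − area at minimal contraction.  Frame
selection uses the *same functional* as the measurement: the frame of
maximal (minimal) contraction is the one with the largest (smallest)
border-closed area, ties broken to the earliest frame, so selection can
never disagree with measurement.  A clip with no area variation returns
frames (0, 0) with a warning rather than an error.

Consequences used as tests: ΔA is invariant to vertical translation of the
window and to frame reordering; for a piston (flat interface) ΔA equals
window width × displacement to machine precision; ΔA/width, M-mode
excursion and apex displacement coincide in the piston limit.

### Extrapolation of partially visible contours

Where the interface disappears near a lateral border (air-filled lung,
rib shadow), the trace is continued from the curve of the visible part: a
quadratic is fit to the outermost 25% of visible points on the gap side
(at least 4), linearly weighted toward the gap, evaluated out to the
border and clamped to the window depth.  Extended points are flagged.  For
a straight visible segment the extension continues the slope exactly; for
a circular arc truncated at 70% of the window the extension stays within
2% of the true radius (tested).  Fewer than 4 visible points are rejected
as insufficient curvature information.

## M-mode and B-mode measurements

**M-mode.**  Intensity is resampled along a fixed scan line at the
depth-pixel pitch and averaged over a narrow beam (±3 px perpendicular to
the line) — real M-mode beams have finite width, and the averaging
suppresses local speckle dips over the thin interface.  Per frame the
interface is the maximum of the Gaussian-smoothed profile (σ = 2 px) with
3-point parabolic sub-pixel refinement; excursion is max − min interface
position over the clip.

**Visibility criterion.**  A frame counts as "diaphragm not visualized"
when its peak is not *dominant*: the peak must exceed the brightest sample
outside its own ±16-px neighborhood by a factor 1.2.  A spread-based
threshold (median + k·MAD) is miscalibrated here because the background is
two-level (dark thorax above, bright organ below): when the interface sits
near mid-depth the MAD equals the inter-tissue spread, not the noise, and
a clearly visible interface gets rejected.  Dominance is invariant to that
split.  If ≥ 20% of frames fail, the clip is rejected — the behavior of
the left mid-clavicular view, where the stomach blocks the window.

**B-mode.**  The apex per frame is the most cranial contour point;
displacement is the range of its depth.  An apex within one pixel of the
top border triggers an "apex clipped" warning, since an obscured top is
the known failure mode of this measurement.

## Semi-automatic detection

The detector emulates manual tracing: per image column, the interface is
the sub-pixel peak of the depth-smoothed column (σ = 2 px); columns whose
peak fails the dominance criterion are flagged.  Flagged columns are
bridged before a lateral median filter (size 5) so garbage peaks cannot
contaminate neighbors; columns farther than 5 px from a wide median over
the visible depth sequence are then demoted (iterated up to 3 times),
because a speckle blob can fake a "visible" column inside an occluded
patch.  Interior gaps are filled with a local quadratic through up to 8
flanking visible points; lateral-end gaps use the extrapolation above.
A frame with more than half its columns flagged is rejected.

## The dome phantom

The phantom emulates a lateral mid-axillary view.  The hemidiaphragm is a
circular arc (sagitta parameterization: chord `c`, apex height `h`, so the
radius is `(c²/4 + h²)/2h`) over flat flanks at the insertion depth, inside
a fixed window (defaults: 12 × 16 cm window, 10 cm chord, 2 cm apex, 6 cm
insertion depth).  One breath translates the dome caudally by the
amplitude; an optional flattening factor shrinks the apex height linearly
with phase (emphysema-like flattening at high volume; note it *increases*
ΔA and apex travel relative to rigid translation, because the apex region
deepens).  The breath phase is a raised cosine over the clip (default 13
frames, so phase 1 falls exactly on a frame).

Rendering: dark thorax (0.08) above the interface, organ level (0.45)
below, a Gaussian-profile bright band (peak 1.0, σ = 2 px) along it;
multiplicative speckle with ~2-px correlation, with the band's modulation
reduced to 40% (a near-specular reflector has a higher coherent component
than diffuse tissue — without this, ordinary speckle occasionally sinks
the thin band into the background, which no real scanner shows for a well
insonated diaphragm).  An optional air-filled-lung artifact attenuates the
band around the apex for a whole clip, exercising the flag-and-fill path.
Identical seeds give bit-identical clips.

Ground truth is analytic or numerically exact: ΔA by trapezoid integration
of the depth difference at 0.005 cm steps (equal to width × amplitude for
any rigid translation — tested both ways), apex excursion in closed form,
scan-line excursion from the depth functions, and an exhaled-volume analog
as the solid of revolution of the dome about the apex axis
(∫ (z₁ − z₀) 2πρ dρ; a piston of radius r sweeping a gives π r² a).

### The accessory-muscle term

All diaphragm measurements lose precision at very high lung volumes, when
secondary respiratory muscles contribute exhaled volume the diaphragm does
not.  The volume model is `V = swept_volume × effort + gain × max(0,
effort − 0.8)`: deterministic, with the accessory term strictly zero up to
the 80% effort threshold.  In the *cohort simulator* the accessory
recruitment additionally varies breath to breath (the gain is scaled by a
uniform random fraction per breath): recruitment of secondary muscles is
not reproducible across maneuvers, and without this variability exhaled
volume would remain strictly monotone in effort and the high-volume
correlation could never degrade — the very phenomenon the subgroup
analysis is designed to expose.

## Cohort simulation

Per subject, dome geometry is drawn once (apex height U(1.5, 2.5) cm,
insertion depth U(5.5, 6.5) cm).  Per breath, effort is uniform such that
amplitudes span 0.5–9 cm — covering shallow breathing through maximal
inspiration.  Measurement noise is a smooth jitter field added to each
frame's contour depth (Gaussian-smoothed white noise, 1 cm correlation
length, sd 0.15 cm by default), emulating tracing error; the three
measurement operations then run on the jittered traces exactly as they
would on detected ones.  The simulated M-mode reading is the jittered
interface depth at the scan line (ideal peak detection on a render of that
trace); the pixel path of `m_mode_excursion` is validated separately on
rendered clips.  Two independent raters (independent jitter fields)
re-trace the first 40 breaths for the ICC study.

What the phantom does *not* emulate: acoustic physics (no wave
propagation, attenuation or PSF), anatomy beyond a single interface
(ribs, pleural line, vessels), out-of-plane motion, probe pressure, and
operator-dependent view quality.  Passing round-trip tests therefore shows
the measurement chain is correct on well-formed cine data, not that
detection is robust to clinical image quality.

## Statistics

* **Spearman r_s** with midranks; CI by Fisher z with variance 1/(n−3)
  (the construction is stated because published CIs for rank correlations
  are often not reproducible otherwise); p exact by full permutation
  enumeration for n ≤ 10, t-approximation above.
* **Mean-split subgroups**: records with exhaled volume ≤ the mean form
  the low stratum; each stratum needs ≥ 4 records.
* **ICC(1,1)**: one-way random effects, single rater —
  `(MSB − MSW)/(MSB + (k−1)·MSW)` with the F test for p.  Identical rater
  columns give exactly 1 (MSW = 0 is handled before the ratio).  The
  estimator is cross-checked against pingouin in the test suite.
* **Exact proportions**: Clopper–Pearson via Beta quantiles
  (statsmodels `proportion_confint(method="beta")`), with the k = 0 and
  k = n bounds pinned to 0 and 1.

Report rounding follows clinical presentation: areas to 0.1 cm²,
excursions to 0.1 cm, correlations/ICC/proportion bounds to 2 decimals.

## Problem sizes and numerical choices

Default render spacing is 0.05 cm/px (240 × 320 px windows, 13 frames) —
fine enough that one pixel is 0.5 mm, the precision clinical calipers
report.  The acceptance checks use 100 random contours against a 0.01 cm
rasterization oracle, 50 noise-free renders across the amplitude range,
20 × 4-breath cohorts with 200 replicates for the stratum comparison, and
2000 targets for ICC calibration; the ICC calibration constructs its
variance components with exact sample moments (orthogonalized noise) so
the check isolates the estimator from Monte Carlo draw error.  All
randomness flows through `numpy.random.default_rng` seeds; identical seeds
reproduce every table byte for byte.

## Known limitations

* The detector assumes one dominant bright interface per column; it will
  follow the pleural line or a rib shadow if those dominate.
* Contours are function graphs in `x`; a folded or vertical interface
  segment cannot be represented.
* The volume analog is a hemidome sweep, not a thorax model; only its
  ordering (and hence rank correlations), not its liter scale, is
  meaningful.
* Extrapolation is quadratic and local: it is accurate for gently curved
  gaps (tested against circular arcs) but has no knowledge of anatomy
  beyond the visible curve.
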