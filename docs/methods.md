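# Methods

This note records the model behind `arcqa`, the parameters that matter,
what the simulator does and does not emulate, and the design choices made
where the design was genuinely open.

## Coordinate frame and geometry surrogate

All positions live in a right-handed patient frame: LR = +x (patient
left), AP = +y (anterior), SI = +z (superior), origin at the array's
geometric centre, lengths in mm. The vendor's exact diode layout is
proprietary; the package uses a single-start helix of 1386 diodes on a
105 mm-radius, 210 mm-long cylinder with the helix angle chosen so the
nearest-neighbour spacing is 10 mm. This preserves every property the
method depends on — diode count, cylindrical shell, ~1 cm resolution —
without claiming hardware fidelity. Each diode carries seven placement
hypotheses (nominal, ±0.5 mm per axis) reflecting the stated 0.5 mm
placement accuracy of the array.

## Body-path plan fixture

The real machine's node set is likewise unpublished. The plan generator
draws beam sources quasi-uniformly (seeded, uniform by area) over a shell:
polar angle from the SI axis in [60°, 120°] — a lateral band, ±30° SI
tilt, so beams are predominantly laterally oriented as a body path around
a supine patient is — azimuth in [−10°, 190°] so no beam fires up through
the couch, and source-to-isocenter distance uniform in [700, 900] mm
around the 800 mm cone-definition distance. All beams aim at the
isocenter with a 5 mm cone and 50 MU; the default plan has 116 beams.
With the default seed this selects 59 of 116 beams for monitoring, and
most attributed errors fall in the SI/AP directions, consistent with the
lateral-beam dominance the physical instrument exhibits.

## Dose kernel

A treatment planning system is deliberately not part of the package; a
single analytic kernel serves as the forward model for curves, per-beam
selection signals and simulated measurements alike:

    dose = MU · rate · (800/d)² · P(r·800/d) · exp(−μ·t)

with `d` the source–point distance, `r` the off-axis distance scaled to
800 mm, `P` a radial profile that is 1 inside a flat core and falls as a
Gaussian beyond it, and `t` the chord of the ray inside the (infinite)
phantom cylinder before the point. Defaults:

| parameter | value | why |
| --- | --- | --- |
| penumbra sigma | 1.776 mm at 800 mm | gives exactly a 2.0 mm 80–20% penumbra, typical of a 5 mm cone once finite diode size and planning-grid resolution smooth the profile |
| flat-core radius | 0.409 mm | puts the 50% isodose diameter at the nominal 5 mm cone size (field-size convention) |
| attenuation μ | 0.005 /mm | effective water-like attenuation; cancels to first order in the RPD ratio |
| reference distance | 800 mm | cone-definition and inverse-square reference |

Narrower penumbras (field edges of a bare small field are ~1 mm) make the
per-diode gradients vary strongly across the ±0.5 mm placement
hypotheses; the smoothed value above matches what a planning-system
export sampled at diode positions actually looks like and keeps the
placement-hypothesis step well behaved. Both parameters are
config-exposed for sensitivity studies. The only property the method
needs from any dose model — steep, smooth gradients at the field edge so
sub-millimetre shifts produce percent-level dose changes — is insensitive
to the functional form.

The phantom is modelled as an infinite attenuating cylinder (no end
caps, no acrylic shell or insert structure); chord lengths and diode
positions move rigidly together under an alignment shift, which makes
"shift the phantom by +δ" exactly equivalent to "shift every source by
−δ" (tested to 1e−9 relative).

## Selection

Per-beam dose vectors (the linear decomposition of the full delivery)
replace the physical movie-file/beam-ID synchronisation. A beam's
candidate diode is its maximum-signal responder at or above 10% of the
maximum single-diode signal (global reference by default; per-beam
available). A diode responding above threshold to two or more beams is
excluded outright — the conservative reading of the cross-talk criterion.
Entries whose diode receives, from a beam opposing its matched beam
(within 5°), at least 10% of the matched beam's own signal are also
removed: opposing exit dose cancels or exaggerates the inverted error.
The bar for this last filter is relative to the matched beam's signal
because anything above the global selection threshold is already caught
by the multi-beam criterion. Every exclusion is logged with a reason, so
a selection is reproducible from the signals alone.

## Curves and inversion

Curves sample C(δ) on the canonical grid {±5, ±4, ±3, ±2, ±1, ±0.75,
±0.5, ±0.25, 0} mm per direction; the spacing outside ±1 mm is 1 mm, the
unique uniform choice that lets the three directions share one zero
calculation for 3·16 + 1 = 49 total. Interpolation is piecewise linear
(monotone, oscillation-free; spline ringing could create spurious roots),
and inversion finds all roots of the interpolant exactly. Conventions,
all recorded here because no authority fixes them:

* among several roots, the smallest |δ| wins; exact ties go to the
  negative root (the estimator deliberately under- rather than
  over-states);
* with no root the grid shift minimising |C − rpd| is returned flagged
  "unsolvable"; residual ties prefer the *larger* |δ| node, so flat
  directions surface as implausibly large shifts that the
  cross-direction minimum then discards;
* wherever a minimum is taken (direction, margin branch, placement
  hypothesis), solvable inversions take precedence over flagged
  minimizers. Without this, a hypothesis sitting on a local dose maximum
  (whose curve is non-positive everywhere) would answer any positive RPD
  with a flagged δ = 0 and silently zero out genuine detections. Flagged
  values still enter reports — counted separately, never clipped — when
  nothing is solvable;
* a positive RPD means the measurement exceeded the baseline.

## Analysis pipeline

Step 1 inverts the RPD in all three directions and keeps the minimum
|δ|. Step 2 computes the per-diode sample SD (n−1) over five same-day
deliveries as a percent of their mean, inverts it under all seven
placement hypotheses, and freezes the hypothesis with the smallest error
(exact ties → nominal). Step 3 inverts RPD − m, RPD, RPD + m (margin m =
1.0 percentage point, additive) and reports the joint minimum over
direction × branch. The margin is the instrument budget the test cannot
see: diode consistency and linearity plus daily output variation.

Because the same-day SD is noise-driven, the Step-2 minimum is in effect
a steepest-curve selector: it cannot identify a diode's true placement
(no statistic of unmoved repeat deliveries can), but it reliably picks a
hypothesis at least as consistent with the observed variation as the
nominal one, which is the step's actual purpose. A side effect is a mild
systematic underestimate of recovered shift magnitudes — inverting
through the steepest of 21 curves shaves |δ| by the gradient spread
across the ±0.5 mm hypotheses. Together with the minimum-direction rule
(whose own underestimation factor is the ratio of the true direction's
slope to the steepest direction's slope) the simulated recovery of an
introduced SI shift δ* comes out at roughly 0.5–0.65·δ* under the default
noise model, and 0.63–0.72·δ* noise-free. The detection power is
unaffected: every introduced shift from 0.3 to 2.0 mm is flagged in 100
of 100 simulated campaigns, while the null false-alarm rate matches its
5% construction.

Detection uses two criteria, either sufficient: the measurement's mean
|δ| exceeds the 95th percentile of a simulated null distribution (≥100
no-shift campaigns), or its RMS exceeds the 0.5 mm clinical action
threshold.

## Simulator and noise budget

A campaign is six baseline deliveries on separate days, five same-day
deliveries sharing one day-level output factor, and test deliveries with
introduced alignment shifts (rigid phantom translations — pulling the
phantom insert out along SI is equivalent to an alignment-centre shift).
Noise is multiplicative lognormal (SDs are small, so effectively
Gaussian):

| source | SD | scope |
| --- | --- | --- |
| day-to-day output | 1% | one factor per day |
| same-day output | 0.5% | one factor per delivery |
| diode consistency | 0.5% | per diode per delivery |
| diode placement | 0.25 mm/axis, truncated at ±0.5 mm | static truth per campaign |

The stated 1% consistency / 0.5% linearity budget is split: its static
part cancels identically against the baseline and is therefore not
simulated; the per-delivery part is the 0.5% above. Placement errors are
drawn once per campaign (the diodes do not move between deliveries) and
recorded, with every other truth quantity, in a JSON manifest for
recovery scoring. One master seed spawns named substreams, so campaigns
are bit-reproducible.

What the simulator does **not** emulate: angular, dose-rate and
field-size dependence of the diode response (these cancel against the
baseline in a constancy design), imaging/tracking alignment residuals,
couch or insert mechanics, TPS beam-model differences, and any
heterogeneity or scatter physics beyond effective attenuation. Passing
tests therefore demonstrate the estimator's arithmetic, its noise
robustness and its sensitivity under this idealisation — not vendor-level
dosimetric fidelity.

## Numerical choices and degenerate inputs

* Curve values are stored to 6 decimals; writers emit sorted keys and
  fixed float formats so identical inputs give byte-identical files.
* The inversion oracle tolerance is 0.002 mm against a 0.001 mm
  brute-force scan.
* A baseline of bit-identical deliveries returns that delivery exactly,
  keeping the noise-free null free of floating-point residue (every δ
  exactly 0).
* Diodes with zero unshifted dose are skipped with a warning when curves
  are built; non-positive baselines drop a diode from the RPD map.
* Dose-grid sampling is trilinear and refuses out-of-bounds points by
  naming the point and bounds; cross-path consistency between the kernel
  and a rasterized grid holds to 0.5% of the local peak at 0.25 mm grid
  spacing (trilinear error grows quadratically with spacing — a 1 mm
  grid of a 5 mm cone is several percent off at the field edge).
* Beams behind a point contribute zero dose; rays parallel to the
  cylinder axis outside it get zero chord.

## Known limitations

* The helical lattice and node fixture are surrogates; absolute selected
  counts (59 of 116 by default) are geometry-dependent regression
  values, not hardware claims.
* The estimator's minimum-selection rules systematically understate the
  magnitude of a true drift (by design, trading magnitude accuracy for
  false-positive control); the verdict should be read as
  "drift / no drift at tolerance", with magnitudes as lower bounds.
* Directions are inverted independently; no joint 3D inversion is
  attempted, and a detected drift cannot be attributed to the robot
  versus the alignment system.
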