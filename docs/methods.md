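# Methods

## Color model and pixel classification

All color reasoning happens in HSV on the OpenCV integer scale: hue is
halved to 0–180 so it fits one byte, saturation and value are 0–255. The
conversion implements the standard hexcone formula with half-even
rounding; the arithmetic uses integer numerators and a single float
division per channel so exact-half cases round reproducibly, and a
scalar rational-arithmetic oracle in the test suite pins the behaviour
on random triples. Hue values that round to 180 at the red wraparound
are kept at 180, so near-360° hues stay inside the upper red range.

The palette is eight named colors over nine inclusive HSV boxes (red is
split across the hue wraparound). The six chromatic hue intervals
partition 0–180 (red 0–10 and 146–180, yellow 11–36, green 37–83, blue
84–124, purple 125–145); black (V ≤ 70 at any saturation), white
(S ≤ 30, V ≥ 230) and gray (S ≤ 25, 71 ≤ V ≤ 229) are bounded in
saturation/value only. Because the black box overlaps the low-value
corner of every chromatic box, classification uses a fixed precedence —
black, white, gray, then the chromatic ranges — making dark ambiguous
pixels black, which matches how a V ≤ 70/255 pixel reads to the eye.
Pixels in none of the boxes (saturation 26–45 between gray and the
chromatic minima, for instance) are *unclassified*.

## The seven features

"Drawn" means outside the white box — the blank canvas. Per drawing:

| feature | definition | default |
|---|---|---|
| prominent color | expressive color with the largest share; ties broken by fixed palette order | — |
| color percentages | share of *classified* drawn pixels per expressive color | — |
| number of colors | expressive colors with share > `min_share` | `min_share` = 1 % |
| saturation % | mean S over drawn pixels / 255 · 100 | — |
| brightness % | mean V over drawn pixels / 255 · 100 | — |
| color fill % | drawn pixels / canvas pixels · 100 | — |
| image coverage % | hole-filled drawn area / canvas pixels · 100 | 4-connectivity |

Two conventions matter and are deliberate:

* **Color percentages are shares of classified drawn pixels**, not of
  the whole canvas. With typical fill around 25–35 % a modal color could
  never average above ~35 % of total pixels, while published per-emotion
  composition tables have modal shares of 50–72 % that sum to exactly
  100 per emotion — both facts force the classified-drawn-pixel
  denominator. Unclassified pixels still count toward fill, coverage and
  the saturation/brightness means (they are ink on the canvas), but are
  excluded from the share numerator and denominator; the shares are
  reduced with rational arithmetic so they sum to 100 exactly.
* **Saturation and brightness are averaged over drawn pixels only.**
  Averaging over the full canvas would pin brightness near 100 for any
  sparse drawing.

Coverage fills holes by flood-filling the background from the canvas
border (4-connectivity by default, 8-connectivity available): any blank
region unreachable from the border counts as covered. Hole-filling can
only add pixels, so fill ≤ coverage for every mask.

The `min_share` threshold on the color count exists because lossy
(JPEG) inputs scatter trace amounts of spurious colors along edges; 1 %
of drawn pixels removes them without touching genuine small color
fields.

## Statistics

Cross-emotion comparisons use the Pearson chi-square test of
independence and one-way ANOVA (delegated to scipy; the degenerate
all-constant case returns F = 0 by convention). Inter-rater agreement
reports pairwise Cohen's kappa, Fleiss' kappa for three or more raters
(via statsmodels) and raw percent agreement separately — an agreement
"percentage" and a kappa are different quantities and are never
conflated. Constant ratings leave chance agreement undefined; the report
flags this instead of returning a number.

The emotion classifier is a multinomial logit with softmax link fitted
by Newton–Raphson on the full log-likelihood. Predictors are
standardised internally; steps are halved whenever they would decrease
the log-likelihood; convergence requires max |score| < 1e-8 or a
relative log-likelihood change < 1e-10, with at most 100 iterations.
(Quasi-)complete separation is detected two ways — coefficients running
past a bound during iteration, or every observation fitted essentially
perfectly at convergence — and raises instead of returning a diverged
fit. The null (intercept-only) log-likelihood has the closed form
Σ nₖ log(nₖ/n); Nagelkerke's pseudo-R² is
[1 − exp(2(L₀−L₁)/n)] / [1 − exp(2L₀/n)]. Bootstrap intervals are
percentile intervals over case resamples with a seeded generator;
non-convergent resamples are counted and excluded. The classification
table is in-sample (apparent) accuracy, the convention of SPSS-style
multinomial output.

Design-matrix choices: the prominent-color categorical enters as dummy
indicators with a dropped reference level, and the raw color percentages
are excluded from the default design — they are compositional (sum to
100), so the block is exactly singular. The reference emotion defaults
to happiness (a positive-valence baseline) and is configurable. Rows are
treated as independent even though each participant contributes four
drawings; no clustering adjustment is applied, which is a known
limitation of the modelled analysis.

## Synthetic-drawing generator

The generator exists so the whole pipeline can be exercised end-to-end,
at the original study scale (182 drawings per emotion), without any
participant data. Each emotion has a profile: per-color (mean, SD) of
composition shares, a multinomial over prominent colors, (mean, SD) for
saturation, brightness, fill and coverage, and Bernoulli rates for the
five style labels. The shipped defaults are the published per-emotion
values of the drawing study this package models.

**Composition sampling.** The published tables constrain the joint
distribution only through per-color means/SDs and the prominence
multinomial, and no simple independent-draw scheme honours both (with
anger's moments, independent truncated normals make red the maximum 87 %
of the time, not 73 %). The generator therefore uses an explicit
two-component mixture per drawing: the prominent color c* is drawn from
its multinomial; its share comes from a truncated normal on [0.5, 100]
whose location is calibrated per color; the remaining mass is divided
among the other colors proportionally to normals at the published
(mean, SD) clipped at zero, capped strictly below the prominent share so
c* holds the argmax by construction. Realized share SDs come out close
to the published SDs; the realized color-count mean (≈1.2–2.2 across
emotions) brackets the published 1.69–1.81 but is an emergent statistic,
not separately calibrated.

**Scalar metrics.** Saturation, brightness, fill and coverage are
truncated normals on [0, 100]; coverage ≥ fill is enforced by joint
resampling with a swap fallback. Style labels are independent
Bernoullis.

**Calibration.** Clipping, renormalisation, capping and the renderer's
feasibility projection all shift raw means, so the generator solves for
its location parameters rather than using the target means directly: the
conditional prominent-share means satisfy a linear consistency system
(solved by least squares; the system is rank-deficient by the
sum-to-100 identity), each location is then recovered by inverting the
1-D truncated-normal mean, and a damped Monte-Carlo correction loop
(common random numbers on a fixed internal seed, independent of the
user-facing cohort seed; batch 20 000, at most 25 iterations, damping
0.8) absorbs the residual bias, which ends below ~0.8 percentage points
on every calibrated cell. The calibration is deterministic and cached
per profile, so cohort generation stays byte-reproducible from the user
seed alone.

**Rendering.** A drawing is a random star-shaped blob: radii over angle
are 1 plus a low-order random cosine series, and the pixel set is the
exact `coverage`-percent count with the smallest distance/radius ratio,
so coverage is realised to pixel precision. An interior hole of
`coverage − fill` pixels is carved from the blob's eroded interior
(never touching the blob or canvas boundary), so border flood-fill
cannot enter it and the coverage metric recovers the full blob. Drawn
pixels are partitioned among colors by largest-remainder rounding of the
shares and painted as contiguous angular wedges. Each color is painted
with a single HSV triple: hue at the center of its range; S and V by
water-filling within safe per-color bounds (3 units inside every
classification box and clear of the black V ≤ 70 precedence cut) so the
drawn-pixel mean S and V hit the ground-truth saturation/brightness
whenever the color mix makes them feasible. Infeasible requests (a
mostly-black drawing cannot be bright) are projected onto the feasible
set. Painted RGB triples are verified to classify back to their color
after the integer round trip, with a small local search as fallback. The
*achieved* ground truth — exact pixel counts and realized S/V values —
is recomputed from the renderer's own bookkeeping and returned with the
image; feature extraction reproduces it exactly for count-based metrics
and to numerical precision for saturation/brightness.

**What the generator does not emulate.** Real drawings contain shapes,
faces and symbols; synthetic ones are abstract blobs, so depiction-style
labels are sampled metadata with the published prevalences, never
visual content (style recognition is a human task). Real drawings are
JPEG with compression noise that lands in the unclassified gaps;
synthetic fixtures are lossless PNG with zero unclassified pixels.
Within-drawing spatial color arrangement (wedges vs. scattered strokes)
is arbitrary, since every metric is arrangement-invariant. Passing tests
therefore validate the measurement pipeline and the statistics on data
with known ground truth; they do not validate conclusions about real
drawings' content.

## Numerical and design choices

* Canvas default 256 × 256 PNG: large enough for ±0.01-point share
  granularity, fast enough to render 728 drawings in well under a
  minute. The test suite uses 64–128 px canvases for speed; the
  full-size cohort appears in the acceptance checks.
* Emotion labels come from the `{participant}_{emotion}` file-name
  convention or a manifest, never from image content.
* Blank or unreadable images are rejected with named errors and listed
  in a rejects log; they never enter statistics silently.
* All percentages are reported on the 0–100 scale; kappa on [−1, 1].
* Determinism contract: one sequential RNG per cohort seed drives
  sampling and rendering; identical seeds give byte-identical PNGs,
  CSVs and model reports.

## Known limitations

* The mixture composition model matches means, prominence and
  (approximately) dispersion, but not higher moments or the real
  zero-inflation pattern of color use.
* Saturation/brightness feasibility depends on the color mix; extreme
  sampled combinations are projected, slightly narrowing the tails of
  those metrics.
* The classifier treats the four drawings per participant as
  independent observations.
* No perceptually uniform color spaces (Lab/LCh/Munsell): the
  measurement model is HSV boxes by design, and findings inherit HSV's
  perceptual non-uniformity.
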