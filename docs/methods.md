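# Methods

This note documents the models, numerical choices and open design decisions
behind the package, and what the synthetic validation does and does not
establish about real data.

## Signal models and fitting

All relaxation maps come from pixel-wise two-parameter least-squares fits of
magnitude data:

* RAFF2 / T1ρ / T2: `S(t) = S0 · exp(−t/T)`, with `t` the cumulative
  pulse-train duration, spin-lock time or echo time. Decay during the RAFF2
  pulse train is modeled as purely mono-exponential in cumulative pulse
  time — the same model used for map reconstruction in practice — with no
  attempt to simulate the fictitious-field spin dynamics inside a pulse.
* T1, magnitude inversion recovery (7 T default):
  `S(TI) = S0 · |1 − 2 · exp(−TI/T1)|`.
* T1, saturation recovery (3 T default): `S(TI) = S0 · (1 − exp(−TI/T1))`.
* MTR: `100 · (S_ref − S_sat)/S_ref` in percent, from a two-frame
  off-resonance pair. Offsets are stored ascending, so the *first* frame is
  the saturated one and the larger offset is the reference; `compute_mtr`
  takes the two frames explicitly to keep the convention visible.

The fitter initializes the exponential decays from a log-linear regression
on frames above the signal floor, and the T1 models from a variable-
projection grid over T1 (64 log-spaced points in the bounds) to step over
the magnitude model's sign ambiguity. Refinement is a damped Gauss–Newton
(Levenberg–Marquardt) iteration vectorized over pixels, with parameters
projected into bounds `T ∈ [1, 10000] ms`, `S0 ≥ 0`; relative tolerance
1e−8, at most 200 iterations. Unit tests pin the fitter to two independent
oracles: a dense profiled grid search on noiseless data and
`scipy.optimize.curve_fit` per pixel on noisy data.

Pixel validity: for decays, every frame must clear
`max(3σ, 10⁻⁶ · max signal)`; this suppresses the signal-free
perfluoropolyether background, whose magnitude data are Rayleigh
distributed. T1 and MTR maps can legitimately pass near zero at the null or
under saturation, so they are gated on a single frame — with the floor
doubled (6σ), because the maximum of a few Rayleigh draws clears 3σ far too
often (P ≈ 1% per frame). Pixels with R² < 0.5 are also invalidated, and
negative MTR values are kept in the map but flagged invalid.

## Phantom

The phantom is a rectangular tissue block inside a signal-free margin, with
an epicardial fibrotic band (≥1 pixel) along the top tissue edge and an
axis-aligned (optionally tilted) SAN ellipse beneath it; in 3D the SAN is an
ellipsoid across slices. Defaults follow the 7 T protocol: 64×64 matrix,
15 mm field of view (234.375 µm pixels), SAN 2.5 × 12 mm. Pixel centers sit
at `(i + 0.5) · spacing`; areas are pixel counts × spacing².

Tissue values are the published 7 T / 3 T cohort means for SAN and
myocardium. The epicardial fibrotic layer has no published row, so it
carries synthetic values chosen consistently with its near-pure collagen
content: relaxation times above the SAN (e.g. T_RAFF2 170 ms at 7 T, 260 ms
at 3 T) and MTR below it. These values only need to order the classes and
keep them separable; no quantitative claim rests on them.

Noise is Rician, `sqrt((x+n₁)² + n₂²)` with independent Gaussians of scale
σ, the correct model for magnitude MRI. The default σ = 0.02 at S0 = 1 is
SNR 50. One master seed drives everything: `numpy.random.SeedSequence`
children are spawned per heart, and within a heart per stage (parameter
jitter, geometry, one stream per contrast, histology texture), so any heart
is reproducible in isolation.

Per-heart variability has two parts:

* **Tissue parameters.** Gaussian jitter with the published across-sample
  SDs, built as `ρ · z_heart + sqrt(1−ρ²) · z_class` with ρ = 0.9. The
  shared heart-level factor is not optional ornament: independent draws
  would give a per-heart RAFF2 contrast SD of ≈0.15, whereas the published
  per-heart contrast SD is 0.06 — within a heart, SAN and myocardium times
  co-vary strongly, and ρ ≈ 0.9 reproduces that.
* **Geometry.** SAN thickness uniform in the anatomical 2–3 mm, length
  uniform in 10–12.2 mm — the anatomical range is 10–20 mm but the 15 mm
  field of view minus margins caps what the grid can hold.

Synthetic histology renders the label map at 46.875 µm (an integer fifth of
the MRI pitch) with the blue channel proportional to each class's fibrosis
fraction (myocardium 0.10, SAN 0.74 as measured in swine, epicardial layer
0.95) plus seeded Gaussian texture (SD 8 of 255), and the red channel
anti-correlated. What it does **not** emulate: staining variability,
sectioning distortion and tears, the SAN artery, partial-volume mixing
beyond pixelation, or any mis-registration between section and imaging
plane. Passing agreement tests therefore demonstrate internal consistency
of the pipeline, not histology-grade validation on real sections.

## Segmentation

Multi-Otsu thresholds maximize between-class variance of a binned
histogram: 256 bins over the valid-value min–max range for maps, the native
0–255 range for 8-bit histology. The search is exhaustive over all ordered
tuples of interior bin edges (vectorized; ≤ 255³ candidates at three
thresholds), so the result provably equals brute-force enumeration. Exact
ties occur whenever a cut slides across empty bins; ties within a 1e−9
relative band are broken toward the lexicographically smallest tuple, which
makes the operation deterministic and lets an independent enumeration oracle
match it exactly. A value equal to a threshold joins the upper interval.

On maps the signal-free background is pre-masked (invalid pixels), so the
three tissue classes need two thresholds; histology keeps all four classes
under three thresholds. Interval-to-class order is explicit configuration:
ascending relaxation time (myocardium < SAN ≤ epicardial layer), ascending
blue intensity for histology, and *descending* for MTR, where fibrotic
tissue has the lower value.

Per-heart SAN areas take the largest connected component of the SAN class
(8-connectivity in 2D, 26 in 3D) — the programmatic counterpart of manually
cropping the region of interest around the node, and the step that discards
noise speckle misclassified into the SAN intensity interval. Regional means
for the contrast metrics instead use histology-informed ROIs: the segmented
section is resampled to the MRI grid and eroded (1 pixel for the SAN, 2 for
remote myocardium) so means are taken over region cores. The SAN threshold
rule (`myocardium mean × (1 + fraction)`, default 20%) and 3D thresholding
with per-structure histograms are exposed for the volumetric use case.

## Statistics

RRTD and MTC are computed per heart and then averaged (the ratio-of-means
variant is also reported as `contrast_of_means`). Both metrics are bounded
by ±2, antisymmetric and scale-invariant, and satisfy
`MTC(s, m) = RRTD(m, s)` algebraically. Agreement between MRI and histology
SAN areas uses Pearson correlation (two-sided p from the t distribution
with n−2 df) and Bland–Altman bias ± 1.96 · SD of the paired differences
(SD with n−1). Group comparisons: Welch's t-test by default (the pooled
variant is available), one-way ANOVA over the per-heart contrast values,
and Benjamini–Hochberg step-up adjustment over an explicit comparison
family — by default each method against the RAFF2 reference, plus a second
family of the five SAN-vs-myocardium tests. Stars follow the usual
0.05 / 0.01 / 0.001 convention after adjustment.

One deliberate deviation: at the published group separation (124 ± 15 vs
90 ± 8 ms, n = 7) the Monte-Carlo power of a Welch test at α = 0.001 is
only ≈0.64 (≈0.94 at α = 0.01), so the test suite asserts those simulated
rates rather than near-certain detection at the strictest threshold.

## Problem sizes and known limitations

Validation runs use the 64×64 single-slice phantom, cohorts of 7 (agreement
analyses) and 20 (contrast-band checks) hearts at SNR 50 — sizes chosen to
mirror the N = 7 study design while keeping a full simulate–fit–segment–
quantify cohort run in the tens of seconds.

Known limitations: no B0/B1 inhomogeneity fields in the phantom (the QC
operations accept externally supplied maps); no cardiac motion or flow; the
two-pool physics behind magnetization transfer is reduced to a fixed MTR
per class; T1-IR at 7 T samples TIs only up to 1200 ms, below the ~1300 ms
SAN T1, so its per-pixel precision is the worst of the five contrasts, and
its map-based segmentation is correspondingly fragile — consistent with T1
being the weakest SAN discriminator. For hearts whose jittered SAN
parameters drift toward the myocardium or epicardial values, map-based
class boundaries blur and SAN-area estimates degrade; with the default
conditions this is visible as MRI-vs-histology r² varying over roughly
0.8–0.99 across cohort seeds, against ~0.99 for histology against ground
truth.
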