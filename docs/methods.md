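# Methods

This note documents the models behind `tensiongrad`, the parameters that
matter, what the synthetic data emulate (and do not), and the numerical
choices made where the design was genuinely open.

## Lifetime estimation

TCSPC photon-arrival histograms are modeled as a two-component exponential
decay convolved with a Gaussian IRF, folded into the excitation window
`W = 1000/rep_rate` ns (50 ns at the default 20 MHz; photons arriving after
`W` wrap, as under periodic pulsed excitation).

**Barycenter ("fast lifetime").** The estimate is the count-weighted mean of
the decay-histogram bin centers minus the IRF barycenter. It uses all bins
with no background subtraction by default (an optional pre-rise constant
subtraction exists as a flag). Empty pixels yield NaN, as do negative values
(a decay apparently preceding the IRF) — invalid, never clipped. The
window-folded mono-exponential barycenter equals `τ − W/(e^{W/τ} − 1)`; at
τ ≈ 4–5 ns and W = 50 ns the truncation deficit is ≲ 0.01 ns, which is why
the barycenter and the fitted intensity-weighted mean agree to well under 1%.

**Bi-exponential reconvolution fit.** Poisson maximum likelihood on the
multinomial histogram shape with three free parameters (fast-component
intensity fraction, τ₁, τ₂); the total count is fixed to the observed sum.
The model is the wrapped bi-exponential circularly convolved with the binned
IRF; because convolving two *separately binned* distributions lands the sum
half a bin late, a +0.5-bin spectral shift restores the single-binning time
base (without it the fit is biased by ~Δbin/2 ≈ 0.1 ns). Initialization is
scale-aware (τ₁ = τ̄/2, τ₂ = 1.5 τ̄ from the barycenter, equal fractions),
bounds τ ∈ [0.1, 20] ns, fits below 100 photons are refused, and
non-convergence is flagged on the result rather than raised. Degenerate
τ₁ ≈ τ₂ solutions are legitimate (mono-exponential data).

**Image operations.** Masking invalidates lifetimes strictly below the photon
threshold (default 20: a 19-photon pixel is masked, a 20-photon pixel kept —
the boundary is configurable). The 3×3 median filter is NaN-aware (invalid
neighbors ignored, reflection at borders, invalid pixels stay invalid) and is
an *image/display* operation; region averages are computed on unfiltered
masked lifetimes, photon-weighted: `τ̄ = Σnᵢτᵢ/Σnᵢ`. The lifetime→tension
map is a user-supplied linear calibration; the package ships only an example
slope (1.25 mN/m per ns) in documentation, never as truth.

## Synthetic scenes and photon simulation

A scene is a cell/pattern geometry plus a noiseless lifetime field

```
τ(p) = baseline + slope·x(p) + edge(d_edge(p)) + plane_offset
```

with `x` the polarity-axis coordinate relative to the cell centroid, and the
edge term either `amp·e^{−d/L}` or `amp·max(0, 1−d/L)` against the inward
distance to the cell edge. The plane offset models the top-vs-bottom
difference of adherent cells as a constant. Geometries are parametric
stand-ins: a half-annulus crescent (keratocyte-like, ~40 µm wide), a large
ellipse with a frontal lobe for the polarized cell (~150 µm tip-to-tail,
sized after well-spread Cos7-scale fibroblasts — large sectors keep the
photon-limited region means informative), and cross / crossbow / ring / disc
micropatterns with the cell filling the pattern's convex hull. Default pixel
size is 0.25 µm (so the 3-pixel median kernel spans 0.75 µm); SLB fields use
0.5 µm.

Photons are simulated per pixel as Poisson counts (default mean 30, the
10–50/pixel regime of gentle live imaging) whose arrival times come from the
bi-exponential realizing the pixel's target mean lifetime with the fixed
component pair (τ₁, τ₂) = (1.5, 6.0) ns — the probe's two-state
photochemistry leaves one degree of freedom per pixel, the intensity fraction
`α₁ = (τ₂ − τ̄)/(τ₂ − τ₁)`. Times get Gaussian IRF jitter (σ = 0.2 ns,
center 2 ns; configurable — instrument-typical values, no specific hardware
implied), fold into the window and are binned (256 bins default). All
randomness flows from one seeded generator per call; identical seeds give
bit-identical stacks.

**Shot-noise floor.** The arrival-time SD of the (1.5, 6.0) mixture at
τ̄ ≈ 4.5 ns is ≈ 5.4 ns, so any photon-weighted ROI mean has
SD ≈ 5.4/√(total photons): ≈ 0.04 ns for 500 pixels at 30 photons, ≈ 0.01 ns
for a 10⁴-pixel sector. Recovery tests are sized against this floor; passing
them demonstrates correct estimation at the photon budget, not super-Poisson
precision on real data.

## Spatial statistics

Distance fields are exact Euclidean distance transforms to boundary pixels,
signed (negative inside) for pattern boundaries and unsigned inward for
cell-edge profiles. Profiles use 1-µm bins, photon-weighted (weighting is a
package choice made for estimator-variance reasons; unweighted mode exists),
and slope fits are weighted least squares with per-bin pixel counts as
weights. `hist2d_mean` shares the accumulation code with `decay_profile`, so
marginalizing the 2D map reproduces the 1D profile exactly.

Front/rear systems: area-fraction regions assign rank-tie groups wholly (at
fraction 0.5 ties go to the front); angular sectors are ±30° about an
externally supplied polarity angle (morphology-derived, never
lifetime-derived), 0–10 µm from the edge. Decile regions take the top/bottom
two lifetime deciles of a control average map, tie groups assigned wholly,
and refuse constant maps.

Pattern registration is translation (centroid match) plus the template's
discrete symmetry rotations only (cross: 90° multiples); free
rotation/scaling is excluded because patterns are manufactured at fixed size
and orientation and free registration could smear gradients. Cells are
dropped below a 50% Jaccard overlap floor (configurable). Averages are
photon-weighted (equal-weighted for MSI z-maps). Contour profiles trace the
sub-pixel boundary, smooth the polygon with a short circular moving average
(the raw marching-squares length overestimates a circle's perimeter by ~5%),
and sample a 1-µm inward band assigned to nearest contour vertices.

## Edge kinematics and SLB spreading

Edge velocity is the frame-to-frame difference of signed distance maps
(positive inside), evaluated per contour pixel of the earlier frame and
scaled to µm/min. Two numerical details matter: (i) right at a boundary pixel
the two maps carry different raster-quantization biases (the earlier frame's
distance is pinned to exactly one pixel), so the difference is sampled three
pixels inward, where both maps are smooth and the biases cancel, and assigned
to the nearest contour pixel (thin masks fall back to the contour itself);
(ii) each contour pixel carries the arc length of the traced sub-pixel
boundary it represents, so the contour integral `Σ v·ds·dt` reproduces the
swept area within a few percent — plain boundary-pixel counting
under-measures perimeter by 10–20%.

Protruding/retracting classification uses the symmetric ±0.2 µm/min
threshold; the |v| ≤ 0.2 band stays unclassified (the two populations are
kept distinct rather than merged). Classified contour pixels seed regions
extending 0–10 µm inward via nearest-contour-pixel assignment, which makes
the two regions disjoint by construction.

The synthetic SLB is a rectangular crop of a large spreading patch: a
near-straight front, tilted by 0.1 so rasterization phases average out across
rows, advancing with `v(t) = v0 (1+t/t0)^{−β}` (defaults v0 = 10 µm/min,
t0 = 1 min, β = 0.7 — fast initial spreading with power-law slowdown). Each
frame's lifetime field is linear in distance-from-front over a 100-µm window
with slope `s = c·v`; the coupling `c` (default 0.0015 ns·min/µm²) is defined
against the *area-based* spreading speed `ΔA/(dt·width)` measured from the
rasterized masks themselves, because that is the observable the analysis
reports (raster quantization would otherwise leak into the constructed
truth). Spreading speed and per-frame slope fits then recover the coupling
within the fit confidence intervals, and the slope relaxes to zero as the
spreading stalls.

## Fluctuation spectroscopy

The line-scan simulator moves particles in 2D (per-coordinate step variance
`2D·line_time`, optional drift along the scan axis) on a periodic domain 3×
the scanned line (and 3 µm across it), and detects them through a Gaussian
PSF of 1/e² waist 0.25 µm with Poisson counting. Defaults mirror the standard
acquisition geometry: 64 pixels × 0.16 µm, 960 µs line time, 5.2 µs dwell.

Column ACFs are computed by FFT at multi-tau (quasi-logarithmic) integer line
lags, averaged over three sections (pixels 1–21, 22–42, 43–63 in 1-based
inclusive notation; half-open 0-based internally). The fit model is a
two-component 2D diffusion law `G = G0 Σ fᵢ/(1+τ/τ_{D,i})`, `τ_D = w²/4D` —
the standard form for membrane scanning FCS; the reported `D0` is the
fraction-weighted mean (both components are also reported, since the
convention is not unique). Detrending divides out a per-column moving-average
trend and restores the column mean; the default window is 10,000 lines
(~9.6 s). A shorter window is unsafe: 2D diffusion correlations decay only
as 1/lag, and a ~1 s window folds that tail into a spurious anticorrelation
dip that biases fitted D upward by tens of percent.

pCF correlates columns δr = 5 pixels apart (forward: 1–59 with 6–64; reverse
mirrored). Peaks are fitted with a Gaussian on the log₁₀(lag) axis,
restricted to ±0.6 decades around the smoothed maximum — the diffusive
early-arrival shoulder is strongly skewed in log-lag and would otherwise drag
the fitted center early. Even so the physical pCF maximum precedes the
ballistic transit time `δr·px/v` by `~(D/v + w²-term)/v`; the directed-
transport demonstration therefore uses a slow-mobility species
(D = 0.02 µm²/s at v = 0.8 µm/s, Péclet ≈ 30, cargo-like rather than free
lipid), where the peak sits within ~10% of the transit time. Transport
efficiency is the pCF peak amplitude over the ACF G0. Flow detection (used
for the false-positive check) compares forward/reverse smoothed peak
amplitudes and fitted arrival times: flow is declared for a one-sided peak or
a ratio ≥ 3 — thresholds fixed a priori; pure diffusion is symmetric and
stays below them.

## FRAP

Traces are corrected as `(F − bg)/(ref − bg)`, scaled to 0 at the first
post-bleach sample and 1 at the mean of the 5 s before the bleach, then
fitted with `M(1 − e^{−kt})`; `t½ = ln2/k`. Immobile traces (plateau < 0.02)
leave k unidentifiable and are flagged, not raised. Individual noisy traces
are averaged after bleach alignment before fitting — the standard protocol;
single 2%-noise traces carry ~10% half-time uncertainty, 10-trace averages
~2%. Line-FRAP integrates 100 pixels (11 µm) parallel to the bleached line,
tracks the parabola-vertex minimum over 12 frames (0.5 s/frame), and reports
the flow velocity as the slope of position versus time; tracks truncate with
a warning when the dip recovers away.

## MSI

Lipid fractions divide each species' summed peak intensities by the total
over *known* peaks only; pixels with zero known intensity are invalid rather
than zero-fraction, so off-cell background cannot dilute the statistics
pooled across cells ("all cells, all pixels" is read as all in-cell pixels).
Multi-peak species sum their relative abundances. Z-scoring uses the pooled
mean/SD over all cells' valid pixels and refuses zero-SD species. The peak
table (channel → m/z → species) is a required user input; test tables are
synthetic. MSI pixels carry 0.5 µm size so the spatial module applies
unchanged.

## What the synthetic data do not emulate

No detector afterpulsing or dead time, no measured-IRF asymmetry, no
background fluorescence in FLIM scenes, no segmentation errors (masks are
exact), no cell-shape variability within a condition, no z-dependence or
optical sectioning, no triplet/blinking photophysics in FCS, and no MSI peak
overlap or matrix effects. Passing the recovery suites therefore validates
the estimators and pipeline plumbing under ideal segmentation and pure shot
noise — not robustness to those experimental artefacts.

## Problem sizes used by the validation suites

Gradient recovery runs 50 seeds of a 672² polarized scene at 30
photons/pixel; estimator identity uses 100 pixels of 10⁴ photons; the
closed-form barycenter check uses 1.6×10⁷ photons on a 4096-bin δ-IRF
configuration (at 10⁶ photons the shot-noise SD equals the 0.1% tolerance,
so the larger draw makes the check a bias test); FCS recovery uses
50,000-line kymographs (10 seeds per diffusion coefficient, 20 zero-flow
seeds); the reproduction script uses smaller seed counts of the same
experiments. These sizes are the package's validation design and are stated
here so results can be reproduced exactly.
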