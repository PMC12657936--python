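# tensiongrad

Quantification of plasma-membrane tension gradients from fluorescence-lifetime
(FLIM) images of the mechanosensitive probe Flipper-TR, with companion analyses
for membrane dynamics: edge kinematics, supported-lipid-bilayer (SLB)
spreading, line-scan fluctuation spectroscopy (ACF/pCF), FRAP, and MALDI-MSI
lipid maps. A fully synthetic test bench generates every input with known
ground truth, so the whole chain is verifiable without any experimental
download.

**Who it is for.** Membrane biophysicists and cell-mechanics labs that acquire
TCSPC-FLIM images of tension probes and want a reproducible, scriptable route
from photon-arrival histograms to spatial tension statistics.

## The science in brief

Flipper-TR inserts into the bilayer and its fluorescence lifetime increases
with lipid packing, hence with membrane tension. TCSPC produces, per pixel, a
histogram of photon arrival times following a bi-exponential decay
`I(t) = A1 e^(-t/τ1) + A2 e^(-t/τ2)` convolved with the instrument response
function (IRF). The package estimates the mean lifetime two ways:

* **barycenter ("fast lifetime")** — first moment of the decay histogram minus
  the first moment of the IRF; robust at the 10–50 photons/pixel of gentle
  live imaging, and numerically equivalent to
* **intensity-weighted fit mean** `τ̄ = Σ αᵢ τᵢ` (with `αᵢ = Aᵢτᵢ/ΣAⱼτⱼ`) from
  a Poisson maximum-likelihood bi-exponential reconvolution fit.

Lifetime images (τ raster + photon-count raster) are masked below 20
photons, median-filtered for display maps, and averaged over regions with
photon weighting, `τ̄_ROI = Σ nᵢτᵢ / Σ nᵢ`. Spatial gradients are quantified
against Euclidean distance fields (cell edge, micropattern boundary, SLB
front): per-micron decay profiles, weighted linear slopes (ns/µm), front/rear
regions (closest/farthest area fractions, or 60° angular sectors extending
0–10 µm from the edge), lifetime-decile regions of pattern-aligned average
maps, and condition-difference maps against a reference (e.g. an
actin-frozen baseline). Edge velocity comes from frame-to-frame differences of
signed distance maps; protruding/retracting regions use a symmetric
±0.2 µm/min threshold. A user-supplied linear calibration converts lifetime
differences to tension differences (mN/m); it is configuration, not shipped
truth.

The fluctuation-spectroscopy module autocorrelates line-scan kymograph columns
(`G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩²`), fits a two-component 2D-diffusion model
`G = G0 Σ fᵢ/(1+τ/τ_{D,i})` with `τ_D = w²/4D`, and pair-correlates columns
δr = 5 pixels apart to detect directed transport via the arrival-time peak and
the forward/reverse asymmetry. FRAP traces are normalized to [0, 1] and fitted
with `M(1−e^(−kt))` (mobile fraction, `t½ = ln2/k`); a drifting bleached-line
minimum reports in-plane flow. MSI channel stacks become per-species lipid
fractions over the known peaks only, z-scored against statistics pooled over
all cells.

## Worked example

Recover the lifetime gradient of a synthetic polarized cell (150 µm
Cos7-like geometry, 30 photons/pixel, 0.02 ns/µm axial gradient plus a
0.3 ns edge term decaying over 2 µm):

```python
from tensiongrad import workflows, flim

r = workflows.recover_polarized_gradient(seed=0)
print("front lifetime      : %.3f ns" % r["front_est"])
print("rear lifetime       : %.3f ns" % r["rear_est"])
print("front-rear delta    : %.3f ns  (ground truth %.3f ns)" % (r["delta_est"], r["delta_true"]))
print("gradient slope      : %.4f ns/um (ground truth %.4f ns/um)" % (r["slope_est"], r["slope_true"]))

cal = flim.TensionCalibration(slope=1.25, source="example config")
print("tension difference  : %.2f mN/m (example calibration, 0.20 ns)"
      % flim.tension_from_lifetime(0.20, cal))
```

prints

```
front lifetime      : 5.291 ns
rear lifetime       : 3.030 ns
front-rear delta    : 2.261 ns  (ground truth 2.276 ns)
gradient slope      : -0.0329 ns/um (ground truth -0.0324 ns/um)
tension difference  : 0.25 mN/m (example calibration, 0.20 ns)
```

The measured front/rear photon-weighted means and the weighted profile slope
track the constructed ground truth to within the photon shot-noise floor
(here ~0.01 ns on the sector difference). The negative slope is the lifetime
*decay* with distance from the leading edge. The final line converts a 0.20 ns
lifetime difference into a 0.25 mN/m tension difference under an example
linear calibration — supply your own calibration for real data.

A thin CLI covers the simulation and image-processing entry points:

```bash
tensiongrad simulate scene --config scene.yaml --seed 1 --out out/
tensiongrad flim out/scene.tif --mask-threshold 20 --median 3 --out out/proc.tif
tensiongrad frap fit frap.csv --bleach-index 25
```

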