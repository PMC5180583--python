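# Methods

## The measurement model

Hairiness is operationalized as local Shannon entropy of the specimen
photograph. A hair ~4 px wide crossing a pixel's neighborhood spreads the
neighborhood's gray-value histogram over many bins; bare cuticle
concentrates it in few. For channel c ∈ {R, G, B} and pixel (i, j), the
filter forms the 256-bin histogram of the channel values inside a disk of
radius r centered on the pixel, normalizes it to probabilities p, and sets

    E_c(i, j) = −Σ_v p_v log₂ p_v   (bits, 0 ≤ E_c ≤ log₂ min(256, N_r))

where N_r is the disk size (149 lattice points at r = 7). The combined
entropy is the per-pixel product E_S = E_R·E_G·E_B (bits³, reported
unitless), and a region's trait value is the mean of E_S over the valid
pixels inside its polygon; the sample SD (n−1) accompanies it.

Assumptions: 8-bit sRGB input at a scale where hairs are a few pixels
wide; diffuse illumination (specular highlights raise entropy for
non-hair reasons); one trait value per region per image.

### Parameters

| parameter | default | meaning |
|---|---|---|
| radius of influence r | 7 px | disk radius of the entropy neighborhood; ~2× hair width at the original imaging scale. Exposed because it depends on the px/mm factor of the user's rig. |
| min_area | 8 px² | artifact objects smaller than this are deleted |
| circ_tol | 0.05 | objects with \|S − 1\| ≤ circ_tol are deleted as pollen-like |
| threshold_window | 15 px | square window of the local-mean threshold |
| threshold_sensitivity | 0.5 | foreground iff value > sensitivity × local mean (bright polarity) |
| polarity | bright | side of the local mean that counts as foreground |

The disk is the exact Euclidean lattice disk {(di,dj): di²+dj² ≤ r²}. A
well-known MATLAB `strel('disk', 7)` approximation covers 160 pixels
instead of 149; we use the exact disk and document the difference rather
than replicate the approximation.

### Numerical choices

- **Histogram counts by FFT.** Per-gray-value indicator planes are
  convolved with the disk kernel via real FFTs; counts are integers, so
  rounding the convolution output makes the result equal to a direct
  per-pixel histogram (verified against a naive oracle to 1e-10, which is
  accumulation-order roundoff only).
- **Borders.** Reflect (symmetric) padding; constant padding would
  manufacture edge entropy.
- **Excluded pixels** (deleted artifacts) are removed from every
  neighborhood histogram they fall in, are assigned E = 0 with
  `valid = false`, and never enter region statistics. A fully excluded
  neighborhood is invalid, not an error.
- **Region crops.** Entropy is computed on each region's bounding box
  dilated by r. For in-region pixels this is identical to a whole-image
  computation: interior crop edges supply real pixels through the
  dilation, and crop edges clipped at the image boundary coincide with
  the image's own reflection boundary.
- **Rasterization rule.** A pixel belongs to a polygon iff its center
  (col + 0.5, row + 0.5) is strictly inside under the even-odd rule;
  boundary ties are outside. Unambiguous, exactly testable (an axis-
  aligned k×k square with integer corners covers exactly k² pixels), and
  equivariant under integer translation.
- **Perimeter.** Closed Moore-neighbor trace of the outer boundary; the
  perimeter is the accumulated center-to-center step length (1 or √2).
  One-pixel-wide spurs are traversed on both sides, which is the
  "accumulated distance across the border" reading; holes are ignored
  (pollen grains are solid). A single pixel has perimeter 0 and undefined
  circularity; such objects only survive the area filter at min_area = 1
  and are then treated as deleted specks.

### Artifact segmentation and its operating envelope

"Foreground iff value > 0.5 × local mean" marks any near-uniform surface
as foreground (a pixel equal to its neighborhood mean always exceeds half
of it). Compact bright objects are nonetheless isolated: they inflate the
local mean of an annulus around themselves, pushing those background
pixels *below* threshold and cutting a moat that disconnects the object.
The mechanism needs the object to out-shine its surroundings by roughly
the inverse sensitivity plus window-dilution factor — in practice a
luminance ratio ≳ 6 between grain and pelt at the default window. Bright
yellow pollen on dark-bodied insects satisfies this comfortably; pale,
low-contrast grains on pale cuticle would not, and users can switch
polarity or sensitivity for such material, or disable pre-processing.

Small digital disks are a second envelope limit: under the center-to-
center perimeter, segmentation-recovered disks of radius 3–4.5 px measure
S ≈ 1.05–1.24 (discretization bias), outside the 5% circularity band, and
so are caught only by the area filter when small enough. From radius
≈ 6 px the measured S stays within the band ~95–100% of the time.

## The synthetic data layer

Generated specimens emulate what the pipeline responds to, not what an
insect looks like: a flat dark cuticle base (luminance ~16), straight
anti-aliased hair strokes 3.5–4.5 px wide with random orientation and
length 15–30 px (dim, luminance ~30), additive Gaussian sensor noise
(SD 2 gray levels), and bright pollen disks (luminance ~225, radius
6–9 px — large grains, chosen inside the circularity-band envelope
above). `hair_density` is the target areal coverage: the stroke count is
Poisson with mean `density · area / mean-stroke-area`, so 0 is bare
cuticle and 0.8 dense fur (realized coverage is lower through overlap).
Region polygons in generated fixtures are axis-aligned rectangles;
polygon handling is exercised separately.

Passing synthetic tests therefore shows the operators respond correctly
to texture density, repeat across renderings, and remove compact bright
contaminants — not that the method is robust to specular highlights,
focus-stacking artifacts, curved or overlapping real hairs, or
low-contrast pollen, none of which the generator attempts.

Synthetic trait tables draw the eight region entropies and body length
from an equicorrelated multivariate normal (mean 50, SD 15 entropy units;
body length 10 ± 3 mm; pairwise correlation 0.3 — regions of one insect
are hairy together, so independence would be unrealistically easy) and
build the response as intercept + β_face·face + β_td·thorax_dorsal +
Gaussian noise, with the residual SD solved from β'Σβ so the true model's
population R² hits the 0.95 target; n = 10 species matches the scale of
species-level pollination datasets.

## Model selection layer

OLS with intercept via least squares; Gaussian log-likelihood including
normalizing constants, logL = −n/2·(log(2π·RSS/n) + 1), the R `lm`/`AIC`
convention, so absolute AICc values are comparable across software;
k = p + 2 counts intercept, slopes, and residual variance. Candidates are
all subsets of the global main effects (512 for 8 regions + body length),
optionally expanded with body-length × region interactions under
marginality; subsets with more than n − 4 terms are dropped so AICc keeps
finite-sample headroom. Ties in AICc break toward fewer terms, then
lexicographic term names. A perfect fit (RSS = 0) dominates any finite
AICc and is ranked first, but has no defined likelihood scale, so it is
excluded from the Akaike-weight normalization (NaN weight) with a
warning. VIF_j = 1/(1 − R²_j) from auxiliary regressions; exact
collinearity reports an infinite sentinel rather than failing.

## Problem sizes

Synthetic acceptance checks run on 160×160 px regions (128×128 for the
repeatability rendering set), 5 scenes × 5 grains for pollen removal, and
200 replicate trait tables for the recovery rate — sizes at which every
quantity is stable to the few-percent level while the whole suite stays
interactive. Full-resolution photographs (e.g., 5,616 × 3,744) process
identically but take correspondingly longer; the per-region crop keeps
cost proportional to region size, not image size.

## Known limitations

- The entropy trait conflates hairiness with any fine texture (sculptured
  cuticle, scales, specularity); the method is a proxy, not a hair count.
- Circularity-based pollen removal misses grains far from the
  discretization band (small radii) and non-circular debris; clumped
  grains merge into elongated objects and are kept.
- The adaptive threshold's literal contract (see envelope above) cannot
  isolate low-contrast artifacts.
- Entropy values depend on r and on the px/mm scale; trait values are
  comparable only within a consistent imaging protocol.
- With n ≈ 10 species, all-subsets selection over 9 predictors is
  honest about overfitting only through AICc's correction; the recovery
  simulations show ~20–25% of replicates still top-rank a wrong (usually
  superset) model at R² = 0.95.
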