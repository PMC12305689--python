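# Methods

This note documents the models, numerical conventions, and design choices
behind `gfapquant`, in the spirit of a methods section a maintainer can
check the code against.

## Coordinate and lattice conventions

All rasters are (row, col), 0-based, pixel centers at integer coordinates;
physical position = index × pixel size (μm). The tile lattice is anchored
at the image origin; tile (i, j) covers pixels `[i·t, (i+1)·t) ×
[j·t, (j+1)·t)` and its center sits at `((i+0.5)·t − 0.5, (j+0.5)·t −
0.5)`. Partial tiles at the far edges are flagged and excluded from ROI
means and profiles by default (their denominators differ). ROI membership
is by tile center, inclusive on both bounds. Mirroring about the midline
column m maps column c to 2m − c; with the default midline at
(n_cols − 1)/2 and tile-divisible image widths, tile centers map exactly
onto tile centers, so mirrored-ROI means on a symmetric map are exactly
equal.

## Segmentation chain

* **Rolling-ball background.** The background is the grayscale opening of
  the image with a non-flat ball structuring element (height
  √(r² − d²)), i.e. the classic ball rolled under the intensity surface,
  computed with `scipy.ndimage` erosion + dilation. Note that
  `skimage.restoration.rolling_ball` computes only the erosion half; the
  full opening is what makes a constant image (and any constant offset)
  map to exactly zero residue. The radius in pixels is
  `round(radius/pixel_size)` (half away from zero) and must be ≥ 1 pixel —
  a sub-pixel ball would be a no-op, so it is rejected.
* **8-bit conversion.** Linear min–max rescale to 0..255 with
  half-away-from-zero rounding; constant images map to zeros with a
  warning and are rejected by the thresholding stage.
* **Otsu threshold.** Computed over the full 256-bin histogram of the
  whole slice (not per tile); the integer threshold maximizes the
  between-class variance with ties broken toward the lower threshold, and
  the mask is `values > t`. The implementation (scikit-image on an
  explicit histogram) is tested bit-exactly against an exhaustive search
  over all 256 candidate thresholds.
* **Area filter.** Connected components (8-neighbour by default, so 1-px
  diagonal processes stay connected) with area in μm² =
  pixel count × pixel_size²; components strictly below 7 μm² or strictly
  above 1000 μm² are removed. The bounds themselves are retained — the
  exclusion rule is "below 7 / above 1000", which we read as exclusive
  removal. Thresholds are converted to μm², never to rounded pixel
  counts, so the bounds stay exact across resolutions (at 0.65 μm pixels
  a 16-px component is removed, a 17-px one kept).
* Erythrocyte-like and autofluorescent punctae are deliberately **not**
  removed: they fall inside the size band and are part of the measured
  signal in the assay; the phantom injects them so their contribution is
  measurable (they add a small dose-independent offset, not slope).

## Dose model and registration

The analytic beam replaces Monte Carlo transport: depth-dose is an
entrance plateau (35% of maximum) rising as a Gaussian (σ_peak, default
400 μm) to a single Bragg-peak maximum at the configured depth, followed
by a Gaussian distal falloff (σ_distal, default 150 μm; < 1% of maximum
within ~3σ ≈ 0.5 mm). The lateral profile is a top-hat of the collimator
diameter (4 mm) convolved with a Gaussian penumbra (σ 300 μm). The grid
maximum is normalized to the prescription exactly, so the whole field is
linear in the prescription; doses below 0.2% of the prescription are
clamped to 0 Gy so the contralateral hemisphere is exactly unirradiated.

Registration of the planning grid into slice pixels is a 6-parameter
affine fitted to ≥ 3 non-collinear landmark pairs by least squares — a
deliberate simplification of contour-based slice-to-volume registration;
the analysis surface (ROI means, tile profiles) tolerates the 0.5–1.5 mm
registration uncertainty such pipelines report, and an affine is fully
testable (round-trip RMSE < 1% of maximum on smooth fields). Resampling
is bilinear with out-of-footprint positions set to 0 Gy; the planning-grid
spacing (50 μm default) and the interpolation order are package choices,
not assay constants.

## Phantom: the stated world

The phantom generates, per slice: a GFAP channel, a DAPI channel, the
planning-grid dose with its ground-truth affine, a true object mask, and
the expected density field.

* **Objects.** Branched random-walk polylines, 1–2 px stroke width,
  target areas 40–120 μm². Width matters: astrocyte processes (~1–2 μm)
  are narrower than the 3.25 μm rolling ball, so the background estimate
  cannot climb into them; wider strokes would be partially absorbed as
  background and break the linear-response assumption.
* **Density budget.** Each 250 μm generation cell receives objects until
  the drawn area reaches `Σ_pixels clip(baseline(band) + slope × dose,
  0, 1)`; the final budget-exceeding object is stamped with probability
  remaining/area so the expected area is unbiased. This makes the
  realized per-tile fraction track the expected field to a few percent —
  sub-Poisson variance, which is what lets tile-level statistics converge
  on 12-slice cohorts.
* **Bands.** Columns within 600 μm of either lateral edge are "cortex"
  (baseline 0.004), the rest "central brain" (baseline 0.010) — symmetric
  about the midline so sham phantoms are mirror symmetric in expectation.
* **Response.** slope = 0.0015 per Gy of local dose. With the ROI-mean
  local dose at ~0.6 of prescription, the expected right-ROI fraction
  rises from ~0.05 at 45 Gy to ~0.087 at 85 Gy — roughly doubling, the
  regime the headline claim describes. (A linear model with positive
  baseline cannot exceed the 85/45 dose ratio of 1.89.) The absolute
  levels are free parameters of the phantom — the assay's absolute
  GFAP⁺ fractions are not published — chosen so that peak densities
  (~0.14) stay below the regime where stroke overlap merges segments past
  the 1000 μm² filter; measured segmentation recall is ~0.95–0.98,
  i.e. slope attenuation well inside the 30% allowance the recovery tests
  grant.
* **Confounders and noise.** Punctate discs (1–2 px radius) at 20/mm²,
  a smooth background plane (level 1500, ±30% gradient), additive
  Gaussian noise (σ 300 on the 16-bit scale), object amplitudes
  22000 ± 25%. DAPI holds uniformly scattered ~8 μm nuclei and is carried
  as plumbing only.
* **Scale.** Default 2400 × 3000 px at 2 μm/px (4.8 × 6 mm, ~3× coarser
  than the 0.65 μm assay) so a 12-slice cohort runs in ~2 minutes;
  `PhantomConfig.small()` (600 × 800 px, scaled beam, 100 μm tiles,
  0.6 mm ROI) is used for replicate studies. Pixel size is a config field
  everywhere, never hard-coded.

What a green test on the phantom does **not** establish: realistic
astrocyte morphology (no processes-per-cell structure, no 3-D tissue, no
optical PSF), tissue-boundary GFAP peaks, staining variability between
slices, or deformable registration error. The phantom validates the
measurement chain, not the biology.

## Statistics

`scipy.stats.linregress` supplies the OLS fit and the two-sided Wald
t-test (n − 2 df) — the same routine the assay's analysis used. One
departure: for a constant response linregress returns p = NaN (0/0 in the
t statistic); we define p = 1 there, since a zero slope with zero
residual variance cannot reject the null. Per-level summaries use the
sample SD (ddof = 1; NaN for a single slice). The regression runs on
per-slice means (n = 12 for four levels × three slices); sham inclusion
is configurable and on by default. Mixed-effects modelling of
slice-within-animal correlation is out of scope at these cohort sizes.

## Numerical choices and degenerate inputs

* Tile fractions are stored as integer pixel counts over integer tile
  areas, so conservation (Σ fraction × tile area = retained pixels) is
  exact.
* An all-zero dose field gives an empty isodose mask (not an error);
  constant images are rejected by Otsu but only warned about in the 8-bit
  stage; an empty mask yields an empty (not invalid) segment set.
* Pipeline slice seeds derive from one master seed via
  `numpy.random.SeedSequence.spawn`, keeping every generated value below
  2³¹ and the whole run bit-reproducible.
* Profiles assume the beam axis is aligned with the image column axis
  (lateral irradiation geometry); rotated acquisitions should be rotated
  upright before tiling rather than tiled obliquely.

## Known limitations

* The affine registration cannot express the deformable component of real
  slice-to-volume matching; on real data the dose–histology alignment
  error would enter the profiles directly.
* Otsu on a whole slice assumes a reasonably stable foreground fraction;
  slices with almost no GFAP signal would push the threshold into the
  noise floor.
* The cortex/central bands are rectangles supplied by configuration, not
  atlas-derived anatomy; they only approximate the anatomical regions, as
  the underlying assay itself notes.
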