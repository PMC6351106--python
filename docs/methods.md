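# Methods

## Scope and model of the measurement

`lc3quant` quantifies autophagy from registered 2D multi-channel fluorescence
images. The measurement model is deliberately simple and matches common
wide-field practice:

- **Nuclei** are compact, roughly disc-shaped DAPI-bright regions whose
  histogram is bimodal against the background, so a global Otsu threshold on
  the smoothed blue channel separates them.
- **LC3 puncta** are bright, approximately isotropic Gaussian spots of scale
  σ ≈ 1–5 px riding on a flat background. Because vesicle clustering makes
  per-spot counts unreliable, the readout is total puncta area per cell.
- **The tandem reporter** renders every punctum in red (mCherry) and only
  non-acidified puncta in green (GFP); classification is therefore a
  green-positivity decision on red-detected puncta.
- Puncta are assigned to images/conditions, not to individual cells; no
  cytoplasm segmentation is attempted.

All geometry is in pixels: no magnification or physical pixel size is assumed
anywhere. Coordinates are (row, col), 0-based, pixel-centered.

## Nuclear workflow

1. **Smoothing + Otsu** (`make_nuclei_mask`): Gaussian σ = 2 px, then the
   threshold maximizing between-class variance over a 256-bin histogram
   spanning the smoothed raster's own min–max range. A constant raster is a
   hard error ("degenerate histogram").
2. **Watershed split** (`split_touching_nuclei`): seeds are local maxima of
   the Euclidean distance transform with minimum separation
   0.5·√(min_area/π) (≈ 4 px at the default min_area = 200 px²); the
   watershed floods the raw negated distance map. *Numerical choice:* the
   distance map is smoothed (σ = half the seed separation) **for seed
   detection only** — the medial ridge of a border-clipped nucleus is nearly
   flat and otherwise sheds spurious seeds that fragment the nucleus. Seeds
   are relabeled in lexicographic (row, col) order, making the labeling
   deterministic including ties.
3. **Area filter** (`filter_small_regions`): labels below min_area = 200 px²
   are removed; survivors are recompacted to 1..K preserving order.
4. **Fractional counting** (`count_cells`): the mean interior nucleus area is
   estimated over **the whole dataset** (not per image); each border-touching
   label contributes min(1, area/mean). The cap encodes that a clipped
   nucleus cannot represent more than one cell. A dataset with no interior
   nucleus cannot be calibrated and raises.
5. **Bright-cell exclusion** (`flag_bright_cells`): per-nucleus mean intensity
   is measured **on the green (puncta) channel by default** — the purpose of
   the rule is that puncta are indistinguishable over a saturating cell, which
   is a property of the puncta channel; the blue channel is available via
   config. Labels above Q₃ + 1.5·IQR are flagged; fewer than 4 labels flags
   nothing (the fence is meaningless). Flagged labels dilated by
   halo_radius = 25 px form the exclusion mask. Excluded nuclei are ignored
   by *all* downstream accounting, including the effective cell count — the
   cell is removed from numerator and denominator alike.

## Puncta detection

The detector builds scale-normalized responses −σ²·(∇²G_σ ∗ I) at 10 linearly
spaced scales over [1, 5] px, takes 3×3×3 (scale, row, col) local maxima above
threshold, and greedily prunes overlapping detections (disc radius √2σ,
overlap fraction relative to the smaller disc, max 0.5) keeping the stronger
response. Candidates are ordered by (response desc, row, col, σ) so tie-breaks
are deterministic. For an ideal Gaussian spot of scale σ_t the response peaks
at σ = σ_t with magnitude A/2 (amplitude A), which motivates:

- **Threshold**: expressed relative to the raster maximum (default 0.1·max)
  so 8- and 16-bit data behave alike. The pipeline computes the reference max
  over *non-excluded* pixels; otherwise a single saturating bright cell would
  raise the threshold above genuine puncta. `detect_blobs_log` also accepts an
  absolute threshold.
- **Radius coefficient**: radius = √2·σ (the scale-selection optimum relating
  detecting scale to the radius of a Gaussian blob), area = π(√2σ)², so
  area/σ² ≡ 2π exactly. The coefficient is configurable and echoed into run
  metadata.
- **Scale accuracy**: with 10 linear scales over [1, 5] the grid step is
  0.44 px, bounding the quantization error of σ̂ at ~11% for σ ≥ 2 px.

Blobs whose **center pixel** lies in a nucleus label or exclusion halo are
discarded (disk-overlap membership would be stricter; center membership is
the simplest reading of "inside the nucleus region" and is the default).
The optional median despeckler uses truncated in-image neighborhoods at the
borders, so edge pixels are medians of real data, never padding.

## Tandem classification

Detection runs on red because mCherry marks both compartments. The green
background b is the median of green over pixels outside every punctum disk
and outside exclusions; a punctum is an autophagosome iff its disk mean green
exceeds f·b with f = 2.0 by default. A background-relative rule was chosen
over Otsu on the punctum intensities because it remains well-defined when one
class is absent (all-autophagosome or all-autolysosome fields). With the
default rendering (amplitude ≈ 8× background) an autophagosome's disk mean
sits ≈ 5× background, an autolysosome's at ≈ 1×, so f = 2 splits the classes
with a wide margin; f is monotone (raising it can only shrink the
autophagosome count).

## Colocalization

Pearson r per ROI; the default ROI is the whole image minus bright-cell
halos, with a nuclei-excluded ROI available. r is undefined (raised as an
error) when *either* channel is constant on the ROI, since the denominator
vanishes. No Manders/Costes variants are provided. The sampling SD of r is
≈ (1 − ρ²)/√n_eff, where n_eff is reduced by spatial smoothing — the
synthetic pair generator therefore uses light smoothing (σ = 1 px) to keep
texture realistic while keeping n_eff ≈ n/4π large.

## Statistics

Pooled-variance Student's t (not Welch — Welch is behind a flag), two-sided,
df = n₁+n₂−2, α = 0.05; mean ± SD with the n−1 denominator, since replicates
are independent experiments. Degenerate inputs: zero pooled variance with
equal means returns t = 0, p = 1; with unequal means it is an error. No
multiple-testing correction is applied. When replicates are experiments, the
pipeline's per-experiment value is total puncta area over total effective
cells across that experiment's images.

## Synthetic data: what it emulates, and what it does not

The generator renders, per field: cosine-taper-edged nucleus discs
(radius ~ N(18, 2²) px on 512², 12 nuclei of which 2 border-clipped) so the
blue histogram is cleanly bimodal; Gaussian puncta (σ ∈ [2, 4] px, amplitude
800 on background 100, Poisson(6) per cell) placed in an annular cytoplasm
band, never overlapping nuclei, with a minimum center separation (8 px
default); tandem classes drawn Bernoulli(autolysosome_fraction) per punctum;
optional bright cells as a saturating green plateau (20× punctum amplitude)
with a Gaussian halo; and additive Gaussian noise (SD 20, i.e. spot SNR 40)
or Poisson or salt-impulse "speckle" noise. Bright cells receive no puncta of
their own, matching their wholesale exclusion from analysis. Ground truth
records every nucleus (center, radius, border/bright flags), every punctum
(center, σ, class, owner) and the exact effective cell count under the
fractional border rule (computed from rasterized half-amplitude discs, the
same radius Otsu recovers).

Per-image seeds derive from (condition seed, condition index, image index)
via a seed sequence, so datasets are bit-reproducible and the nuclei channel
is invariant to puncta parameters.

Not emulated: real PSFs beyond the Gaussian approximation, 3D stacks, uneven
illumination, autofluorescence, camera-specific noise, cell-to-cell
heterogeneity of puncta brightness, and touching nuclei (the watershed's
splitting is exercised on constructed masks instead). Passing tests therefore
show the pipeline is correct *under its own assumptions*; they do not
certify performance on data that violates them (dense clumped nuclei,
strongly textured cytoplasm, saturated detectors).

## Problem sizes and tolerances used in validation

The validation suite measures: Otsu vs exhaustive search on 50 random 8-bit
bimodal fixtures (exact agreement); effective cell counts on 20 default
fields (±0.5 per image); detection precision/recall on 20 fields of ~50
well-separated puncta (≥6σ spacing; both ≥ 0.95, σ̂ within 20%); suppression
exactness on planted nuclear/halo blobs; a 2× condition contrast over 2×3
experiments of 9 fields (~100+ cells each; ratio within 15%, p < 0.05);
autolysosome fraction 0.4 over ~400 tandem puncta (±5 points); Pearson
identities to 1e-12 and ρ = 0.5 at 512² within ±0.02; t-test hand values and
type-I calibration over 10⁴ null replicates (rate in [0.045, 0.055]); and
byte-identical CSVs on pipeline reruns.

## Known limitations

- Center-pixel suppression can keep a blob whose disk substantially overlaps
  a nucleus; disk-overlap mode exists but is not the default.
- The relative detection threshold couples sensitivity to the brightest
  non-excluded structure in the image; for datasets with strong intensity
  drift an absolute threshold should be configured instead.
- Fractional counting assumes nucleus sizes are comparable across the
  dataset; mixed populations with very different nuclear sizes bias border
  fractions.
- The tandem rule is intensity-thresholded, not ratiometric; it assumes
  roughly uniform GFP brightness across autophagosomes.
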