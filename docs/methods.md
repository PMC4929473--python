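# Methods

## The ranking model

`iqrank` assigns no absolute quality score. Every measure is computed
per image, then divided by its maximum within the processed dataset, so
all measures live on a common 0–1 scale and images are ordered by one
measure or by the mean of several. This makes the method a *relative*,
no-reference ranking: results are only meaningful within one dataset,
and a dataset needs at least two images.

Two assumptions drive the measure design:

1. A good fluorescence image has contrast: bright detail on a dark
   background, with many distinct gray levels in use. The *masked
   histogram entropy* quantifies this.
2. Blur removes fine detail and therefore attenuates the high-frequency
   tail of the power spectrum, while noise inflates it. The *spectral
   tail statistics* quantify this, and because large spatial structures
   (which legitimately differ between images) live at low frequencies,
   only the tail above a frequency threshold is used.

## Contrast: masked histogram entropy

The detail mask selects pixels whose *locally averaged* intensity is in
the top 20%: the image is smoothed with a square uniform mean filter of
side `2r+1` (default `r = 100` px, reflect padding) and thresholded
strictly above the 80th percentile of the smoothed values. The large
filter prevents isolated bright specks (dust, hot pixels) from
qualifying. Strict inequality keeps coverage ≤ 20% even with ties; a
constant image, where nothing is strictly above the threshold, falls
back to an all-true mask so downstream code never sees an empty
selection. For images smaller than the filter the radius is clamped to
`min_dim/2 − 1` with a warning.

The histogram of the *original* pixel values inside the mask is taken
over 256 equal-width bins (natural for 8-bit data; configurable)
spanning the min–max of the selected values, and scored by Shannon
entropy in bits, `H = −Σ Pᵢ log₂ Pᵢ` with `0·log₂0 = 0`. Using the
min–max range means entropy measures occupancy of the values actually
present — contrast-stretch invariance is deliberately not provided; a
fixed sensor range can be passed instead. The log base only rescales
all entropies uniformly and cannot change any ranking.

The percentile is taken over the *smoothed* image (the mask is a
threshold on local averages, not on raw pixels); this is also what makes
the 80/20 split exact on continuous-valued images.

## Detail, blur, noise: spectral tail statistics

The 2D power spectrum is the squared magnitude of the centered discrete
Fourier transform, divided by the image mean gray level and the pixel
count. Before that normalization it satisfies Parseval's identity
(`Σ|F|²/N = Σg²`), which the tests verify; after it, scaling all pixels
by `k` scales the spectrum by exactly `k` (not `k²`), so a common
brightness factor largely cancels between images and never changes rank
order within a series. An all-zero image has no defined normalization
and is rejected.

Two 1D reductions are provided:

- **radial** — mean power at each integer radius (rounded Euclidean
  distance) from the zero-frequency center, up to the maximum inscribed
  radius. Exactly equal, by test, to a brute-force per-pixel binning
  loop.
- **summed** (default, much faster) — all rows summed into a profile
  over horizontal frequency and all columns into one over vertical
  frequency; each folded by adding negative frequencies onto their
  positive twins; the two folded profiles added. For non-square images
  the shorter profile is linearly interpolated onto the longer one's
  frequency-fraction grid before summing.

Frequencies are expressed as fractions of the maximum representable
frequency, so thresholds are image-size independent. Above the
threshold (default **0.40**; **0.02** when a wide blur-detection dynamic
range is wanted, as in autofocus series) the tail yields: fMean, fSTD
(population STD), cv = fSTD/fMean, skewness and excess kurtosis
(moment-based, Fisher convention — the convention shifts values, never
ranks), spectral entropy of the tail renormalized to unit mass, the
summed power above 0.90, and MeanBin, the mean of the first five tail
samples. A tail shorter than five samples raises an error instructing a
lower threshold. A constant tail defines skewness and kurtosis as 0.
The DC sample is excluded by construction (threshold > 0).

Inverse measures (`invSTD`, `invSkew`, `invMeanBin`) are materialized
after dataset normalization as `1 − normalized value`; they favor the
opposite trait (e.g. invSTD favors non-noisy images). Both direct and
inverse columns are emitted in one pass, so a mixed noisy/blurred
dataset needs no second run.

## Autofocus baselines

- **Brenner**: `Σᵢⱼ (G_{i,j+2} − G_{i,j})²`, the classic two-pixel-shift
  squared derivative, computed along the row (horizontal) direction.
  One axis suffices for every monotonicity comparison; the score is
  consequently not transposition-invariant, which is documented
  behavior.
- **Spectral Moments**: the summed 1D spectrum normalized to unit mass,
  then `Σᵢ log₂(1+i)·Pᵢ` over the *entire* spectrum (no tail crop). The
  logarithmic index weight grows with frequency, so high frequencies are
  emphasized relative to an unweighted sum, but far less steeply than a
  tail crop — which is exactly why its dynamic range over a blur series
  is orders of magnitude smaller than fSTD's at the 40% threshold (the
  tests assert this ratio). Both formulas sit in isolated pure functions.

## Ranking, output, triage

Normalization divides each measure column by its dataset maximum
(absolute values first for signed measures — skewness); an all-zero
column maps to zeros with a warning rather than NaN. Composites are
arithmetic means of selected normalized columns. Sorting is stable with
ties broken lexicographically by image id, and never touches the
record order: the results CSV (image id, raw measures, `norm_`-prefixed
normalized measures, inverse columns, optional composite; floats at 9
significant digits) is always written in dataset enumeration order, so
time-course data stays in acquisition order and the source images are
never modified. Two-level triage labels each record from a normalized
score and two cuts: below the low cut `out_of_focus`, between the cuts
`blurred`, above `in_focus`. The cuts themselves are chosen by the
user from a review of the ranked output; the package supplies the
mechanics, not the thresholds.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions for all validation:

- **filaments** — random anti-aliased line segments with Gaussian
  cross-section (σ = 1.5 px), emulating intermediate-filament stains;
- **beads** — 50 Gaussian spots (σ = 2 px) at random positions,
  emulating nanoparticle images;
- **ramp** — a linear horizontal gradient, the designated smooth base;
- **white_noise** — i.i.d. uniform pixels.

Filament and bead images carry additive Gaussian detector noise
(σ = 2 gray levels on the 0–255 scale) and a constant background offset
of 10, as real fluorescence exports do; the ramp is noise-free so the
noise-response property has a clean smooth base, and white noise needs
none. Blur series cover radii 0–29 ("radius" = Gaussian σ, the common
ImageJ-style convention; only the monotone radius–blur relation matters
anywhere). A mixed dataset blurs 12 distinct bases (kinds cycled, seeds
varied) with radii {0, 1, 2}, emulating a photograph collection with
blurred duplicates. The HCS-like time course ramps object count from 3
to ~47 over 30 frames with heavy (σ = 8) and medium (σ = 2) blur at
designated frames, and writes a ground-truth CSV.

**Blur boundary handling.** `gaussian_blur` uses circular (wrap)
convolution. This is a deliberate choice: the spectral measures are
defined on the DFT, whose implicit periodization means a non-periodic
boundary rule (reflect, nearest) injects a border-mismatch artifact
into the spectrum; once genuine content is attenuated (already at
radius ≈ 2 at the 40% threshold) that artifact dominates the tail and
can even *raise* it. Circular convolution is exactly diagonal in the
DFT basis, so every non-zero frequency is attenuated strictly
monotonically in σ and the focus series tests the measures rather than
boundary effects. Total intensity is conserved exactly.

Series are written as 8-bit TIFFs clipped to [0, 255], matching typical
exports. This quantization sets a noise floor: at extreme blur the tail
differences of fSTD/MeanBin fall below one gray level, which is why the
full-range (radii 0–29) monotonicity checks run on the float images
in memory while file-based checks use the moderate radii where the
format is not the limiting factor.

What passing these tests does *not* show: the bases are noiseless-PSF
free abstractions (no Born–Wolf/Gibson–Lanni optics, no photon-count
calibrated noise), image content is stationary apart from the object
count, and all blur is isotropic Gaussian. Real datasets add focus
anisotropy, illumination drift and compression artifacts; the measures
are global statistics and are expected to degrade gracefully, but the
synthetic results quantify the mechanism, not field performance.

## Known limitations and degenerate behaviors

- **fSTD on spectrally flat images**: for a white-noise base the tail
  STD *rises* between radius 0 and 1 before decreasing — a flat
  spectrum has only sampling spread, while mild attenuation creates
  systematic spread. fMean and MeanBin are unaffected. On images with
  decaying spectra (every structured base) fSTD is strictly monotone.
- **Brenner on gradient images under circular blur**: smearing the
  ramp's wrap discontinuity creates steep in-image edges that a spatial
  derivative metric scores higher than the sharp original; Brenner is
  generally the least robust baseline on content that is not a blurred
  version of one structured scene.
- Nearly empty frames legitimately rank below detail-packed ones even
  after spectral normalization (the background offset keeps the mean
  finite while the content power shrinks); triage cuts must be chosen
  with this in mind.
- Measures are global: local defects (a blurred corner, a bright
  artifact) dilute into the whole-image statistic.

## Problem sizes and numerical choices

Validation runs use 128×128 bases for the blur-monotonicity and
mixed-dataset checks, 192×192 for the 30-frame HCS-like series, and
200×200 for the mask-split check — sizes at which every qualitative
property of interest is stable across seeds. Histogram mass sums are
enforced to 1 within 1e-9; intensity conservation under blur to 1e-6
relative; the Parseval identity holds to ~1e-15 in practice. Percentile
thresholds use strict inequality; ranking ties break lexicographically;
all randomness flows through explicit integer seeds
(`numpy.random.default_rng`), making every dataset and results file
bit-reproducible.
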