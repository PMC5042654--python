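# Methods

## Pipeline model and assumptions

The detector treats each pixel's scattering spectrum as a mixture of a few
recurring spectral signatures: the two histological stains and their blends,
the nanoparticle plasmon line, and a red-shifted chromatic-aberration
spectrum that appears on high-contrast tissue edges.  Classification is
purely spectral and per-pixel — no spatial regularization or morphological
cleanup — so every result is reproducible from the spectra alone and
errors stay local.

Assumptions worth stating explicitly:

* **Uniform wavelength axis.** All spectra live on one uniform inclusive
  grid (default 400–1000 nm, 361 samples, 5/3 nm spacing).  Mismatched
  grids are an error, never silently resampled.
* **One preprocessing chain.** Truncate below the noise cutoff (566 nm) →
  Savitzky–Golay smooth → normalize to unit maximum, identically at
  training and classification time.  Max-normalization removes brightness,
  so classification responds to line shape only.
* **Candidates only.** Clustering and classification see only pixels above
  the adaptive candidate threshold.  Dim pixels are never classified; this
  is also the default scoring protocol for sensitivity/specificity.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| cutoff | 566 nm | short-wavelength noise cutoff before clustering |
| SG window / order | 11 samples / 3 | smoothing; preserves ~60 nm-wide plasmon lines on a 5/3 nm grid |
| histogram bins / resample step | 510 / 5 intensity units | segmentation histogram granularity |
| α (background multiplier) | 1.05 | slightly above the first histogram minimum |
| β (tissue-peak multiplier) | 1.5 | candidate threshold above the tissue mode |
| d (vignetting falloff) | 2 mm | fitted instrument constant; pitch 410 × 408 nm at 40× |
| k (clusters) | 4 | stained tissue; 3 for unstained, 2 for particle mixtures |
| k-means seed / restarts | 0 / 10 | k-means++ initialization, deterministic per seed |
| NP band | 833–988 nm | plasmon band for cluster selection and band signal |
| PSF σ | 0.21 λ/NA | Gaussian spot approximation (0.25 µm at 910 nm, NA 0.75) |

α and β are per-study tuning knobs (exposed on the CLI); every other
default is an instrument or protocol constant.

## Numerical and design choices

* **Histogram minimum search.** The 510-bin histogram is linearly re-read
  every 5 intensity units; the background threshold is the first strict
  local minimum after the first *substantial* local maximum (≥ 5 % of the
  histogram's global peak).  The height condition exists because a handful
  of dark outlier pixels can otherwise form a spurious first "peak" at
  intensity ~0 and collapse the background threshold.
* **Savitzky–Golay edges** use the boundary-polynomial fit (no padding), so
  polynomials of degree ≤ order are reproduced exactly end to end.
* **Band membership is closed-interval on wavelengths,** not on indices, so
  band statistics are grid-resolution independent.
* **Centroid ordering.** k-means centroid order is initialization-dependent,
  so learned centroids are re-sorted by peak wavelength and re-normalized to
  unit maximum; training is bit-reproducible given (inputs, k, seed).
* **NP-cluster selection.** Among centroids peaking inside the NP band the
  *narrowest* (fewest samples ≥ 0.5) is the particle line; single-particle
  plasmon resonances are narrow whereas aberration spectra peaking in the
  same band are much broader.  A larger-band-mean rule would invert this
  choice exactly when k-means isolates the edge-artifact spectra into their
  own centroid, which happens routinely once edge pixels are a percent of
  the training pool.  Other in-band centroids are role-tagged `aberration`:
  they count as negative at detection time but are tracked separately.
  Explicit `np_index` always overrides.
* **Ties** in nearest-centroid assignment go to the lowest cluster index.
* **Re-classified training pixels** land on their own k-means cluster up to
  the small perturbation introduced by centroid re-normalization; the test
  suite checks exact agreement of the classifier against a direct distance
  computation, not against the raw k-means labels.
* **Relative NP signal** uses the median (not mean) band signal of NP⁺
  pixels in the denominator; with a single NP⁺ pixel the ratio collapses to
  1/N_tissue by construction.  The statistic is exactly invariant to global
  intensity scaling.
* **Log-method CI** for p = a/n uses SE(ln p) = √(1/a − 1/n); at a = 0 the
  method is undefined and the rule-of-three bound (0, 3/n) is returned.
* **Slide protocol.** Pure-particle preparations have no tissue mode, so the
  peak-based candidate threshold is meaningless; `segment_slide` labels
  every above-background pixel a potential particle.

## The phantom generator

`generate_phantom` composes, in order: tissue blobs (thresholded smoothed
Gaussian random field, 25 % cover) carrying convex mixtures of two broad
stain Gaussians (~560 and ~620 nm, widths ≥ 85 nm) with log-normal
brightness (median peak ≈ 1100 counts); particles as sub-pixel point
sources convolved with the instrument's Gaussian PSF, carrying a Lorentzian
plasmon line (default: intrinsic 820 nm + 80 nm mounting-medium red shift =
900 nm, half-width 30 nm, peak 8000 counts — in dark field a particle
locally outshines tissue); aggregates (10 % of particles) with blue-shifted
split-peak hybridized lines at 1.5× amplitude; edge artifacts on 2 % of
tissue-boundary pixels (broad 915 nm line, 3000 counts); cos⁴ vignetting;
additive Gaussian noise with σ = 5 % of the particle peak, clipped at zero.
Tissue geometry, particle placement, edge placement and noise draw from
independent child streams of the seed, so changing the particle density
leaves the tissue geometry fixed.

**Ground truth for sub-pixel sources.** A point source spread by a
σ ≈ 0.62 px PSF deposits appreciable light in several pixels.  A pixel is
truth-positive when it receives a majority share (> 0.5) of the peak
point-source energy; pixels with a 0.05–0.5 share form a *don't-care halo*
that is excluded from benchmark scoring, because their spectra are
genuinely mixed and their correct label is ill-defined.  Aggregate pixels
are likewise excluded from sensitivity denominators (hybridized spectra are
expected to evade detection) — a flag on the truth masks lets callers widen
the scoring.

**What passing phantoms does and does not show.** The phantom reproduces
the *spectral* structure of the problem (distinct narrow/broad lines,
stain continua, red-shifted edges, medium shifts) and its first-order
spatial structure (PSF spots, vignetting), but not real histology texture,
spatially correlated staining, focus drift, or electromagnetic scattering
physics (the Lorentzian is a surrogate line shape).  Benchmark numbers on
phantoms therefore validate the algorithmic machinery, not instrument-level
diagnostic performance on real sections.

## Benchmark problem sizes

The end-to-end benchmark trains on three 256 × 256 × 361 phantom fields
plus two particle-free controls and tests a held-out field — the full
camera spectral depth at a quarter of the sensor area, enough for ~250
scored particle pixels and ~3400 scored negatives per run.  The
quantification-linearity study uses five particle densities
(0.002–0.03 of tissue pixels) × three 128 × 128 fields each, mirroring the
multi-field-per-condition averaging a biodistribution study would use; the
two-template unmixing study uses 128 × 128 slides.

## Known limitations

* Measurements are relative, not absolute gold mass; there is no
  cross-calibration against elemental analysis.
* Aggregated particles with strongly hybridized spectra are by design not
  detected; uptake in aggregate-rich tissue is underestimated.
* The single-particle check compares against a *pixel-centered* Gaussian;
  detections whose sub-pixel position is near a pixel corner fail the
  profile RMSE even when they are true single particles (the check is a
  confirmatory tool, not a filter).
* The aberration cluster absorbs edge artifacts only as well as the
  negative controls represent them; controls prepared differently from the
  study samples would leave residual edge false positives.
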