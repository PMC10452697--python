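# Methods

## The device and the estimation problem

The package models a chamber-array digital-PCR chip: 108 rows × 198
cylindrical microchambers (21,384 total; the geometric count from rows ×
chambers-per-row is used everywhere, in preference to round-number
descriptions of the array), each 87 µm in diameter and 120 µm tall. The
cylinder volume is π·(d/2)²·h = 0.7133 nL, carried at full precision
internally and rounded only for display (0.71 nL). Where the volume feeds
the concentration formula it is expressed in µL (7.133×10⁻⁴ µL), so
concentrations come out in copies/µL.

Lengths are µm throughout; the chamber pitch (110 µm default) is a
rendering parameter only — it positions chambers in synthetic images and
anchors grid registration but never enters any statistic.

## Partition statistics

Template molecules of each species are loaded into chambers as independent
Poisson draws with per-chamber mean λ_s = C_s·Vd, where C_s is the
in-chamber (final reaction mix) concentration. Independent per-chamber
draws are equivalent to multinomially assigning a Poisson-distributed
total, which is the regime the inversion assumes. The estimator

    C = -ln(1 - d/n) / Vd

is the closed-form maximum-likelihood solution of the binomial likelihood
of observing d positive chambers in n; the test suite checks this
equivalence against numerical likelihood maximization to six significant
digits.

Stock concentrations are mapped to in-chamber concentrations by a
volumetric dilution factor, default 3.5/31.7 ≈ 0.1104 (3.5 µL of serially
diluted template in a ≈31.7 µL reaction mix). The simulator's default
mixture experiment — stock 2×10⁴ copies/µL — therefore loads chambers at
≈2208 copies/µL, i.e. λ ≈ 1.57 and ≈79% positive chambers.

### Confidence intervals

The binomial proportion d/n gets a 95% Wilson score interval (chosen for
its behaviour at very small and very large d), transformed through the
monotone map p ↦ -ln(1-p)/Vd. Conventions at the boundaries:

* d = 0 → C = 0 with the interval [0, C(p_upper)];
* d = n → the estimate is undefined, so the result carries a `saturated`
  flag, reports the lower-bound value obtained with d = n-1, and an
  unbounded upper limit. The default experiment's top dilution (λ ≈ 1.57)
  stays far from saturation.

Replicate chips are combined by pooling counts (Σd, Σn) — equivalent to
one larger partition set — with per-chip estimates reported alongside.

Coverage of the transformed Wilson interval is verified by simulation
(200 chips per occupancy level at λ from 0.01 to 2; observed coverage must
stay ≥ 92% at nominal 95%).

## The synthetic-data generator

The generator is the package's ground-truth oracle. It emulates:

* Poisson loading of any number of template species (species named in the
  panel's target map are mutants; anything else is wild-type);
* detection efficiency as per-molecule binomial thinning (default 1.0);
* unfilled chambers (default fraction 0) that hold no reaction;
* end-point fluorescence per channel as a bimodal model — one intensity
  draw per chamber from Normal(mu_neg, sigma_neg) or
  Normal(mu_pos, sigma_pos), defaults 5,000/30,000 with sigma 1,500 on the
  16-bit scale, plus optional "rain" (a fraction of positives drawn
  uniformly between the two modes);
* imaging: chambers rendered as filled disks on a grid (10 µm/pixel
  default) over a background of 2,000 counts with additive per-pixel
  Gaussian noise (sd 200 default), clipped to 16-bit.

The intensity defaults are arbitrary but well separated (the
positive–negative gap is ≈16 pooled sigmas), which the real assay's
reported clear mode separation justifies; everything is overridable per
channel. Seeds are mandatory; partitioning and rendering consume
independent streams spawned from the one seed, and the seed is echoed into
every output file.

What the generator does **not** emulate: optics (PSF, vignetting,
flat-field error), chamber-to-chamber volume variability, fluorescence
cross-talk between channels, amplification kinetics, and spatially
correlated filling defects. Passing tests therefore demonstrate the
correctness of the statistics and of the image-processing chain under the
stated noise model — not robustness to real-microscope artefacts.

## Image analysis

Because the grid is always known from the layout, chamber recovery is
geometry-driven rather than blob-based: a synthetic disk template built
from the layout is registered to the image by phase cross-correlation
(subpixel, upsampling ×10), and the nominal centres are shifted by the
recovered translation. This guarantees exactly n centres in row-major
order — the same n the Poisson estimate divides by — and is robust to
global translations up to about half a pitch. A normalised correlation
score at the chosen shift serves as the registration diagnostic; low
scores raise an error carrying the score.

Intensities are disk means with the disk shrunk to 0.8 of the chamber
radius to avoid edge pixels. Thresholding is exact two-class 1-D k-means
(optimal split of the sorted intensities by within-class SSE), with the
threshold at the midpoint of the two centroids; this is deterministic and
invariant under positive affine rescaling of intensities. Otsu's method is
available by option. If the two centroids are separated by less than 4×
the pooled within-class SD, the channel is declared to have no positive
population and all chambers are called negative — on a pure-noise channel
two-means centroids sit ≈2.7 pooled SDs apart, while the default bimodal
model yields ≈16, so the factor 4 cleanly separates the two cases while
still allowing a single positive chamber among thousands of negatives to
be called (its within-class SSE contribution is zero). Intermediate
"rain" intensities are handled solely by the threshold; there is no
exclusion band.

Unfilled-chamber detection from images is deliberately conservative: a
chamber is marked unfilled only when an explicit `fill_threshold` is
supplied (all channels below it), because a data-driven background/negative
separation would require knowing the background level, which real readers
calibrate per instrument. By default all chambers are treated as filled;
unfilled chambers, when flagged, are excluded from both d and n (an option
includes them in n).

## Mutation typing

Per mutation, filled chambers partition into double-positive (reference
and mutation channel), wild-only (reference only), empty (neither), and
anomalous (mutation without reference). The mutant concentration is
estimated from double positives only — the reference gate — and the
mutation rate is P = C_mutant/C_reference × 100. The ungated alternative
(all mutation-channel positives) is available for comparison. Note that
with multi-template co-occupancy the gate needs no chamber-exclusivity
assumption: each channel's positive count is inverted independently.

The confidence interval on P combines the two Wilson intervals by interval
arithmetic ([mut_lo/ref_hi, mut_hi/ref_lo]); the two estimates share the
same chambers, so this is conservative (wider than an exact ratio
interval), which is documented behaviour rather than a defect.

A mutation is *detected* when at least one double-positive chamber is
present. At the default study conditions (stock 2×10⁴ copies/µL), a 0.2%
mutant fraction loads an expected ≈67 mutant-positive chambers per chip,
so the probability of a chip with zero double positives is e^(-67) —
detection at 0.2% is effectively certain, and at fraction 0 (with
detection efficiency 1 and no rain) it never fires.

## Study conditions baked into defaults

* dilution series: stocks 2×10¹…2×10⁴ copies/µL, tenfold steps, 20 chips
  per level, pooled per level, linearity assessed by OLS on
  log10(estimate) vs log10(truth). The log scale is the default because
  the series spans four decades and a linear-scale fit is dominated by the
  top level; the linear-scale R² is reported alongside.
* mutation series: fractions 100%, 10%, 1%, 0.2% (and 0 as the negative
  control) of a 2×10⁴ copies/µL total stock, 100 chips per fraction. The
  total concentration for the mutation series is the same stock as the
  quantification series' top level.
* problem sizes: performance tests run at the full 21,384-chamber scale;
  module unit tests use a 600-chamber layout with identical chamber
  geometry, which keeps the whole suite in seconds without changing any
  per-chamber statistics.

## Numerical and design choices

* `log1p`/`expm1` forms are used near the occupancy boundaries.
* The small-occupancy limit C → (d/n)/Vd (within 1% for d/n < 0.02) is
  asserted as a closed-form sanity check.
* Row-major chamber indexing from the top-left; pixel coordinates are
  0-based, x right, y down.
* The image-size cap (8192 px per side by default) guards against
  accidentally rendering at excessive resolution.
* CLI exit codes: 0 success, 2 configuration error, 3 analysis failure;
  every run writes a manifest with the config snapshot, seed and version
  so stochastic outputs reproduce bit-for-bit.

## Known limitations

* No volume-variability (CV of Vd) correction; chamber volume is treated
  as exact, so concentration estimates inherit any systematic volume
  error 1:1.
* No flat-field or illumination correction and no handling of non-grid
  (droplet) partitions.
* The ratio CI on P is conservative, not exact.
* Image-based unfilled detection requires a user-supplied threshold (see
  above).
* The commercial reader's proprietary analysis cannot be compared against;
  the simulator's ground truth is the oracle throughout.
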