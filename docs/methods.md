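# Methods

## Physical model

The scanner is modelled as two parallel planar antenna arrays a distance
`d` apart with the breast compressed between them.  Propagation between a
transmitter and a receiver is a straight ray; refraction, multipath,
radiation patterns and frequency dispersion of tissue are not modelled.  The
2D permittivity map on the mid-plane is assumed homogeneous through the
plate gap, so the delay of the 3D segment (length `L = sqrt(d^2 + offset^2)`)
is `tau = (L/c) * mean(sqrt(eps_r))`, with the mean taken over samples of the
projected 2D segment at a step of half a pixel.  A measured spectrum is a
pure delay shaped by a raised-cosine (Hann) window over the 0.1–8 GHz band
(201 points by default) plus complex white Gaussian noise at a configurable
SNR defined against the mean spectral power.  The identical window is applied
to the air references, so envelope-peak alignment is unbiased; references are
generated per path at the same separation and obliquity.

Reconstruction evaluates the inverse chirp-Z transform of each one-sided
band spectrum on a zoomed time window (0–3 ns, 1024 samples by default; the
window accommodates slab delays for eps_r <= 30 at d <= 90 mm).  Because the
band is one-sided the complex reconstruction is analytic and its magnitude
is the envelope.  The arrival time is the global envelope maximum refined by
three-point parabolic interpolation (the refinement shift is clipped to half
a sample to guard degenerate plateaus).  The arrival-time difference against
the reference inverts to `eps_r = (1 + c*dt/L)^2`; negative differences,
possible under noise, clamp to the air value 1 and are counted in the image
metadata.  Each path estimate is painted on a 6 mm disk footprint at the
path midpoint; overlaps are resolved by unweighted averaging and uncovered
pixels keep the air baseline 1.0.  With the defaults the noiseless
homogeneous round trip is exact to well below 0.1%, and 30 dB SNR perturbs
recovered slab permittivities by well under 1%.

## Array geometry

The plates carry 247 transmitting and 240 receiving antennas.  Their layout
is chosen here as regular 19 x 13 and 20 x 12 lattices spanning the
210 mm x 160 mm aperture (those are the factorizations consistent with the
antenna counts and the plate aspect ratio).  A transmitter is paired with
every receiver within a 25 mm lateral radius, giving 2716 paths — the
pairing rule and radius are free choices constrained by the requirement that
well over 2000 paths cover the aperture.

## Synthetic phantoms and what they emulate

Each phantom is a semi-elliptical breast abutting the chest-wall edge of the
image.  Fat is homogeneous at a per-subject value drawn from eps_r 4–7;
glandular tissue is a Gaussian-smoothed (15 mm correlation length) random
field thresholded to a target areal fraction, with pixel values drawn from a
density-dependent band: A -> [8, 11], B -> [10, 14], C -> [13, 18],
D -> [17, 23].  The bands are chosen so the glandular modes of categories
B/C/D fall in the fixed threshold regions R2/R3/R4.  Default glandular
fractions rise with density (0.20/0.35/0.50/0.65 ± 0.05).  MLO views are
independent texture re-realizations of the same subject parameters with the
imaged breast area scaled by 0.8, reflecting the harder oblique positioning;
the 0.8 factor is a free calibration.  Each subject carries two plate
separations D1 (drawn 50–70 mm) and D2 = D1 − 5 mm; images use the smaller
separation.  The separation is scan metadata only — the compression-induced
property change it implies in real tissue is not modelled.

Healthy left/right asymmetry is controlled by a per-subject parameter `a`
drawn half-normal with mean 0.05: the two sides' glandular fractions are
offset so that the fractional gap of the true breast averages equals `a`.
This calibrates the healthy cohort to the ~1.05 mean CC contralateral ratio
(and keeps the typical gap within the expected 10%).

Tumors are elliptical inclusions whose permittivity is
`(1 + contrast) * expected average of the tissue they replace`.  This
parameterization makes zero contrast an exact no-op in expectation, so the
contrast axis cleanly separates "inclusion present" from "inclusion
detectable"; it is what makes the null comparison at zero contrast
meaningful.  The default contrast 0.9 with 27 mm x 22 mm semi-axes was
calibrated on generator ground truth so a default cancer cohort's true mean
CC ratio is ~1.15.  The absolute inclusion values land at 15–20, i.e. about
10% above the glandular bands, but the inclusions are larger than typical
clinical lesions: in this model only the inclusion itself raises the breast
average, whereas in patients the affected breast differs more broadly, so
the inclusion size absorbs that missing whole-breast effect.  Cancer
subjects carry one tumor on one side, visible in both views of that side by
default (configurable to CC-only/MLO-only to emulate lesions evident in a
single view).

What the generator does **not** emulate: anatomically realistic tissue
layout, 3D structure, compression biomechanics, dielectric dispersion,
positioning variability of small breasts, or any coupling between separation
and tissue properties.  Passing cohort-level tests therefore demonstrates
that the measurement-and-analysis chain recovers the bilateral statistics it
is fed, not that those statistics have clinical sensitivity.

## Segmentation

The breast area is found by two-cluster k-means with the higher-mean cluster
taken as tissue and its largest 8-connected component as the breast.  The
clustering runs on log-permittivity: on raw values the minimum-variance
bipartition of a dense-breast image separates the glandular band from
everything else (the glandular values dominate the variance), which would
shrink the mask to the glandular blobs; log compression makes air-vs-tissue
the dominant split for every density category.  The fat/glandular tissue
split inside the mask runs on raw values with two clusters reported as
ascending means.  Threshold regions use upper-closed bands exactly at
8/13/18, so a pixel at 8 is R1, at 13 R2, at 18 R3.  k-means is Lloyd's
algorithm with k-means++ seeding (10 restarts, seeded), which attains the
optimal scalar bipartition on every small instance we test exhaustively.

## Statistics

The normalized difference `delta = (L - R) / mean(L, R)` and the
contralateral ratio `rho = max/min` are algebraically linked by
`|delta| = 2(rho - 1)/(rho + 1)`.  One-way ANOVA across the four views is
computed from explicit sums of squares; the two-group t-test uses the pooled
variance (the choice between pooled and Welch is open; pooled matches the
F = t^2 identity used as a cross-check).  The two-way group x view ANOVA
uses Type-II sums of squares, the standard choice for testing main effects
in unbalanced designs (20 vs 14 subjects) when the interaction is not given
priority.  Significance is fixed at 0.05 with no multiple-testing
correction.  Ratio comparisons are reported as t-tests (two-sided) alongside
the ANOVA battery; for two groups the two are equivalent.

## Numerical and interface choices

* Millimetres, nanoseconds and GHz throughout; c = 299.792458 mm/ns.
* Pixel (iy, ix) covers a half-open extent with its centre at
  ((ix+0.5)p, (iy+0.5)p); CSV matrices are row = y with row 0 at the
  chest-wall edge, and carry a JSON sidecar with grid and scan metadata.
* Reconstruction is order-independent in the path list, and every stage is a
  pure function of its seed, so a fixed master seed reproduces byte-identical
  pipeline tables.
* A reference permittivity other than air can be passed to the inversion
  chain, but air is the default reference material.
* Each separation yields its own image; downstream analysis uses the smaller
  separation D2.

## Problem sizes

Cohort-level checks run on the full study sizes (20 healthy, 14 cancer) at a
4 mm reconstruction grid and 30 dB SNR, where one scan reconstructs in under
a second.  Physics round-trips use a 60 mm x 40 mm slab grid with a spread
subsample of paths.  The contrast-sweep and null-calibration checks use an
8 mm grid with smaller cohorts (12 cancer subjects for the sweep; ten
repetitions of 6 vs 6 for the null), sizes chosen to estimate the relevant
means and test levels without redundancy.

## Known limitations

* Straight-ray physics understates the blur and bias a real system shows;
  the reconstructed breast average sits a few percent below ground truth
  (path averages of sqrt(eps) are Jensen-biased low in textured media), which
  largely cancels in bilateral ratios but not in absolute averages.
* The breast-area mask inflates slightly at boundaries (footprint spill),
  so reported area ratios are upper estimates at coarse grids.
* With a strong contralateral asymmetry opposing the tumor side, a cancer
  subject's ratio can sit near 1 — inherent to the bilateral statistic, and
  seen in real patients as well.
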