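# tmscan

Transmission microwave breast imaging, simulated end to end.

A planar transmission microwave scanner holds the breast between two antenna
plates — 247 transmitting patch antennas above, 240 receivers below — and
measures ultra-wideband (0.1–8 GHz) signals through the tissue over more than
2000 transmitter/receiver paths covering a ~21 cm × 16 cm aperture, in the
same CC and MLO views as mammography.  Because water-rich glandular and tumor
tissue has a higher relative permittivity εr than fat, a pulse crossing the
breast is delayed by

    τ = (1/c) ∫ √εr(s) ds ,

and comparing its time of arrival against an air reference of the same
thickness yields a path-average permittivity

    εr = (1 + c·Δt / L)² ,   L = √(d² + offset²) ,

which is painted onto a footprint on the mid-plane to form a 2D permittivity
image.  Tumor detection then rests on *bilateral symmetry*: in each view the
two breasts' average permittivities are compared through the contralateral
ratio ρ = max(ε̄_L, ε̄_R) / min(ε̄_L, ε̄_R), which stays near 1.05 for healthy
subjects but is elevated (≈1.15 in the CC view) when one breast carries a
tumor.

No patient scans are public, so this package makes the whole chain
reproducible on synthetic data:

* **`tmscan.phantom`** — bilateral four-view breast phantoms: semi-elliptical
  breasts, fat background (εr 4–7), Gaussian-textured glandular tissue in
  density-dependent bands (categories A–D), a calibrated healthy left/right
  asymmetry, and unilateral ellipsoidal tumor inclusions; cohort generation.
* **`tmscan.forward`** — array lattices, path enumeration, straight-ray
  delays, raised-cosine band-shaped spectra with complex AWGN at a given SNR.
* **`tmscan.recon`** — inverse chirp-Z transform to a zoomed time window,
  envelope-peak arrival times with parabolic refinement, permittivity
  inversion, disk-footprint mapping with overlap averaging.
* **`tmscan.segment`** — k-means breast-area identification, two-cluster
  fat/glandular split, fixed threshold regions R1 (≤8), R2 (8–13], R3
  (13–18], R4 (>18), area summaries.
* **`tmscan.stats`** — normalized differences, contralateral ratios, one-way
  and two-way (Type-II) ANOVA, pooled t-tests, cohort report tables.
* **`tmscan.pipeline` / `tmscan.cli`** — a deterministic end-to-end driver
  (`tmscan run-all --config run.yaml`) plus per-stage subcommands
  (`simulate-cohort`, `forward`, `reconstruct`, `segment`, `analyze`).

## Worked example

Simulate one cancer patient (density C, tumor in the left breast), scan both
CC views at 30 dB SNR and compare the breasts:

```python
from tmscan import (GridSpec, SubjectSpec, FreqSweep, generate_subject,
                    build_array, enumerate_paths, reconstruct_phantom,
                    segment_scan, breast_average, contralateral_ratio)

grid = GridSpec(pixel_mm=4.0)
subject = generate_subject(SubjectSpec("demo", "cancer", density="C", grid=grid), seed=7)
pairs = enumerate_paths(build_array(grid, d_mm=60.0))
eps = {}
for view in ("LCC", "RCC"):
    image = reconstruct_phantom(subject.phantoms[view], pairs, FreqSweep(), snr_db=30.0, seed=1)
    seg = segment_scan(image)
    eps[view] = breast_average(image, seg.breast_mask)
    print(f"{view}: breast average = {eps[view]:.2f} "
          f"(ground truth {subject.true_averages[view]:.2f}), "
          f"area ratio = {seg.breast_area_ratio:.2f}")
print(f"contralateral ratio rho = {contralateral_ratio(eps['LCC'], eps['RCC']):.3f}")
```

prints

```
LCC: breast average = 11.54 (ground truth 12.81), area ratio = 0.38
RCC: breast average = 10.27 (ground truth 11.17), area ratio = 0.38
contralateral ratio rho = 1.123
```

The tumor-bearing left breast reconstructs ~12% higher than the right; the
reconstructed averages track the ground truth (a small downward bias from
path averaging affects both sides alike, so the ratio is preserved).

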