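# introndot

Quantification of nascent-transcription dynamics in syncytial-blastoderm
*Drosophila* embryos from confocal "intron dot" FISH images, together
with a synthetic embryo-image generator that makes the whole pipeline
verifiable end to end without microscope data.

## The scientific problem

In the early fly embryo the Bicoid (Bcd) morphogen gradient drives
*hunchback* (*hb*) transcription in an anterior domain with a sharp
posterior boundary near mid-embryo. Intron-targeted FISH probes light up
nascent transcripts at the gene locus as diffraction-limited puncta
("intron dots"), at most two per nucleus (one per allele), giving a
snapshot of transcriptional activity nucleus by nucleus. Tracking the
mean dot count per nucleus across embryos ranked by age reveals that
Bcd-dependent *hb* transcription shuts down within minutes of entering
the interphase of nuclear cycle 14A, while the *Kruppel* (*Kr*) central
stripe stays active — a dynamic feature of the anterior–posterior (AP)
patterning network.

This package implements the full quantitative analysis behind that kind
of study:

- **Spot calling with a self-calibrating threshold.** Dots are
  8-connected components of suprathreshold pixels on the maximum
  z-projection, with a ≥3-pixel size filter. The per-embryo intensity
  threshold is the lowest level at which no nucleus in the expression
  domain carries more than two dots (two gene copies).
- **Nucleus segmentation** from a nuclear-envelope (WGA) channel: ring
  interiors by Otsu thresholding, hole analysis, area filtering and a
  watershed split for merged pairs.
- **AP profiling.** Each embryo is divided into 50 equal bins of
  fractional embryo length *x/L*; ρ(*x/L*) is the mean dot count per
  nucleus per bin. The expression boundary *x_hb* is the position of
  half-maximal signal; **ρ_plat** is the mean of the 5 consecutive bins
  ending 0.1 *x/L* anterior to *x_hb* (clear of the PS4 stripe), and
  **ρ_peak** the mean of 3 bins centred on a stripe maximum. The same
  binning applied to pixel intensities yields **hb_plat**
  (background-subtracted cytoplasmic mRNA) and **B_max** (raw Bcd
  gradient amplitude).
- **Staging.** Nuclear cycle from nucleus counts (midsagittal dorsal
  counts of ~55–65 → cycle 13, ~70–80 → 14A; surface counts 787–1296 →
  13, 1530–2463 → 14A). Within early cycle 14A, embryos are ranked by
  mean apical–basal nuclear height — which grows nearly linearly,
  doubling in under 15 min — and binned into ~1-min (t1…t9) or ~5-min
  (T1…T4) time classes.
- **Reporting.** Per-class means and SDs, pooled-variance Student's
  t-tests, the shutdown half-time interpolated on the class-mean
  trajectory, and a position-independence diagnostic across the five
  plateau bins.
- **Synthetic embryos.** A generator renders multi-channel surface
  z-stacks (envelope rings + binomially sampled allele puncta under a
  logistic-plus-stripe activity profile q(x)), midsagittal sections with
  time-dependent nuclear elongation, and smooth exponential-gradient /
  mRNA-plateau intensity channels — all with per-nucleus ground truth
  and bit-for-bit seeded reproducibility.

## Worked example

```python
import numpy as np
from introndot import (SynthConfig, sample_nuclei, render_surface, segment_nuclei,
                       fit_axis, attach_axis, calibrate_threshold, detect_dots,
                       assign_dots, bin_rho, find_boundary, plateau_stat)

cfg = SynthConfig()                      # defaults: cycle-14A embryo, L = 310 um
rng = np.random.default_rng(48)
gt = sample_nuclei(cfg, "14A", rng)      # ground truth: nuclei + allele states
images = render_surface(gt, cfg, rng)    # envelope + nascent-transcript channels

table, mask = segment_nuclei(images.envelope)
axis = fit_axis(mask > 0)
table = attach_axis(table, axis)

calib = calibrate_threshold(images.signal, mask, table, expression_domain=(0.05, 0.53))
dots = detect_dots(images.signal, calib.chosen_threshold)
counts = assign_dots(dots, mask, table)

profile = bin_rho(counts.table)
boundary = find_boundary(profile, (0.20, 0.60))
plat = plateau_stat(profile, boundary)
```

This prints (via the obvious `print` calls):

```
nuclei detected:      1932 (true: 1926)
calibrated threshold: 19.9 a.u.
intron dots detected: 939
boundary x_hb:        0.475 x/L (true x_b: 0.48)
rho_plat:             0.914 dots/nucleus (expected 2*q_plat = 1.0)
```

The segmentation finds 1932 of 1926 true nuclei (0.3% error, inside the
1530–2463 capture range typical of cycle-14A surfaces); the calibrated
threshold admits at most two dots per expression-domain nucleus; the
half-maximal boundary lands within half a bin of the generator's true
boundary; and ρ_plat recovers the plateau expectation 2·q_plat to within
the binomial sampling noise of ~1900 nuclei.

Cohort-level analyses (time-class summaries, t-tests, shutdown timing)
run through `introndot.make_cohort` / `introndot.analyze_cohort` or the
`run_pipeline` config runner; `introndot.reference` carries published
per-time-class statistics used to calibrate validation cohorts.

## Command line

```bash
introndot simulate --out embryo/ --seed 3 --midsagittal
introndot segment  --in embryo/surface.tif --out nuclei.csv --mask mask.tif
introndot spots    --in embryo/surface.tif --mask mask.tif --nuclei nuclei.csv --out counts.csv
introndot profile  --nuclei counts.csv --out profile.csv --stats stats.json
introndot heights  --in embryo/midsagittal.tif
introndot stage    --heights heights.csv --scheme t --out classes.csv
introndot analyze  --config pipeline.yaml --out report/
```

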