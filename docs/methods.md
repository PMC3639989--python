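# Methods

This note documents the models behind `introndot`, the parameter choices
that matter, and what the synthetic validation does and does not
establish. All empirical figures quoted here are computed by the test
suite or the acceptance script; nothing below is asserted that the code
does not measure.

## Allele-activity model

Transcriptional activity along the AP axis is a per-allele Bernoulli
probability

q(x) = q_plat · s((x_b − x)/w) + A_s · exp(−(x − x_s)² / 2σ_s²),
clipped to [0, 1],

with s the standard logistic. The logistic term is the Bcd-dependent
anterior domain (plateau probability `q_plat`, boundary `x_b`, width
`w`); the Gaussian term is a Bcd-independent stripe — the PS4 stripe for
*hb*-like patterns (default centre 0.62, σ 0.02) or the central stripe
for *Kr*-like patterns (centre 0.52, σ 0.05). A nucleus's true dot count
is Binomial(`allele_count`, q(x)) with `allele_count = 2`: observed dot
counts rarely exceed two per nucleus, consistent with either
pre-replication transcription or tightly paired sister chromatids, so a
two-copy binomial is the natural generative model. On the plateau the
expected mean dot count is 2·q_plat, which is how validation cohorts are
calibrated: q_plat is set to half the target class mean.

Spurious "false dots" are Poisson per nucleus (default rate 0.05) and
rendered at 10% of the true-punctum amplitude. They model the dim
sub-threshold junk that the intensity calibration is designed to reject;
the non-zero late-class floor of the ρ_plat trajectory is carried by the
residual activity probability itself (the calibration prescription sets
q_plat from the class mean for every class, floor included), not by
surviving false detections. With both mechanisms at once the floor would
be double-counted.

## Image formation

*Surface stacks.* Each nucleus is an envelope-stain ring (Gaussian
stroke, σ 0.2 µm) on a jittered hexagonal lattice inside a 2.7:1
ellipse; densities are calibrated so one imaged surface holds ~500,
~1000 and ~2000 nuclei at cycles 12/13/14A — about half of the
~1500/3000/6000 nuclei on the whole periphery, matching reported capture
ranges (787–1296 for cycle 13, 1530–2463 for 14A). Puncta are isotropic
2-D Gaussians (σ 0.3 µm, a realistic confocal spot width that still
leaves ≥3 suprathreshold pixels per dot at 0.31 µm/pixel) placed inside
their nucleus at a random z-section and split across at most two
adjacent sections (fraction 0.6–1.0 in the brighter section). The two
allele puncta of a 2-dot nucleus are placed near-opposite at 0.70–0.85
of the nucleus radius: alleles sit on distinct chromosome territories,
and this keeps pairs resolvable on the maximum projection at cycle-14A
packing. Punctum amplitudes carry log-normal jitter (σ 0.12).

*Noise.* Additive background (mean 8, SD 1.5 a.u.) plus a
signal-dependent shot-noise term with variance intensity/`photon_scale`
(default 2 counts per a.u.), applied as its Gaussian approximation —
adequate at ≥~5 expected counts per pixel and an order of magnitude
faster than exact Poisson sampling on full stacks. Intensities are
floored at zero and never saturate, matching linear-range acquisition.

*Midsagittal sections.* Peripheral nuclei are elongated envelope rings
with apical edge on the embryo outline and long axis along the local
normal; heights follow h(t) = h0 + k·t with h0 = 5 µm and k = h0/15
µm/min so that height doubles in 15 min. The published analysis relies
on an external height-vs-time fit whose coefficients are not available,
so h0 and k are stand-ins with the documented doubling behaviour; all
staging maps heights to minutes through this same linear model, making
the pipeline self-consistent. The rendered ring is shrunk by the
half-max half-width of the membrane stroke so that the *measured*
outer-edge-to-outer-edge distance equals h(t) — heights are defined
operationally as the distance between the outer membrane edges.

*Intensity channels.* The Bcd-like gradient is B·exp(−x/λ) + offset
(λ = 0.2 x/L) and the mature-mRNA pattern a logistic plateau; both are
rendered over the embryo ellipse with the same noise model. Because a
50-bin average of an exponential underestimates the point maximum,
calibration of validation cohorts inverts the anterior-bin average
analytically (`gradient_amplitude_for`), including the additive camera
background.

## Cohorts and embryo-to-embryo variability

`make_cohort` derives per-embryo seeds deterministically from a master
seed. Embryo ages are the class nominal midpoint plus a uniform jitter
of full width 0.7 min — the published staging uncertainty is ~0.6–0.9
min, and a full-width reading (±0.35 min) is the only one under which
1-min classes remain ~80–90% recoverable, which they empirically are.
Expression levels carry a log-normal embryo-to-embryo factor (unit
mean). For validation cohorts the per-class coefficient of variation is
derived from the published class SDs by removing the per-embryo binomial
sampling noise in quadrature (floored at 3%); a single flat CV would
overstate the spread of exactly the classes with the tightest published
SDs (t2, t3) and understate the loose ones (t5–t7, t9).

## Analysis choices

- **Detection on the maximum z-projection** (8-connectivity, strict
  `>` threshold, ≥3 connected pixels). Dots are counted per nucleus
  across the whole stack and no z-merging rule is published; projection
  is the simplest rule consistent with ≤2 dots/nucleus. A per-z mode
  with xy-overlap chaining across adjacent sections is available
  (`mode="per_z"`).
- **Threshold calibration** scans an ascending grid of intensity
  quantiles (200 steps) of the projected signal restricted to the
  expression domain's bounding box, and returns the smallest candidate
  at which no domain nucleus exceeds two dots. Candidates start at a
  robust noise floor (median + 5 scaled MADs of the projection; one
  tenth of the dynamic range above the median when the background is
  noiseless): below the noise floor the ≤2 constraint loses meaning, as
  shot-noise clusters and footprint merging interact non-monotonically.
  An image with nothing above the floor calibrates trivially to the
  floor (zero detections). The expression domain defaults to
  x/L ∈ [0.05, 0.53) for anterior-domain channels and stripe centre
  ±0.10 for central-stripe channels.
- **Dot assignment**: a dot goes to the label under its centroid, or the
  nearest label within 2 px, else it is discarded (conserved and
  reported).
- **Boundary finding**: the reference maximum is the largest bin value
  in a search window; x_hb interpolates linearly between the last bin at
  or above half-max and the first below it on the most anterior
  *sustained* descent (≥2 consecutive sub-half bins where available —
  a guard against single noisy bins at low signal). The library default
  window is [0.05, 0.60] (excluding the PS4 stripe); the cohort pipeline
  narrows it to [0.20, 0.60] because the anterior cap hosts a variable
  anterior stripe in real data and, at late-class signal levels
  (ρ ~ 0.13 against per-bin sampling noise of similar size), spurious
  anterior crossings otherwise misplace the boundary in a few percent of
  embryos.
- **Plateau statistic**: the 5 consecutive bins whose most posterior bin
  centre is nearest x_hb − 0.1 (exact half-bin ties broken anterior,
  with distances rounded to 9 decimals so ties are not decided by float
  noise). The alternative reading — window *centred* at x_hb − 0.1 — is
  available through the `offset` argument. The window never overlaps
  bins posterior to x_hb.
- **Peak statistic**: argmax bin in the stripe window (ties anterior),
  averaged with its two flanking bins.
- **B_max** is the single maximum bin value of the raw profile; no
  smoothing. Background policy defaults: none for gradient channels
  ("raw" amplitudes), minimum-bin subtraction for mRNA channels.
- **Statistics**: sample SDs use n−1; class comparisons use the
  two-sided pooled-variance Student's t-test (the published analyses
  name Student's test without qualification); all-pairs comparisons are
  reported as raw p-values without multiplicity correction, matching the
  original usage. The shutdown half-time interpolates the class-mean
  trajectory piecewise-linearly against nominal class midpoint times
  (t_k at k − 0.5 min, T_k at 5k − 2.5 min). The background-onset rule —
  first post-peak class whose mean does not differ from the next at
  α = 0.05 — can fire early when class variances are large; it is a
  coarse operationalisation of the published t8-vs-t9 argument.
- **Position independence**: for each embryo the 5 plateau-bin values
  are kept separately; the dispersion index (largest across classes of
  the range of the five per-bin class means over the pooled class mean)
  is this package's own diagnostic, labelled as such in outputs.

## What the synthetic validation shows — and what it does not

The validation cohorts (8 embryos per class, full renders at default
geometry, ~1.9k nuclei per cycle-14A surface) demonstrate that the
pipeline recovers known truth through the complete image-formation →
detection → profiling chain: per-class ρ_plat, ρ_peak, hb_plat and B_max
means within one published SD, boundary positions within half a bin, and
per-nucleus dot counts matching truth for ≥99% of nuclei on noise-free
renders. Detection bias on the plateau statistic is below ~0.015
dots/nucleus across activity levels.

The generator does not emulate several features of real data: optical
sectioning physics (the z-dimension is a placement label, not a PSF
profile), chromatic aberration, embryo flattening mechanics, mitotic
waves, autofluorescence texture, nucleus shape irregularity, or spatial
correlations in background noise. Passing these tests therefore shows
the analysis logic is correct and self-consistent, not that the specific
thresholds would be optimal on any particular microscope's data — the
self-calibrating threshold is designed to absorb exactly that variation.

## Problem sizes and determinism

Validation runs use 9 × 8 (hb), 4 × 8 (Kr) and 4 × 8 (intensity)
cohorts at the default raster (~1024 × 418 px, 9 z-sections), chosen so
the full suite completes in a few minutes on one CPU while keeping
cycle-14A surfaces at their realistic ~2000-nucleus occupancy. Every
stochastic step draws from a single seeded `numpy.random.Generator`
(per-embryo seeds spawned from the master seed), and identical
config + seed reproduce images bit for bit.

## Known limitations

- x_hb is ill-conditioned when the plateau level approaches the per-bin
  sampling noise (late classes); the plateau statistic remains stable
  because any window anterior of the true boundary samples the same
  flat profile, but boundary positions themselves should not be trusted
  below ρ ≈ 0.2 at ~40 nuclei/bin.
- Projection-based detection can merge two puncta that overlap in xy
  regardless of their z separation; at cycle-14A packing this costs
  ≲1.5% of dots. The per-z mode trades this for sensitivity to
  z-splitting.
- The detected-dot monotonicity property (raising the threshold never
  increases the count) holds for resolved puncta but can be violated
  when one merged component splits into two components that both pass
  the ≥3-pixel filter.
- Height-based staging saturates: beyond ~20 min of interphase nuclear
  height stops tracking time, so estimated times are clipped to [0, 20]
  min and classes to t9 / T4.
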