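# Methods

`mcsquant` implements a quantitative fluorescence-microscopy workflow for
asking where an ER-resident protein sits relative to membrane contact
sites (MCS): wavelet-based compartment masking, compartment-normalized
biosensor intensities, a per-cell MCS enrichment index, TIRF/epi ratios,
normalized recruitment traces, contact-site occupancy, and the
nonparametric statistics used to compare cell populations. Because such
experiments are rarely accompanied by public raw data, the package ships a
synthetic-scene generator whose ground truth makes every stage testable.

## Compartment masks: à trous multiscale product

A per-cell image is first normalized to the mean pixel intensity of its
cell ROI (correcting for expression level), then decomposed with the
undecimated ("à trous") wavelet scheme:

- Smoothing kernel: the separable B3-spline Gaussian approximation
  `h = [1/16, 1/4, 3/8, 1/4, 1/16]`, applied rows then columns.
- Scales: `I_s = h_s * I_{s-1}` for s = 1..S (default S = 3), where `h_s`
  is `h` dilated with `2^{s-1} − 1` interleaved zeros.
- Wavelet planes: `W_s = I_{s-1} − I_s` (the *standard* convention, in
  which bright structures give positive coefficients). The opposite sign,
  `W_s = I_s − I_{s-1}`, is available as `sign_convention="literal"`; the
  test suite demonstrates that after clipping negatives the literal
  convention nulls bright structures — it exists for auditability, not use.
- Filtered image: product of the clipped planes `max(W_s, 0)`. Only
  structure supported across all S scales survives the product.
- Mask: `filtered > k × SD(filtered)`, default k = 3. The SD population is
  configurable: the whole per-cell sub-image (default) or in-ROI pixels
  only, which matters for tightly cropped cells. The threshold actually
  used is recorded on the mask object. A zero-variance filtered image
  (constant input) gives an empty mask with a warning, not a failure.

Boundary handling is mirror reflection by default; periodic (`wrap`) is
available, under which the kernel's unit mass makes smoothing exactly
mean-preserving. Images smaller than the dilated kernel support are
rejected for non-periodic boundaries. The whole pipeline (normalization +
relative threshold) is invariant to multiplying the input by any positive
constant.

## Per-cell measures

**Compartment intensity.** Mean of the cell-mean-normalized reporter over
a compartment mask: 1 means "indistinguishable from the cell average";
because the reporter is normalized first, the value is automatically the
ratio to total cell intensity. Empty masks yield NaN with a recorded
status, never 0.

**MCS index.** Three channels (test protein, MCS marker, ER marker) are
each scaled to their in-ROI maximum (range 0–1; a robust upper-percentile
option exists because a single hot pixel otherwise sets the scale). With
`dev_X = mean |I_X − I_test|` over ROI pixels, the index is
`dev_ER − dev_MCS`: positive for MCS-like, negative for ER-like test
proteins. The per-pixel deviation maps are reduced to one scalar per cell
by the in-ROI mean, the minimal-assumption reduction that keeps both
deviations in [0, 1] and the index in [−1, 1]. The index is exactly
antisymmetric under swapping the two markers. For TIRF inputs the
channels are background subtracted (1st-percentile scalar by default)
before scoring.

**TIRF/epi ratio.** Ratio of in-ROI means of background-subtracted TIRF
and epi-illumination images; reports enrichment within the evanescent
field near the basal PM.

**Recruitment traces.** Per-frame in-ROI means are normalized to the mean
over a pre-stimulation frame window (`F_t/F_pre`); the pre-window mean of
the normalized trace is exactly 1 and `∆ = F_t/F_pre − 1`. Optional
non-overlapping frame averaging is provided for low signal-to-noise
time-lapses; it is applied to frames before trace extraction.

**Occupancy.** The fraction of induced contact-site pixels (wavelet mask
of the recruiter channel) whose probe-channel wavelet mask — computed with
the same parameters — is also positive. "Occupied" therefore means
"jointly detected", which is threshold-consistent between the two
channels and monotone under erosion of the probe structure.

**Helical linker length.** `n` tandem EAAAR repeats in an α-helix span
`n × 5 residues × 1.5 Å = 0.75·n nm` (0.75 nm for one repeat, 1.5–7.5 nm
for 2–10 repeats).

## Statistics

Per-cell measures from imaging are rarely Gaussian, so the default
comparison route is nonparametric:

- **Normality screening:** D'Agostino–Pearson K² per group; groups below
  the test's validity floor (n < 8) are reported as missing with a reason.
- **Kruskal–Wallis** omnibus test with tie correction; fully tied data
  yield H = 0, p = 1 rather than an error.
- **Dunn's post-hoc:** z statistics on pooled mean ranks with the tie
  correction `Σ(t³−t)/(12(N−1))`, Bonferroni-adjusted over the declared
  contrast family — every group versus a control, or all pairs. This
  matches the "Dunn's multiple comparison test" convention of Prism.
- **Split-plot two-way ANOVA** for time courses: condition varies between
  cells, time within cells, on natural-log-transformed values (values must
  be strictly positive; offending cells are named). The implementation is
  the balanced split-plot sums-of-squares decomposition with the
  between-cell error term for the condition effect and the within-cell
  error term for time and interaction; it is cross-checked in the tests
  against `pingouin.mixed_anova`. Pairwise condition contrasts use Tukey's
  HSD on cell-level means against the between-cell error. No sphericity
  correction is applied by default; Greenhouse–Geisser is available by
  flag. Cells are treated as independent replicates; experiment IDs are
  carried through but not modelled hierarchically.
- **Summaries:** median, quartiles and percentile whiskers (5–95 or 10–90)
  with linear interpolation between order statistics (Prism-compatible),
  plus mean ± s.e.

Both omnibus procedures are calibration-tested: under seeded null
simulations their type-I error at α = 0.05 must stay within [0.03, 0.07]
(2000 and 1000 replicates respectively).

## Synthetic scenes

The generator emulates the three kinds of data the pipeline consumes:

1. **Confocal sections / TIRF footprints** — an elliptical cell with a
   nuclear exclusion disc; a reticular ER skeleton grown as persistent
   4-connected random branching walks with a minimum inter-tubule spacing
   (emulating the peripheral ER polygon spacing), dilated to the tubule
   width (default 3 px); MCS puncta as discs centred on skeleton pixels
   with enforced separation so they form exactly the configured number of
   connected components; the ER support is extended to include them
   (contact sites are ER subdomains). The PM is a boundary band (confocal)
   or the full adherent sheet (TIRF).
2. **A test-protein channel** mixing the two pools:
   `α·MCS + (1−α)·ER`, scaled by a per-cell expression level
   (lognormal, σ = 0.4 by default); α = 0 is a purely reticular protein,
   α = 1 a purely punctate one. The MCS-marker channel optionally carries a
   faint reticular baseline (default 0.1), as real MCS markers do.
3. **Time-lapse recruitment** — the punctate pattern rises on a constant
   reticular background following one of four kinetic classes:
   fast-transient (τ_rise 10 s, τ_decay 40 s, E-Syt1-like), slow-transient
   (45 s / 180 s, STIM1-like), sustained (saturating rise, τ 90 s,
   Nir2-like) and flat. The pattern is scaled after PSF blurring so the
   in-cell mean at time t is exactly `(1 + ∆(t)) × F_pre`; the noise-free
   recovered trace equals the profile by construction, which is what makes
   it an oracle.

Rendering is density maps → isotropic Gaussian PSF (σ = 1 px default) →
Poisson shot noise at a photon scale (default 200 photons at unit
density) → additive Gaussian read noise (σ = 2 counts) → constant offset
(100 counts): the standard sCMOS Poisson–Gaussian model. One global seed
drives per-scene deterministic substreams (`numpy` `SeedSequence` spawns),
so batches are reproducible cell-by-cell and bit-identical across reruns.

### Calibration of the scene defaults, and what they do not emulate

The default ER skeleton density (0.15 µm per µm² of cell area, with the
cell covering roughly a third of the field) was chosen in a pilot so that
the default mask rule — the product of three clipped planes
thresholded at 3×SD of the filtered image — recovers ≥ 80% of
ground-truth ER pixels on noise-free scenes. This is a property of the
threshold rule: the band-edge pixels of a 3-px tubule carry only about a
third of the crest's multiscale product, so the 3×SD threshold clears
them only when the structure occupies a few percent of the sub-image.
Real cortical ER is considerably denser (on the order of 1–3 µm/µm²), and
on such dense networks this threshold rule segments only tubule cores.
Passing tests therefore demonstrate correctness of the implementation on
recoverable scenes, not segmentation completeness on real micrographs.

Other simplifications: no evanescent-field depth profile (TIRF is a
geometry change plus optional per-compartment brightness factors in
tests), no photobleaching, no drift, no illumination inhomogeneity, flat
fluorophore density within compartments, and an isotropic Gaussian PSF.

## Problem sizes and numerical choices

- Scenes are 128×128 px at 0.1 µm/px; batches for the power analysis use
  3 groups × 30 cells and 100 replicate runs, sized to finish in minutes
  on one CPU.
- Montages tile positions row-major on a near-square grid; the offset
  table maps montage coordinates back to positions losslessly.
- ImageJ ROI rasterization uses half-open pixel boundaries (a pixel
  belongs to a ROI iff its centre is inside the shape); pixel centres
  exactly on a polygon edge are convention-dependent and excluded from
  oracle comparisons in the tests.
- Background subtraction clips negatives to zero and logs the subtracted
  scalar per frame and channel. The 1st-percentile fallback estimator is
  biased low by ≈2.3× the read noise; with shot-noise-dominated cameras
  this is within a couple of counts.
- Quantiles use linear interpolation between order statistics everywhere.
- Missing values (empty masks, zero denominators, undersized groups)
  propagate as NaN with a recorded reason, never as zeros.
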