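# mcsquant

Quantitative fluorescence-microscopy analysis of protein enrichment at
membrane contact sites (MCS) — the regions of ~15–25 nm apposition between
the endoplasmic reticulum (ER) and other organelle membranes, such as
ER–plasma-membrane (ER-PM) junctions.

A recurring question in organelle cell biology is whether an ER-resident
protein (a lipid phosphatase, a tether, a transfer protein) is *enriched*
at contact sites or merely present there because the ER is everywhere.
`mcsquant` implements the image-analysis pipeline used to answer it:

- **À trous wavelet compartment masks.** Per-cell images are normalized to
  the cell-ROI mean, smoothed with the separable B3-spline kernel
  `[1/16, 1/4, 3/8, 1/4, 1/16]` over three dyadically dilated scales, the
  clipped wavelet planes `W_s = I_{s−1} − I_s` are multiplied, and the
  product is thresholded at 3× its standard deviation to give a binary
  ER/PM mask.
- **Compartment-normalized intensities.** Mean biosensor intensity within
  a mask, with the reporter pre-normalized to the cell mean so the value
  is a ratio to total cell intensity (1 = unenriched).
- **MCS index.** For a test protein imaged with an ER marker and an MCS
  marker, each channel max-normalized within the cell ROI, the index is
  `dev_ER − dev_MCS` where `dev_X = mean |I_X − I_test|`: positive for
  MCS-like, negative for ER-like distributions, bounded in [−1, 1].
- **TIRF/epi ratio** for PM-proximal enrichment, **F_t/F_pre recruitment
  traces** (`∆(F_t/F_pre)`) for agonist-evoked relocation, **contact-site
  occupancy** for induced junctions, and the **helical-linker length**
  prediction (0.75 nm per EAAAR repeat).
- **Statistics** as such data demand: D'Agostino–Pearson normality
  screening, Kruskal–Wallis with Dunn's multiple comparisons, and a
  split-plot two-way ANOVA on ln-transformed time courses with Tukey
  contrasts.
- **Synthetic scenes with ground truth.** A seeded generator renders
  reticular ER networks, MCS puncta, mixed test-protein channels and
  recruitment time-lapses through a Poisson–Gaussian camera model, so
  every stage of the pipeline is validated against known truth.

See `docs/methods.md` for the model details, parameter defaults and known
limitations.

## Worked example

Simulate three populations of 10 cells whose test protein is purely
ER-like (mixing fraction α = 0), half-mixed (α = 0.5) or purely MCS-like
(α = 1), measure the MCS index of every cell, and compare groups:

```toml
# run.toml
seed = 1
outdir = "demo/out"
control_group = "er-like"

[groups.er-like]
alpha = 0.0
n_cells = 10

[groups.half-mix]
alpha = 0.5
n_cells = 10

[groups.mcs-like]
alpha = 1.0
n_cells = 10
```

```sh
mcsquant run --config run.toml
```

prints

```
measure: mcs_index
Kruskal-Wallis: statistic = 25.81, p = 2.49e-06

group summaries:
   group  n    median        q1        q3        p5       p95      mean      sem
 er-like 10 -0.020118 -0.021232 -0.018395 -0.022697 -0.017151 -0.019899 0.000652
half-mix 10  0.000368 -0.001098  0.002106 -0.002627  0.003010  0.000363 0.000677
mcs-like 10  0.022173  0.020830  0.023737  0.019880  0.024792  0.022307 0.000598

pairwise comparisons:
  group1  group2        z  p_unadjusted   p_adjusted
half-mix er-like 2.540003  1.108517e-02 2.217033e-02
mcs-like er-like 5.080005  3.774248e-07 7.548496e-07
```

The ER-like population scores a negative median index (its deviation from
the MCS marker exceeds its deviation from the ER marker), the MCS-like
population a positive one, and the mixture sits in between; the
Kruskal–Wallis omnibus test and Dunn's comparisons against the ER-like
control separate the populations despite camera noise and per-cell
expression variation. The same chain is available programmatically
(`mcsquant.pipeline.run_all`) and as separate `simulate`, `measure` and
`stats` commands; every output carries the seed and a hash of the
configuration.

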