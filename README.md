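# swehist

Histogram-based quantitation of breast shear-wave elastography (SWE)
pseudocolor heatmaps, packaged as a tested library and CLI:

- **`swehist.colormap`** — invertible stiffness ↔ RGB lookup on the 0–180 kPa
  scale (linear blue→green→red ramp by default, a jet-like variant for
  sensitivity checks), plus chromatic/achromatic pixel classification so
  grayscale overlays and black signal voids never enter any statistic.
- **`swehist.histograms`** — per-channel (warm/R, intermediate/G, cool/B)
  250-bin histograms over valid pixels, normalized per image; bin-range AUC
  descriptors over the noise (1–14, 201–250), low (15–100) and high
  (101–200) bin ranges; weighted Fisher–Pearson skewness per channel.
- **`swehist.roi_metrics`** — conventional circular-ROI comparators: decoded
  per-pixel kPa mean/min/max/SD and the target/reference Q-box ratio.
- **`swehist.stats`** — two-sample Kolmogorov–Smirnov on vectorized
  histograms (plus a statistically conventional pooled mode), Mann–Whitney
  rank sum (exact enumeration for small samples), Kruskal–Wallis with
  Dunn's post hoc, Shapiro–Wilk screen, and ROC analysis with Youden index
  and sensitivity at fixed specificity.
- **`swehist.simulate`** — seeded synthetic elastogram cohorts (two-component
  soft/intermediate background, lesion disc, optional stiff rim, random
  signal voids) standing in for clinical data; bit-identical regeneration
  under a fixed seed.
- **`swehist.cli`** — `simulate` / `extract` / `compare` / `run-all`
  subcommands wiring the pipeline together deterministically.

## CLI

```sh
# synthetic cohort: PNGs + manifest.csv + truth.csv
swehist simulate --out cohort/ --seed 7 --n-benign 32 --n-malignant 64

# per-image descriptors and normalized histograms
swehist extract --manifest cohort/manifest.csv \
    --out cohort/features.csv --hists-out cohort/hists.csv

# benign-vs-malignant report: KS per channel, rank sums, ROC on the
# cool-channel low-bin AUC biomarker
swehist compare --features cohort/features.csv --hists cohort/hists.csv \
    --out cohort/report.json --ks-mode faithful --spec-targets 0.90

# or everything at once
swehist run-all --out cohort/ --seed 7
```

Cohort parameters can also be given as YAML via `--config` (see
`swehist.simulate.CohortSpec.to_dict()` for the schema). Rerunning any
command with the same inputs produces byte-identical outputs.

Note: the default `faithful` KS mode compares the two groups' mean
normalized histograms as value vectors. This reproduces the original
workflow but treats bin heights as samples, which is statistically
unorthodox; prefer `--ks-mode pooled` for conventional inference.

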