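# lamincycle

Analysis pipeline for the dynamics of **lamin A** — the intermediate-filament
protein of the nuclear lamina — across the cell cycle, built for
imaging-flow-cytometry galleries of single cells and continuous-photobleaching
(CP) recordings from a confocal microscope.

The package is aimed at quantitative cell biologists who have (a) per-cell
multichannel images (brightfield, lamin A, tubulin, chromatin/DNA) and want
phase-resolved localization statistics, and/or (b) CP time traces and want the
free vs chromatin-bound fraction of the protein. Because raw single-cell data
of this kind are rarely redistributable, the package ships a synthetic
ground-truth generator so every stage can be exercised and validated without
any download.

## What it computes

**Serial gating.** Cells are filtered and classified with a serial gate tree:
single cells (brightfield area, aspect ratio), uncropped cells (centroid-x),
focused cells (gradient RMS), exclusion of nuclear-intensity extremes, then a
mitotic split on the lamin A *max pixel* over the peri-nuclear ring — dividing
cells disperse lamin A, so their ring maximum is low. Mitotic cells split into
prophase / metaphase / anaphase by nuclear aspect ratio and nuclear spot
count; telophase is drawn from the non-mitotic pool (low aspect ratio, two
spots); the rest is interphase.

**Masked colocalization.** Per cell, the Pearson correlation between lamin A
(L) and chromatin or tubulin (C), over the cell-area mask only:

    r = Σ (L_mn − L̄)(C_mn − C̄) / sqrt( Σ (L_mn − L̄)² · Σ (C_mn − C̄)² )

with Spearman's ρ alongside as a linearity check. Per-phase summaries give
median, mean, IQR and sign fractions.

**Lamina morphometry.** Cross-section intensity profiles along the cell
diameter, and the periphery/interior ratio: mean lamin A in a 2-px erosion
band of the nuclear mask divided by the mean over the eroded interior.
Ratio > 1 ⇔ lamina assembled (interphase, telophase/early G1); ratio < 1 ⇔
lamin dispersed (prophase, metaphase).

**CP kinetics.** Traces are smoothed (0.1 s window), truncated at laser-on
(maximal derivative), peak-normalized and fitted to

    I(t) = a·e^(−b·t) + c·t + d

where the exponential is the bleaching bound pool and the linear term the
freely diffusing pool. The free fraction is d/(a+d), reported per phase as
mean ± SD in percent.

## Worked example

Simulate a 50-cell gallery (10 per phase), run the imaging pipeline, then fit
65 simulated G1 CP traces:

```
lamincycle simulate-images --n 10 --seed 0 --out gallery
lamincycle all --input-dir gallery --output-dir results
lamincycle simulate-cp --preset G1 --n 65 --seed 0 --out cp_g1.csv
lamincycle cpfit --traces cp_g1.csv --output-dir cp_results
```

`results/labels.csv` classifies all 50 cells correctly (10 per phase).
`results/correlation_summary.csv` shows the cell-cycle trend:

```
     phase             pair  mean_r  median_r  fraction_positive  n_cells
interphase laminA-chromatin   0.856     0.856                1.0       10
  prophase laminA-chromatin   0.456     0.456                1.0       10
 metaphase laminA-chromatin  -0.509    -0.511                0.0       10
 telophase laminA-chromatin   0.794     0.795                1.0       10
interphase   laminA-tubulin  -0.616    -0.617                0.0       10
  prophase   laminA-tubulin   0.140     0.142                1.0       10
 metaphase   laminA-tubulin   0.252     0.252                1.0       10
 telophase   laminA-tubulin  -0.553    -0.553                0.0       10
```

lamin–chromatin correlation collapses from interphase into metaphase and
recovers at telophase, while lamin–tubulin does the opposite — lamin A leaves
the nucleus during early mitosis and mixes with the spindle region. The median
periphery/interior ratios from `results/ratios.csv` (interphase 1.20,
prophase 0.76, metaphase 0.71, telophase 1.22) show the lamina disassembling in
early mitosis and re-forming at telophase. `cp_results/cp_summary.csv`:

```
label  mean_free_fraction_percent  std_free_fraction_percent  n_fits
   G1                       84.97                       0.42      65
```

i.e. the fit recovers the G1 preset's ground truth of 85 % free lamin A.

Every stage is also callable as a library function; see
`lamincycle/pipeline.py` for the orchestration entry points and
`docs/methods.md` for the underlying models and parameter choices.

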