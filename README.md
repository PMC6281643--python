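# pcpquant

Image-based quantification of **planar cell polarity (PCP)** in multiciliated
epithelia (e.g. the ependyma lining the brain ventricles), with a synthetic
epithelial-sheet generator providing full ground truth for every stage.

Multiciliated ependymal cells beat their cilia in a common direction, which
requires two kinds of planar polarity:

- **Translational PCP (tPCP)** — the basal-body (BB) patch of each cell is
  displaced toward one side of the apical surface. It is measured as the
  vector from the cell centre to the BB-patch centroid, with magnitude in
  µm and on-screen angle in [0°, 360°).
- **Rotational PCP (rPCP)** — the cilia of one cell share a beat
  orientation. Each basal body carries a FOP dot adjacent to its
  γ-tubulin dot on the side opposite the basal foot, so the FOP→γ-tubulin
  vector gives a per-BB *rotational angle* (RA) with respect to the
  horizontal axis. Per cell, the mean RA and the circular standard
  deviation CSD = √(−2 ln R̄) (with R̄ the mean resultant length) summarise
  orientation and its spread; genotypes are compared with the two-sample
  Watson U² test (permutation p-value).

The package also quantifies marker localisation at the plasma membrane
(mean fluorescence intensity over a blur → threshold → skeletonize →
dilate membrane selection; membrane dot counts and intensities), classifies
basal-body docking from z-stacks (docked vs scattered, compared with
Fisher's exact test), and implements the supporting statistical decision
tree (D'Agostino–Pearson-gated t vs Mann–Whitney, Kruskal–Wallis with
Dunn's comparisons, 2^ΔCt relative expression).

## Who this is for

Groups quantifying PCP phenotypes from multichannel fluorescence images
(junctional marker + γ-tubulin + FOP + optional quantification channels)
who want a scripted, reproducible replacement for interactive ImageJ/Oriana
workflows — and a simulator with known ground truth to validate every step.

## Worked example

Simulate a two-genotype experiment (WT-like: strong, coordinated polarity;
KO-like: weak displacement, dispersed rotation, sparse membrane dots,
failed docking) and push it through the whole pipeline:

```python
from pcpquant import pipeline

cfg = {
    "seed": 11,
    "n_fields": 2,
    "base": {"field_size_um": [40.0, 40.0], "n_cells": 16, "z_planes": 5,
             "z_step_um": 0.75, "scatter_depth_um": 2.5},
    "docking": {"min_bb": 6},
    "rpcp": {"min_bb": 4},
}
run = "demo_run"
pipeline.run_simulate(cfg, run)
pipeline.run_segment(run)
pipeline.run_tpcp(run)
pipeline.run_rpcp(run)
pipeline.run_membrane(run)
pipeline.run_docking(run)
pipeline.run_report(run)
print(open(run + "/report.txt").read())
```

prints

```
pcpquant report
===============
tpcp  WT: mean displacement 1.91 um (n=13)
tpcp  KO: mean displacement 0.26 um (n=11)
tpcp  test: t_unpaired_two_tailed p=5.22e-15
rpcp  WT: median per-cell CSD 20.6 deg (n=13)
rpcp  KO: median per-cell CSD 77.7 deg (n=11)
rpcp  Watson U2=0.122 p=0.191
membrane  WT: mean dots/cell 20.2
membrane  KO: mean dots/cell 4.3
docking  WT: docked 13 / scattered 0
docking  KO: docked 2 / scattered 9
docking  Fisher p=4.21e-05
```

Reading the numbers: the WT-like arm recovers a mean BB-patch displacement
of 1.91 µm against 0.26 µm in the KO-like arm (unpaired two-tailed t after
both groups pass the normality gate); per-cell rotational spread (CSD) is
~21° in WT vs ~78° in KO; membrane p-MLC-style dot counts and docking
proportions separate accordingly. The Watson U² here compares the
*mean-angle* samples, which share a common tissue direction in this small
demo — dispersion differences show in the CSD comparison. Every output CSV
and JSON embeds the config hash and seed; rerunning with the same
configuration reproduces byte-identical outputs.

The same stages are available on the command line
(`pcpquant simulate|segment|tpcp|rpcp|membrane|docking|report`).

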