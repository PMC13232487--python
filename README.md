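# adipoquant

Quantification of adipose-tissue histology from brightfield micrographs:
adipocyte morphometry from H&E sections and crown-like-structure (CLS)
detection from F4/80-stained IHC sections, with nested per-field →
per-animal → per-group statistics. It is written for researchers studying
adipose inflammation in diet-induced obesity models who need a
reproducible, scriptable replacement for manual or semi-manual image
scoring.

## The method

A CLS is a ring of F4/80-positive macrophages surrounding a dead or dying
adipocyte — the histological hallmark of white-adipose-tissue
inflammation. The pipeline implements the classic thresholding recipe:

1. **Segmentation.** The RGB field is converted to grayscale
   (ITU-R 601 luminance, 0.299 R + 0.587 G + 0.114 B) and a global binary
   threshold (Otsu by default) separates the bright lipid lumina from the
   dark membranes. Each adipocyte is one 8-connected component of the
   foreground. Areas are calibrated as
   `area_µm² = area_px · pixel_size²`. Manual artifact correction is
   replaced by explicit rules: an area band (default 200–16,000 µm²) and
   exclusion of border-touching components.
2. **Stain calling.** A pixel is F4/80-positive iff its raw red-to-blue
   channel ratio strictly exceeds 1.05 (`R/B > 1.05` on the original
   8-bit values).
3. **CLS rule.** For each cell, a morphological membrane annulus
   (dilation ⊖ erosion with a disk of radius 3 px) is scored for stain
   coverage; a cell is a CLS iff the stained fraction of its annulus is
   strictly greater than 0.30 — more than 30 % of the membrane area.
4. **Statistics.** Per-field %CLS and mean adipocyte area are averaged
   within each animal (≥ 10 fields per mouse enforced), group means ± SEM
   are taken across animals, and groups are compared with one-way ANOVA
   plus Tukey's multiple-comparison test (significance at p < 0.05).

Because real annotated micrographs are not required, the package ships a
seeded synthetic-histology generator (`adipoquant.synthetic`) that renders
fields with the statistics the detector assumes — bright circular lumina,
dark membranes, bluish counterstain, reddish stain arcs covering a planted
fraction of each crowned cell's membrane — together with the full per-cell
ground truth, so every stage is validated against planted labels.

## Worked example

Simulate a two-group cohort (control: 5 % of cells crowned; obese: 40 %),
3 animals per group, 10 fields per animal, then run the full pipeline:

```python
from adipoquant import PipelineConfig, simulate_command, run_pipeline
import pandas as pd, json

config = PipelineConfig(output_dir="cohort", master_seed=1)
config.fields_per_animal = 10
simulate_command(config)                 # writes images + truth + manifest

config.manifest = "cohort/manifest.csv"
config.output_dir = "out"
out = run_pipeline(config)
print(pd.read_csv(out / "per_group.csv").to_string(index=False))
stats = json.loads((out / "stats.json").read_text())
print("ANOVA on %CLS: F = {anova_f:.1f}, p = {anova_p:.2e}".format(**stats["pct_cls"]))
```

which prints

```
  group  n_animals  pct_cls_mean  pct_cls_sem  mean_area_um2  sem_area_um2
control          3      6.111111     1.001542    1091.658333     23.828266
  obese          3     36.111111     2.373334    1030.330556     16.960265
ANOVA on %CLS: F = 135.6, p = 3.11e-04
```

The measured group %CLS (6.1 % vs 36.1 %) recovers the planted crown
fractions, the SEM is taken across the 3 animals (the biological
replicate), and the ANOVA flags the group difference. The same run is
available from the shell:

```bash
adipoquant simulate --out cohort --seed 1
adipoquant run --manifest cohort/manifest.csv --out out
```

Other subcommands: `segment` and `detect-cls` for single fields (with
`--ratio-threshold`, `--cls-fraction-threshold`, `--ring-width` overrides)
and `morphometry` to aggregate an existing per-field table.

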