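# circuitquant

Quantitative analysis pipelines for characterizing RAS-sensing synthetic
gene circuits. Engineered circuits that read out oncogenic RAS activity
(e.g. KRAS-G12D vs wild type) are evaluated with four kinds of experiments,
and this package implements the corresponding analysis stages as a tested,
reusable library with a thin CLI:

- **Membrane quantification** — sensors that bind RAS-GTP relocate to the
  plasma membrane. From 3-channel confocal images (nuclear stain, membrane
  stain, reporter), every nucleus seeds one cell, membrane pixels are
  assigned to the nearest nucleus, defective objects (broken rings,
  multi-nucleated cells, debris) are excluded, and each cell's
  membrane-to-total reporter ratio is reported.
- **Cytometry normalization** — per-event tables are gated (live →
  singlets → two-detector true signal → high-transfection bin at control
  > 10³), then summarized per well as AU = frequency-of-parent × mean and
  RU = AU_output / AU_control. Dynamic range between ON (mutant-RAS) and
  OFF (wild-type) wells is a fold change with the delta-method uncertainty
  `sd = fold · sqrt((SD_ON/mean_ON)² + (SD_OFF/mean_OFF)²)`.
- **Part-effect screen** — a Gaussian identity-link model on log10(RU)
  (ordinary least squares) with treatment coding against the reference
  sensor estimates the log10 effect of swapping each circuit part, with
  Wald tests, three nested interaction variants selected by fitted-vs-
  measured correlation, and >100-fold dynamic-range hit calling.
- **Killing assay** — confluence time series are background adjusted to
  the constitutive suicide-gene condition at drug addition
  (`mean(t) + (mean_ref(46h) − mean(46h))`), endpoint killing is the fold
  change control/condition, and conditions are compared to the control by
  one-way ANOVA with Dunnett's test.

Every stage has a synthetic-data generator with attached ground truth
(`circuitquant.synthetic`), so the full pipeline is validated end-to-end
without any experimental data.

## Worked example

```python
import numpy as np
from circuitquant import (ImageSpec, generate_image_set, analyze_image,
                          EventTableSpec, generate_event_table, GateConfig,
                          apply_gates, summarize_well, fold_change)

# a field of 15 cells, 60% of reporter on the membrane, plus defects
spec = ImageSpec(width=384, height=384, n_cells=15, membrane_fraction=0.6,
                 n_broken_ring=2, n_debris=2, noise_sd=5.0, seed=1)
field = generate_image_set(spec)
cells = analyze_image(field.nuclear, field.membrane, field.reporter)
ok = cells[~cells.excluded]
print(f"{len(ok)} cells kept, {cells.excluded.sum()} excluded")
print(f"mean membrane-to-total ratio = {ok.ratio.mean():.3f} (truth 0.6)")

# an ON/OFF well pair with a true 10x expression ratio
cfg = GateConfig()
rus = {}
for cond in ("ON", "OFF"):
    ev = apply_gates(generate_event_table(EventTableSpec(seed=2), cond), cfg)
    rus[cond] = summarize_well(ev, cfg).ru
fc = fold_change([rus["ON"]], [rus["OFF"]])
print(f"RU_ON = {rus['ON']:.3f}, RU_OFF = {rus['OFF']:.4f}, "
      f"dynamic range = {fc.value:.1f}-fold")
```

prints

```
13 cells kept, 4 excluded
mean membrane-to-total ratio = 0.600 (truth 0.6)
RU_ON = 0.506, RU_OFF = 0.0496, dynamic range = 10.2-fold
```

The two broken-ring and two debris objects are excluded with their reasons,
the surviving cells recover the true membrane fraction, and the normalized
cytometry readout recovers the generator's true 10× ON/OFF expression ratio
(10.2-fold measured).

The same stages are available from the shell:

```sh
circuitquant simulate --kind image --seed 3 --out scratch/field
circuitquant membrane-quant --images scratch/ --out scratch/cells.csv
circuitquant screen-glm --table screen.csv --variant auto --out scratch/glm/
circuitquant killing --series conf.csv --reference EF1a_HSVTK \
    --control GFP --out scratch/kill/
```

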