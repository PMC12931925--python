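# Methods

`circuitquant` implements the quantitative analysis stages used to
characterize RAS-sensing synthetic gene circuits: per-cell quantification of
reporter membrane localization from confocal images, flow-cytometry gating
and ratiometric normalization, a log-scale regression screen of circuit-part
effects, and confluence-based killing-assay analysis. Each stage ships with a
matched synthetic-data generator carrying ground truth, so the whole pipeline
is testable without any experimental data.

## Synthetic data: what it emulates, and what it does not

**Images.** Cells are rendered as circles with an annular membrane
(`membrane_thickness`, default 2 px) and a central nucleus
(`nucleus_radius_fraction` = 0.4 of the cell radius). A fraction
`membrane_fraction` of each cell's reporter total (default 5×10⁴ intensity
units) is spread uniformly over the annulus, the rest uniformly over the
interior, so the true membrane-to-total ratio of a rendered cell equals
`membrane_fraction` exactly and total reporter is conserved (plus
`background_level` × area). Three defect classes emulate what a per-cell
pipeline must reject: broken rings (an arc gap of `gap_width` px, emulating
incomplete membrane staining), binucleate cells (two nuclei at 0.8× the
normal nucleus radius, offset ±0.45 r inside one annulus), and debris
(membrane-stain blobs without a nucleus). Placement is rejection sampling
with a safety margin; an impossible density raises rather than silently
overlapping. Noise is additive Gaussian clipped at zero (optional Poisson).
Circular geometry deliberately ignores real cell morphology, optics and PSF:
passing tests demonstrate the correctness of the operators (assignment,
fill, exclusion, ratio arithmetic), not robustness to irregular shapes or
uneven staining.

**Cytometry events.** Each event carries scatter values, a
transfection-control signal, and circuit output read on two detectors.
Transfected events (probability `transfection_efficiency`) draw a base-10
log-normal control signal (`control_mean` = 3.4, `control_sd` = 0.5 log10
units). The efficiency parameter additionally shifts the per-cell dose by
log10(2·efficiency), emulating wells delivered with different plasmid
amounts — the experimental manipulation behind transfection-efficiency
differences. Circuit output is produced only above an
`activation_threshold` on the control channel (default 10³, reflecting that
weakly transfected cells rarely activate the circuit); this nonlinearity is
what makes un-binned normalization sensitive to transfection efficiency and
binned normalization robust, the behaviour the high-transfection bin exists
to exploit. The ON condition multiplies the circuit-driven component by
`output_ratio_on_off`; autofluorescence is added afterwards, so a ratio of 1
reproduces the OFF table bit-for-bit under the same seed. Doublets carry
FSC-H ≈ 0.5 × FSC-A. Spectral spillover and compensation are not modelled.

**Screens.** log10(RU) per well is a sum: condition intercept + log10 part
effects + optional interaction effects + batch offset + centred linear
covariate terms + Gaussian replicate noise (default SD 0.05 log10 units,
3 replicates). Reference levels carry effect 0 by construction, matching the
regression's treatment coding.

**Confluence.** Exponential growth at `growth_rate` (default 0.02 /h from
~10% initial confluence) switching to `growth_rate − kill_rate` at
`kill_onset` (default 46 h, the drug-addition time), clipped to [0, 100]%.
Replicates add Gaussian noise before aggregation to mean ± SD.

## Membrane quantification

Six steps: (1) nuclei are Otsu-thresholded connected components above a
minimum area (default 20 px), labelled in raster-scan order; (2) every
above-threshold membrane pixel is assigned to the nucleus with the nearest
*pixel* (KD-tree over nucleus pixels; exact ties go to the lower label; a
centroid-based alternative is configurable); (3) connected membrane
components are classified — one enclosed nucleus centroid = a cell, several
= multi-nucleated (excluded), none = broken ring or debris; (4) masks are
filled with a 4-connected exterior flood fill, so a ring of thickness ≥ 2 px
is watertight; (5) reporter fluorescence is summed over the membrane and
filled masks; (6) the ratio membrane/total is reported per cell.

A mask is *closed* iff its fill encloses at least `min_interior` pixels
(default = the nucleus minimum area) beyond the membrane itself. Distinguishing
a broken ring from debris is inherently ambiguous when no centroid is
enclosed; the package attributes such a component to the majority owner
nucleus only when that nucleus lies within the component's own pixel radius
(a broken ring surrounds its nucleus; debris sits near someone else's cell).
Exclusion reasons are `non_closed`, `multi_nucleus`, `no_nucleus`,
`below_background` and `too_small`; exclusions are flags, never failures.

No per-pixel background subtraction is applied before summation; background
enters only as an inclusion threshold on per-cell totals, estimated as an
upper quantile (default 99th percentile) of total-cell fluorescence in
untransfected control images. Both the quantile and all thresholds are
configurable because the underlying experimental convention leaves them
open.

## Cytometry normalization

Hand-drawn gates are replaced by parametric stand-ins: a rectangular live
gate on (FSC-A, SSC-A), a singlet band |FSC-H/FSC-A − 1| ≤ 0.2, and a
two-detector agreement band of factor k = 3 on the log scale after removing
the median offset (which absorbs the detectors' gain ratio). The
high-transfection bin keeps events with control signal strictly above 10³.
AU = frequency-of-parent × mean fluorescence among positive cells
(positivity default: above a fixed threshold, estimable as the 99th
percentile of untransfected events); RU = AU_output / AU_control. Means are
arithmetic on the linear fluorescence scale. Dynamic range is
mean_ON/mean_OFF over replicate RU values with the first-order propagated
SD fold × sqrt(CV_ON² + CV_OFF²); replicate SDs use the n−1 denominator. A
zero OFF mean is reported as an infinite dynamic range, not an exception.

## Part-effect regression

The Gaussian identity-link model on log10(RU) is fitted by ordinary least
squares — the same estimator, with Student-t Wald p-values per coefficient
(matching what a Gaussian GLM summary reports at these sample sizes).
Treatment coding uses the reference circuit (EF1a-driven sensor, RBDCRD
binding domain, 6× flexible linker, VP48 transactivation domain), so each
coefficient is the log10 change in output when one reference part is
swapped. Covariates (transfection efficiency, plasmid amounts) enter as
numeric columns; batch as a fixed-effect factor if included among the
factors. Three nested interaction variants are provided — (1) none,
(2) response element × regulated component, (3) variant 2 plus response
element × transactivation domain and the three-way term — as configurable
stand-ins; explicit interaction tuples can replace them. Model selection
fits all candidates and keeps the best fitted-vs-measured Pearson R²
(Spearman is reported alongside), breaking exact ties toward fewer
parameters; since the variants are nested, interaction-bearing data reliably
selects variant 3. Rank-deficient designs raise an error naming the aliased
columns rather than silently dropping them. p-values are reported raw (an
optional Holm adjustment is deliberately not applied by default). Hits are
circuits with dynamic range > 100-fold; the default rule annotates the
propagated SD, a strict variant requires fold − SD > 100.

## Killing assays

Confluence series are background adjusted to the constitutive-HSV-TK
reference at the drug-addition time (46 h): a constant offset
(reference@46 − series@46) is added to every time point. SDs are left
unchanged — the adjustment is a rigid shift of the mean, and recomputing
replicate SDs after a deterministic shift would not change them anyway.
Endpoint killing (default 180 h) is the fold change control/condition, so
stronger killing gives a larger fold, with the same delta-method SD as the
cytometry fold change. Conditions are compared to the control by one-way
ANOVA followed by Dunnett's many-to-one test (multivariate-t formulation,
as implemented in scipy), requiring ≥ 2 replicates per group.

## Numerical choices and edge cases

- All generators derive their randomness from one integer seed through
  `numpy.random.SeedSequence`; identical spec + seed is bit-reproducible.
- Distance ties in nearest-nucleus assignment are exact: squared pixel
  distances are integers, so floating-point equality is reliable.
- Constant images produce zero nuclei (not an error); zero nuclei make
  membrane assignment an explicit error (nothing to assign to).
- A cell with zero total signal is excluded with a reason, never a division
  error; FSC-A = 0 events simply fail the singlet gate; nonpositive detector
  values are floored at the instrument minimum before logging.
- Validation sizes: the recovery sweep uses 200 noise-free cells per
  membrane fraction; null-calibration runs use 1000 model fits and 1000
  Dunnett simulations; `scripts/acceptance.py` uses moderately smaller
  replicates (500 fits/simulations, 8 binning seeds) as its standard
  problem sizes.

## Known limitations

Circular cells only; no 3-D segmentation or learned segmentation. No FCS
file ingestion (event tables are CSV/DataFrame). No spillover compensation
or automated gate learning. The three interaction variants are plausible
stand-ins, not a recovered specification of the original candidate models.
Mixed-effects treatment of batch, dose–response fitting and bystander-effect
modelling are out of scope.
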