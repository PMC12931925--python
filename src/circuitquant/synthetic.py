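"""Synthetic data generators with attached ground truth.

Every downstream stage of the package (membrane quantification, cytometry
normalization, part-effect regression, killing-assay analysis) is exercised on
data produced here, so each generator returns both the observable data and the
latent truth used to produce it.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so individual stages can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageSpec",
    "GroundTruthImage",
    "EventTableSpec",
    "ScreenSpec",
    "ConfluenceCondition",
    "ConfluenceSpec",
    "ConfluenceSeries",
    "ScreenTable",
    "generate_image_set",
    "generate_event_table",
    "generate_screen_table",
    "generate_confluence",
    "confluence_curve",
]

DEFECT_NONE = "none"
DEFECT_BROKEN = "broken_ring"
DEFECT_BINUCLEATE = "binucleate"
DEFECT_DEBRIS = "debris"


# ---------------------------------------------------------------------------
# Microscopy images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Parameters for a 3-channel (nuclear / membrane / reporter) field of cells.

    Cells are circles with an annular membrane of ``membrane_thickness`` pixels
    and a central nucleus; ``membrane_fraction`` of each cell's total reporter
    signal is spread uniformly over the annulus and the remainder uniformly
    over the interior.  Defect cells emulate the failure modes a per-cell
    segmentation pipeline must reject: broken rings (incomplete membrane
    staining), binucleate cells, and nucleus-free membrane-stain debris.
    """

    width: int = 256
    height: int = 256
    n_cells: int = 12
    cell_radius_range: tuple[float, float] = (9.0, 12.0)
    membrane_thickness: float = 2.0
    nucleus_radius_fraction: float = 0.4
    membrane_fraction: float = 0.5
    reporter_total: float = 50_000.0
    n_broken_ring: int = 0
    gap_width: float = 4.0
    n_binucleate: int = 0
    n_debris: int = 0
    noise_sd: float = 0.0
    background_level: float = 0.0
    nuclear_intensity: float = 1000.0
    membrane_intensity: float = 1000.0
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells < 0 or self.n_debris < 0:
            raise ValueError("object counts must be nonnegative")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError("cell_radius_range must satisfy 0 < lo <= hi")
        if not 0.0 <= self.membrane_fraction <= 1.0:
            raise ValueError("membrane_fraction must lie in [0, 1]")
        if not 0.0 < self.nucleus_radius_fraction < 1.0:
            raise ValueError("nucleus_radius_fraction must lie in (0, 1)")
        if self.membrane_thickness <= 0:
            raise ValueError("membrane_thickness must be positive")
        if self.n_broken_ring + self.n_binucleate > self.n_cells:
            raise ValueError("defect cell counts exceed n_cells")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")


@dataclass
class GroundTruthImage:
    """A rendered field plus the per-object truth table.

    ``cells`` has one row per synthetic object with columns
    ``cell, row, col, radius, membrane_fraction, defect``.
    """

    nuclear: np.ndarray
    membrane: np.ndarray
    reporter: np.ndarray
    cells: pd.DataFrame
    spec: ImageSpec

    def to_tiff(self, path) -> None:
        """Write channels as a (3, H, W) multi-channel TIFF (nuclear, membrane, reporter)."""
        stack = np.stack([self.nuclear, self.membrane, self.reporter]).astype(np.float32)
        tifffile.imwrite(path, stack, photometric="minisblack")

    @staticmethod
    def from_tiff(path, cells: pd.DataFrame | None = None,
                  spec: ImageSpec | None = None) -> "GroundTruthImage":
        stack = tifffile.imread(path).astype(float)
        if stack.ndim != 3 or stack.shape[0] != 3:
            raise ValueError("expected a (3, H, W) channel stack")
        empty = pd.DataFrame(columns=["cell", "row", "col", "radius",
                                      "membrane_fraction", "defect"])
        return GroundTruthImage(stack[0], stack[1], stack[2],
                                cells if cells is not None else empty,
                                spec if spec is not None else ImageSpec())


def _place_centers(rng: np.random.Generator, spec: ImageSpec,
                   radii: np.ndarray) -> np.ndarray:
    """Rejection-sample non-overlapping circle centers with a safety margin."""
    margin = spec.membrane_thickness + 3.0
    centers: list[tuple[float, float]] = []
    max_tries = 20_000 * max(len(radii), 1)
    tries = 0
    for i, r in enumerate(radii):
        pad = r + margin
        if 2 * pad >= min(spec.width, spec.height):
            raise RuntimeError("cells too large for the requested image size")
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "could not place non-overlapping cells at the requested "
                    "density; reduce n_cells or enlarge the image"
                )
            cr = rng.uniform(pad, spec.height - pad)
            cc = rng.uniform(pad, spec.width - pad)
            ok = True
            for j, (pr, pc) in enumerate(centers):
                if math.hypot(cr - pr, cc - pc) < r + radii[j] + margin:
                    ok = False
                    break
            if ok:
                centers.append((cr, cc))
                break
    return np.asarray(centers, dtype=float).reshape(len(radii), 2)


def _disk_coords(shape, cr, cc, radius):
    """Row/col index grids of the bounding box around a circle, with distances."""
    h, w = shape
    r0 = max(int(np.floor(cr - radius)) - 1, 0)
    r1 = min(int(np.ceil(cr + radius)) + 2, h)
    c0 = max(int(np.floor(cc - radius)) - 1, 0)
    c1 = min(int(np.ceil(cc + radius)) + 2, w)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    dist = np.hypot(rows - cr, cols - cc)
    return (slice(r0, r1), slice(c0, c1)), dist, rows, cols


def generate_image_set(spec: ImageSpec) -> GroundTruthImage:
    """Render one synthetic 3-channel field according to ``spec``.

    Deterministic given ``spec.seed``.  Raises :class:`RuntimeError` when
    overlap-free placement is impossible at the requested density.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    h, w = spec.height, spec.width

    n_total = spec.n_cells + spec.n_debris
    lo, hi = spec.cell_radius_range
    cell_radii = rng.uniform(lo, hi, size=spec.n_cells)
    debris_radii = rng.uniform(0.3 * lo, 0.5 * lo, size=spec.n_debris)
    radii = np.concatenate([cell_radii, debris_radii])
    centers = _place_centers(rng, spec, radii)

    # defect labels for the real cells, in random positions
    labels = np.array([DEFECT_BROKEN] * spec.n_broken_ring
                      + [DEFECT_BINUCLEATE] * spec.n_binucleate
                      + [DEFECT_NONE] * (spec.n_cells - spec.n_broken_ring
                                         - spec.n_binucleate))
    rng.shuffle(labels)
    labels = np.concatenate([labels, np.array([DEFECT_DEBRIS] * spec.n_debris)])

    nuclear = np.zeros((h, w))
    membrane = np.zeros((h, w))
    reporter = np.zeros((h, w))

    records = []
    for i in range(n_total):
        cr, cc = centers[i]
        r = radii[i]
        defect = labels[i]
        box, dist, rows, cols = _disk_coords((h, w), cr, cc, r)

        if defect == DEFECT_DEBRIS:
            blob = dist <= r
            membrane[box][blob] = spec.membrane_intensity
            records.append((i, cr, cc, r, np.nan, defect))
            continue

        annulus = (dist <= r) & (dist > r - spec.membrane_thickness)
        interior = dist <= r - spec.membrane_thickness

        if defect == DEFECT_BROKEN:
            # carve an arc gap of chord length ~gap_width at a random bearing
            theta = np.arctan2(rows - cr, cols - cc)
            gap_center = rng.uniform(-np.pi, np.pi)
            half = spec.gap_width / (2.0 * max(r - spec.membrane_thickness / 2, 1.0))
            dtheta = np.angle(np.exp(1j * (theta - gap_center)))
            annulus = annulus & (np.abs(dtheta) > half)

        membrane[box][annulus] = spec.membrane_intensity

        nuc_r = spec.nucleus_radius_fraction * r
        if defect == DEFECT_BINUCLEATE:
            ang = rng.uniform(0, 2 * np.pi)
            off = 0.45 * r
            for s in (-1.0, 1.0):
                ncr = cr + s * off * math.sin(ang)
                ncc = cc + s * off * math.cos(ang)
                nbox, ndist, _, _ = _disk_coords((h, w), ncr, ncc, 0.8 * nuc_r)
                nuclear[nbox][ndist <= 0.8 * nuc_r] = spec.nuclear_intensity
        else:
            nbox, ndist, _, _ = _disk_coords((h, w), cr, cc, nuc_r)
            nuclear[nbox][ndist <= nuc_r] = spec.nuclear_intensity

        f = spec.membrane_fraction
        n_ann = int(annulus.sum())
        n_int = int(interior.sum())
        rep = np.zeros_like(dist)
        if n_ann:
            rep[annulus] = f * spec.reporter_total / n_ann
        if n_int:
            rep[interior] = (1.0 - f) * spec.reporter_total / n_int
        reporter[box] += rep
        records.append((i, cr, cc, r, f, defect))

    reporter += spec.background_level

    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            for chan in (nuclear, membrane, reporter):
                chan += rng.normal(0.0, spec.noise_sd, size=chan.shape)
                np.clip(chan, 0.0, None, out=chan)
        else:
            scale = spec.noise_sd  # Poisson: sd parameter acts as gain
            for chan in (nuclear, membrane, reporter):
                chan[:] = rng.poisson(np.clip(chan / scale, 0, None)) * scale

    cells = pd.DataFrame(records, columns=["cell", "row", "col", "radius",
                                           "membrane_fraction", "defect"])
    return GroundTruthImage(nuclear, membrane, reporter, cells, spec)


# ---------------------------------------------------------------------------
# Flow-cytometry event tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventTableSpec:
    """Parameters for a per-event cytometry table.

    Transfected events carry a base-10 log-normal transfection-control signal
    (``control_mean``/``control_sd`` on the log10 scale).  ``transfection_efficiency``
    sets both the transfected fraction and a per-cell plasmid-dose shift of
    ``log10(2 * efficiency)`` on the control channel, emulating wells delivered
    with different plasmid amounts.  Circuit output is produced only by cells
    whose control signal exceeds ``activation_threshold`` (cells below it
    rarely activate the circuit); the ON condition multiplies that circuit
    component by ``output_ratio_on_off``.  The output is read on two detectors
    with correlated signal and independent measurement noise.
    """

    n_events: int = 20_000
    transfection_efficiency: float = 0.5
    control_mean: float = 3.4     # log10 fluorescence units among transfected
    control_sd: float = 0.5       # log10 units
    output_ratio_on_off: float = 10.0
    autofluorescence_level: float = 10.0
    doublet_fraction: float = 0.05
    activation_threshold: float = 1e3     # control units; below: no circuit output
    output_rate: float = 0.05             # OFF-state output per unit control
    detector_noise_sd: float = 0.05       # log10 units, independent per detector
    detector2_gain: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if not 0.0 < self.transfection_efficiency < 1.0:
            raise ValueError("transfection_efficiency must lie in (0, 1)")
        if self.output_ratio_on_off <= 0:
            raise ValueError("output_ratio_on_off must be > 0")
        if not 0.0 <= self.doublet_fraction < 1.0:
            raise ValueError("doublet_fraction must lie in [0, 1)")
        if self.control_sd < 0 or self.detector_noise_sd < 0:
            raise ValueError("scale parameters must be >= 0")


def generate_event_table(spec: EventTableSpec, condition: str) -> pd.DataFrame:
    """Draw one well's events for ``condition`` in {"ON", "OFF"}.

    Columns: ``fsc_a, fsc_h, ssc_a, output_d1, output_d2, control`` plus the
    ground-truth ``truth_transfected, truth_doublet, truth_output``.  The same
    seed yields the same draws for both conditions, with the ON condition's
    circuit output scaled by ``output_ratio_on_off``.
    """
    spec.validate()
    if condition not in ("ON", "OFF"):
        raise ValueError("condition must be 'ON' or 'OFF'")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_events

    transfected = rng.random(n) < spec.transfection_efficiency
    doublet = rng.random(n) < spec.doublet_fraction

    fsc_a = 10 ** rng.normal(5.0, 0.08, n)
    fsc_a = np.where(doublet, 2.0 * fsc_a, fsc_a)
    fsc_h = fsc_a * np.where(doublet, 0.5, 1.0) * (1.0 + rng.normal(0, 0.03, n))
    ssc_a = 10 ** rng.normal(4.8, 0.12, n)

    dose_shift = np.log10(2.0 * spec.transfection_efficiency)
    control = np.where(
        transfected,
        10 ** (spec.control_mean + dose_shift + rng.normal(0, spec.control_sd, n)),
        spec.autofluorescence_level * 10 ** rng.normal(0, 0.2, n),
    )

    active = transfected & (control > spec.activation_threshold)
    base_output = np.where(active, spec.output_rate * control, 0.0)
    ratio = spec.output_ratio_on_off if condition == "ON" else 1.0
    true_output = base_output * ratio

    d1_noise = 10 ** rng.normal(0, spec.detector_noise_sd, n)
    d2_noise = 10 ** rng.normal(0, spec.detector_noise_sd, n)
    autofl1 = spec.autofluorescence_level * 10 ** rng.normal(0, 0.2, n)
    autofl2 = spec.autofluorescence_level * 10 ** rng.normal(0, 0.2, n)
    output_d1 = true_output * d1_noise + autofl1
    output_d2 = true_output * spec.detector2_gain * d2_noise + autofl2

    return pd.DataFrame({
        "fsc_a": fsc_a,
        "fsc_h": fsc_h,
        "ssc_a": ssc_a,
        "output_d1": output_d1,
        "output_d2": output_d2,
        "control": control,
        "truth_transfected": transfected,
        "truth_doublet": doublet,
        "truth_output": true_output,
    })


# ---------------------------------------------------------------------------
# Part-effect screens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSpec:
    """Ground truth for a combinatorial circuit-part screen.

    ``parts`` maps each factor (e.g. response element, regulated component,
    binding domain, transactivation domain, linker) to its levels;
    ``reference`` names the reference level per factor, which carries effect 0
    by definition.  ``effects[factor][level]`` is a pair of log10 effects
    (ON condition, OFF condition) for each non-reference level.
    ``interaction_effects`` entries are ``(level_map, eff_on, eff_off)`` added
    to rows matching every (factor, level) pair in ``level_map``.  Covariates
    enter linearly on the log10 scale, centred at their range midpoints.
    """

    parts: dict[str, tuple[str, ...]] = field(default_factory=lambda: {
        "response_element": ("RE1", "RE2"),
        "regulated_component": ("NarL", "NarX"),
        "binding_domain": ("RBDCRD", "RBD"),
        "transactivation_domain": ("VP48", "FLT"),
        "linker": ("6x_flex", "2x_flex"),
    })
    reference: dict[str, str] = field(default_factory=lambda: {
        "response_element": "RE1",
        "regulated_component": "NarL",
        "binding_domain": "RBDCRD",
        "transactivation_domain": "VP48",
        "linker": "6x_flex",
    })
    effects: dict = field(default_factory=dict)
    interaction_effects: tuple = ()
    intercept_on: float = 0.5      # log10 RU in the ON (mutant-RAS) condition
    intercept_off: float = -1.0    # log10 RU in the OFF (wild-type) condition
    n_replicates: int = 3
    n_batches: int = 1
    batch_sd: float = 0.0
    replicate_sd: float = 0.05
    covariate_ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "transfection_efficiency": (0.3, 0.7),
        "narx_amount": (5.0, 15.0),
        "narl_amount": (5.0, 15.0),
    })
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.parts or any(len(v) == 0 for v in self.parts.values()):
            raise ValueError("part catalog must be non-empty for every factor")
        for f, ref in self.reference.items():
            if f not in self.parts or ref not in self.parts[f]:
                raise ValueError(f"reference level {ref!r} unknown for factor {f!r}")
        for f in self.parts:
            if f not in self.reference:
                raise ValueError(f"factor {f!r} lacks a reference level")
        for f, levels in self.effects.items():
            if f not in self.parts:
                raise ValueError(f"effects refer to unknown factor {f!r}")
            for lev in levels:
                if lev not in self.parts[f]:
                    raise ValueError(f"effects refer to unknown level {lev!r} of {f!r}")
                if lev == self.reference[f]:
                    raise ValueError(f"reference level {lev!r} must carry effect 0")
        for level_map, _, _ in self.interaction_effects:
            for f, lev in level_map.items():
                if f not in self.parts or lev not in self.parts[f]:
                    raise ValueError(f"interaction refers to unknown level {lev!r} of {f!r}")
        if self.batch_sd < 0 or self.replicate_sd < 0:
            raise ValueError("all SDs must be >= 0")
        if self.n_replicates < 1 or self.n_batches < 1:
            raise ValueError("n_replicates and n_batches must be >= 1")


@dataclass
class ScreenTable:
    """One row per circuit configuration x RAS condition x replicate, with truth."""

    data: pd.DataFrame
    truth: pd.DataFrame          # factor, level, effect_on, effect_off
    truth_interactions: pd.DataFrame
    spec: ScreenSpec


def generate_screen_table(spec: ScreenSpec) -> ScreenTable:
    """Simulate a full-factorial screen with log10-additive part effects.

    log10(RU) per row = condition intercept + sum of its levels' effects
    + matching interaction effects + batch effect + centred covariate terms
    + replicate noise.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    factors = list(spec.parts)
    combos = list(itertools.product(*(spec.parts[f] for f in factors)))
    batch_offsets = rng.normal(0.0, spec.batch_sd, spec.n_batches) if spec.batch_sd > 0 \
        else np.zeros(spec.n_batches)

    cov_names = list(spec.covariate_ranges)
    rows = []
    for ci, combo in enumerate(combos):
        level_of = dict(zip(factors, combo))
        part_eff_on = part_eff_off = 0.0
        for f, lev in level_of.items():
            eff = spec.effects.get(f, {}).get(lev)
            if eff is not None:
                part_eff_on += eff[0]
                part_eff_off += eff[1]
        for level_map, ion, ioff in spec.interaction_effects:
            if all(level_of.get(f) == lev for f, lev in level_map.items()):
                part_eff_on += ion
                part_eff_off += ioff
        for rep in range(spec.n_replicates):
            batch = rep % spec.n_batches
            covs = {name: rng.uniform(lo, hi)
                    for name, (lo, hi) in spec.covariate_ranges.items()}
            cov_term = sum(
                spec.covariate_effects.get(name, 0.0)
                * (covs[name] - 0.5 * (spec.covariate_ranges[name][0]
                                       + spec.covariate_ranges[name][1]))
                for name in cov_names
            )
            for cond, intercept, eff in (
                ("mutant", spec.intercept_on, part_eff_on),
                ("wild_type", spec.intercept_off, part_eff_off),
            ):
                noise = rng.normal(0.0, spec.replicate_sd) if spec.replicate_sd > 0 else 0.0
                log_ru = intercept + eff + batch_offsets[batch] + cov_term + noise
                rows.append({
                    "circuit": ci,
                    **level_of,
                    "condition": cond,
                    "replicate": rep,
                    "batch": batch,
                    **covs,
                    "ru": 10.0 ** log_ru,
                })

    truth_rows = []
    for f in factors:
        for lev in spec.parts[f]:
            if lev == spec.reference[f]:
                continue
            eff = spec.effects.get(f, {}).get(lev, (0.0, 0.0))
            truth_rows.append({"factor": f, "level": lev,
                               "effect_on": eff[0], "effect_off": eff[1]})
    truth = pd.DataFrame(truth_rows, columns=["factor", "level", "effect_on", "effect_off"])
    truth_inter = pd.DataFrame(
        [{"levels": dict(m), "effect_on": a, "effect_off": b}
         for m, a, b in spec.interaction_effects],
        columns=["levels", "effect_on", "effect_off"],
    )
    return ScreenTable(pd.DataFrame(rows), truth, truth_inter, spec)


# ---------------------------------------------------------------------------
# Confluence time series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfluenceCondition:
    """Exponential growth with an optional kill phase after ``kill_onset`` hours."""

    name: str
    initial: float = 10.0        # % confluence at t=0
    growth_rate: float = 0.02    # 1/h
    kill_onset: float = 46.0     # h
    kill_rate: float = 0.0       # 1/h, subtracted from growth after onset


@dataclass(frozen=True)
class ConfluenceSpec:
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 181, 2))
    conditions: tuple[ConfluenceCondition, ...] = ()
    noise_sd: float = 0.0        # % confluence, per replicate and time point
    n_replicates: int = 3
    channel: str = "brightfield"
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing with >= 2 points")
        if not self.conditions:
            raise ValueError("at least one condition required")
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise ValueError("noise_sd >= 0 and n_replicates >= 1 required")


@dataclass
class ConfluenceSeries:
    """Mean +/- SD confluence over time for one condition and channel."""

    condition: str
    channel: str
    time: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def at(self, t: float) -> tuple[float, float]:
        """(mean, sd) at time ``t``; raises KeyError if ``t`` is not on the grid."""
        idx = np.flatnonzero(np.isclose(self.time, t))
        if idx.size == 0:
            raise KeyError(f"time {t} h not present in series {self.condition!r}")
        return float(self.mean[idx[0]]), float(self.sd[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition, "channel": self.channel,
            "time_h": self.time, "mean": self.mean, "sd": self.sd, "n": self.n,
        })


def confluence_curve(t: np.ndarray, cond: ConfluenceCondition) -> np.ndarray:
    """Closed-form noise-free confluence (%) on grid ``t``, clipped to [0, 100]."""
    t = np.asarray(t, dtype=float)
    pre = cond.initial * np.exp(cond.growth_rate * t)
    at_onset = cond.initial * np.exp(cond.growth_rate * cond.kill_onset)
    post = at_onset * np.exp((cond.growth_rate - cond.kill_rate) * (t - cond.kill_onset))
    return np.clip(np.where(t < cond.kill_onset, pre, post), 0.0, 100.0)


def generate_confluence(spec: ConfluenceSpec) -> list[ConfluenceSeries]:
    """Simulate replicate confluence curves and aggregate to mean +/- SD."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    t = np.asarray(spec.times, dtype=float)
    out = []
    for cond in spec.conditions:
        base = confluence_curve(t, cond)
        reps = np.clip(
            base[None, :] + rng.normal(0.0, spec.noise_sd, (spec.n_replicates, t.size))
            if spec.noise_sd > 0 else np.tile(base, (spec.n_replicates, 1)),
            0.0, 100.0,
        )
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if spec.n_replicates > 1 else np.zeros_like(mean)
        out.append(ConfluenceSeries(cond.name, spec.channel, t, mean, sd,
                                    spec.n_replicates))
    return out
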