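"""Per-cell membrane-localization quantification from 3-channel microscopy.

The pipeline follows six steps: (1) segment nuclei, each nucleus seeding one
cell; (2) assign every membrane-stain pixel to its nearest nucleus;
(3) post-process membrane masks to exclude non-closed objects, debris and
multi-nucleated cells; (4) fill membrane masks to obtain full cell masks;
(5) sum reporter fluorescence over the membrane and full-cell masks;
(6) report the per-cell membrane-to-total signal ratio.  A set of
untransfected control images supplies the background threshold on total cell
fluorescence below which cells are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "MembraneConfig",
    "NucleusLabels",
    "CellMasks",
    "BackgroundModel",
    "segment_nuclei",
    "assign_membrane",
    "build_cell_masks",
    "filter_cells",
    "quantify_cells",
    "estimate_background",
    "analyze_image",
]

REASON_NON_CLOSED = "non_closed"
REASON_MULTI_NUCLEUS = "multi_nucleus"
REASON_NO_NUCLEUS = "no_nucleus"
REASON_BELOW_BACKGROUND = "below_background"
REASON_TOO_SMALL = "too_small"

# 4-connected structuring element: flood fill of the exterior cannot leak
# through diagonal touching of ring pixels
_FILL_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class MembraneConfig:
    """Tunable thresholds of the six-step pipeline.

    ``None`` thresholds fall back to an automatic Otsu threshold per channel.
    ``min_interior`` (the closedness tolerance: minimum number of enclosed
    pixels for a membrane mask to count as closed) defaults to
    ``min_nucleus_area``.
    """

    min_nucleus_area: int = 20
    min_interior: int | None = None
    min_membrane_px: int = 10
    nuclear_threshold: float | None = None
    membrane_threshold: float | None = None
    assignment: str = "pixel"    # nearest nucleus pixel; "centroid" as alternative
    background_quantile: float = 0.99

    @property
    def interior_min(self) -> int:
        return self.min_nucleus_area if self.min_interior is None else self.min_interior


@dataclass
class NucleusLabels:
    """Labeled nuclei: 0 = background, labels 1..n in raster-scan order."""

    labels: np.ndarray
    centroids: np.ndarray        # (n, 2) row/col
    areas: np.ndarray            # (n,)

    @property
    def n(self) -> int:
        return len(self.areas)


@dataclass
class CellMasks:
    """One candidate object: a connected membrane component and its fill."""

    cell_id: int
    nucleus_label: int           # 0 when no nucleus is associated
    membrane_idx: np.ndarray     # flat pixel indices of the membrane mask
    filled_idx: np.ndarray       # flat pixel indices of the filled cell mask
    n_nuclei_inside: int
    excluded: bool = False
    reason: str = ""


@dataclass(frozen=True)
class BackgroundModel:
    """Total-cell-fluorescence threshold learned from untransfected controls."""

    threshold: float
    quantile: float = 0.99
    n_control_cells: int = 0


def _auto_threshold(img: np.ndarray) -> float:
    img = np.asarray(img, dtype=float)
    if img.min() == img.max():
        return np.inf  # constant image: nothing above threshold
    return float(threshold_otsu(img))


def _raster_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n by raster-scan order of each region's first pixel."""
    flat = labels.ravel()
    ids = np.unique(flat)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels
    first = np.full(ids.max() + 1, flat.size, dtype=np.int64)
    # first occurrence per label
    idx_sorted = np.argsort(flat, kind="stable")
    sorted_vals = flat[idx_sorted]
    starts = np.searchsorted(sorted_vals, ids)
    first[ids] = idx_sorted[starts]
    # np.searchsorted on sorted flat values gives the first position in the
    # sorted order, which is the minimum flat index thanks to stable sort
    order = ids[np.argsort(first[ids])]
    remap = np.zeros(ids.max() + 1, dtype=labels.dtype)
    remap[order] = np.arange(1, len(order) + 1)
    return remap[labels]


def segment_nuclei(nuclear_channel: np.ndarray,
                   min_area: int = 20,
                   threshold: float | None = None) -> NucleusLabels:
    """Threshold, size-filter and label nuclei.

    Connected bright regions above ``threshold`` (Otsu when ``None``) of at
    least ``min_area`` pixels become labels 1..n, numbered by raster-scan
    order of each region's first pixel.  A constant image yields zero labels.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("nuclear channel must be a nonempty 2-D array")
    if np.any(img < 0):
        raise ValueError("nuclear channel must be nonnegative")
    thr = _auto_threshold(img) if threshold is None else threshold
    mask = img > thr
    lab = cc_label(mask, connectivity=2)
    if lab.max() > 0:
        areas = np.bincount(lab.ravel())
        keep = np.flatnonzero(areas >= min_area)
        keep = keep[keep > 0]
        lut = np.zeros(lab.max() + 1, dtype=lab.dtype)
        lut[keep] = keep
        lab = _raster_relabel(lut[lab])
    n = int(lab.max())
    if n == 0:
        return NucleusLabels(np.zeros_like(lab), np.empty((0, 2)), np.empty(0, dtype=int))
    centroids = np.array(ndimage.center_of_mass(np.ones_like(lab), lab,
                                                index=np.arange(1, n + 1)))
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return NucleusLabels(lab, centroids, areas.astype(int))


def _nearest_label(tree: cKDTree, point_labels: np.ndarray,
                   query_pts: np.ndarray) -> np.ndarray:
    """Label of the nearest tree point per query, lowest label on exact ties.

    Squared pixel distances are integers, so equal distances compare exactly
    in floating point.  The neighbour count is doubled until every query's
    tie group is fully enumerated.
    """
    n_pts = tree.n
    k = min(8, n_pts)
    while True:
        dist, idx = tree.query(query_pts, k=k)
        if k == 1:
            return point_labels[idx]
        tied = dist == dist[:, :1]
        # unresolved: every returned neighbour is tied and more points exist
        unresolved = tied.all(axis=1) & (k < n_pts)
        if not unresolved.any():
            break
        k = min(2 * k, n_pts)
    labs = np.where(tied, point_labels[idx], np.iinfo(point_labels.dtype).max)
    return labs.min(axis=1)


def assign_membrane(membrane_channel: np.ndarray,
                    nuclei: NucleusLabels,
                    threshold: float | None = None,
                    assignment: str = "pixel") -> np.ndarray:
    """Assign every above-threshold membrane pixel to its nearest nucleus.

    Returns an owner map (0 = unassigned background).  ``assignment="pixel"``
    minimizes the Euclidean distance to the nearest pixel of each nucleus;
    ``"centroid"`` uses nucleus centroids instead.  Distance ties are broken
    toward the lower label index.
    """
    if nuclei.n == 0:
        raise ValueError("no nuclei to assign membrane pixels to")
    img = np.asarray(membrane_channel, dtype=float)
    thr = _auto_threshold(img) if threshold is None else threshold
    mem = img > thr

    owner = np.zeros(img.shape, dtype=np.int32)
    if assignment == "pixel":
        nuc_pts = np.argwhere(nuclei.labels > 0)
        nuc_labs = nuclei.labels[nuc_pts[:, 0], nuc_pts[:, 1]]
        tree = cKDTree(nuc_pts)
        mem_pts = np.argwhere(mem)
        if mem_pts.size:
            owner[mem_pts[:, 0], mem_pts[:, 1]] = _nearest_label(tree, nuc_labs, mem_pts)
    elif assignment == "centroid":
        rows, cols = np.nonzero(mem)
        d2 = ((rows[:, None] - nuclei.centroids[None, :, 0]) ** 2
              + (cols[:, None] - nuclei.centroids[None, :, 1]) ** 2)
        owner[rows, cols] = np.argmin(d2, axis=1) + 1  # argmin takes lower index on ties
        owner[~mem] = 0
        return owner
    else:
        raise ValueError("assignment must be 'pixel' or 'centroid'")
    owner[~mem] = 0
    return owner


def _fill_component(comp_mask: np.ndarray) -> np.ndarray:
    """Fill enclosed holes of a component with a 4-connected exterior fill."""
    return ndimage.binary_fill_holes(comp_mask, structure=_FILL_STRUCTURE)


def build_cell_masks(owner: np.ndarray, nuclei: NucleusLabels) -> list[CellMasks]:
    """Group assigned membrane pixels into per-object masks.

    Connected components of the membrane pixel set become candidate objects.
    A component whose filled mask contains exactly one nucleus centroid is
    that nucleus's cell; components containing several centroids (merged or
    binucleate cells) and components containing none (broken rings, debris)
    are carried forward as candidate objects for :func:`filter_cells` to flag.
    Every assigned membrane pixel belongs to exactly one object.
    """
    mem = owner > 0
    comps = cc_label(mem, connectivity=2)
    records: list[CellMasks] = []
    shape = owner.shape
    cent_rc = np.round(nuclei.centroids).astype(int) if nuclei.n else np.empty((0, 2), int)
    objects = ndimage.find_objects(comps)
    for cid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = comps[sl] == cid
        filled = _fill_component(sub)
        # nucleus centroids inside the filled mask
        inside = []
        for k, (r, c) in enumerate(cent_rc, start=1):
            rr, cc = r - sl[0].start, c - sl[1].start
            if 0 <= rr < filled.shape[0] and 0 <= cc < filled.shape[1] and filled[rr, cc]:
                inside.append(k)
        if len(inside) == 1:
            nuc = inside[0]
        elif len(inside) > 1:
            nuc = min(inside)
        else:
            # no centroid enclosed: attribute to the majority pixel owner only
            # if that nucleus sits within the component's own pixel radius
            # (a broken ring surrounds its nucleus); otherwise it is debris
            owners = owner[sl][sub]
            nuc = int(np.bincount(owners).argmax())
            rows, cols = np.nonzero(sub)
            cr, cc0 = rows.mean(), cols.mean()
            radius = np.hypot(rows - cr, cols - cc0).max()
            nr, nc = nuclei.centroids[nuc - 1]
            if np.hypot(nr - (cr + sl[0].start), nc - (cc0 + sl[1].start)) > radius + 1.0:
                nuc = 0
        # flat indices in the full image grid
        rows, cols = np.nonzero(sub)
        mem_idx = np.ravel_multi_index((rows + sl[0].start, cols + sl[1].start), shape)
        frows, fcols = np.nonzero(filled)
        fill_idx = np.ravel_multi_index((frows + sl[0].start, fcols + sl[1].start), shape)
        records.append(CellMasks(cid, nuc, np.sort(mem_idx), np.sort(fill_idx),
                                 len(inside)))
    return records


def filter_cells(masks: list[CellMasks], nuclei: NucleusLabels,
                 min_interior: int = 30, min_membrane_px: int = 10) -> list[CellMasks]:
    """Flag defective objects; exclusions are flags, never failures.

    An object is closed iff its filled mask encloses at least ``min_interior``
    pixels beyond the membrane itself.  Objects with >= 2 nucleus centroids are
    multi-nucleated; objects not attributable to any nucleus are debris.
    """
    for m in masks:
        if m.nucleus_label == 0:
            m.excluded, m.reason = True, REASON_NO_NUCLEUS
        elif m.n_nuclei_inside >= 2:
            m.excluded, m.reason = True, REASON_MULTI_NUCLEUS
        elif m.membrane_idx.size < min_membrane_px:
            m.excluded, m.reason = True, REASON_TOO_SMALL
        else:
            interior = m.filled_idx.size - m.membrane_idx.size
            if interior < min_interior:
                m.excluded, m.reason = True, REASON_NON_CLOSED
    return masks


def quantify_cells(reporter_channel: np.ndarray, masks: list[CellMasks],
                   background: BackgroundModel | None = None) -> pd.DataFrame:
    """Sum reporter signal over membrane and filled masks; compute the ratio.

    Cells whose total signal does not exceed the background threshold are
    flagged ``below_background``.  Returns one row per object with columns
    ``cell, nucleus, membrane_signal, total_signal, ratio, excluded, reason``.
    """
    rep = np.asarray(reporter_channel, dtype=float).ravel()
    thr = background.threshold if background is not None else 0.0
    rows = []
    for m in masks:
        mem_sig = float(rep[m.membrane_idx].sum())
        tot_sig = float(rep[m.filled_idx].sum())
        excluded, reason = m.excluded, m.reason
        if not excluded and tot_sig <= thr:
            excluded, reason = True, REASON_BELOW_BACKGROUND
        ratio = mem_sig / tot_sig if tot_sig > 0 else np.nan
        rows.append({
            "cell": m.cell_id, "nucleus": m.nucleus_label,
            "membrane_signal": mem_sig, "total_signal": tot_sig,
            "ratio": ratio, "excluded": excluded, "reason": reason,
        })
    return pd.DataFrame(rows, columns=["cell", "nucleus", "membrane_signal",
                                       "total_signal", "ratio", "excluded", "reason"])


def analyze_image(nuclear: np.ndarray, membrane: np.ndarray, reporter: np.ndarray,
                  config: MembraneConfig = MembraneConfig(),
                  background: BackgroundModel | None = None) -> pd.DataFrame:
    """Run the full six-step pipeline on one 3-channel field."""
    nuclei = segment_nuclei(nuclear, min_area=config.min_nucleus_area,
                            threshold=config.nuclear_threshold)
    if nuclei.n == 0:
        return pd.DataFrame(columns=["cell", "nucleus", "membrane_signal",
                                     "total_signal", "ratio", "excluded", "reason"])
    owner = assign_membrane(membrane, nuclei, threshold=config.membrane_threshold,
                            assignment=config.assignment)
    masks = build_cell_masks(owner, nuclei)
    masks = filter_cells(masks, nuclei, min_interior=config.interior_min,
                         min_membrane_px=config.min_membrane_px)
    return quantify_cells(reporter, masks, background)


def estimate_background(control_images, config: MembraneConfig = MembraneConfig(),
                        quantile: float | None = None) -> BackgroundModel:
    """Learn the background threshold from untransfected control images.

    The threshold is an upper quantile (default the config's 99th percentile)
    of total-cell reporter fluorescence among control cells that pass the
    morphology filters.
    """
    q = config.background_quantile if quantile is None else quantile
    totals = []
    for img in control_images:
        df = analyze_image(img.nuclear, img.membrane, img.reporter, config)
        ok = df[~df["excluded"] | (df["reason"] == REASON_BELOW_BACKGROUND)]
        totals.extend(ok["total_signal"].tolist())
    if not totals:
        raise ValueError("no cells detected in control images")
    return BackgroundModel(float(np.quantile(totals, q)), q, len(totals))
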