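"""Cell and puncta segmentation.

Cells are segmented from the brightfield channel by intensity thresholding
followed by a distance-transform-seeded watershed to split touching
objects.  Rule-based curation then removes dead cells (low chlorophyll) and
overlapping/merged objects (low solidity or excessive area).  Carboxysome
and procarboxysome puncta are segmented from the GFP signal restricted to
cell interiors, assigned to parent cells, and size-filtered: puncta smaller
than 62 pixels are excluded (by default only for the procarboxysome /
dCcmO strain class, where dim background spots are easily misidentified).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.feature import peak_local_max
from skimage.segmentation import clear_border, watershed

logger = logging.getLogger(__name__)

#: Minimum retained punctum area (px). Puncta smaller than this are
#: discarded as likely background noise; a punctum of exactly this area
#: is retained.
DEFAULT_PUNCTA_MIN_AREA = 62


class ThresholdMethod(str, enum.Enum):
    otsu = "otsu"
    fixed = "fixed"


class DegenerateThresholdError(ValueError):
    """Otsu thresholding on a constant image is undefined."""


class SegmentationParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    threshold_method: ThresholdMethod = ThresholdMethod.otsu
    fixed_threshold: float = 0.0
    connectivity: int = Field(default=2, ge=1, le=2)  # scikit-image rank: 2 = 8-connected
    watershed_min_seed_distance: int = Field(default=25, ge=1)
    min_cell_area: int = Field(default=100, ge=0)
    border_policy: str = "drop"  # drop | keep
    puncta_threshold_method: ThresholdMethod = ThresholdMethod.otsu
    puncta_fixed_threshold: float = 0.0
    puncta_connectivity: int = Field(default=1, ge=1, le=2)  # 4-connected
    puncta_min_area: int = Field(default=DEFAULT_PUNCTA_MIN_AREA, ge=1)


@dataclass
class LabelMap:
    """Integer-labeled objects on the image grid; 0 is background."""

    labels: np.ndarray
    provenance: str  # "cell" | "puncta"
    frame_index: int = 0

    @property
    def n_objects(self) -> int:
        return int(np.unique(self.labels[self.labels > 0]).size)


def _threshold(image: np.ndarray, method: ThresholdMethod, fixed: float) -> float:
    if method is ThresholdMethod.fixed:
        return fixed
    if np.ptp(image) == 0:
        raise DegenerateThresholdError(
            "constant image: Otsu threshold undefined; use a fixed threshold"
        )
    return float(threshold_otsu(image))


def segment_cells(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    frame_index: int = 0,
) -> LabelMap:
    """Threshold + watershed cell segmentation of one 2D frame.

    Foreground is pixels above the threshold; touching objects are split by
    a watershed seeded at maxima of the (smoothed) distance transform, with
    seeds closer than ``watershed_min_seed_distance`` suppressed.  Objects
    below ``min_cell_area`` are removed; border objects are dropped under
    the default border policy.  An all-background image yields an empty map.
    """
    params = params or SegmentationParams()
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("segment_cells expects a single 2D channel")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    thr = _threshold(img, params.threshold_method, params.fixed_threshold)
    fg = img > thr
    if not fg.any():
        return LabelMap(np.zeros_like(img, dtype=np.int32), "cell", frame_index)

    components = cc_label(fg, connectivity=params.connectivity)
    dist = ndi.distance_transform_edt(fg)
    dist_s = ndi.gaussian_filter(dist, 1.0)
    peaks = peak_local_max(
        dist_s,
        min_distance=params.watershed_min_seed_distance,
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros_like(components)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    # guarantee at least one seed per connected component
    seeded = set(np.unique(components[markers > 0]))
    next_marker = len(peaks) + 1
    for prop in regionprops(components):
        if prop.label in seeded:
            continue
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        best = np.argmax(dist_s[rr, cc])
        markers[rr[best], cc[best]] = next_marker
        next_marker += 1
    labels = watershed(-dist_s, markers, mask=fg)

    if params.border_policy == "drop":
        labels = clear_border(labels)
    if params.min_cell_area > 0:
        counts = np.bincount(labels.ravel())
        small = np.nonzero(counts < params.min_cell_area)[0]
        labels[np.isin(labels, small[small > 0])] = 0
    labels = _relabel(labels)
    return LabelMap(labels.astype(np.int32), "cell", frame_index)


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


class CurationRules(BaseModel):
    """Thresholds for rule-based removal of dead and overlapped cells."""

    model_config = ConfigDict(frozen=True)

    dead_chlorophyll_fraction: float = 0.3  # of the frame's median object chlorophyll
    min_solidity: float = 0.85
    max_area: Optional[int] = None


@dataclass
class CurationLog:
    removed: list[tuple[int, int, str]] = field(default_factory=list)  # (frame, label, reason)


def curate_cells(
    cells: Sequence[LabelMap],
    chlorophyll: Sequence[np.ndarray],
    rules: CurationRules | None = None,
) -> tuple[list[LabelMap], CurationLog]:
    """Remove dead (chlorophyll-dark) and overlapped (low-solidity or
    oversized) objects from per-frame cell maps; removals are logged with
    reasons.  Empty inputs pass through unchanged."""
    rules = rules or CurationRules()
    log = CurationLog()
    out: list[LabelMap] = []
    for lm, chl in zip(cells, chlorophyll):
        labels = lm.labels.copy()
        props = regionprops(labels, intensity_image=np.asarray(chl, float))
        if not props:
            out.append(LabelMap(labels, lm.provenance, lm.frame_index))
            continue
        med_chl = float(np.median([p.intensity_mean for p in props]))
        for p in props:
            reason = None
            if med_chl > 0 and p.intensity_mean < rules.dead_chlorophyll_fraction * med_chl:
                reason = "dead"
            elif p.solidity < rules.min_solidity:
                reason = "overlap"
            elif rules.max_area is not None and p.area > rules.max_area:
                reason = "overlap"
            if reason:
                labels[labels == p.label] = 0
                log.removed.append((lm.frame_index, p.label, reason))
                logger.info("frame %d: removed cell %d (%s)", lm.frame_index, p.label, reason)
        out.append(LabelMap(labels, lm.provenance, lm.frame_index))
    return out, log


@dataclass
class PunctaResult:
    labels: LabelMap
    parent_cell: dict[int, int]  # punctum label -> cell label
    n_removed_small: int


def segment_puncta(
    gfp_image: np.ndarray,
    cells: LabelMap,
    params: SegmentationParams | None = None,
    size_filter: bool = True,
) -> PunctaResult:
    """Segment bright GFP puncta inside segmented cells.

    The puncta threshold is computed over in-cell pixels only; connected
    bright regions become puncta.  Each punctum is assigned to the cell
    containing its centroid, falling back to majority pixel overlap (ties
    broken toward the lower cell label, logged).  When ``size_filter`` is
    on, puncta with area < ``puncta_min_area`` are discarded.
    """
    params = params or SegmentationParams()
    img = np.asarray(gfp_image, float)
    cell_mask = cells.labels > 0
    labels = np.zeros_like(cells.labels, dtype=np.int32)
    if not cell_mask.any():
        return PunctaResult(LabelMap(labels, "puncta", cells.frame_index), {}, 0)
    inside = img[cell_mask]
    thr = _threshold(inside, params.puncta_threshold_method, params.puncta_fixed_threshold)
    fg = (img > thr) & cell_mask
    raw = cc_label(fg, connectivity=params.puncta_connectivity)
    parent: dict[int, int] = {}
    n_removed = 0
    next_id = 0
    for p in regionprops(raw):
        if size_filter and p.area < params.puncta_min_area:
            n_removed += 1
            continue
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        cr, cc0 = int(round(p.centroid[0])), int(round(p.centroid[1]))
        owner = int(cells.labels[cr, cc0])
        if owner == 0:
            overlap = np.bincount(cells.labels[rr, cc])
            overlap[0] = 0
            if overlap.sum() == 0:
                continue  # entirely outside cells (cannot happen given masking)
            best = int(overlap.max())
            winners = np.nonzero(overlap == best)[0]
            owner = int(winners.min())
            if winners.size > 1:
                logger.info(
                    "frame %d: punctum overlap tie between cells %s; assigned %d",
                    cells.frame_index, winners.tolist(), owner,
                )
        next_id += 1
        labels[rr, cc] = next_id
        parent[next_id] = owner
    return PunctaResult(LabelMap(labels, "puncta", cells.frame_index), parent, n_removed)
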