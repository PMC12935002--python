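"""Synthetic timelapse generator for dual-excitation roGFP2 microscopy.

Emulates rod-shaped cyanobacteria on an agar pad imaged every 20 minutes in
four channels (395 nm excitation, 470 nm excitation, chlorophyll
autofluorescence, brightfield).  Three probe localization classes are
modeled — diffuse cytosolic signal, carboxysome puncta, and procarboxysome
puncta — plus probe-free wild-type cells whose 395/470 channel intensity
(autofluorescence + camera background) provides the background estimate the
analysis subtracts.

Every rendered object carries a known oxidation fraction whose trajectory
follows a first-order relaxation toward the mean of the current CO2
condition, with an optional initial burn-in transient and an optional
persistent offset after a high-CO2 -> air return (hysteresis).  The emitted
label maps are the exact rendered geometry and serve as oracle masks for
recovery tests; they are distinct from anything the segmentation pipeline
produces.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.ndimage import gaussian_filter

from ..optics import NoiseModel, OpticalModel

CHANNELS = ("ex395", "ex470", "chlorophyll", "brightfield")


class Condition(str, enum.Enum):
    """CO2 condition of a frame interval."""

    air = "air"  # ambient, 0.04% CO2
    high = "high"  # elevated, 3% CO2


class Compartment(str, enum.Enum):
    cytosol = "cytosol"
    carboxysome = "carboxysome"
    procarboxysome = "procarboxysome"
    wt = "wt"


class ScenePlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap (scene too crowded)."""


class StrainSpec(BaseModel):
    """One strain population in the scene.

    ``oxd_air`` / ``oxd_high`` are the mean oxidation fractions the strain's
    probe objects relax toward under each CO2 condition; per-object means are
    drawn once with standard deviation ``oxd_sd``.  Under high CO2 a fraction
    ``bimodal_fraction_high`` of objects instead targets a second (reduced)
    mode at ``oxd_high_alt``, producing the bimodal subpopulation.  WT strains
    carry no probe signal at any wavelength.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    compartment: Compartment
    n_cells: int = Field(ge=1)
    oxd_air: float = Field(default=0.0, ge=0.0, le=1.0)
    oxd_high: float = Field(default=0.0, ge=0.0, le=1.0)
    oxd_sd: float = Field(default=0.04, ge=0.0)
    bimodal_fraction_high: float = Field(default=0.0, ge=0.0, le=1.0)
    oxd_high_alt: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    puncta_per_cell: int = Field(default=0, ge=0)
    puncta_area_px: float = Field(default=75.0, gt=0.0)
    division_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    probe_level: float = Field(default=1000.0, ge=0.0)
    hysteresis_offset: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "StrainSpec":
        if self.bimodal_fraction_high > 0 and self.oxd_high_alt is None:
            raise ValueError("bimodal_fraction_high > 0 requires oxd_high_alt")
        if self.compartment in (Compartment.carboxysome, Compartment.procarboxysome):
            if self.puncta_per_cell < 1:
                raise ValueError("puncta strains need puncta_per_cell >= 1")
        return self

    @property
    def has_probe(self) -> bool:
        return self.compartment is not Compartment.wt


class SceneSpec(BaseModel):
    """Full scene description: geometry, strains, CO2 schedule, kinetics."""

    model_config = ConfigDict(frozen=True)

    image_shape: tuple[int, int] = (512, 512)
    n_frames: int = Field(ge=1)
    frame_interval_min: float = Field(default=20.0, gt=0.0)
    strains: list[StrainSpec]
    co2_schedule: list[tuple[int, Condition]] = [(0, Condition.air)]
    rng_seed: int = 0

    # kinetics
    relaxation_tau_min: float = Field(default=60.0, gt=0.0)
    burn_in_offset: float = 0.10

    # cell geometry (pixels); length is tip-to-tip
    cell_length_mean: float = 26.0
    cell_length_sd: float = 3.0
    cell_width: float = 11.0
    min_gap_px: float = 3.0
    placement_retries: int = 500

    # rendering
    blur_sigma_px: float = 0.0
    chlorophyll_mean: float = 800.0
    chlorophyll_background: float = 10.0
    brightfield_background: float = 200.0
    brightfield_cell: float = 1000.0

    @model_validator(mode="after")
    def _check(self) -> "SceneSpec":
        if not self.strains:
            raise ValueError("at least one strain required")
        frames = [f for f, _ in self.co2_schedule]
        if not frames or frames[0] != 0:
            raise ValueError("co2_schedule must start at frame 0")
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("co2_schedule frame indices must be strictly increasing")
        if frames[-1] >= self.n_frames:
            raise ValueError("co2_schedule extends beyond n_frames")
        return self

    def condition_per_frame(self) -> list[Condition]:
        out: list[Condition] = []
        sched = list(self.co2_schedule) + [(self.n_frames, None)]
        for (start, cond), (end, _) in zip(sched, sched[1:]):
            out.extend([cond] * (end - start))
        return out


@dataclass
class _Cell:
    cell_id: int
    strain: StrainSpec
    center: np.ndarray  # (row, col)
    direction: np.ndarray  # unit vector
    length: float
    width: float
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)


@dataclass
class _ProbeObject:
    object_id: int
    kind: str  # "cell" | "punctum"
    parent: _Cell
    pixels: tuple[np.ndarray, np.ndarray]
    oxd: float = np.nan
    target_air: float = np.nan
    target_high: float = np.nan
    returned_to_air: bool = False


@dataclass
class ChannelStack:
    """Multichannel, multi-frame image array with acquisition metadata."""

    data: np.ndarray  # (n_frames, n_channels, H, W), counts
    channels: tuple[str, ...] = CHANNELS
    frame_interval_min: float = 20.0
    conditions: list[Condition] = field(default_factory=list)

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.frame_interval_min

    def channel(self, name: str, frame: int) -> np.ndarray:
        return self.data[frame, self.channels.index(name)]


@dataclass
class SceneResult:
    stack: ChannelStack
    cell_labels: list[np.ndarray]  # per frame, oracle cell masks
    puncta_labels: list[np.ndarray]  # per frame, oracle puncta masks
    truth: pd.DataFrame  # one row per labeled object per frame
    spec: SceneSpec
    optics: OpticalModel


def _capsule_pixels(
    center: np.ndarray,
    direction: np.ndarray,
    length: float,
    width: float,
    shape: tuple[int, int],
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Pixel coordinates of a capsule (rod) or None if it leaves the image."""
    half_seg = max(length - width, 0.0) / 2.0
    p0 = center - direction * half_seg
    p1 = center + direction * half_seg
    r = width / 2.0
    rmin = int(np.floor(min(p0[0], p1[0]) - r))
    rmax = int(np.ceil(max(p0[0], p1[0]) + r))
    cmin = int(np.floor(min(p0[1], p1[1]) - r))
    cmax = int(np.ceil(max(p0[1], p1[1]) + r))
    if rmin < 0 or cmin < 0 or rmax >= shape[0] or cmax >= shape[1]:
        return None
    rr, cc = np.meshgrid(np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij")
    # distance from each pixel to the segment p0-p1
    d = p1 - p0
    seg_len2 = float(d @ d)
    pr = rr - p0[0]
    pc = cc - p0[1]
    if seg_len2 > 0:
        t = np.clip((pr * d[0] + pc * d[1]) / seg_len2, 0.0, 1.0)
    else:
        t = np.zeros_like(pr, dtype=float)
    dist2 = (pr - t * d[0]) ** 2 + (pc - t * d[1]) ** 2
    inside = dist2 <= r * r
    return rr[inside], cc[inside]


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> list[_Cell]:
    """Rejection-sample non-overlapping rods; explicit error when crowded."""
    shape = spec.image_shape
    occupied = np.zeros(shape, dtype=bool)
    cells: list[_Cell] = []
    cell_id = 0
    for strain in spec.strains:
        for _ in range(strain.n_cells):
            placed = False
            for _try in range(spec.placement_retries):
                center = np.array(
                    [rng.uniform(0, shape[0]), rng.uniform(0, shape[1])]
                )
                theta = rng.uniform(0, np.pi)
                direction = np.array([np.sin(theta), np.cos(theta)])
                length = float(
                    np.clip(
                        rng.normal(spec.cell_length_mean, spec.cell_length_sd),
                        spec.cell_width * 1.3,
                        spec.cell_length_mean + 3 * spec.cell_length_sd,
                    )
                )
                dilated = _capsule_pixels(
                    center, direction, length + 2 * spec.min_gap_px,
                    spec.cell_width + 2 * spec.min_gap_px, shape,
                )
                if dilated is None or occupied[dilated].any():
                    continue
                body = _capsule_pixels(center, direction, length, spec.cell_width, shape)
                occupied[dilated] = True
                cell_id += 1
                cells.append(
                    _Cell(cell_id, strain, center, direction, length, spec.cell_width, body)
                )
                placed = True
                break
            if not placed:
                raise ScenePlacementError(
                    f"could not place cell {len(cells) + 1} after "
                    f"{spec.placement_retries} retries; reduce n_cells or enlarge image"
                )
    return cells


def _puncta_for_cell(
    cell: _Cell, strain: StrainSpec, rng: np.random.Generator
) -> list[tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]]:
    """Puncta as compact pixel sets fully inside the parent cell.

    A punctum is the set of cell pixels nearest its center, grown until the
    target area is reached, so containment holds even when the nominal disk
    would overhang the rod boundary.
    """
    k = strain.puncta_per_cell
    if k == 0:
        return []
    import heapq

    rows, cols = cell.pixels
    allowed = {(int(r), int(c)) for r, c in zip(rows, cols)}
    used: set[tuple[int, int]] = set()
    out = []
    # spread punctum centers at axis midpoints (k=1 -> center, k=2 -> +/-L/4 ...)
    span = max(cell.length - cell.width, 1.0)
    offsets = ((np.arange(k) + 0.5) / k - 0.5) * span
    offsets = offsets + rng.normal(0, 0.03 * span, size=k)
    target = int(round(strain.puncta_area_px))
    for off in offsets:
        centre = cell.center + cell.direction * off
        free = allowed - used
        if not free:
            continue
        # grow a 4-connected region from the free pixel nearest the center,
        # always expanding at the frontier pixel closest to the center
        seed_px = min(free, key=lambda p: (p[0] - centre[0]) ** 2 + (p[1] - centre[1]) ** 2)
        chosen: set[tuple[int, int]] = set()
        heap = [((seed_px[0] - centre[0]) ** 2 + (seed_px[1] - centre[1]) ** 2, seed_px)]
        seen = {seed_px}
        while heap and len(chosen) < min(target, len(free)):
            _, (r, c) = heapq.heappop(heap)
            chosen.add((r, c))
            for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if nb in free and nb not in seen:
                    seen.add(nb)
                    heapq.heappush(
                        heap, ((nb[0] - centre[0]) ** 2 + (nb[1] - centre[1]) ** 2, nb)
                    )
        if not chosen:
            continue
        used |= chosen
        # block a 1-px ring so neighbouring puncta stay disconnected
        for r, c in list(chosen):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    used.add((r + dr, c + dc))
        arr = np.array(sorted(chosen))
        out.append((centre, (arr[:, 0], arr[:, 1])))
    return out


def _draw_target(mean: float, sd: float, rng: np.random.Generator) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def _init_objects(
    cells: list[_Cell], spec: SceneSpec, rng: np.random.Generator, next_id: int
) -> tuple[list[_ProbeObject], int]:
    """Create probe objects (cytosol cells or puncta) with per-object targets."""
    objects: list[_ProbeObject] = []
    for cell in cells:
        strain = cell.strain
        if not strain.has_probe:
            continue
        if strain.compartment is Compartment.cytosol:
            pix_sets = [(None, cell.pixels)]
            kind = "cell"
        else:
            pix_sets = _puncta_for_cell(cell, strain, rng)
            kind = "punctum"
        for _, pix in pix_sets:
            next_id += 1
            obj = _ProbeObject(next_id, kind, cell, pix)
            obj.target_air = _draw_target(strain.oxd_air, strain.oxd_sd, rng)
            if strain.bimodal_fraction_high > 0 and rng.uniform() < strain.bimodal_fraction_high:
                obj.target_high = _draw_target(strain.oxd_high_alt, strain.oxd_sd, rng)
            else:
                obj.target_high = _draw_target(strain.oxd_high, strain.oxd_sd, rng)
            objects.append(obj)
    return objects, next_id


def _object_target(obj: _ProbeObject, cond: Condition) -> float:
    if cond is Condition.high:
        return obj.target_high
    t = obj.target_air
    if obj.returned_to_air:
        t = float(np.clip(t + obj.parent.strain.hysteresis_offset, 0.0, 1.0))
    return t


def _split_cell(
    cell: _Cell, next_id: int
) -> tuple[_Cell, _Cell, int]:
    """Divide a rod into two daughters by the transverse midline."""
    rows, cols = cell.pixels
    proj = (rows - cell.center[0]) * cell.direction[0] + (cols - cell.center[1]) * cell.direction[1]
    a = proj < 0
    halves = []
    for mask in (a, ~a):
        r, c = rows[mask], cols[mask]
        next_id += 1
        halves.append(
            _Cell(
                next_id,
                cell.strain,
                np.array([r.mean(), c.mean()]),
                cell.direction,
                cell.length / 2.0,
                cell.width,
                (r, c),
            )
        )
    return halves[0], halves[1], next_id


def generate_scene(spec: SceneSpec, optics: OpticalModel) -> SceneResult:
    """Render the full timelapse with ground truth.

    Returns the 4-channel stack, per-frame oracle cell and puncta label maps,
    and a truth table with one row per labeled object per frame (WT cells and
    probe-free cell bodies carry NaN oxidation state).
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.image_shape
    conditions = spec.condition_per_frame()

    cells = _place_cells(spec, rng)
    next_id = max(c.cell_id for c in cells)
    objects, next_id = _init_objects(cells, spec, rng, next_id)

    # initial state: condition-0 target plus the burn-in transient
    for obj in objects:
        obj.oxd = float(
            np.clip(_object_target(obj, conditions[0]) + spec.burn_in_offset, 0.0, 1.0)
        )

    decay = float(np.exp(-spec.frame_interval_min / spec.relaxation_tau_min))
    n_frames = spec.n_frames
    stack = np.empty((n_frames, len(CHANNELS), *shape), dtype=np.float64)
    cell_label_maps: list[np.ndarray] = []
    puncta_label_maps: list[np.ndarray] = []
    records: list[dict] = []
    prev_cond = conditions[0]

    for f in range(n_frames):
        cond = conditions[f]
        if cond is not prev_cond:
            if cond is Condition.air:
                for obj in objects:
                    obj.returned_to_air = True
            prev_cond = cond
        if f > 0:
            # first-order relaxation toward the condition target
            for obj in objects:
                tgt = _object_target(obj, cond)
                obj.oxd = float(np.clip(tgt + (obj.oxd - tgt) * decay, 0.0, 1.0))
            # divisions
            new_cells: list[_Cell] = []
            dead: set[int] = set()
            for cell in cells:
                rate = cell.strain.division_rate
                if rate > 0 and len(cell.pixels[0]) >= 2 and rng.uniform() < rate:
                    d1, d2, next_id = _split_cell(cell, next_id)
                    new_cells.extend([d1, d2])
                    dead.add(cell.cell_id)
                    # reattach probe objects to the daughter holding their centroid
                    for obj in objects:
                        if obj.parent is not cell:
                            continue
                        if obj.kind == "cell":
                            # diffuse object follows the cell split: clone state
                            for daughter in (d1, d2):
                                next_id += 1
                                child = _ProbeObject(
                                    next_id, "cell", daughter, daughter.pixels,
                                    oxd=obj.oxd, target_air=obj.target_air,
                                    target_high=obj.target_high,
                                    returned_to_air=obj.returned_to_air,
                                )
                                objects.append(child)
                            obj.parent = None  # retire mother object
                        else:
                            rmean = obj.pixels[0].mean()
                            cmean = obj.pixels[1].mean()
                            proj = (
                                (rmean - cell.center[0]) * cell.direction[0]
                                + (cmean - cell.center[1]) * cell.direction[1]
                            )
                            obj.parent = d1 if proj < 0 else d2
                else:
                    new_cells.append(cell)
            cells = new_cells
            objects = [o for o in objects if o.parent is not None]

        # render
        ex395 = np.full(shape, optics.background_mean, dtype=np.float64)
        ex470 = np.full(shape, optics.background_mean, dtype=np.float64)
        chl = np.full(shape, spec.chlorophyll_background, dtype=np.float64)
        bf = np.full(shape, spec.brightfield_background, dtype=np.float64)
        cell_map = np.zeros(shape, dtype=np.int32)
        puncta_map = np.zeros(shape, dtype=np.int32)

        for cell in cells:
            ex395[cell.pixels] += optics.autofluor_mean
            ex470[cell.pixels] += optics.autofluor_mean
            chl[cell.pixels] += spec.chlorophyll_mean - spec.chlorophyll_background
            bf[cell.pixels] = spec.brightfield_cell
            cell_map[cell.pixels] = cell.cell_id

        for obj in objects:
            s395, s470 = optics.channel_signal(obj.oxd, probe=obj.parent.strain.probe_level)
            ex395[obj.pixels] += float(s395)
            ex470[obj.pixels] += float(s470)
            if obj.kind == "punctum":
                puncta_map[obj.pixels] = obj.object_id

        frame = np.stack([ex395, ex470, chl, bf])
        if spec.blur_sigma_px > 0:
            for c in range(frame.shape[0]):
                frame[c] = gaussian_filter(frame[c], spec.blur_sigma_px)
        if optics.noise_model is NoiseModel.poisson_gaussian:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(np.float64)
            if optics.noise_scale > 0:
                frame += rng.normal(0.0, optics.noise_scale, size=frame.shape)
        elif optics.noise_scale > 0:
            frame = frame + rng.normal(0.0, optics.noise_scale, size=frame.shape)
        stack[f] = frame
        cell_label_maps.append(cell_map)
        puncta_label_maps.append(puncta_map)

        # truth records: all labeled objects this frame
        t_min = f * spec.frame_interval_min
        probe_by_cell = {
            o.parent.cell_id: o for o in objects if o.kind == "cell"
        }
        for cell in cells:
            probe = probe_by_cell.get(cell.cell_id)
            oxd = probe.oxd if probe is not None else np.nan
            records.append(
                dict(
                    object_id=(probe.object_id if probe is not None else cell.cell_id),
                    kind="cell",
                    parent_cell_id=cell.cell_id,
                    strain=cell.strain.name,
                    compartment=cell.strain.compartment.value,
                    frame=f,
                    time_min=t_min,
                    condition=cond.value,
                    true_oxd=oxd,
                    true_ratio=(optics.ratio_from_oxd(oxd) if probe is not None else np.nan),
                    area_px=len(cell.pixels[0]),
                    centroid_r=float(cell.pixels[0].mean()),
                    centroid_c=float(cell.pixels[1].mean()),
                )
            )
        for obj in objects:
            if obj.kind != "punctum":
                continue
            records.append(
                dict(
                    object_id=obj.object_id,
                    kind="punctum",
                    parent_cell_id=obj.parent.cell_id,
                    strain=obj.parent.strain.name,
                    compartment=obj.parent.strain.compartment.value,
                    frame=f,
                    time_min=t_min,
                    condition=cond.value,
                    true_oxd=obj.oxd,
                    true_ratio=float(optics.ratio_from_oxd(obj.oxd)),
                    area_px=len(obj.pixels[0]),
                    centroid_r=float(obj.pixels[0].mean()),
                    centroid_c=float(obj.pixels[1].mean()),
                )
            )

    # cytosol-strain cell labels must match their probe object ids so that
    # truth rows map 1:1 onto label-map pixels
    truth = pd.DataFrame.from_records(records)
    for f in range(n_frames):
        sub = truth[(truth.frame == f) & (truth.kind == "cell")]
        remap = dict(zip(sub.parent_cell_id, sub.object_id))
        if any(k != v for k, v in remap.items()):
            cm = cell_label_maps[f]
            out = cm.copy()
            for old, new in remap.items():
                if old != new:
                    out[cm == old] = new
            cell_label_maps[f] = out

    ch_stack = ChannelStack(
        data=stack,
        channels=CHANNELS,
        frame_interval_min=spec.frame_interval_min,
        conditions=conditions,
    )
    return SceneResult(ch_stack, cell_label_maps, puncta_label_maps, truth, spec, optics)
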