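"""Background-subtracted redox ratios and ratiometric rendering.

The redox readout of an object (cell or punctum) is

    R395/470 = (I395 - b395) / (I470 - b470)

where I395/I470 are the object-mean intensities in the two excitation
channels and b395/b470 are backgrounds estimated as the mean intensity of
probe-free wild-type objects.  To handle low 470-channel signal, any
numerator or denominator that falls below zero after subtraction is clipped
to zero; a zero denominator makes the ratio undefined and the object is
excluded from aggregates (and counted).  The ratio is invariant to any
common rescaling of intensities and backgrounds, i.e. independent of probe
concentration.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import matplotlib

from .segmentation import LabelMap

logger = logging.getLogger(__name__)


class BackgroundScope(str, enum.Enum):
    global_ = "global"
    per_frame = "per_frame"


@dataclass(frozen=True)
class BackgroundModel:
    """WT-derived channel backgrounds (counts)."""

    b_395: float
    b_470: float
    n_wt_objects: int
    scope: BackgroundScope = BackgroundScope.global_
    frame: Optional[int] = None

    def __post_init__(self):
        if not (np.isfinite(self.b_395) and np.isfinite(self.b_470)):
            raise ValueError("backgrounds must be finite")
        if self.b_395 < 0 or self.b_470 < 0:
            raise ValueError("backgrounds must be >= 0")
        if self.n_wt_objects < 1:
            raise ValueError("background requires at least one WT object")


def estimate_background(
    wt_measurements: pd.DataFrame,
    scope: BackgroundScope | str = BackgroundScope.global_,
) -> BackgroundModel | dict[int, BackgroundModel]:
    """Mean WT object intensity per channel.

    ``wt_measurements`` needs columns ``i_395``, ``i_470`` (object means)
    and, for per-frame scope, ``frame``.  Raises when no WT objects are
    provided — a silent zero background would bias every ratio.
    """
    scope = BackgroundScope(scope)
    if wt_measurements.empty:
        raise ValueError("no WT objects: cannot estimate background")
    if scope is BackgroundScope.global_:
        return BackgroundModel(
            float(wt_measurements["i_395"].mean()),
            float(wt_measurements["i_470"].mean()),
            len(wt_measurements),
            scope,
        )
    out: dict[int, BackgroundModel] = {}
    for frame, g in wt_measurements.groupby("frame"):
        out[int(frame)] = BackgroundModel(
            float(g["i_395"].mean()), float(g["i_470"].mean()), len(g), scope, int(frame)
        )
    return out


@dataclass(frozen=True)
class RedoxMeasurement:
    """One object at one frame, before and after background subtraction."""

    object_id: int
    frame: int
    i_395: float
    i_470: float
    num: float  # max(i_395 - b_395, 0)
    den: float  # max(i_470 - b_470, 0)
    ratio: float  # num / den; NaN when undefined (den == 0)
    area_px: int = 0
    compartment: str = ""

    @property
    def defined(self) -> bool:
        return not np.isnan(self.ratio)


def compute_ratio(
    i_395: float,
    i_470: float,
    bg: BackgroundModel,
    object_id: int = 0,
    frame: int = 0,
    **extra,
) -> RedoxMeasurement:
    """Apply background subtraction, clipping and the ratio formula to one
    object's channel means.

    Negative raw intensities indicate corrupt input and raise; negative
    *subtracted* values are clipped to zero.  A zero denominator yields an
    undefined (NaN) ratio; callers must exclude such objects from averages.
    """
    if i_395 < 0 or i_470 < 0:
        raise ValueError("raw object intensities must be non-negative")
    num = max(i_395 - bg.b_395, 0.0)
    den = max(i_470 - bg.b_470, 0.0)
    if den > 0:
        ratio = num / den
    else:
        ratio = np.nan
        logger.info("object %d frame %d: zero denominator, ratio undefined", object_id, frame)
    return RedoxMeasurement(object_id, frame, i_395, i_470, num, den, ratio, **extra)


def measure_objects(
    ch395: np.ndarray,
    ch470: np.ndarray,
    labelmap: LabelMap,
    statistic: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Raw per-object channel statistics over each object's own pixels.

    Returns a tidy table with columns object_id, frame, i_395, i_470,
    area_px (no background applied yet).
    """
    labels = labelmap.labels
    ids = np.unique(labels[labels > 0])
    rows = []
    for lab in ids:
        mask = labels == lab
        px395 = np.asarray(ch395, float)[mask]
        px470 = np.asarray(ch470, float)[mask]
        stat = np.mean if statistic == "mean" else np.median
        rows.append(
            dict(
                object_id=int(lab),
                frame=labelmap.frame_index,
                i_395=float(stat(px395)),
                i_470=float(stat(px470)),
                area_px=int(mask.sum()),
            )
        )
    return pd.DataFrame(rows, columns=["object_id", "frame", "i_395", "i_470", "area_px"])


def add_ratios(
    measurements: pd.DataFrame,
    bg: BackgroundModel | dict[int, BackgroundModel],
) -> pd.DataFrame:
    """Vectorized ratio computation over a raw measurement table.

    Accepts a global background or a per-frame mapping; adds columns num,
    den, ratio (NaN where undefined).
    """
    df = measurements.copy()
    if (df[["i_395", "i_470"]] < 0).any().any():
        raise ValueError("raw object intensities must be non-negative")
    if isinstance(bg, dict):
        b395 = df["frame"].map({f: m.b_395 for f, m in bg.items()})
        b470 = df["frame"].map({f: m.b_470 for f, m in bg.items()})
        if b395.isna().any():
            raise ValueError("per-frame background missing for some frames")
    else:
        b395, b470 = bg.b_395, bg.b_470
    df["num"] = np.maximum(df["i_395"] - b395, 0.0)
    df["den"] = np.maximum(df["i_470"] - b470, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = np.where(df["den"] > 0, df["num"] / df["den"], np.nan)
    n_undef = int(df["ratio"].isna().sum())
    if n_undef:
        logger.info("%d object(s) with undefined ratio (zero denominator)", n_undef)
    return df


#: Sentinel RGB for objects whose ratio is undefined.
UNDEFINED_COLOR = (0.5, 0.5, 0.5)


def render_ratiometric(
    labelmap: LabelMap,
    measurements: pd.DataFrame,
    limits: tuple[float, float] = (0.0, 0.3),
    colormap: str = "viridis",
) -> np.ndarray:
    """Ratio overlay image: each object's pixels colored by its clipped
    ratio, background black, undefined objects in a sentinel gray.

    Default limits (0, 0.3) follow the timelapse figures; use (0, 0.5) for
    puncta close-ups.
    """
    lo, hi = limits
    if lo >= hi:
        raise ValueError("limits must satisfy lo < hi")
    cmap = matplotlib.colormaps[colormap]
    labels = labelmap.labels
    out = np.zeros((*labels.shape, 3), dtype=float)
    by_id = measurements.set_index("object_id")
    for lab in np.unique(labels[labels > 0]):
        if lab not in by_id.index:
            raise ValueError(f"object {lab} has no measurement")
        ratio = by_id.loc[lab, "ratio"]
        mask = labels == lab
        if np.isnan(ratio):
            out[mask] = UNDEFINED_COLOR
        else:
            frac = (min(max(ratio, lo), hi) - lo) / (hi - lo)
            out[mask] = cmap(frac)[:3]
    return out
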