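"""Population-level readouts of single-object redox ratios.

Aggregates per-object R395/470 measurements into per-frame time series
(mean +/- SEM), frequency histograms, a Gaussian-mixture bimodality
decision, a pre/post hysteresis comparison, and the classical unpaired
t-test used for group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

#: Methods-style significance ladder: p < .05 -> *, < .001 -> **, < .0001 -> ***
DEFAULT_STAR_THRESHOLDS = (0.05, 0.001, 0.0001)


@dataclass(frozen=True)
class CompareResult:
    t_statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int


def stars_for_p(p: float, thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS) -> str:
    if np.isnan(p):
        return ""
    n = sum(p < t for t in thresholds)
    return "*" * n


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    star_thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS,
    equal_var: bool = True,
) -> CompareResult:
    """Unpaired two-tailed Student's t-test (equal variance by default)
    with a star annotation of the p-value.

    Degenerate case: both groups constant with equal means gives p = 1 by
    convention (no evidence of difference), with a warning.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("both groups constant and equal; p = 1 by convention")
            return CompareResult(0.0, 1.0, "", a.size, b.size)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return CompareResult(float(t), float(p), stars_for_p(float(p), star_thresholds), a.size, b.size)


def aggregate_timeseries(
    measurements: pd.DataFrame,
    grouping: Sequence[str] = ("compartment",),
    burn_in_hours: float = 3.0,
    ratio_col: str = "ratio",
) -> pd.DataFrame:
    """Per-group, per-frame mean ratio with SEM and n.

    ``measurements`` must carry ``frame``, ``time_min`` and a ratio column;
    undefined ratios (NaN) are dropped from the aggregates.  Frames whose
    start time falls within the first ``burn_in_hours`` are flagged
    ``burn_in=True`` — they stay in the table but downstream condition
    comparisons exclude them (cells equilibrate to the imaging environment
    over the first 2-3 h).
    """
    df = measurements.dropna(subset=[ratio_col])
    if df.empty:
        warnings.warn("no defined ratios to aggregate")
        return pd.DataFrame(
            columns=[*grouping, "frame", "time_min", "mean_ratio", "sem", "n", "burn_in"]
        )
    keys = [*grouping, "frame", "time_min"]
    extra = [c for c in ("condition",) if c in df.columns and c not in keys]

    def _agg(g: pd.DataFrame) -> pd.Series:
        x = g[ratio_col].to_numpy()
        out = {
            "mean_ratio": float(x.mean()),
            "sem": float(x.std(ddof=1) / np.sqrt(x.size)) if x.size >= 2 else np.nan,
            "n": int(x.size),
        }
        for c in extra:
            out[c] = g[c].iloc[0]
        return pd.Series(out)

    series = df.groupby(keys, sort=True).apply(_agg, include_groups=False).reset_index()
    series["n"] = series["n"].astype(int)
    series["burn_in"] = series["time_min"] < burn_in_hours * 60.0
    return series


def ratio_histogram(
    ratios: Iterable[float],
    bins: int = 30,
    range: tuple[float, float] = (0.0, 0.3),
) -> pd.DataFrame:
    """Frequency table of redox ratios over fixed bins.

    Values above the upper edge land in a logged overflow row; undefined
    (NaN) ratios are excluded and counted in the attrs.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    x = np.asarray(list(ratios), float)
    n_undefined = int(np.isnan(x).sum())
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("at least one defined ratio required")
    lo, hi = range
    counts, edges = np.histogram(x, bins=bins, range=(lo, hi))
    n_over = int((x > hi).sum())
    n_under = int((x < lo).sum())
    rows = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
        }
    )
    # np.histogram drops out-of-range values; carry them as overflow rows
    if n_under:
        rows = pd.concat(
            [pd.DataFrame({"bin_left": [-np.inf], "bin_right": [lo], "count": [n_under]}), rows],
            ignore_index=True,
        )
    if n_over:
        rows = pd.concat(
            [rows, pd.DataFrame({"bin_left": [hi], "bin_right": [np.inf], "count": [n_over]})],
            ignore_index=True,
        )
        warnings.warn(f"{n_over} ratio(s) above histogram range {hi}")
    rows["frequency"] = rows["count"] / rows["count"].sum()
    rows.attrs["n_undefined"] = n_undefined
    rows.attrs["n_total_defined"] = int(x.size)
    return rows


def ashman_d(mu1: float, mu2: float, s1: float, s2: float) -> float:
    """Two-mode separation statistic |mu1-mu2| / sqrt((s1^2+s2^2)/2)."""
    return float(abs(mu1 - mu2) / np.sqrt((s1**2 + s2**2) / 2.0))


@dataclass(frozen=True)
class BimodalityResult:
    n_components: int  # 1 or 2; 0 when insufficient data
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    delta_bic: float
    ashman_d: float
    threshold: float
    min_ashman_d: float
    n: int
    sufficient: bool = True
    min_weight: float = 0.05


def detect_bimodality(
    ratios: Sequence[float],
    min_n: int = 50,
    delta_bic_threshold: float = 10.0,
    min_separation_d: float = 2.0,
    min_weight: float = 0.05,
    seed: int = 0,
) -> BimodalityResult:
    """Decide between one and two Gaussian modes in a ratio sample.

    Fits 1- and 2-component Gaussian mixtures (k-means initialization,
    fixed seed) and reports two modes iff delta-BIC = BIC1 - BIC2 exceeds
    ``delta_bic_threshold``, the fitted components are separated by an
    Ashman D of at least ``min_separation_d``, and both components carry at
    least ``min_weight`` of the mass (a component tracking a handful of
    outliers is a degeneracy, not a mode).  Deterministic for a given seed.
    Samples below ``min_n`` yield an explicit insufficient-data result
    rather than a guess.
    """
    x = np.asarray(ratios, float)
    x = x[~np.isnan(x)]
    if x.size < min_n:
        return BimodalityResult(
            0, (), (), (), np.nan, np.nan, delta_bic_threshold, min_separation_d,
            int(x.size), sufficient=False, min_weight=min_weight,
        )
    X = x.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=seed).fit(X)
    gm2 = GaussianMixture(
        2, random_state=seed, init_params="kmeans", n_init=3, reg_covar=1e-6
    ).fit(X)
    delta_bic = float(gm1.bic(X) - gm2.bic(X))
    mus = gm2.means_.ravel()
    sds = np.sqrt(gm2.covariances_.ravel())
    wts = gm2.weights_.ravel()
    order = np.argsort(mus)
    mus, sds, wts = mus[order], sds[order], wts[order]
    d = ashman_d(mus[0], mus[1], sds[0], sds[1])
    bimodal = (
        delta_bic > delta_bic_threshold
        and d >= min_separation_d
        and wts.min() >= min_weight
    )
    if bimodal:
        return BimodalityResult(
            2, tuple(mus), tuple(sds), tuple(wts), delta_bic, d,
            delta_bic_threshold, min_separation_d, int(x.size),
            min_weight=min_weight,
        )
    return BimodalityResult(
        1,
        (float(gm1.means_.ravel()[0]),),
        (float(np.sqrt(gm1.covariances_.ravel()[0])),),
        (1.0,),
        delta_bic,
        d,
        delta_bic_threshold,
        min_separation_d,
        int(x.size),
        min_weight=min_weight,
    )


@dataclass(frozen=True)
class HysteresisResult:
    pre_mean: float
    post_mean: float
    difference: float  # pre - post; positive = more oxidized before the shift
    p_value: float
    pre_window: tuple[int, int]  # frame range [start, stop)
    post_window: tuple[int, int]


def assess_hysteresis(
    series: pd.DataFrame,
    shift_frame: int,
    window_frames: int,
    return_frame: Optional[int] = None,
) -> HysteresisResult:
    """Compare the steady state before a CO2 up-shift with the steady state
    after the return to the original condition.

    The pre window is the ``window_frames`` frames ending just before
    ``shift_frame``; the post window is the final ``window_frames`` frames of
    the series (which must lie after ``return_frame`` when given).  Means are
    compared with a two-tailed Welch test over per-frame mean ratios; the
    reported difference is pre - post, so a *negative* value means the
    population failed to return and stayed more oxidized (or the converse
    for positive values).
    """
    s = series.sort_values("frame").reset_index(drop=True)
    frames = s["frame"].to_numpy()
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2 for a test")
    pre_lo, pre_hi = shift_frame - window_frames, shift_frame
    post_hi = int(frames.max()) + 1
    post_lo = post_hi - window_frames
    if pre_lo < frames.min():
        raise ValueError("pre-shift window extends before the series")
    if return_frame is not None and post_lo < return_frame:
        raise ValueError("post-return window is longer than the post-return data")
    if post_lo < pre_hi:
        raise ValueError("pre and post windows overlap")
    pre = s.loc[(frames >= pre_lo) & (frames < pre_hi), "mean_ratio"].to_numpy()
    post = s.loc[(frames >= post_lo) & (frames < post_hi), "mean_ratio"].to_numpy()
    if pre.size < 2 or post.size < 2:
        raise ValueError("window longer than available frames")
    t, p = stats.ttest_ind(pre, post, equal_var=False)
    return HysteresisResult(
        float(pre.mean()),
        float(post.mean()),
        float(pre.mean() - post.mean()),
        float(p),
        (pre_lo, pre_hi),
        (post_lo, post_hi),
    )
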