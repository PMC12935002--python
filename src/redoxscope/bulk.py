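"""Bulk spectrofluorometer workflow.

Cultures are normalized to equal chlorophyll a content (methanol extraction,
absorbance at 665 nm), then excitation spectra of the Grx1-roGFP2 sensor are
collected from 350 to 480 nm (1-nm steps, emission 510 nm).  The redox
readout is the background-subtracted excitation ratio

    R395/470 = (I395 - b395) / (I470 - b470)

where b395 and b470 are the mean wild-type (probe-free) intensities at the
two lines.  Ratios are computed per replicate and then averaged
(mean-of-ratios); a ratio-of-mean-intensities variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .optics import WAVELENGTHS_NM
from .population import CompareResult, compare_groups

#: Chlorophyll a (ug/mL) per absorbance unit at 665 nm in methanol extracts.
CHL_A_COEFF_UG_PER_ML = 16.29

#: Chlorophyll concentration the assay dilutes cultures to (ug/mL).
CHL_TARGET_UG_PER_ML = 3.0


@dataclass(frozen=True)
class ChlorophyllResult:
    abs_665: float
    chl_conc_ug_ml: float
    dilution_factor: float


def chlorophyll_concentration(abs_665: float) -> ChlorophyllResult:
    """Chlorophyll a concentration from 665-nm absorbance of a methanol
    extract, with the dilution factor needed to reach the 3 ug/mL assay
    target.

    Raises ``ValueError`` for negative absorbance.
    """
    if abs_665 < 0:
        raise ValueError(f"absorbance must be >= 0, got {abs_665}")
    conc = CHL_A_COEFF_UG_PER_ML * abs_665
    dilution = conc / CHL_TARGET_UG_PER_ML if conc > CHL_TARGET_UG_PER_ML else 1.0
    return ChlorophyllResult(abs_665, conc, dilution)


@dataclass
class SpectrumTrace:
    """One excitation spectrum: intensity vs excitation wavelength at fixed
    emission, annotated with strain / treatment / condition / replicate."""

    intensity: np.ndarray
    wavelengths_nm: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())
    strain: str = ""
    treatment: str = "none"  # none | DTT | H2O2
    condition: str = "air"  # air | high
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.intensity.shape != self.wavelengths_nm.shape:
            raise ValueError("intensity and wavelength grids differ in length")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def at(self, wavelength_nm: float) -> float:
        """Intensity at an exact grid wavelength."""
        idx = np.nonzero(np.isclose(self.wavelengths_nm, wavelength_nm))[0]
        if idx.size != 1:
            raise ValueError(f"wavelength {wavelength_nm} nm not on the trace grid")
        return float(self.intensity[idx[0]])


@dataclass
class BulkRatioResult:
    mean_ratio: float
    sd_ratio: float
    per_replicate: list[float]
    n_used: int
    n_excluded: int
    b_395: float
    b_470: float


def bulk_ratio(
    strain_traces: Sequence[SpectrumTrace],
    wt_traces: Sequence[SpectrumTrace],
    method: Literal["mean_of_ratios", "ratio_of_means"] = "mean_of_ratios",
) -> BulkRatioResult:
    """R395/470 of a strain against wild-type backgrounds.

    WT intensities at 395 and 470 nm are averaged across WT replicates to
    give b395/b470; each strain replicate is then background-subtracted and
    ratioed, and replicate ratios averaged.  Replicates with non-positive
    denominator are excluded and counted.
    """
    if not strain_traces:
        raise ValueError("at least one strain replicate required")
    if not wt_traces:
        raise ValueError("at least one WT replicate required")
    b395 = float(np.mean([t.at(395.0) for t in wt_traces]))
    b470 = float(np.mean([t.at(470.0) for t in wt_traces]))
    i395 = np.array([t.at(395.0) for t in strain_traces])
    i470 = np.array([t.at(470.0) for t in strain_traces])
    if method == "ratio_of_means":
        den = float(i470.mean() - b470)
        if den <= 0:
            return BulkRatioResult(np.nan, np.nan, [], 0, len(strain_traces), b395, b470)
        r = float((i395.mean() - b395) / den)
        return BulkRatioResult(r, np.nan, [r], len(strain_traces), 0, b395, b470)
    num = i395 - b395
    den = i470 - b470
    ok = den > 0
    ratios = list(num[ok] / den[ok])
    if not ratios:
        return BulkRatioResult(np.nan, np.nan, [], 0, int((~ok).sum()), b395, b470)
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else np.nan
    return BulkRatioResult(mean, sd, ratios, len(ratios), int((~ok).sum()), b395, b470)


def treatment_response(
    traces_by_treatment: dict[str, Sequence[SpectrumTrace]],
    wt_traces: Sequence[SpectrumTrace],
    baseline: str = "none",
    **compare_kwargs,
) -> pd.DataFrame:
    """Per-treatment mean ratio with a two-tailed t-test of each treatment
    against the untreated baseline (the DTT / H2O2 sensitivity panel).

    Returns a tidy table with columns treatment, mean_ratio, sd_ratio, n,
    p_value, stars (baseline row has NaN p-value).
    """
    if baseline not in traces_by_treatment:
        raise ValueError(f"missing untreated baseline group {baseline!r}")
    results = {
        name: bulk_ratio(traces, wt_traces)
        for name, traces in traces_by_treatment.items()
    }
    base = results[baseline]
    rows = []
    for name, res in results.items():
        if name == baseline or len(res.per_replicate) < 2 or len(base.per_replicate) < 2:
            p, stars = (np.nan, "")
        else:
            cmp: CompareResult = compare_groups(
                base.per_replicate, res.per_replicate, **compare_kwargs
            )
            p, stars = cmp.p_value, cmp.stars
        rows.append(
            dict(
                treatment=name,
                mean_ratio=res.mean_ratio,
                sd_ratio=res.sd_ratio,
                n=res.n_used,
                n_excluded=res.n_excluded,
                p_value=p,
                stars=stars,
            )
        )
    return pd.DataFrame(rows)
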