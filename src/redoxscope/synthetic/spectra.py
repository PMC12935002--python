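"""Synthetic bulk excitation spectra with known oxidation state.

Each trace is the linear two-state mixture of the oxidized and reduced
endmember spectra, scaled by an amplitude (probe abundance x instrument
gain), plus a probe-free blank and optional Gaussian noise.  Matched WT
blank traces (blank + noise only) accompany every sample so the bulk
analysis can estimate its backgrounds the same way the assay does.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..bulk import SpectrumTrace
from ..optics import WAVELENGTHS_NM, SpectralEndmembers


def generate_spectrum(
    oxd: float,
    endmembers: SpectralEndmembers | None = None,
    amplitude: float = 1000.0,
    blank_level: float = 5.0,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    strain: str = "probe",
    treatment: str = "none",
    condition: str = "air",
) -> tuple[list[SpectrumTrace], list[SpectrumTrace]]:
    """Generate replicate probe traces and matched WT blanks.

    Returns ``(probe_traces, wt_blanks)``; each trace has 131 points on the
    350-480 nm grid.  Raises for ``oxd`` outside [0, 1].
    """
    if not 0.0 <= oxd <= 1.0:
        raise ValueError(f"oxd must lie in [0, 1], got {oxd}")
    em = endmembers or SpectralEndmembers()
    rng = np.random.default_rng(seed)
    signal = amplitude * em.mixture(oxd)
    probe, blanks = [], []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, WAVELENGTHS_NM.size) if noise_sd > 0 else 0.0
        probe.append(
            SpectrumTrace(
                intensity=signal + blank_level + noise,
                strain=strain,
                treatment=treatment,
                condition=condition,
                replicate_id=rep,
            )
        )
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, WAVELENGTHS_NM.size) if noise_sd > 0 else 0.0
        blanks.append(
            SpectrumTrace(
                intensity=np.full(WAVELENGTHS_NM.size, blank_level, float) + noise,
                strain="WT",
                treatment=treatment,
                condition=condition,
                replicate_id=rep,
            )
        )
    return probe, blanks
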