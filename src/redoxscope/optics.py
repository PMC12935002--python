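"""Two-state spectral model of the roGFP2 sensor.

roGFP2 interconverts between an oxidized (disulfide) and a reduced (dithiol)
form with distinct excitation spectra: the oxidized form is excited
efficiently near 395 nm, the reduced form near 470 nm.  Any intermediate
degree of oxidation OxD mixes the two endmember spectra linearly, so the
background-subtracted excitation ratio R395/470 is a monotone, concentration-
independent readout of OxD.

This module holds the endmember description used both by the synthetic image
generator (per-channel excitation efficiencies) and by the synthetic bulk
spectra (full 350-480 nm curves).  The two are kept consistent: the
per-channel efficiencies are the endmember curves evaluated at 395 and
470 nm, so bulk and imaging ratios of the same OxD agree exactly in the
noise-free limit.
"""

from __future__ import annotations

import enum
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

#: Excitation wavelength grid of the bulk assay (nm, 1-nm steps, 131 points).
WAVELENGTHS_NM = np.arange(350.0, 481.0, 1.0)

#: The two excitation lines used for the ratiometric readout (nm).
EX_RATIO_LINES = (395.0, 470.0)


class NoiseModel(str, enum.Enum):
    """Pixel noise model for rendered images."""

    gaussian = "gaussian"
    poisson_gaussian = "poisson_gaussian"


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


class SpectralEndmembers(BaseModel):
    """Smooth parametric endmember excitation spectra.

    The oxidized endmember is a two-Gaussian curve (dominant peak near
    395 nm plus a minor shoulder near 470 nm); the reduced endmember is a
    single Gaussian peaked near 470 nm.  Amplitudes are relative excitation
    efficiencies (dimensionless).
    """

    model_config = ConfigDict(frozen=True)

    ox_peak_nm: float = 395.0
    ox_peak_amp: float = 1.0
    ox_peak_sigma: float = 25.0
    ox_shoulder_nm: float = 470.0
    ox_shoulder_amp: float = 0.30
    ox_shoulder_sigma: float = 20.0
    red_peak_nm: float = 470.0
    red_peak_amp: float = 1.0
    red_peak_sigma: float = 20.0

    def oxidized(self, wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
        lam = WAVELENGTHS_NM if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
        return self.ox_peak_amp * _gauss(lam, self.ox_peak_nm, self.ox_peak_sigma) + (
            self.ox_shoulder_amp * _gauss(lam, self.ox_shoulder_nm, self.ox_shoulder_sigma)
        )

    def reduced(self, wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
        lam = WAVELENGTHS_NM if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
        return self.red_peak_amp * _gauss(lam, self.red_peak_nm, self.red_peak_sigma)

    def mixture(self, oxd: float, wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
        """Linear two-state mixture ``oxd * S_ox + (1 - oxd) * S_red``."""
        if not 0.0 <= oxd <= 1.0:
            raise ValueError(f"oxd must lie in [0, 1], got {oxd}")
        return oxd * self.oxidized(wavelengths_nm) + (1.0 - oxd) * self.reduced(wavelengths_nm)


class OpticalModel(BaseModel):
    """Imaging-side optical model: endmember efficiencies at the two
    excitation lines, detector gain, and additive signal components.

    ``s_ox_395`` etc. are relative excitation efficiencies of the fully
    oxidized / fully reduced sensor at 395 and 470 nm excitation.  A probe
    object with oxidation fraction ``oxd`` and per-pixel probe abundance
    ``probe`` contributes ``gain * probe * (oxd * s_ox_c + (1-oxd) * s_red_c)``
    counts at channel ``c``, on top of cellular autofluorescence and camera
    background.
    """

    model_config = ConfigDict(frozen=True)

    s_ox_395: float
    s_ox_470: float
    s_red_395: float
    s_red_470: float
    gain: float = 1.0
    autofluor_mean: float = 50.0
    background_mean: float = 100.0
    noise_model: NoiseModel = NoiseModel.poisson_gaussian
    noise_scale: float = 3.0

    @model_validator(mode="after")
    def _check(self) -> "OpticalModel":
        for name in ("s_ox_395", "s_ox_470", "s_red_395", "s_red_470", "gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.s_ox_395 / self.s_ox_470 <= self.s_red_395 / self.s_red_470:
            raise ValueError(
                "oxidized endmember must have the higher 395/470 ratio "
                "(s_ox_395/s_ox_470 > s_red_395/s_red_470)"
            )
        return self

    @classmethod
    def from_endmembers(
        cls,
        endmembers: SpectralEndmembers | None = None,
        **overrides,
    ) -> "OpticalModel":
        """Build the per-channel model by evaluating endmember curves at the
        395/470 nm excitation lines, guaranteeing bulk/imaging consistency."""
        em = endmembers or SpectralEndmembers()
        lines = np.array(EX_RATIO_LINES)
        s_ox = em.oxidized(lines)
        s_red = em.reduced(lines)
        return cls(
            s_ox_395=float(s_ox[0]),
            s_ox_470=float(s_ox[1]),
            s_red_395=float(s_red[0]),
            s_red_470=float(s_red[1]),
            **overrides,
        )

    def channel_signal(self, oxd, probe: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Noise-free probe signal (counts) at the 395 and 470 nm channels."""
        oxd = np.asarray(oxd, float)
        s395 = self.gain * probe * (oxd * self.s_ox_395 + (1.0 - oxd) * self.s_red_395)
        s470 = self.gain * probe * (oxd * self.s_ox_470 + (1.0 - oxd) * self.s_red_470)
        return s395, s470

    def ratio_from_oxd(self, oxd):
        """True background-free ratio R395/470 implied by oxidation fraction.

        Strictly increasing in ``oxd`` on [0, 1] for any valid model, and
        independent of probe abundance and gain.
        """
        s395, s470 = self.channel_signal(oxd, probe=1.0)
        return s395 / s470


def noise_free(model: OpticalModel) -> OpticalModel:
    """Copy of ``model`` with all stochastic components switched off."""
    return model.model_copy(update={"noise_model": NoiseModel.gaussian, "noise_scale": 0.0})


#: Default endmembers and imaging model shared by generator defaults.
DEFAULT_ENDMEMBERS = SpectralEndmembers()


def default_optical_model(**overrides) -> OpticalModel:
    return OpticalModel.from_endmembers(DEFAULT_ENDMEMBERS, **overrides)
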