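"""Parametric scalar optics model for the doughnut-scan microscope.

The excitation focus is the vortex ("doughnut") profile

    Exc(rho) ∝ (rho^2 / w^2) * exp(-2 rho^2 / w^2),

which is exactly zero on axis, radially symmetric, and peaks on the ring
rho = w / sqrt(2). The detection point-spread function is an isotropic 2D
Gaussian of standard deviation sigma_det, integrated over each detector
element's square active area (the array is descanned, so element positions
are fixed in sample space). Defaults tie both widths to the diffraction
scale: w = 0.61 * lambda_exc / NA and sigma_det = 0.21 * lambda_em / NA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = ["OpticsModel"]


@dataclass(frozen=True)
class OpticsModel:
    """Optical parameters of the excitation and detection paths.

    All lengths in nm. ``doughnut_waist`` and ``detection_sigma`` may be set
    explicitly; when left ``None`` they derive from the wavelengths and NA.
    """

    wavelength_exc: float = 635.0
    wavelength_em: float = 660.0
    numerical_aperture: float = 1.4
    refractive_index: float = 1.5
    doughnut_waist: float | None = None
    detection_sigma: float | None = None

    def __post_init__(self):
        for name in ("wavelength_exc", "wavelength_em",
                     "numerical_aperture", "refractive_index"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.numerical_aperture > self.refractive_index:
            raise ValueError("NA cannot exceed the refractive index")
        if self.doughnut_waist is None:
            object.__setattr__(
                self, "doughnut_waist",
                0.61 * self.wavelength_exc / self.numerical_aperture)
        if self.detection_sigma is None:
            object.__setattr__(
                self, "detection_sigma",
                0.21 * self.wavelength_em / self.numerical_aperture)
        if self.doughnut_waist <= 0 or self.detection_sigma <= 0:
            raise ValueError("derived optical widths must be positive")

    @property
    def doughnut_peak_radius(self) -> float:
        """Radius of the doughnut intensity maximum, w/sqrt(2) [nm]."""
        return self.doughnut_waist / np.sqrt(2.0)

    def excitation(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Doughnut excitation intensity at sample points (unnormalized).

        Peak value is exp(-1)/2 at rho = w/sqrt(2); exactly 0 at the origin.
        """
        w2 = self.doughnut_waist ** 2
        rho2 = np.asarray(x, float) ** 2 + np.asarray(y, float) ** 2
        return (rho2 / w2) * np.exp(-2.0 * rho2 / w2)

    def element_detection_1d(self, coord: np.ndarray, center: float,
                             size: float) -> np.ndarray:
        """Gaussian detection PSF integrated over one axis of a square element.

        Probability (per that axis) that a photon from an emitter at ``coord``
        lands inside [center - size/2, center + size/2].
        """
        s = self.detection_sigma
        u = np.asarray(coord, float)
        return (ndtr((center + size / 2 - u) / s)
                - ndtr((center - size / 2 - u) / s))
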