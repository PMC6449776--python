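"""Partial volume correction by iterative reblurred Van Cittert deconvolution.

PET scanners blur the true tracer distribution with a point spread
function (PSF) that is wide relative to small brain structures, causing
spill-out of signal from hot regions and spill-in from their surround.
The reblurred Van Cittert iteration inverts this blur approximately:

    f_0 = g,      f_{k+1} = f_k + alpha * h (x) (g - h (x) f_k)

where ``g`` is the observed image, ``h`` an isotropic 3-D Gaussian PSF,
``(x)`` convolution, and ``alpha`` the step length.  Reblurring the
residual with ``h`` damps the noise amplification of the classic Van
Cittert scheme.  The iteration stops once the relative percent change
between successive iterates falls below a tolerance (default 1%), with
step length alpha = 1.5 and an 8 mm FWHM PSF as defaults.

Iterates are *not* clipped to non-negative values: clipping would break
the linear flux-transfer property (the global sum error contracts by a
factor |1 - alpha| per iteration), so small negative excursions are
reported to the caller instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import VolumeImage

__all__ = [
    "PSFModel",
    "PVCConfig",
    "PVCResult",
    "DivergenceError",
    "fwhm_to_sigma",
    "gaussian_blur",
    "relative_percent_change",
    "reblurred_van_cittert",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class DivergenceError(RuntimeError):
    """Raised when the deconvolution residual change grows instead of contracting."""


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    if fwhm_mm < 0:
        raise ValueError(f"FWHM must be non-negative, got {fwhm_mm}")
    return fwhm_mm / _FWHM_PER_SIGMA


@dataclass(frozen=True)
class PSFModel:
    """Isotropic 3-D Gaussian point spread function."""

    fwhm_mm: float

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError(f"PSF FWHM must be non-negative, got {self.fwhm_mm}")

    @property
    def sigma_mm(self) -> float:
        return fwhm_to_sigma(self.fwhm_mm)


@dataclass(frozen=True)
class PVCConfig:
    """Iteration settings: step length, stopping tolerance and iteration cap."""

    alpha: float = 1.5
    tol_percent: float = 1.0
    max_iter: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 2:
            raise ValueError(f"alpha must be in (0, 2), got {self.alpha}")
        if self.tol_percent <= 0:
            raise ValueError(f"tol_percent must be positive, got {self.tol_percent}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass(frozen=True)
class PVCResult:
    """Outcome of the deconvolution: corrected image plus iteration diagnostics."""

    corrected: VolumeImage
    n_iterations: int
    change_history: list[float] = field(default_factory=list)
    n_negative_voxels: int = 0


def gaussian_blur(image: VolumeImage, psf: PSFModel) -> VolumeImage:
    """Convolve with the PSF, honouring anisotropic voxel sizes per axis.

    Uses mirror ("reflect") boundary handling so the unit-sum kernel
    conserves flux on constant fields; ``fwhm = 0`` returns the input
    unchanged.
    """
    if psf.fwhm_mm == 0:
        return image
    sigma_vox = [psf.sigma_mm / v for v in image.voxel_size_mm]
    blurred = ndimage.gaussian_filter(image.values, sigma=sigma_vox, mode="reflect")
    return image.with_values(blurred)


def relative_percent_change(f_new: VolumeImage | np.ndarray, f_old: VolumeImage | np.ndarray) -> float:
    """Global L1 change ratio, 100 * sum|f_new - f_old| / sum|f_old|."""
    new = f_new.values if isinstance(f_new, VolumeImage) else np.asarray(f_new, float)
    old = f_old.values if isinstance(f_old, VolumeImage) else np.asarray(f_old, float)
    if new.shape != old.shape:
        raise ValueError(f"shape mismatch: {new.shape} vs {old.shape}")
    denom = np.abs(old).sum()
    if denom == 0:
        raise ValueError("reference image is identically zero")
    return float(100.0 * np.abs(new - old).sum() / denom)


def reblurred_van_cittert(
    observed: VolumeImage,
    psf: PSFModel,
    config: PVCConfig | None = None,
    initial: VolumeImage | None = None,
) -> PVCResult:
    """Deconvolve ``observed`` with the reblurred Van Cittert iteration.

    Returns the final iterate, the number of update steps performed and
    the relative-percent-change history (one entry per update).  A
    divergence guard aborts if the change grows above its initial value
    for three consecutive iterations.  ``initial`` warm-starts the
    iteration (default: the observed image itself); since the global sum
    error contracts by a factor ``1 - alpha`` per step, the corrected
    image's total flux matches the observed image's regardless of the
    start.
    """
    if config is None:
        config = PVCConfig()
    if psf.fwhm_mm <= 0:
        raise ValueError("PSF FWHM must be positive for deconvolution")

    g = observed.values
    if initial is not None:
        if initial.shape != observed.shape:
            raise ValueError("initial image must share the observed image's grid")
        f = initial.values.copy()
    else:
        f = g.copy()
    history: list[float] = []
    n_growth = 0
    for _ in range(config.max_iter):
        residual = g - gaussian_blur(observed.with_values(f), psf).values
        update = config.alpha * gaussian_blur(observed.with_values(residual), psf).values
        f_new = f + update
        change = relative_percent_change(f_new, f)
        history.append(change)
        f = f_new
        if change < config.tol_percent:
            break
        if len(history) > 1 and change > history[-2] and change > history[0]:
            n_growth += 1
            if n_growth >= 3:
                raise DivergenceError(
                    f"relative change grew for 3 consecutive iterations "
                    f"(history tail {history[-4:]})"
                )
        else:
            n_growth = 0

    return PVCResult(
        corrected=observed.with_values(f),
        n_iterations=len(history),
        change_history=history,
        n_negative_voxels=int((f < 0).sum()),
    )
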