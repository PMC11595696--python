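"""Free-space propagators between the sample exit plane and the detector.

Two regimes are supported:

* ``far_field`` — a centered, unitary discrete Fourier transform.  With
  the orthonormal normalization Parseval holds exactly, so the modulus
  projection needs no rescaling.
* ``near_field_asm`` — the angular-spectrum method: multiply the
  spectrum by the transfer function
  ``H(f) = exp(i 2 pi d sqrt(1/lambda^2 - |f|^2))`` and inverse
  transform.  Evanescent components (``|f| > 1/lambda``) are zeroed,
  not attenuated, so the operator remains deterministic and unitary on
  the propagating band.

Spectra are zero-frequency centered throughout; the fftshift
bookkeeping is folded into the operators and never exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2, ifftshift

from .data_model import DetectorGeometry, InvalidInputError


@dataclass(frozen=True)
class PropagatorSpec:
    """Parameters of a free-space propagator.

    For the far field the distance only fixes the effective pixel of the
    reconstruction, not the operator itself; for the angular spectrum
    method ``pixel_m`` is the sampling of the wavefront plane.
    """

    regime: str
    frame_shape: Tuple[int, int]
    wavelength_m: Optional[float] = None
    distance_m: Optional[float] = None
    pixel_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.regime not in ("far_field", "near_field_asm"):
            raise InvalidInputError(f"unknown propagator regime {self.regime!r}")
        if self.regime == "near_field_asm":
            for name in ("wavelength_m", "distance_m", "pixel_m"):
                if getattr(self, name) is None:
                    raise InvalidInputError(f"near-field propagation requires {name}")

    @classmethod
    def from_geometry(cls, geometry: DetectorGeometry) -> "PropagatorSpec":
        regime = "far_field" if geometry.regime == "far_field" else "near_field_asm"
        return cls(
            regime=regime,
            frame_shape=tuple(geometry.frame_shape),
            wavelength_m=geometry.wavelength_m,
            distance_m=geometry.distance_m,
            pixel_m=geometry.pixel_m,
        )


def _check_shape(wavefront: np.ndarray, spec: PropagatorSpec) -> None:
    if wavefront.shape[-2:] != tuple(spec.frame_shape):
        raise InvalidInputError(
            f"wavefront shape {wavefront.shape[-2:]} does not match "
            f"frame_shape {spec.frame_shape}"
        )


def _asm_transfer(spec: PropagatorSpec, distance_m: float) -> np.ndarray:
    lam = spec.wavelength_m
    ny, nx = spec.frame_shape
    fy = fftfreq(ny, d=spec.pixel_m)
    fx = fftfreq(nx, d=spec.pixel_m)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    arg = 1.0 / lam**2 - f2
    propagating = arg > 0
    H = np.zeros((ny, nx), dtype=complex)
    H[propagating] = np.exp(2j * np.pi * distance_m * np.sqrt(arg[propagating]))
    return H


def _asm_sampling_check(spec: PropagatorSpec) -> None:
    # standard aliasing bound for the ASM transfer function
    M = spec.frame_shape[0]
    criterion = spec.wavelength_m * abs(spec.distance_m) / (M * spec.pixel_m**2)
    if criterion > 1.0:
        warnings.warn(
            f"angular-spectrum sampling criterion lambda*d/(M*p^2) = "
            f"{criterion:.3g} exceeds 1; the transfer function is aliased",
            stacklevel=3,
        )


def to_detector(wavefront: np.ndarray, spec: PropagatorSpec) -> np.ndarray:
    """Propagate a (stack of) wavefront(s) to the detector plane."""
    _check_shape(wavefront, spec)
    if spec.regime == "far_field":
        return fftshift(
            fft2(ifftshift(wavefront, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
        )
    _asm_sampling_check(spec)
    H = _asm_transfer(spec, spec.distance_m)
    return ifft2(fft2(wavefront) * H)


def from_detector(detector_wavefront: np.ndarray, spec: PropagatorSpec) -> np.ndarray:
    """Exact inverse of :func:`to_detector` (propagation by ``-d`` for ASM)."""
    _check_shape(detector_wavefront, spec)
    if spec.regime == "far_field":
        return fftshift(
            ifft2(ifftshift(detector_wavefront, axes=(-2, -1)), norm="ortho"),
            axes=(-2, -1),
        )
    _asm_sampling_check(spec)
    H = _asm_transfer(spec, -spec.distance_m)
    return ifft2(fft2(detector_wavefront) * H)
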