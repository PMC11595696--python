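"""Core domain types and geometry math for ptychographic reconstruction.

Conventions used throughout the package:

* arrays are row-major with coordinates ordered ``(y, x)``, origin at the
  top-left of the object canvas, 0-based indices;
* a scan position maps to the offset of the probe window's *top-left*
  corner on the object canvas; windows are half-open, ``[off, off + M)``;
* intensities are stored as 32-bit floats on disk and promoted to float64
  for computation; complex fields are stored as complex64 (pairs of 32-bit
  floats) on disk and promoted to complex128 in memory.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

#: Planck constant times speed of light, in keV * nm.  Fixed here so that
#: wavelength conversions are bit-reproducible across platforms.
HC_KEV_NM = 1.23984193

Regime = Literal["far_field", "near_field"]


class PtychoError(Exception):
    """Base class for errors raised by ptychokit."""


class InvalidInputError(PtychoError, ValueError):
    """A physical or structural precondition on an input was violated."""


class CanvasError(PtychoError, ValueError):
    """A probe window does not fit on the object canvas."""


class DatasetLayoutError(PtychoError, ValueError):
    """An on-disk container does not conform to the documented layout."""


def wavelength_from_energy(energy_keV: float) -> float:
    """Photon wavelength lambda = hc / E, returned in meters.

    Parameters
    ----------
    energy_keV : float
        Photon energy in keV, strictly positive.
    """
    if not np.isfinite(energy_keV) or energy_keV <= 0:
        raise InvalidInputError(f"photon energy must be positive, got {energy_keV!r}")
    return HC_KEV_NM / energy_keV * 1e-9


@dataclass(frozen=True)
class DetectorGeometry:
    """Detector and beam geometry of one acquisition.

    Attributes
    ----------
    energy_keV : float
        Photon energy (keV).
    distance_m : float
        Sample-to-detector distance d (m).
    pixel_m : float
        Detector pixel pitch p (m).
    frame_shape : (int, int)
        Detector frame shape (M, M); square with even side.
    regime : {"far_field", "near_field"}
        Propagation regime between sample and detector.
    """

    energy_keV: float
    distance_m: float
    pixel_m: float
    frame_shape: Tuple[int, int]
    regime: Regime = "far_field"

    def __post_init__(self) -> None:
        for name in ("energy_keV", "distance_m", "pixel_m"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidInputError(f"{name} must be strictly positive, got {v!r}")
        m, n = self.frame_shape
        if m != n or m <= 0 or m % 2:
            raise InvalidInputError(
                f"frame_shape must be square with even side, got {self.frame_shape}"
            )
        if self.regime not in ("far_field", "near_field"):
            raise InvalidInputError(f"unknown regime {self.regime!r}")

    @property
    def wavelength_m(self) -> float:
        """Wavelength lambda = hc/E (m)."""
        return wavelength_from_energy(self.energy_keV)


def effective_pixel_size(geometry: DetectorGeometry) -> float:
    """Real-space sampling interval of the reconstruction (m).

    In the far field the object/probe pixel follows the Fourier sampling
    relation ``dx = lambda * d / (M * p)`` where M is the frame side and p
    the detector pitch.  In the near field the reconstruction pixel equals
    the detector pixel; that value is returned with a notice.
    """
    if geometry.regime == "near_field":
        warnings.warn(
            "near-field reconstruction pixel equals the detector pixel",
            stacklevel=2,
        )
        return geometry.pixel_m
    M = geometry.frame_shape[0]
    return geometry.wavelength_m * geometry.distance_m / (M * geometry.pixel_m)


@dataclass
class ScanPattern:
    """Transverse scan coordinates of the probe on the sample.

    ``positions_m`` holds N rows of metric ``(y, x)`` coordinates.  Pixel
    offsets are derived from them via :func:`positions_to_pixel_offsets`
    and cached in ``positions_px`` (possibly fractional before rounding).
    """

    positions_m: np.ndarray
    positions_px: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions_m = np.atleast_2d(np.asarray(self.positions_m, dtype=float))
        if self.positions_m.ndim != 2 or self.positions_m.shape[1] != 2:
            raise InvalidInputError(
                f"positions must be N x 2, got shape {self.positions_m.shape}"
            )
        if len(self.positions_m) < 1:
            raise InvalidInputError("a scan needs at least one position")

    @property
    def n_positions(self) -> int:
        return len(self.positions_m)


def positions_to_pixel_offsets(
    scan: ScanPattern,
    pixel_m: float,
    rounding: str = "even",
) -> Tuple[np.ndarray, np.ndarray]:
    """Convert metric scan positions to integer pixel offsets.

    Returns ``(offsets, residuals)`` where ``offsets`` is an ``(N, 2)``
    int array and ``residuals`` the sub-pixel remainders (in pixels) lost
    to rounding.  ``rounding='even'`` rounds half to even (the default);
    ``'floor'`` truncates toward minus infinity.
    """
    if pixel_m <= 0:
        raise InvalidInputError(f"pixel size must be positive, got {pixel_m!r}")
    frac = scan.positions_m / pixel_m
    if rounding == "even":
        offsets = np.round(frac).astype(int)
    elif rounding == "floor":
        offsets = np.floor(frac).astype(int)
    else:
        raise InvalidInputError(f"unknown rounding rule {rounding!r}")
    residuals = frac - offsets
    scan.positions_px = frac
    return offsets, residuals


def check_windows_on_canvas(
    offsets: np.ndarray, frame_shape: Tuple[int, int], canvas_shape: Tuple[int, int]
) -> None:
    """Raise :class:`CanvasError` listing every probe window that escapes."""
    m, n = frame_shape
    H, W = canvas_shape
    bad = np.nonzero(
        (offsets[:, 0] < 0)
        | (offsets[:, 1] < 0)
        | (offsets[:, 0] + m > H)
        | (offsets[:, 1] + n > W)
    )[0]
    if bad.size:
        raise CanvasError(
            f"canvas {canvas_shape} too small for {m}x{n} probe windows at "
            f"scan indices {bad.tolist()}"
        )


def normalize_offsets(
    offsets: np.ndarray, frame_shape: Tuple[int, int], margin: int = 8
) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Shift offsets so the scan starts ``margin`` px from the canvas edge.

    Returns the shifted offsets and the canvas shape
    ``(max offset + frame + 2 * margin)`` that contains every window.
    """
    off = np.asarray(offsets, dtype=int)
    off = off - off.min(axis=0) + margin
    H = int(off[:, 0].max()) + frame_shape[0] + margin
    W = int(off[:, 1].max()) + frame_shape[1] + margin
    return off, (H, W)


@dataclass
class DiffractionStack:
    """Measured intensity frames, trust masks, scan and geometry."""

    intensities: np.ndarray
    scan: ScanPattern
    geometry: DetectorGeometry
    masks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise InvalidInputError(
                f"intensities must be N x M x M, got shape {self.intensities.shape}"
            )
        if np.any(self.intensities < 0):
            raise InvalidInputError("intensities must be nonnegative")
        n, m, mm = self.intensities.shape
        if (m, mm) != tuple(self.geometry.frame_shape):
            raise InvalidInputError(
                f"frame shape {(m, mm)} disagrees with geometry "
                f"{self.geometry.frame_shape}"
            )
        if n != self.scan.n_positions:
            raise InvalidInputError(
                f"{n} frames but {self.scan.n_positions} scan positions"
            )
        if self.masks is None:
            self.masks = np.ones((m, mm), dtype=np.uint8)
        else:
            self.masks = np.asarray(self.masks)
            if not np.isin(self.masks, (0, 1)).all():
                raise InvalidInputError("masks must be binary (0/1)")
            if self.masks.shape not in ((m, mm), (n, m, mm)):
                raise InvalidInputError(
                    f"mask shape {self.masks.shape} incompatible with frames"
                )
            self.masks = self.masks.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    def mask_for(self, i: int) -> np.ndarray:
        """Trust mask of frame ``i`` (shared mask broadcast when 2-D)."""
        return self.masks if self.masks.ndim == 2 else self.masks[i]


@dataclass
class ObjectField:
    """Complex transmission function O(r) on a padded canvas."""

    values: np.ndarray
    pixel_m: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise InvalidInputError("object canvas must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("object canvas contains non-finite entries")
        if self.pixel_m <= 0:
            raise InvalidInputError("object pixel size must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass
class ProbeStack:
    """K mutually incoherent probe modes sharing one support grid.

    Modes are ordered by decreasing power; ``occupancies`` are the
    relative mode powers, normalized to sum 1 after orthogonalization.
    """

    modes: np.ndarray
    occupancies: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=complex)
        if self.modes.ndim == 2:
            self.modes = self.modes[None]
        if self.modes.ndim != 3:
            raise InvalidInputError("probe modes must be K x M x M")
        if self.occupancies is None:
            power = np.array([np.sum(np.abs(m) ** 2) for m in self.modes])
            total = power.sum()
            self.occupancies = power / total if total > 0 else power
        else:
            self.occupancies = np.asarray(self.occupancies, dtype=float)
            if len(self.occupancies) != len(self.modes):
                raise InvalidInputError("one occupancy per probe mode required")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.modes.shape[1:]


_ENGINES = ("ap", "dm", "raar", "rpie", "mpie", "ml")


@dataclass
class ReconConfig:
    """Engine selection and hyper-parameters for one reconstruction block.

    ``beta`` is the RAAR relaxation; ``step_o/step_p`` and ``reg_o/reg_p``
    are the rPIE step sizes and regularizers; ``gamma`` the ML misfit
    exponent; ``batch_size``/``n_workers`` drive the batching scheduler.
    """

    engine: str = "dm"
    iterations: int = 100
    beta: float = 0.9
    step_o: float = 1.0
    step_p: float = 1.0
    reg_o: float = 0.1
    reg_p: float = 0.1
    gamma: float = 1.0
    batch_size: Optional[int] = None
    n_workers: int = 1
    probe_support_diameter_m: Optional[float] = None
    probe_update_start: int = 3
    momentum_friction: float = 0.9
    momentum_friction_probe: float = 0.0
    momentum_interval: Optional[int] = None
    position_correction: Optional[dict] = None
    amplitude_error: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.engine not in _ENGINES:
            raise InvalidInputError(
                f"unknown engine {self.engine!r}; choose from {_ENGINES}"
            )
        if self.iterations < 0:
            raise InvalidInputError("iterations must be >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise InvalidInputError(f"RAAR beta must lie in [0, 1], got {self.beta}")
        if self.engine in ("rpie", "mpie"):
            if self.batch_size not in (None, 1):
                raise InvalidInputError(
                    f"{self.engine} is sequential: batch_size must be 1"
                )
            self.batch_size = 1
            if self.n_workers != 1:
                raise InvalidInputError(f"{self.engine} runs on a single worker")
            if not (self.step_o > 0 and self.step_p > 0):
                raise InvalidInputError("rPIE step sizes must be positive")
            for name in ("reg_o", "reg_p"):
                v = getattr(self, name)
                if not 0.0 <= v <= 1.0:
                    raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")
        if self.engine == "ml" and self.gamma not in (0.5, 1.0):
            raise InvalidInputError(f"gamma must be 1/2 or 1, got {self.gamma}")
        if self.n_workers < 1:
            raise InvalidInputError("n_workers must be >= 1")


@dataclass
class ReconResult:
    """Output bundle of a reconstruction run."""

    object: ObjectField
    probe: ProbeStack
    error_trace: np.ndarray
    positions: ScanPattern
    config_echo: Sequence[ReconConfig] = field(default_factory=list)
    offsets_px: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.error_trace = np.asarray(self.error_trace, dtype=float)
        if not np.all(np.isfinite(self.error_trace)):
            raise InvalidInputError("error trace contains non-finite values")


def config_to_dict(cfg: ReconConfig) -> dict:
    return dataclasses.asdict(cfg)
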