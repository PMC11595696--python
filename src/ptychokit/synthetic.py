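"""Forward simulator producing ground-truthed ptychographic datasets.

The generator emulates the statistical structure of a far-field
benchmark acquisition: a complex object built from two grayscale images
(magnitude and phase), a circular constant-phase probe, a jittered
raster scan (the jitter breaks the raster-grid pathology), far-field
intensities, and optional Poisson counting noise.  A procedural phantom
(smooth background, disks, and bar strokes) ships with the package so
no external image assets are needed.

Datasets are pure functions of ``(spec, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .data_model import (
    DetectorGeometry,
    DiffractionStack,
    InvalidInputError,
    ObjectField,
    ProbeStack,
    ScanPattern,
    check_windows_on_canvas,
    effective_pixel_size,
)
from .propagation import PropagatorSpec, to_detector


@dataclass
class PhantomSpec:
    """Full description of a synthetic acquisition.

    ``magnitude_image``/``phase_image`` are grayscale sources rescaled to
    ``[mag_min, 1]`` and ``[0, phase_max]`` rad; when ``None`` the
    procedural phantom is used.  Scan steps and jitter are in object
    pixels.  ``photons_per_frame=None`` means noiseless.
    """

    object_shape: Tuple[int, int] = (400, 400)
    probe_shape: Tuple[int, int] = (180, 180)
    magnitude_image: Optional[np.ndarray] = None
    phase_image: Optional[np.ndarray] = None
    mag_min: float = 0.2
    phase_max: float = np.pi / 2
    grid_shape: Tuple[int, int] = (20, 20)
    step_px: float = 11.0
    jitter_sigma_px: Optional[float] = None
    probe_diameter_px: Optional[float] = None
    photons_per_frame: Optional[float] = None
    geometry: Optional[DetectorGeometry] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mag_min <= 1.0:
            raise InvalidInputError(f"mag_min must lie in (0, 1], got {self.mag_min}")
        if self.jitter_sigma_px is None:
            # small enough to preserve overlap, large enough to break
            # the raster symmetry
            self.jitter_sigma_px = 0.25 * self.step_px
        if self.jitter_sigma_px < 0:
            raise InvalidInputError("jitter sigma must be >= 0")
        if self.probe_diameter_px is None:
            self.probe_diameter_px = 0.75 * self.probe_shape[0]
        if self.geometry is None:
            self.geometry = DetectorGeometry(
                energy_keV=12.0,
                distance_m=1.1,
                pixel_m=55e-6,
                frame_shape=self.probe_shape,
            )


def object_from_refraction(
    delta_map: np.ndarray,
    beta_map: np.ndarray,
    wavelength_m: float,
    pixel_m: float = 1.0,
) -> ObjectField:
    """Thin-sample transmission from projected refractive-index maps.

    Under the projection approximation the complex index
    ``n = 1 - delta + i*beta`` gives, for beam-direction projections
    ``delta_proj``/``beta_proj`` (dimensionless products of index times
    thickness), the transmission

        ``O = exp(-k * beta_proj) * exp(-i * k * delta_proj)``

    with ``k = 2 pi / lambda``.  ``|O| <= 1`` whenever ``beta_proj >= 0``.
    """
    delta_map = np.asarray(delta_map, dtype=float)
    beta_map = np.asarray(beta_map, dtype=float)
    if delta_map.shape != beta_map.shape:
        raise InvalidInputError("delta and beta maps must share a shape")
    if not (np.all(np.isfinite(delta_map)) and np.all(np.isfinite(beta_map))):
        raise InvalidInputError("refraction maps contain non-finite entries")
    if np.any(beta_map < 0):
        warnings.warn(
            "negative beta projection implies amplification (unphysical)",
            stacklevel=2,
        )
    k = 2.0 * np.pi / wavelength_m
    values = np.exp(-k * beta_map) * np.exp(-1j * k * delta_map)
    return ObjectField(values, pixel_m=pixel_m)


def _rescale(img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    span = img.max() - img.min()
    if span == 0:
        return np.full_like(img, (lo + hi) / 2.0)
    return lo + (img - img.min()) * (hi - lo) / span


def object_from_images(
    magnitude_image: np.ndarray,
    phase_image: np.ndarray,
    spec: PhantomSpec,
) -> ObjectField:
    """Complex object from two grayscale images.

    Magnitude is rescaled to ``[mag_min, 1]``, phase to
    ``[0, phase_max]`` rad; ``O = mag * exp(i * phase)``.
    """
    from skimage.transform import resize

    shape = tuple(spec.object_shape)
    mag = np.asarray(magnitude_image, dtype=float)
    pha = np.asarray(phase_image, dtype=float)
    if mag.shape != shape:
        mag = resize(mag, shape, anti_aliasing=True)
    if pha.shape != shape:
        pha = resize(pha, shape, anti_aliasing=True)
    if mag.max() == mag.min() and spec.mag_min == 1.0:
        warnings.warn("constant magnitude with mag_min=1: degenerate contrast",
                      stacklevel=2)
    mag = _rescale(mag, spec.mag_min, 1.0)
    pha = _rescale(pha, 0.0, spec.phase_max)
    px = effective_pixel_size(spec.geometry)
    return ObjectField(mag * np.exp(1j * pha), pixel_m=px)


def phantom_image(shape: Tuple[int, int], seed: int = 0) -> np.ndarray:
    """Deterministic procedural grayscale test image in [0, 1].

    A smooth low-frequency background with randomly placed filled disks
    and bar strokes, giving both smooth gradients and sharp edges.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    img = 0.35 + 0.25 * np.sin(2 * np.pi * xx / W * (1 + rng.uniform())) * np.cos(
        2 * np.pi * yy / H * (1 + rng.uniform())
    )
    for _ in range(12):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        r = rng.uniform(0.04, 0.16) * min(H, W)
        level = rng.uniform(0.0, 1.0)
        img = np.where((yy - cy) ** 2 + (xx - cx) ** 2 < r**2, level, img)
    for _ in range(8):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        h = rng.uniform(0.02, 0.05) * H
        w = rng.uniform(0.1, 0.3) * W
        level = rng.uniform(0.0, 1.0)
        bar = (np.abs(yy - cy) < h / 2) & (np.abs(xx - cx) < w / 2)
        img = np.where(bar, level, img)
    return np.clip(img, 0.0, 1.0)


def probe_circular(spec: PhantomSpec) -> ProbeStack:
    """Single-mode circular top-hat probe of constant phase."""
    M = spec.probe_shape[0]
    d = spec.probe_diameter_px
    if d <= 0:
        raise InvalidInputError("probe diameter must be positive")
    if d > M:
        raise InvalidInputError(f"probe diameter {d} px exceeds frame side {M}")
    c = (M - 1) / 2.0
    yy, xx = np.mgrid[0:M, 0:M].astype(float)
    disk = ((yy - c) ** 2 + (xx - c) ** 2 <= (d / 2.0) ** 2).astype(complex)
    if not disk.any():
        raise InvalidInputError("probe disk rasterizes to zero pixels")
    return ProbeStack(disk[None], occupancies=np.array([1.0]))


def scan_raster_jittered(spec: PhantomSpec) -> Tuple[ScanPattern, np.ndarray, int]:
    """Jittered raster grid in object pixels.

    Returns ``(scan, offsets_px, n_clamped)``: metric positions, integer
    top-left window offsets on the object canvas, and the number of
    coordinates clamped to keep every window on the canvas.
    """
    rng = np.random.default_rng(spec.seed)
    gy, gx = spec.grid_shape
    base = np.array(
        [(iy * spec.step_px, ix * spec.step_px) for iy in range(gy) for ix in range(gx)],
        dtype=float,
    )
    jitter = rng.normal(0.0, spec.jitter_sigma_px, size=base.shape)
    pos_px = base + jitter
    H, W = spec.object_shape
    m = spec.probe_shape[0]
    hi = np.array([H - m, W - m], dtype=float)
    if np.any(hi < 0):
        raise InvalidInputError("probe frame larger than the object canvas")
    clamped = np.clip(pos_px, 0.0, hi)
    n_clamped = int(np.sum(clamped != pos_px))
    offsets = np.round(clamped).astype(int)
    px = effective_pixel_size(spec.geometry)
    scan = ScanPattern(clamped * px)
    return scan, offsets, n_clamped


def forward_intensities(
    obj: ObjectField,
    probe: ProbeStack,
    scan: ScanPattern,
    geometry: DetectorGeometry,
    offsets: Optional[np.ndarray] = None,
) -> DiffractionStack:
    """Noiseless far-/near-field intensities of the multiplicative model.

    ``I_i = sum_m |D_d{P_m * O[window_i]}|^2`` — an incoherent sum over
    probe modes.
    """
    m = probe.frame_shape[0]
    if offsets is None:
        from .data_model import positions_to_pixel_offsets

        offsets, _ = positions_to_pixel_offsets(scan, obj.pixel_m)
    check_windows_on_canvas(offsets, probe.frame_shape, obj.shape)
    spec = PropagatorSpec.from_geometry(geometry)
    n = len(offsets)
    I = np.empty((n, m, m))
    for i, (oy, ox) in enumerate(offsets):
        window = obj.values[oy : oy + m, ox : ox + m]
        psi = probe.modes * window[None]
        I[i] = np.sum(np.abs(to_detector(psi, spec)) ** 2, axis=0)
    return DiffractionStack(
        intensities=I, scan=scan, geometry=geometry, masks=None
    )


def apply_counting_noise(
    stack: DiffractionStack, photons_per_frame: float, seed: int
) -> Tuple[DiffractionStack, float]:
    """Poisson-sample frames at a target mean photon budget.

    Frames are scaled so the mean total count per frame equals
    ``photons_per_frame``, Poisson-sampled, and returned together with
    the applied scale factor (counts per original intensity unit).
    """
    if photons_per_frame <= 0:
        raise InvalidInputError("photon budget must be positive")
    rng = np.random.default_rng(seed)
    mean_sum = stack.intensities.sum(axis=(1, 2)).mean()
    scale = photons_per_frame / mean_sum
    noisy = rng.poisson(stack.intensities * scale).astype(float) / scale
    out = dataclasses.replace(stack, intensities=noisy)
    return out, scale


PRESETS = {
    # the published benchmark geometry: 400x400 object, 180x180 probe,
    # 20x20 jittered raster grid (400 positions)
    "full_benchmark": dict(
        object_shape=(400, 400),
        probe_shape=(180, 180),
        grid_shape=(20, 20),
        step_px=11.0,
    ),
    # small configuration for fast end-to-end checks
    "small_test": dict(
        object_shape=(64, 64),
        probe_shape=(32, 32),
        grid_shape=(5, 5),
        step_px=8.0,
    ),
}


def make_spec(preset: str = "small_test", seed: int = 0, **overrides) -> PhantomSpec:
    if preset not in PRESETS:
        raise InvalidInputError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)} or build "
            "a PhantomSpec directly"
        )
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return PhantomSpec(seed=seed, **kwargs)


def simulate(spec: PhantomSpec):
    """Generate (stack, truth_object, truth_probe, offsets, manifest)."""
    mag = (
        spec.magnitude_image
        if spec.magnitude_image is not None
        else phantom_image(spec.object_shape, seed=spec.seed + 101)
    )
    pha = (
        spec.phase_image
        if spec.phase_image is not None
        else phantom_image(spec.object_shape, seed=spec.seed + 202)
    )
    obj = object_from_images(mag, pha, spec)
    probe = probe_circular(spec)
    scan, offsets, n_clamped = scan_raster_jittered(spec)
    stack = forward_intensities(obj, probe, scan, spec.geometry, offsets=offsets)
    scale = None
    if spec.photons_per_frame is not None:
        stack, scale = apply_counting_noise(
            stack, spec.photons_per_frame, seed=spec.seed + 303
        )
    overlap = 1.0 - spec.step_px / spec.probe_diameter_px
    if overlap < 0.6:
        warnings.warn(
            f"linear probe overlap {overlap:.0%} is below 60%; reconstruction "
            "may be under-determined",
            stacklevel=2,
        )
    manifest = {
        "n_frames": stack.n_frames,
        "object_shape": list(spec.object_shape),
        "probe_shape": list(spec.probe_shape),
        "grid_shape": list(spec.grid_shape),
        "step_px": spec.step_px,
        "jitter_sigma_px": spec.jitter_sigma_px,
        "probe_diameter_px": spec.probe_diameter_px,
        "linear_overlap": overlap,
        "n_clamped": n_clamped,
        "photons_per_frame": spec.photons_per_frame,
        "noise_scale": scale,
        "seed": spec.seed,
    }
    return stack, obj, probe, offsets, manifest


def generate_benchmark_dataset(
    preset: str, out_dir: str, seed: int = 0, **overrides
) -> str:
    """Write a dataset + ground truth + JSON manifest; returns the h5 path."""
    from .io import save_dataset

    spec = make_spec(preset, seed=seed, **overrides)
    stack, obj, probe, offsets, manifest = simulate(spec)
    os.makedirs(out_dir, exist_ok=True)
    h5_path = os.path.join(out_dir, f"{preset}.h5")
    save_dataset(
        stack,
        h5_path,
        ground_truth_object=obj,
        ground_truth_probe=probe,
    )
    with open(os.path.join(out_dir, f"{preset}_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return h5_path
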