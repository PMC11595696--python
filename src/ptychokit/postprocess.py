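"""Ambiguity removal and quality metrics.

A ptychographic reconstruction is only defined up to a global phase, a
global complex scale (traded between object and probe), a linear phase
ramp across the object (paired with a probe shift), and a rigid
translation (with a loose probe support).  This module removes those
ambiguities — magnitude-weighted phase-ramp fitting, probe
center-of-mass alignment, global phase/scale fitting — and computes the
normalized mean squared error against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .data_model import (
    InvalidInputError,
    ObjectField,
    ProbeStack,
    ReconResult,
)


@dataclass
class AlignmentReport:
    """Corrections applied while registering a reconstruction."""

    shift_px: Tuple[int, int] = (0, 0)
    subpixel_shift: Tuple[float, float] = (0.0, 0.0)
    ramp_coeffs: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    global_phase: float = 0.0
    global_scale: float = 1.0
    nmse: Optional[float] = None


def _fit_phase_ramp(values: np.ndarray, weight: np.ndarray):
    """Weighted LSQ fit of a linear ramp to the phase *gradient*.

    Gradients are taken as the argument of neighbor products, which is
    insensitive to phase wrapping; the plane is then integrated back.
    Returns (gy, gx, c) with c the weighted mean phase after deramping.
    """
    wy = weight[1:, :] * weight[:-1, :]
    wx = weight[:, 1:] * weight[:, :-1]
    dy = np.angle(values[1:, :] * values[:-1, :].conj())
    dx = np.angle(values[:, 1:] * values[:, :-1].conj())
    gy = float(np.sum(wy * dy) / np.sum(wy)) if np.sum(wy) > 0 else 0.0
    gx = float(np.sum(wx * dx) / np.sum(wx)) if np.sum(wx) > 0 else 0.0
    return gy, gx


def remove_phase_ramp(
    obj: ObjectField, weight_mask: Optional[np.ndarray] = None
) -> Tuple[ObjectField, Tuple[float, float, float]]:
    """Fit and subtract a linear phase ramp; zero the mean phase.

    The fit is weighted by magnitude squared (times the optional mask)
    so empty canvas regions do not bias the plane.  Returns the
    corrected object and ``(gy, gx, c)``: the per-pixel phase gradients
    and the subtracted mean phase.
    """
    values = obj.values
    weight = np.abs(values) ** 2
    if weight_mask is not None:
        weight = weight * np.asarray(weight_mask, dtype=float)
    if np.count_nonzero(weight) < 3:
        raise InvalidInputError("degenerate weight mask: fewer than 3 pixels")
    gy, gx = _fit_phase_ramp(values, weight)
    H, W = values.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    deramped = values * np.exp(-1j * (gy * yy + gx * xx))
    mean_phase = float(np.angle(np.sum(weight * deramped)))
    out = deramped * np.exp(-1j * mean_phase)
    return ObjectField(out, obj.pixel_m), (gy, gx, mean_phase)


def probe_com(probe: ProbeStack) -> Tuple[float, float]:
    """Center of mass of the summed probe magnitude."""
    mag = np.sum(np.abs(probe.modes), axis=0)
    total = mag.sum()
    if total == 0:
        raise InvalidInputError("probe is identically zero")
    return tuple(ndimage.center_of_mass(mag))


def align_by_probe_com(result: ReconResult) -> Tuple[ReconResult, Tuple[int, int]]:
    """Shift the probe so its magnitude COM sits at the frame center.

    The object is rolled by the opposite amount to compensate, leaving
    the forward model unchanged.  Only integer rolls are applied;
    sub-pixel remainders are reported, not interpolated.
    """
    com = probe_com(result.probe)
    m = result.probe.frame_shape[0]
    center = ((m - 1) / 2.0, (m - 1) / 2.0)
    frac = (com[0] - center[0], com[1] - center[1])
    shift = (int(round(frac[0])), int(round(frac[1])))
    new_probe = np.roll(result.probe.modes, (-shift[0], -shift[1]), axis=(1, 2))
    new_obj = np.roll(result.object.values, (-shift[0], -shift[1]), axis=(0, 1))
    aligned = ReconResult(
        object=ObjectField(new_obj, result.object.pixel_m),
        probe=ProbeStack(new_probe, result.probe.occupancies),
        error_trace=result.error_trace,
        positions=result.positions,
        config_echo=result.config_echo,
        offsets_px=result.offsets_px,
    )
    return aligned, shift


def _fit_phase_scale(recon: np.ndarray, truth: np.ndarray, mask: np.ndarray):
    """Closed-form global complex factor c minimizing ||c*recon - truth||."""
    num = np.sum(mask * truth * recon.conj())
    den = np.sum(mask * np.abs(recon) ** 2)
    if den == 0:
        raise InvalidInputError("reconstruction is zero on the evaluation mask")
    return num / den


def nmse_to_ground_truth(
    recon_object: ObjectField,
    truth_object: ObjectField,
    mask: Optional[np.ndarray] = None,
    *,
    remove_ramp: bool = True,
    report: Optional[AlignmentReport] = None,
) -> float:
    """Ambiguity-corrected NMSE between reconstruction and ground truth.

    Removes the relative linear phase ramp (fitted on the masked
    product ``recon * conj(truth)``), then the closed-form global
    phase/scale, and returns
    ``sum_mask |c * recon - truth|^2 / sum_mask |truth|^2``.
    """
    r, t = recon_object.values, truth_object.values
    if r.shape != t.shape:
        raise InvalidInputError(
            f"shape mismatch: reconstruction {r.shape} vs truth {t.shape}"
        )
    mask = (
        np.ones(r.shape) if mask is None else np.asarray(mask, dtype=float)
    )
    if not mask.any():
        raise InvalidInputError("empty evaluation mask")
    ramp = (0.0, 0.0, 0.0)
    if remove_ramp:
        # relative ramp between recon and truth, fitted on their product
        rel = ObjectField(r * t.conj() + 0j, recon_object.pixel_m)
        try:
            _, ramp = remove_phase_ramp(rel, weight_mask=mask)
        except InvalidInputError:
            ramp = (0.0, 0.0, 0.0)
        H, W = r.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        r = r * np.exp(-1j * (ramp[0] * yy + ramp[1] * xx))
    c = _fit_phase_scale(r, t, mask)
    nmse = float(
        np.sum(mask * np.abs(c * r - t) ** 2) / np.sum(mask * np.abs(t) ** 2)
    )
    if report is not None:
        report.ramp_coeffs = ramp
        report.global_phase = float(np.angle(c))
        report.global_scale = float(np.abs(c))
        report.nmse = nmse
    return nmse


def coverage_mask(
    probe: ProbeStack,
    offsets: np.ndarray,
    canvas_shape: Tuple[int, int],
    threshold: float = 0.5,
) -> np.ndarray:
    """Canvas pixels whose accumulated probe power is a meaningful
    fraction of the maximum — the region the data actually constrains."""
    power = np.sum(np.abs(probe.modes) ** 2, axis=0)
    m = probe.frame_shape[0]
    cov = np.zeros(canvas_shape)
    for oy, ox in offsets:
        cov[oy : oy + m, ox : ox + m] += power
    return cov >= threshold * cov.max()


def register_to_ground_truth(
    result: ReconResult,
    truth_object: ObjectField,
    truth_probe: Optional[ProbeStack] = None,
    mask: Optional[np.ndarray] = None,
) -> Tuple[float, AlignmentReport]:
    """Full registration pipeline: COM alignment, integer-shift search,
    ramp/phase/scale fitting, NMSE.

    The rigid shift between reconstruction and truth is found by
    cross-correlating object magnitudes (FFT phase correlation would be
    thrown off by the ramp ambiguity, magnitudes are invariant to it).
    """
    report = AlignmentReport()
    aligned = result
    if truth_probe is not None:
        aligned, com_shift = align_by_probe_com(result)
        # residual COM offset of the ground-truth probe itself
        t_com = probe_com(truth_probe)
        m = truth_probe.frame_shape[0]
        center = ((m - 1) / 2.0, (m - 1) / 2.0)
        t_shift = (
            int(round(t_com[0] - center[0])),
            int(round(t_com[1] - center[1])),
        )
        if t_shift != (0, 0):
            aligned = ReconResult(
                object=ObjectField(
                    np.roll(aligned.object.values, t_shift, axis=(0, 1)),
                    aligned.object.pixel_m,
                ),
                probe=ProbeStack(
                    np.roll(aligned.probe.modes, t_shift, axis=(1, 2)),
                    aligned.probe.occupancies,
                ),
                error_trace=aligned.error_trace,
                positions=aligned.positions,
                offsets_px=aligned.offsets_px,
            )
            com_shift = (com_shift[0] - t_shift[0], com_shift[1] - t_shift[1])
        report.shift_px = com_shift
    # reconcile canvas sizes: a reconstruction on a larger (padded) canvas
    # is cropped at the offset that best matches the truth
    r_shape = aligned.object.values.shape
    t_shape = truth_object.values.shape
    if r_shape != t_shape:
        if r_shape[0] < t_shape[0] or r_shape[1] < t_shape[1]:
            raise InvalidInputError(
                f"reconstruction canvas {r_shape} smaller than truth {t_shape}"
            )
        best_crop, best_val = (0, 0), np.inf
        for dy in range(r_shape[0] - t_shape[0] + 1):
            for dx in range(r_shape[1] - t_shape[1] + 1):
                cand = ObjectField(
                    aligned.object.values[
                        dy : dy + t_shape[0], dx : dx + t_shape[1]
                    ],
                    aligned.object.pixel_m,
                )
                try:
                    val = nmse_to_ground_truth(cand, truth_object, mask)
                except InvalidInputError:
                    continue
                if val < best_val:
                    best_val, best_crop = val, (dy, dx)
        aligned = ReconResult(
            object=ObjectField(
                aligned.object.values[
                    best_crop[0] : best_crop[0] + t_shape[0],
                    best_crop[1] : best_crop[1] + t_shape[1],
                ],
                aligned.object.pixel_m,
            ),
            probe=aligned.probe,
            error_trace=aligned.error_trace,
            positions=aligned.positions,
            offsets_px=aligned.offsets_px,
        )
        report.shift_px = (
            report.shift_px[0] + best_crop[0],
            report.shift_px[1] + best_crop[1],
        )
    # refine with a small integer-shift search minimizing the target metric
    best = (0, 0)
    best_nmse = np.inf
    search = aligned.object.values.shape == truth_object.values.shape
    for dy, dx in (
        [(dy, dx) for dy in range(-4, 5) for dx in range(-4, 5)]
        if search
        else [(0, 0)]
    ):
        cand = ObjectField(
            np.roll(aligned.object.values, (dy, dx), axis=(0, 1)),
            aligned.object.pixel_m,
        )
        try:
            val = nmse_to_ground_truth(cand, truth_object, mask)
        except InvalidInputError:
            continue
        if val < best_nmse:
            best_nmse, best = val, (dy, dx)
    final = ObjectField(
        np.roll(aligned.object.values, best, axis=(0, 1)),
        aligned.object.pixel_m,
    )
    report.shift_px = (
        report.shift_px[0] + best[0],
        report.shift_px[1] + best[1],
    )
    nmse = nmse_to_ground_truth(final, truth_object, mask, report=report)
    return nmse, report
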