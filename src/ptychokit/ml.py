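"""Cost-function refinement of a reconstruction.

The data misfit is the gamma-parameterized squared residual between
modeled and measured intensities,

    ``C = sum_i sum_uv M_i (|D{psi_i}|^(2 gamma) - I_i^gamma)^2``,

whose exponents ``gamma = 1/2`` and ``gamma = 1`` approximate the
maximum-likelihood estimators for Poisson and Gaussian counting
statistics (up to additive/multiplicative constants).  Gradients with
respect to object and probe are assembled analytically by
back-propagating the detector-plane residual through the unitary
propagator and the multiplicative model; the descent loop uses
steepest descent with Armijo backtracking, which guarantees a monotone
non-increasing cost sequence.

Gradient convention: the returned complex gradient ``G`` satisfies
``dC/dRe(z) = Re(G)`` and ``dC/dIm(z) = Im(G)`` (i.e. ``G = 2 dC/dz*``
in Wirtinger calculus), so a step ``z -= alpha * G`` is plain steepest
descent on the real parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .data_model import (
    DiffractionStack,
    InvalidInputError,
    ObjectField,
    ProbeStack,
    ReconResult,
    ScanPattern,
)
from .propagation import PropagatorSpec, from_detector, to_detector

_TINY = 1e-300  # guards t^(gamma-1) at exactly-zero model intensity


@dataclass
class MLConfig:
    """Settings of the descent loop.

    ``tol`` is the relative cost-decrease threshold; ``armijo_c`` and
    ``shrink`` parameterize the backtracking line search; ``step_rule``
    may be ``"backtracking"`` or ``"fixed"`` (with ``fixed_step``).
    """

    gamma: float = 1.0
    step_rule: str = "backtracking"
    armijo_c: float = 1e-4
    shrink: float = 0.5
    fixed_step: float = 1e-3
    max_iters: int = 50
    tol: float = 1e-8
    update_probe: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma not in (0.5, 1.0):
            raise InvalidInputError(f"gamma must be 1/2 or 1, got {self.gamma}")
        if self.step_rule not in ("backtracking", "fixed"):
            raise InvalidInputError(f"unknown step rule {self.step_rule!r}")
        if min(self.armijo_c, self.shrink, self.fixed_step) <= 0:
            raise InvalidInputError("step parameters must be positive")


def _model_quantities(object_values, probe_modes, stack, offsets, spec):
    """Yield per-frame (Psi_detector, total_intensity, window_slices)."""
    m = probe_modes.shape[-1]
    for i, (oy, ox) in enumerate(offsets):
        window = object_values[oy : oy + m, ox : ox + m]
        Psi = to_detector(probe_modes * window[None], spec)
        yield i, Psi, np.sum(np.abs(Psi) ** 2, axis=0), (
            slice(oy, oy + m),
            slice(ox, ox + m),
        )


def ml_cost(
    obj: ObjectField,
    probe: ProbeStack,
    stack: DiffractionStack,
    offsets: np.ndarray,
    gamma: float,
    spec: Optional[PropagatorSpec] = None,
) -> float:
    """Masked gamma-misfit between modeled and measured intensities."""
    if gamma not in (0.5, 1.0):
        raise InvalidInputError(f"gamma must be 1/2 or 1, got {gamma}")
    if np.any(stack.intensities < 0):
        raise InvalidInputError("measured intensities must be nonnegative")
    spec = spec or PropagatorSpec.from_geometry(stack.geometry)
    cost = 0.0
    for i, _, total, _ in _model_quantities(
        obj.values, probe.modes, stack, offsets, spec
    ):
        mask = np.asarray(stack.mask_for(i), dtype=float)
        residual = total**gamma - stack.intensities[i] ** gamma
        cost += float(np.sum(mask * residual**2))
    return cost


def ml_gradient(
    obj: ObjectField,
    probe: ProbeStack,
    stack: DiffractionStack,
    offsets: np.ndarray,
    gamma: float,
    spec: Optional[PropagatorSpec] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`ml_cost` w.r.t. object and probe.

    Chain rule through ``C = sum M (t^g - I^g)^2`` with
    ``t = sum_m |Psi_m|^2``:

        ``G_Psi_m = 4 g M (t^g - I^g) t^(g-1) Psi_m``

    back-propagated with the adjoint (= inverse, unitary) propagator and
    distributed through ``psi_m = P_m * O[window]``.
    """
    spec = spec or PropagatorSpec.from_geometry(stack.geometry)
    obj_v, probe_m = obj.values, probe.modes
    grad_obj = np.zeros_like(obj_v)
    grad_probe = np.zeros_like(probe_m)
    for i, Psi, total, window in _model_quantities(
        obj_v, probe_m, stack, offsets, spec
    ):
        mask = np.asarray(stack.mask_for(i), dtype=float)
        I = stack.intensities[i]
        residual = total**gamma - I**gamma
        if gamma == 1.0:
            weight = 4.0 * mask * residual
        else:
            weight = 2.0 * mask * residual / np.sqrt(np.maximum(total, _TINY))
        g_psi = from_detector(weight[None] * Psi, spec)
        win = obj_v[window]
        grad_obj[window] += np.sum(probe_m.conj() * g_psi, axis=0)
        grad_probe += win.conj()[None] * g_psi
    return grad_obj, grad_probe


def run_ml_refinement(
    obj: ObjectField,
    probe: ProbeStack,
    stack: DiffractionStack,
    offsets: np.ndarray,
    config: MLConfig,
) -> ReconResult:
    """Steepest-descent refinement, typically warm-started from a
    projection-engine result.

    Records the cost history in ``error_trace``; stops when the relative
    cost decrease falls below ``tol`` or after ``max_iters``.  With
    backtracking active the cost never increases; a divergent fixed step
    aborts once the cost doubles.
    """
    spec = PropagatorSpec.from_geometry(stack.geometry)
    obj_v = obj.values.copy()
    probe_m = probe.modes.copy()

    def cost_of(o, p):
        return ml_cost(
            ObjectField(o, obj.pixel_m), ProbeStack(p), stack, offsets,
            config.gamma, spec,
        )

    cost = cost_of(obj_v, probe_m)
    history = [cost]
    step = config.fixed_step if config.step_rule == "fixed" else 1.0
    initial_cost = cost
    for _ in range(config.max_iters):
        if not np.isfinite(config.tol):
            break
        g_obj, g_probe = ml_gradient(
            ObjectField(obj_v, obj.pixel_m), ProbeStack(probe_m), stack,
            offsets, config.gamma, spec,
        )
        if not config.update_probe:
            g_probe = np.zeros_like(g_probe)
        gnorm2 = float(np.sum(np.abs(g_obj) ** 2) + np.sum(np.abs(g_probe) ** 2))
        if gnorm2 == 0.0:
            break
        if config.step_rule == "fixed":
            obj_v = obj_v - step * g_obj
            probe_m = probe_m - step * g_probe
            new_cost = cost_of(obj_v, probe_m)
            if new_cost > 2.0 * initial_cost:
                raise InvalidInputError(
                    f"fixed step {step} diverges: cost {new_cost:.3g} exceeds "
                    f"twice the starting cost {initial_cost:.3g}"
                )
        else:
            step = min(step * 2.0, 1e12)  # optimistic growth, then backtrack
            while True:
                cand_o = obj_v - step * g_obj
                cand_p = probe_m - step * g_probe
                new_cost = cost_of(cand_o, cand_p)
                if new_cost <= cost - config.armijo_c * step * gnorm2:
                    obj_v, probe_m = cand_o, cand_p
                    break
                step *= config.shrink
                if step < 1e-30:
                    new_cost = cost  # no acceptable step: converged
                    break
        history.append(new_cost)
        if cost > 0 and (cost - new_cost) / cost < config.tol:
            cost = new_cost
            break
        cost = new_cost
    return ReconResult(
        object=ObjectField(obj_v, obj.pixel_m),
        probe=ProbeStack(probe_m, probe.occupancies),
        error_trace=np.asarray(history),
        positions=ScanPattern(stack.scan.positions_m.copy()),
        offsets_px=np.asarray(offsets, dtype=int),
    )
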