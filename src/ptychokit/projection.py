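"""Projection-based reconstruction engines.

The phase problem is attacked with two projectors:

* ``PiM`` (:func:`project_data`) — replace the magnitude of the
  propagated wavefront by the measured ``sqrt(I)`` while keeping its
  phase; with K incoherent probe modes all modes are rescaled by the
  shared factor ``sqrt(I / sum_m |Psi_m|^2)``.
* ``PiO`` (:func:`exit_wave`) — re-impose the multiplicative model
  ``psi_i = P * O[window_i]`` from the current object/probe estimates.

Built from these are the fixed-point schemes

* AP:    ``psi' = PiM{PiO{psi}}``
* DM:    ``psi' = psi + PiM{2 PiO{psi} - psi} - PiO{psi}``
* RAAR:  ``psi' = beta (psi + PiM{2 PiO{psi} - psi}) + (1 - 2 beta) PiO{psi}``

(DM and RAAR coincide for ``beta = 1``), the global least-squares
object/probe updates

* ``O' = sum_i conj(P)(r - r_i) psi_i / sum_i |P(r - r_i)|^2`` (and the
  probe analogue),

and the sequential rPIE/mPIE updates with optional momentum.  The
per-iteration error is the normalized intensity misfit

    ``eps = sum_i sum_uv M (I_i - |D{psi_i'}|^2)^2 / sum_i sum_uv M I_i``

implemented as printed (an amplitude-residual variant is available
behind ``ReconConfig.amplitude_error``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .data_model import (
    CanvasError,
    DiffractionStack,
    InvalidInputError,
    ObjectField,
    ProbeStack,
    ReconConfig,
    ReconResult,
    ScanPattern,
    check_windows_on_canvas,
    effective_pixel_size,
    normalize_offsets,
    positions_to_pixel_offsets,
)
from .propagation import PropagatorSpec, from_detector, to_detector
from .scheduler import (
    UpdateAccumulator,
    broadcast,
    broadcast_consistent,
    partition_batches,
    schedule,
    tree_reduce,
)

# ---------------------------------------------------------------------------
# elementary operations


def exit_wave(
    object_values: np.ndarray, probe_modes: np.ndarray, offset: Sequence[int]
) -> np.ndarray:
    """Multiplicative exit wave ``psi_m = P_m * O[window]`` (K, M, M)."""
    k, m, n = probe_modes.shape
    oy, ox = int(offset[0]), int(offset[1])
    H, W = object_values.shape
    if oy < 0 or ox < 0 or oy + m > H or ox + n > W:
        raise CanvasError(
            f"probe window at offset ({oy}, {ox}) escapes canvas {(H, W)}"
        )
    return probe_modes * object_values[oy : oy + m, ox : ox + n][None]


def project_data(
    psi_modes: np.ndarray,
    intensity: np.ndarray,
    mask: np.ndarray,
    spec: PropagatorSpec,
) -> np.ndarray:
    """Modulus projection ``PiM`` applied through the propagator.

    At trusted pixels the propagated mode ensemble is rescaled by
    ``sqrt(I / sum_m |Psi_m|^2)``; masked-out pixels keep the modeled
    values; pixels where the model is exactly zero but ``I > 0`` receive
    ``sqrt(I/K)`` with zero phase in each mode (deterministic
    tie-break).
    """
    if np.any(intensity < 0):
        raise InvalidInputError("measured intensities must be nonnegative")
    K = psi_modes.shape[0]
    Psi = to_detector(psi_modes, spec)
    total = np.sum(np.abs(Psi) ** 2, axis=0)
    trusted = np.asarray(mask, dtype=bool)
    out = Psi.copy()
    scale_px = trusted & (total > 0)
    factor = np.sqrt(intensity[scale_px] / total[scale_px])
    out[:, scale_px] = Psi[:, scale_px] * factor[None]
    dead_px = trusted & (total == 0) & (intensity > 0)
    if dead_px.any():
        out[:, dead_px] = np.sqrt(intensity[dead_px] / K)
    return from_detector(out, spec)


#: The AP/PIE wavefront update is the bare modulus projection.
ap_update = project_data


def dm_update(
    psi: np.ndarray,
    intensity: np.ndarray,
    mask: np.ndarray,
    consistency: np.ndarray,
    spec: PropagatorSpec,
) -> np.ndarray:
    """Difference-map update ``psi + PiM{2 PiO - psi} - PiO``."""
    reflected = project_data(2.0 * consistency - psi, intensity, mask, spec)
    return psi + reflected - consistency


def raar_update(
    psi: np.ndarray,
    intensity: np.ndarray,
    mask: np.ndarray,
    consistency: np.ndarray,
    beta: float,
    spec: PropagatorSpec,
) -> np.ndarray:
    """RAAR update; equals :func:`dm_update` exactly at ``beta = 1``."""
    if not 0.0 <= beta <= 1.0:
        raise InvalidInputError(f"beta must lie in [0, 1], got {beta}")
    reflected = project_data(2.0 * consistency - psi, intensity, mask, spec)
    return beta * (psi + reflected) + (1.0 - 2.0 * beta) * consistency


def batch_error(
    intensity_batch: np.ndarray,
    psi_prime_batch: np.ndarray,
    masks: Sequence[np.ndarray],
    spec: PropagatorSpec,
    amplitude: bool = False,
) -> Tuple[float, float]:
    """Partial sums of the normalized intensity misfit.

    Returns ``(err_num, err_den)``: the masked sum of squared residuals
    between measured and modeled intensities (or amplitudes when
    ``amplitude=True``) and the masked intensity sum; the driver
    assembles ``eps = err_num / err_den``.
    """
    num = den = 0.0
    for I, psi_p, mask in zip(intensity_batch, psi_prime_batch, masks):
        model = np.sum(np.abs(to_detector(psi_p, spec)) ** 2, axis=0)
        m = np.asarray(mask, dtype=float)
        if amplitude:
            num += float(np.sum(m * (np.sqrt(I) - np.sqrt(model)) ** 2))
        else:
            num += float(np.sum(m * (I - model) ** 2))
        den += float(np.sum(m * I))
    return num, den


def frame_residual(
    intensity: np.ndarray,
    psi_modes: np.ndarray,
    mask: np.ndarray,
    spec: PropagatorSpec,
) -> float:
    """Single-frame numerator of the error metric (position scoring)."""
    model = np.sum(np.abs(to_detector(psi_modes, spec)) ** 2, axis=0)
    return float(np.sum(np.asarray(mask, dtype=float) * (intensity - model) ** 2))


def accumulate_updates(
    psi_prime_batch: Sequence[np.ndarray],
    probe_modes: np.ndarray,
    object_values: np.ndarray,
    offsets: Sequence[Sequence[int]],
    acc: UpdateAccumulator,
) -> UpdateAccumulator:
    """Accumulate numerators/denominators of the global updates in place.

    For each position: ``obj_num[win] += sum_m conj(P_m) psi'_m``,
    ``obj_den[win] += sum_m |P_m|^2``, ``probe_num_m += conj(O[win])
    psi'_m``, ``probe_den += |O[win]|^2``.
    """
    m = probe_modes.shape[1]
    probe_conj = probe_modes.conj()
    probe_pow = np.sum(np.abs(probe_modes) ** 2, axis=0)
    for psi_p, (oy, ox) in zip(psi_prime_batch, offsets):
        window = object_values[oy : oy + m, ox : ox + m]
        acc.obj_num[oy : oy + m, ox : ox + m] += np.sum(probe_conj * psi_p, axis=0)
        acc.obj_den[oy : oy + m, ox : ox + m] += probe_pow
        acc.probe_num += window.conj()[None] * psi_p
        acc.probe_den += np.abs(window) ** 2
    return acc


def apply_global_updates(
    acc: UpdateAccumulator,
    prior_object: np.ndarray,
    prior_probe: np.ndarray,
    eps_frac: float = 1e-6,
    update_probe: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Regularized division of the accumulated sums.

    The regularizer is scale-invariant: ``eps = eps_frac * max(den)``.
    Canvas pixels never visited by a probe window keep the prior object
    value.
    """
    eps_o = eps_frac * (acc.obj_den.max() or 1.0)
    new_obj = acc.obj_num / (acc.obj_den + eps_o)
    unvisited = acc.obj_den == 0
    new_obj[unvisited] = prior_object[unvisited]
    if update_probe:
        eps_p = eps_frac * (acc.probe_den.max() or 1.0)
        new_probe = acc.probe_num / (acc.probe_den + eps_p)[None]
    else:
        new_probe = prior_probe.copy()
    return new_obj, new_probe


# ---------------------------------------------------------------------------
# sequential (PIE-family) updates


def rpie_object_update(
    object_window: np.ndarray,
    probe_modes: np.ndarray,
    psi: np.ndarray,
    psi_prime: np.ndarray,
    step_o: float,
    reg_o: float,
) -> np.ndarray:
    """rPIE object step on one scan window.

    ``O' = O + s_o sum_m conj(P_m)(psi'_m - psi_m) /
    ((1 - r_o) |P|^2 + r_o |P|^2_max)`` with ``|P|^2`` summed over modes.
    """
    power = np.sum(np.abs(probe_modes) ** 2, axis=0)
    pmax = power.max()
    if pmax == 0 and reg_o == 0:
        raise InvalidInputError("all-zero probe with reg_o = 0: division undefined")
    den = (1.0 - reg_o) * power + reg_o * pmax
    num = np.sum(probe_modes.conj() * (psi_prime - psi), axis=0)
    return object_window + step_o * num / den


def rpie_probe_update(
    object_window: np.ndarray,
    probe_modes: np.ndarray,
    psi: np.ndarray,
    psi_prime: np.ndarray,
    step_p: float,
    reg_p: float,
) -> np.ndarray:
    """rPIE probe step (mirror of the object step, per mode)."""
    power = np.abs(object_window) ** 2
    omax = power.max()
    if omax == 0 and reg_p == 0:
        raise InvalidInputError("all-zero object with reg_p = 0: division undefined")
    den = (1.0 - reg_p) * power + reg_p * omax
    return probe_modes + step_p * object_window.conj()[None] * (psi_prime - psi) / den[
        None
    ]


@dataclass
class MomentumState:
    """Velocity and checkpoint buffers for mPIE momentum."""

    v_obj: np.ndarray
    v_probe: np.ndarray
    ckpt_obj: np.ndarray
    ckpt_probe: np.ndarray
    counter: int = 0

    @classmethod
    def init(cls, object_values: np.ndarray, probe_modes: np.ndarray):
        return cls(
            v_obj=np.zeros_like(object_values),
            v_probe=np.zeros_like(probe_modes),
            ckpt_obj=object_values.copy(),
            ckpt_probe=probe_modes.copy(),
        )


def mpie_momentum(
    object_values: np.ndarray,
    probe_modes: np.ndarray,
    state: MomentumState,
    friction: float,
    interval: int,
    friction_probe: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply momentum acceleration every ``interval`` position updates.

    ``v <- friction * v + (X - X_ckpt); X <- X + friction * v``; the
    checkpoint is refreshed to the accelerated iterate.  Object and
    probe carry independent velocities; ``friction_probe`` defaults to
    the object friction but 0 (probe momentum off) is the driver
    default — a high-gain probe velocity destabilizes the sequential
    engine.  With ``friction = 0`` this is a configured no-op.
    """
    if friction_probe is None:
        friction_probe = friction
    state.counter += 1
    if state.counter % interval:
        return object_values, probe_modes
    state.v_obj = friction * state.v_obj + (object_values - state.ckpt_obj)
    state.v_probe = friction_probe * state.v_probe + (
        probe_modes - state.ckpt_probe
    )
    object_values = object_values + friction * state.v_obj
    probe_modes = probe_modes + friction_probe * state.v_probe
    state.ckpt_obj = object_values.copy()
    state.ckpt_probe = probe_modes.copy()
    return object_values, probe_modes


# ---------------------------------------------------------------------------
# probe constraints and position correction


def apply_probe_support(
    probe_modes: np.ndarray, diameter_m: float, pixel_m: float
) -> np.ndarray:
    """Zero all modes outside a centered disk of given physical diameter."""
    if diameter_m <= 0:
        raise InvalidInputError("support diameter must be positive")
    m = probe_modes.shape[-1]
    d_px = diameter_m / pixel_m
    if d_px >= m * np.sqrt(2.0):
        return probe_modes.copy()  # disk covers the whole frame: no-op
    c = (m - 1) / 2.0
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= (d_px / 2.0) ** 2
    return probe_modes * disk[None]


def orthogonalize_probe_modes(probe: ProbeStack) -> ProbeStack:
    """Replace modes by an orthogonal set spanning the same space.

    Eigendecomposition of the K x K Gram matrix; modes come back
    ordered by decreasing power, total power conserved, occupancies
    normalized to sum 1.  Rank-deficient stacks keep (near-)zero modes
    last.
    """
    modes = probe.modes
    K = modes.shape[0]
    if K < 2:
        return ProbeStack(modes.copy(), occupancies=np.array([1.0]))
    flat = modes.reshape(K, -1)
    gram = flat @ flat.conj().T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    new_flat = vecs.conj().T @ flat
    power = np.clip(vals.real, 0.0, None)
    total = power.sum()
    occ = power / total if total > 0 else power
    return ProbeStack(new_flat.reshape(modes.shape), occupancies=occ)


def anneal_positions(
    object_values: np.ndarray,
    probe_modes: np.ndarray,
    stack: DiffractionStack,
    offsets: np.ndarray,
    spec: PropagatorSpec,
    radius_px: int,
    trials: Optional[int],
    rng: np.random.Generator,
    indices: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """One annealing sweep of integer position refinement.

    Per position the single-frame intensity residual is evaluated at the
    current offset and at candidate integer offsets within
    ``radius_px``; ``trials=None`` enumerates all of them, otherwise
    ``trials`` candidates are drawn uniformly.  The strict argmin wins
    (ties keep the current offset).  The caller shrinks the radius by
    its cooling factor between sweeps; radius 0 is a no-op.
    """
    if radius_px <= 0:
        return offsets.copy()
    m = probe_modes.shape[-1]
    H, W = object_values.shape
    new_offsets = offsets.copy()
    if indices is None:
        indices = range(len(offsets))
    if trials is None:
        span = np.arange(-radius_px, radius_px + 1)
        candidates = np.array(
            [(dy, dx) for dy in span for dx in span if (dy, dx) != (0, 0)]
        )
    for i in indices:
        I, mask = stack.intensities[i], stack.mask_for(i)
        best_off = tuple(offsets[i])
        best = frame_residual(
            I, exit_wave(object_values, probe_modes, best_off), mask, spec
        )
        if trials is not None:
            candidates = rng.integers(-radius_px, radius_px + 1, size=(trials, 2))
        for dy, dx in candidates:
            oy, ox = offsets[i, 0] + dy, offsets[i, 1] + dx
            if oy < 0 or ox < 0 or oy + m > H or ox + m > W:
                continue
            r = frame_residual(
                I, exit_wave(object_values, probe_modes, (oy, ox)), mask, spec
            )
            if r < best:
                best, best_off = r, (oy, ox)
        new_offsets[i] = best_off
    return new_offsets


# ---------------------------------------------------------------------------
# initialization conventions


def default_object_init(
    canvas_shape: Tuple[int, int], pixel_m: float, rng: np.random.Generator
) -> ObjectField:
    """Random magnitude (uniform in [0.9, 1.0]) and constant zero phase."""
    mag = rng.uniform(0.9, 1.0, size=canvas_shape)
    return ObjectField(mag.astype(complex), pixel_m=pixel_m)


def default_probe_init(
    stack: DiffractionStack,
    spec: PropagatorSpec,
    n_modes: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> ProbeStack:
    """Inverse transform of the averaged measurements.

    Mode 0 is the back-propagated square root of the frame-averaged
    intensity (zero detector phase); higher modes are weak random
    perturbations of it so the orthogonalization has something to work
    with.
    """
    mean_amp = np.sqrt(stack.intensities.mean(axis=0))
    p0 = from_detector(mean_amp.astype(complex)[None], spec)[0]
    modes = [p0]
    if n_modes > 1:
        rng = rng or np.random.default_rng(0)
        scale = 0.1 * np.abs(p0).max()
        for _ in range(n_modes - 1):
            noise = rng.normal(size=p0.shape) + 1j * rng.normal(size=p0.shape)
            modes.append(scale * noise / np.sqrt(2.0))
    return ProbeStack(np.stack(modes))


# ---------------------------------------------------------------------------
# iteration driver


@dataclass
class EngineState:
    """Per-iteration bundle of the reconstruction driver."""

    object: ObjectField
    probe: ProbeStack
    offsets: np.ndarray
    iteration: int = 0
    error_trace: list = field(default_factory=list)
    exit_waves: Optional[np.ndarray] = None
    rng: Optional[np.random.Generator] = None
    momentum: Optional[MomentumState] = None


def _resolve_offsets(stack, pixel_m, init):
    if init and init.get("offsets_px") is not None:
        return np.asarray(init["offsets_px"], dtype=int), init.get("object")
    offsets, _ = positions_to_pixel_offsets(stack.scan, pixel_m)
    obj = init.get("object") if init else None
    if obj is not None:
        check_windows_on_canvas(offsets, stack.geometry.frame_shape, obj.shape)
        return offsets, obj
    offsets, canvas = normalize_offsets(offsets, stack.geometry.frame_shape)
    return offsets, canvas


def _run_batched(state, stack, cfg, spec, it_offset):
    """One engine block of AP/DM/RAAR iterations.

    Each iteration makes two batched sweeps: the first updates every
    wavefront in parallel and accumulates the object
    numerator/denominator (with the current probe); after the object
    update a second sweep over the stored ``psi'`` accumulates the probe
    sums against the *new* object.  Updating object and probe
    simultaneously from each other's stale counterparts is unstable for
    DM/RAAR; the alternated form is the stable overlap projection.
    Both sweeps go through the per-worker partial accumulators and the
    binary reduction tree, so results are invariant to (B, W).
    """
    N = stack.n_frames
    B = cfg.batch_size or N
    plan = schedule(partition_batches(N, B), cfg.n_workers)
    obj, probe = state.object.values, state.probe.modes
    if cfg.engine in ("dm", "raar") and state.exit_waves is None:
        state.exit_waves = np.stack(
            [exit_wave(obj, probe, off) for off in state.offsets]
        )
    pc = cfg.position_correction or {}
    radius = pc.get("radius_px", 0)
    occupancies = state.probe.occupancies
    for it in range(cfg.iterations):
        workers_used = sorted(set(plan.assignments))
        partials = {
            w: UpdateAccumulator.zeros(obj.shape, probe.shape[0], probe.shape[1:])
            for w in workers_used
        }
        psi_store = (
            state.exit_waves
            if state.exit_waves is not None
            else np.empty((N, *probe.shape), dtype=complex)
        )
        for k, batch in enumerate(plan.batches):
            acc = partials[plan.assignments[k]]
            for i in batch:
                off = state.offsets[i]
                I, mask = stack.intensities[i], stack.mask_for(i)
                consistency = exit_wave(obj, probe, off)
                if cfg.engine == "ap":
                    psi_p = ap_update(consistency, I, mask, spec)
                elif cfg.engine == "dm":
                    psi_p = dm_update(psi_store[i], I, mask, consistency, spec)
                else:
                    psi_p = raar_update(
                        psi_store[i], I, mask, consistency, cfg.beta, spec
                    )
                psi_store[i] = psi_p
                # the misfit is scored on the model wavefront P*O[window]:
                # scoring the PiM output instead is degenerate (identically
                # zero for AP/PIE, non-vanishing for DM even at the solution)
                num, den = batch_error(
                    I[None], [consistency], [mask], spec,
                    amplitude=cfg.amplitude_error,
                )
                acc.err_num += num
                acc.err_den += den
                accumulate_updates([psi_p], probe, obj, [off], acc)
        total = tree_reduce([partials[w] for w in workers_used])
        if total.err_den == 0:
            raise InvalidInputError("all pixels masked out: error undefined")
        state.error_trace.append(total.err_num / total.err_den)
        update_probe = (it_offset + it) >= cfg.probe_update_start
        obj, _ = apply_global_updates(total, obj, probe, update_probe=False)
        if update_probe:
            m = probe.shape[-1]
            probe_partials = {
                w: UpdateAccumulator.zeros(obj.shape, probe.shape[0], (m, m))
                for w in workers_used
            }
            for k, batch in enumerate(plan.batches):
                acc = probe_partials[plan.assignments[k]]
                for i in batch:
                    oy, ox = state.offsets[i]
                    window = obj[oy : oy + m, ox : ox + m]
                    acc.probe_num += window.conj()[None] * psi_store[i]
                    acc.probe_den += np.abs(window) ** 2
            ptotal = tree_reduce([probe_partials[w] for w in workers_used])
            eps_p = 1e-6 * (ptotal.probe_den.max() or 1.0)
            probe = ptotal.probe_num / (ptotal.probe_den + eps_p)[None]
        if cfg.probe_support_diameter_m and update_probe:
            obj_px = state.object.pixel_m
            probe = apply_probe_support(
                probe, cfg.probe_support_diameter_m, obj_px
            )
        if probe.shape[0] > 1 and update_probe:
            stack_p = orthogonalize_probe_modes(ProbeStack(probe))
            probe = stack_p.modes
            occupancies = stack_p.occupancies
        if radius and (it_offset + it) >= pc.get("start", 1) and (
            (it_offset + it) % pc.get("interval", 1) == 0
        ):
            r_now = int(round(radius * pc.get("cooling", 0.95) ** it))
            state.offsets = anneal_positions(
                obj, probe, stack, state.offsets, spec,
                radius_px=r_now, trials=pc.get("trials", 8), rng=state.rng,
            )
            if cfg.engine in ("dm", "raar"):
                state.exit_waves = np.stack(
                    [exit_wave(obj, probe, off) for off in state.offsets]
                )
        handles = broadcast((obj, probe), plan.W)
        assert broadcast_consistent(handles)
        state.iteration += 1
    state.object = ObjectField(obj, state.object.pixel_m)
    state.probe = ProbeStack(probe, occupancies)
    return state


def _run_sequential(state, stack, cfg, spec, it_offset):
    """One engine block of rPIE/mPIE iterations (random-order sweeps)."""
    N = stack.n_frames
    obj = state.object.values.copy()
    probe = state.probe.modes.copy()
    m = probe.shape[-1]
    interval = cfg.momentum_interval or N
    if cfg.engine == "mpie" and state.momentum is None:
        state.momentum = MomentumState.init(obj, probe)
    for it in range(cfg.iterations):
        order = state.rng.permutation(N)
        err_num = err_den = 0.0
        update_probe = (it_offset + it) >= cfg.probe_update_start
        for i in order:
            oy, ox = state.offsets[i]
            I, mask = stack.intensities[i], stack.mask_for(i)
            window = obj[oy : oy + m, ox : ox + m].copy()
            psi = probe * window[None]
            psi_p = project_data(psi, I, mask, spec)
            num, den = batch_error(
                I[None], [psi], [mask], spec, amplitude=cfg.amplitude_error
            )
            err_num += num
            err_den += den
            obj[oy : oy + m, ox : ox + m] = rpie_object_update(
                window, probe, psi, psi_p, cfg.step_o, cfg.reg_o
            )
            if update_probe:
                probe = rpie_probe_update(
                    window, probe, psi, psi_p, cfg.step_p, cfg.reg_p
                )
            if cfg.engine == "mpie":
                obj, probe = mpie_momentum(
                    obj, probe, state.momentum, cfg.momentum_friction, interval,
                    friction_probe=cfg.momentum_friction_probe,
                )
        if err_den == 0:
            raise InvalidInputError("all pixels masked out: error undefined")
        state.error_trace.append(err_num / err_den)
        if cfg.probe_support_diameter_m and update_probe:
            probe = apply_probe_support(
                probe, cfg.probe_support_diameter_m, state.object.pixel_m
            )
        state.iteration += 1
    state.object = ObjectField(obj, state.object.pixel_m)
    state.probe = ProbeStack(probe, state.probe.occupancies)
    return state


def run_reconstruction(
    stack: DiffractionStack,
    config: Union[ReconConfig, Sequence[ReconConfig]],
    init: Optional[dict] = None,
) -> ReconResult:
    """Run one engine or an ordered engine chain.

    ``init`` may carry ``object`` (:class:`ObjectField`), ``probe``
    (:class:`ProbeStack`), ``offsets_px`` and ``n_probe_modes``; missing
    pieces follow the default convention: object of random magnitude in
    [0.9, 1.0] with constant zero phase, probe from the inverse
    transform of the averaged measurements.
    """
    configs = [config] if isinstance(config, ReconConfig) else list(config)
    if not configs:
        raise InvalidInputError("empty engine chain")
    geometry = stack.geometry
    pixel_m = (
        effective_pixel_size(geometry)
        if geometry.regime == "far_field"
        else geometry.pixel_m
    )
    spec = PropagatorSpec.from_geometry(geometry)
    init = init or {}
    rng = np.random.default_rng(configs[0].seed)
    offsets, obj_or_canvas = _resolve_offsets(stack, pixel_m, init)
    if isinstance(obj_or_canvas, ObjectField):
        obj = ObjectField(obj_or_canvas.values.astype(complex), obj_or_canvas.pixel_m)
    else:
        canvas = obj_or_canvas
        if canvas is None:
            # explicit offsets without an object: build the tightest canvas
            # around them without shifting
            if offsets.min() < 0:
                raise CanvasError("explicit pixel offsets must be nonnegative")
            m, n = geometry.frame_shape
            canvas = (int(offsets[:, 0].max()) + m, int(offsets[:, 1].max()) + n)
        obj = default_object_init(canvas, pixel_m, rng)
    check_windows_on_canvas(offsets, geometry.frame_shape, obj.shape)
    probe = init.get("probe")
    if probe is None:
        probe = default_probe_init(
            stack, spec, n_modes=init.get("n_probe_modes", 1), rng=rng
        )
    else:
        probe = ProbeStack(probe.modes.astype(complex), probe.occupancies)
    state = EngineState(object=obj, probe=probe, offsets=offsets.copy(), rng=rng)
    it_offset = 0
    for cfg in configs:
        if cfg.engine in ("ap", "dm", "raar"):
            state = _run_batched(state, stack, cfg, spec, it_offset)
        elif cfg.engine in ("rpie", "mpie"):
            state = _run_sequential(state, stack, cfg, spec, it_offset)
        elif cfg.engine == "ml":
            from .ml import MLConfig, run_ml_refinement

            ml_cfg = MLConfig(
                gamma=cfg.gamma, max_iters=cfg.iterations, seed=cfg.seed
            )
            ml_res = run_ml_refinement(
                state.object, state.probe, stack, state.offsets, ml_cfg
            )
            state.object, state.probe = ml_res.object, ml_res.probe
            state.error_trace.extend(ml_res.error_trace.tolist())
            state.iteration += len(ml_res.error_trace)
        it_offset = state.iteration
    positions = ScanPattern(stack.scan.positions_m.copy())
    positions.positions_px = state.offsets.astype(float)
    return ReconResult(
        object=state.object,
        probe=state.probe,
        error_trace=np.asarray(state.error_trace),
        positions=positions,
        config_echo=configs,
        offsets_px=state.offsets,
    )
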