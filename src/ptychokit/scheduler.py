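"""Batch partitioning, worker assignment, and associative reduction.

The batched engines (AP/DM/RAAR) never need the whole measurement stack
resident at once: scan indices are split into contiguous batches of at
most ``B`` frames, batches are assigned to ``W`` emulated workers by a
deterministic availability queue (unit cost per batch, i.e. round
robin), each worker accumulates partial numerator/denominator sums, and
the partials are combined with a binary reduction tree before the
global object/probe update is broadcast back.  Because the accumulators
are plain sums, the batch/worker split changes memory residency, never
the result (up to float summation order).

The sequential engines (rPIE/mPIE) bypass this module entirely: they
process one measurement at a time by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .data_model import InvalidInputError


@dataclass
class UpdateAccumulator:
    """Numerator/denominator partial sums for the global updates.

    ``obj_num/obj_den`` live on the object canvas and accumulate
    ``sum_m conj(P_m) * psi`` and ``sum_m |P_m|^2`` stamped at each scan
    window; ``probe_num/probe_den`` are frame-shaped analogues;
    ``err_num/err_den`` collect the intensity-misfit sums.  Addition is
    elementwise, so accumulation is associative (within float
    tolerance) and safe to tree-reduce.
    """

    obj_num: np.ndarray
    obj_den: np.ndarray
    probe_num: np.ndarray  # (K, M, M)
    probe_den: np.ndarray
    err_num: float = 0.0
    err_den: float = 0.0

    @classmethod
    def zeros(cls, canvas_shape, n_modes, frame_shape) -> "UpdateAccumulator":
        m = tuple(frame_shape)
        return cls(
            obj_num=np.zeros(canvas_shape, dtype=complex),
            obj_den=np.zeros(canvas_shape, dtype=float),
            probe_num=np.zeros((n_modes, *m), dtype=complex),
            probe_den=np.zeros(m, dtype=float),
        )

    def __add__(self, other: "UpdateAccumulator") -> "UpdateAccumulator":
        if self.obj_num.shape != other.obj_num.shape or (
            self.probe_num.shape != other.probe_num.shape
        ):
            raise InvalidInputError("cannot combine shape-mismatched accumulators")
        return UpdateAccumulator(
            obj_num=self.obj_num + other.obj_num,
            obj_den=self.obj_den + other.obj_den,
            probe_num=self.probe_num + other.probe_num,
            probe_den=self.probe_den + other.probe_den,
            err_num=self.err_num + other.err_num,
            err_den=self.err_den + other.err_den,
        )


@dataclass
class BatchPlan:
    """Partition of scan indices 0..N-1 into ordered contiguous batches."""

    batches: List[range]
    B: int
    assignments: List[int] = field(default_factory=list)
    W: int = 1

    @property
    def n_batches(self) -> int:
        return len(self.batches)


def partition_batches(N: int, B: int) -> BatchPlan:
    """Split N scan indices into ceil(N/B) contiguous batches of size <= B.

    All batches have size B except possibly the last.
    """
    if N < 1 or B < 1:
        raise InvalidInputError(f"need N >= 1 and B >= 1, got N={N}, B={B}")
    batches = [range(start, min(start + B, N)) for start in range(0, N, B)]
    return BatchPlan(batches=batches, B=B)


def schedule(plan: BatchPlan, W: int) -> BatchPlan:
    """Assign batches to W workers with a unit-cost availability queue.

    With every batch costing one unit the queue degenerates to round
    robin: batch k goes to worker k mod W.  The assignment is recorded
    on the plan for reproducibility.
    """
    if W < 1:
        raise InvalidInputError(f"need W >= 1, got {W}")
    plan.assignments = [k % W for k in range(plan.n_batches)]
    plan.W = W
    return plan


def reduction_rounds(n_partials: int) -> int:
    """Number of combine rounds of the binary reduction tree."""
    if n_partials < 1:
        raise InvalidInputError("need at least one partial")
    return math.ceil(math.log2(n_partials)) if n_partials > 1 else 0


def tree_reduce(partials: Sequence):
    """Pairwise binary-tree summation of partial accumulators.

    Combines neighbors round by round (``ceil(log2 n)`` rounds) and
    returns the total; a single partial is returned unchanged.  The
    result equals a serial left-fold up to float summation order.
    """
    items = list(partials)
    if not items:
        raise InvalidInputError("need at least one partial")
    while len(items) > 1:
        items = [
            items[i] + items[i + 1] if i + 1 < len(items) else items[i]
            for i in range(0, len(items), 2)
        ]
    return items[0]


def broadcast(model, workers: int) -> List:
    """Hand every emulated worker the updated model for the next iteration.

    In-process this is a value-equality contract, not a copy
    requirement: all returned handles reference the same object/probe.
    """
    if workers < 1:
        raise InvalidInputError(f"need at least one worker, got {workers}")
    return [model] * workers


def broadcast_consistent(handles: Sequence) -> bool:
    """Check that all per-worker handles hold identical model values."""
    if not handles:
        return True
    ref = handles[0]
    return all(
        np.array_equal(np.asarray(h[0]), np.asarray(ref[0]))
        and np.array_equal(np.asarray(h[1]), np.asarray(ref[1]))
        for h in handles[1:]
    )
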