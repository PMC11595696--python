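# Methods

This note documents the models, numerical choices, and limitations of
ptychokit, in the spirit of the methods documentation of mature
scientific packages.

## Forward model

The sample is a complex transmission function `O(r)` on a pixel grid;
within the projection (thin-sample) approximation it relates to the
projected refractive-index decrements by
`O = exp(-k beta_proj) exp(-i k delta_proj)` with `k = 2 pi / lambda`
(`object_from_refraction`).  The illumination is a stack of `K`
mutually incoherent probe modes `P_m(r)`; the exit wave at scan
position `r_i` is the multiplicative approximation
`psi_im = P_m O[window_i]`, and the measured frame is the incoherent
sum `I_i = sum_m |D_d{psi_im}|^2`.

Two propagators `D_d` are provided.  The far-field operator is a
centered discrete Fourier transform with orthonormal (`1/M`)
normalization, so Parseval holds exactly and the modulus projection
needs no rescaling; zero frequency sits at pixel `(M/2, M/2)` and the
fftshift bookkeeping is internal.  The near-field operator is the
angular-spectrum method with transfer function
`H(f) = exp(i 2 pi d sqrt(1/lambda^2 - |f|^2))`; evanescent components
are zeroed rather than attenuated so the operator is deterministic and
exactly unitary on the propagating band.  The standard aliasing bound
`lambda d / (M p^2) <= 1` is checked and only warns, since the correct
criterion depends on the field's support.

The real-space sampling interval of a far-field reconstruction is
`dx = lambda d / (M p)`; physical constants enter only through
`hc = 1.23984193 keV nm`, fixed so wavelength math is reproducible to
the last bit.

## Projection engines

All engines are built from the data projector `PiM` (modulus
replacement behind the propagator; with multiple modes, one shared
factor `sqrt(I / sum_m |Psi_m|^2)`) and the consistency map `PiO`
(re-evaluation of `P * O[window]` from the current estimates).  Pixels
where the modeled intensity is exactly zero but the measurement is
positive receive `sqrt(I/K)` with zero phase — a deterministic
tie-break.  Masked-out detector pixels are left untouched by `PiM`,
which is how dead pixels and beamstops are ignored.

**Batched engines (AP, DM, RAAR).**  Every iteration makes two sweeps
over the scan.  The first updates all wavefronts in parallel (AP
recomputes `psi` from the model; DM and RAAR keep persistent exit
waves across iterations) and accumulates the object update's
numerator `sum_i conj(P) psi_i'` and denominator `sum_i |P|^2`.  After
the object update, a second sweep over the stored `psi'` accumulates
the probe sums against the *new* object.  This alternation matters:
updating object and probe simultaneously from each other's stale
counterparts is unstable for DM/RAAR (the coupled error modes grow
geometrically), while the alternated form is the standard overlap
projection and converges on noiseless data to float precision.  Both
sweeps run through per-worker partial accumulators combined by a
binary reduction tree, so the result is invariant to the batch size
and worker count up to float summation order — batching changes
memory residency, never results.  The per-batch resident set is one
batch of frames plus the accumulators, which is the memory contract
the scheduler emulates.

**Sequential engines (rPIE, mPIE).**  One measurement at a time in
random sweep order, with the regularized gradient-like steps
(`step 1.0`, `regularizer 0.1` by default; regularizer 1.0 reduces to
the constant-denominator classic update).  mPIE adds momentum every
full sweep: `v <- f v + (X - X_ckpt); X <- X + f v`, checkpoint
refreshed to the accelerated iterate.  The object friction defaults
to 0.9, following the accelerated-PIE literature; the probe friction
defaults to 0 because a high-gain probe velocity reliably destabilizes
the late iterations (the object-only form converges monotonically to
machine precision on the noiseless phantom, the coupled form diverges
after initial convergence).

**Error metric.**  The per-iteration trace is the normalized intensity
misfit `eps = sum_i sum_uv M (I_i - |D{psi_i}|^2)^2 / sum_i sum_uv M I_i`
evaluated on the *model* wavefronts `P O[window]`.  Evaluating it on
the `PiM` output instead would be degenerate: identically ~0 for
AP/rPIE (whose update *is* the modulus projection) and bounded away
from zero for DM even at its fixed point (the DM state is not the
solution; its image under the projectors is).  The metric is a squared
intensity residual over a plain intensity sum, so it carries intensity
units; an amplitude-residual variant (`(sqrt I - sqrt model)^2`) is
available behind `ReconConfig.amplitude_error` for a dimensionless
alternative.  Error traces are not asserted monotone — stochastic
engines fluctuate by design; only finiteness and final thresholds are
contractual.

**Initialization.**  Object: magnitudes uniform in [0.9, 1.0],
constant zero phase.  Probe: the back-propagated square root of the
frame-averaged intensity (zero detector phase); additional modes start
as weak random perturbations (10% of the peak) so orthogonalization
has a nonzero span to work with.  Probe updates are delayed until
iteration 3 by default — the object needs a few iterations of shape
before the probe division is well conditioned — and this is
configurable down to 0.

**Probe constraints.**  An optional loose circular support of given
physical diameter is applied after every probe update; a support
larger than the frame diagonal is a no-op.  With `K >= 2`, modes are
re-orthogonalized each iteration by eigendecomposition of their Gram
matrix: the new modes span the same space, come back ordered by
decreasing power, conserve total power, and carry occupancies
normalized to 1.

**Position correction.**  Annealing: per frame, the single-frame
intensity residual is evaluated at the current integer offset and at
candidate offsets within a radius (either an exhaustive enumeration or
a fixed number of uniform draws); the strict argmin wins, so on
noiseless data true positions are never abandoned.  The radius shrinks
by a cooling factor (default 0.95) per sweep.  Defaults (radius 2 px,
8 trials) are deliberate order-of-magnitude choices and fully
configurable.

**Scale and gauge.**  A reconstruction is only defined up to a global
phase, a global complex scale traded between object and probe, a
linear phase ramp paired with a probe shift, and (with a loose
support) a rigid translation.  Engines never fix these gauges; the
postprocessing module removes them explicitly — magnitude²-weighted
least-squares fit of the phase-gradient plane (gradients taken as
arguments of neighbor products, immune to wrapping), probe
center-of-mass alignment with integer rolls only (sub-pixel remainders
are reported, not interpolated, to avoid interpolation artifacts), and
the closed-form global phase/scale factor.  The NMSE against ground
truth is computed after these corrections, on the scan-covered region
by default (pixels whose accumulated probe power is at least half the
maximum); pixels the data never constrained are not scored.

## Maximum-likelihood refinement

The misfit `C = sum_i sum_uv M_i (|D{psi_i}|^(2 gamma) - I_i^gamma)^2`
with `gamma in {1/2, 1}` approximates the Poisson and Gaussian
maximum-likelihood estimators up to constants.  Gradients with
respect to object and probe are assembled analytically: the
detector-plane residual weight `4 gamma M (t^gamma - I^gamma)
t^(gamma-1) Psi_m` (with `t` the mode-summed model intensity, guarded
at `t = 0`) is pulled back through the adjoint propagator and the
multiplicative model.  The returned complex gradient `G` satisfies
`dC/dRe = Re(G)`, `dC/dIm = Im(G)`, so `z -= alpha G` is plain
steepest descent; gradients are validated against central finite
differences at 8×8 scale in the test suite.  The optimizer is
steepest descent with Armijo backtracking (`c = 1e-4`, shrink 0.5,
optimistic step growth between iterations) — the simplest rule that
guarantees a monotone cost sequence; curvature methods and automatic
differentiation are intentionally out of scope.  A fixed-step mode
exists and aborts with a diagnostic once the cost doubles.

## Scheduler

`partition_batches` makes contiguous batches of size ≤ B (only the
last may be smaller), `schedule` assigns them to W workers with a
deterministic unit-cost availability queue (round robin),
`tree_reduce` combines partial accumulators pairwise in
`ceil(log2 n)` rounds, and `broadcast` hands every worker the updated
model (an in-process value-equality contract, not a copy).  Workers
are emulated in one process; real device placement, pinned memory and
interconnect are outside the package's scope — what the tests assert
is the value contract: identical results for any (B, W), bounded
per-worker resident data.

## Synthetic data

The generator emulates a far-field benchmark acquisition: a complex
object built from two grayscale images (magnitude rescaled to
[0.2, 1], phase to [0, pi/2] — bounds chosen to avoid zero-amplitude
pathology while keeping the phase unwrapped), a circular constant-
phase probe, a raster grid with i.i.d. normal jitter (default sigma =
0.25 × step: small enough to preserve overlap, large enough to break
the raster-grid pathology), and optional Poisson noise at a target
photon budget per frame.  A procedural phantom (smooth background,
disks, bar strokes) ships with the package so no external image assets
are needed; any pair of grayscale images can be substituted.  Two
presets: `full_benchmark` (400×400 object, 180×180 probe, 20×20 grid,
step 11 px — grid step and jitter are not fixed by the reference
configuration and are exposed) and `small_test` (64×64 object, 32×32
probe, 5×5 grid, step 8 px, probe diameter 24 px → 67% linear
overlap), the desk-scale configuration used throughout the tests.
Generation is a pure function of (spec, seed); the manifest reports
the linear overlap and warns below 60%.

What the simulator does *not* model: partial coherence beyond mode
mixing, fly-scan trajectory integration, detector point-spread and
readout noise, positioning drift within a frame.  Passing tests
therefore demonstrate algorithmic correctness of the engines on data
exactly satisfying the forward model (plus Poisson noise), not
robustness to every artifact of beamline data.

## Problem sizes and degenerate inputs

The test suite and the acceptance checks run on the 64×64/32×32/25-
position phantom (seconds per engine on one CPU) with operator-level
oracles at 2×2–8×8; the full 400×400 benchmark geometry is generated
and validated structurally.  Degenerate inputs are handled
deterministically: all-masked datasets raise (the error metric is
undefined), zero probes and empty masks raise, rank-deficient mode
stacks keep their zero modes last with a warning, division guards are
scale-invariant (`1e-6 × max(denominator)`).

## Known limitations

Cold-started AP stalls on the joint object/probe problem (misfit
plateau near 1e-1 on the noiseless phantom) — a known property of
bare alternating projections, which is why practice warm-starts AP
from stochastic sweeps; the engine-recovery tests run AP in that
chained configuration.  No orthogonal probe relaxation, multi-slice,
ADMM or WASP variants; no event-list detector formats; no sub-pixel
scan interpolation (positions round to the nearest integer pixel,
ties to even, with residuals reported).  The near-field effective
pixel equals the detector pixel; single-step scaled Fresnel
propagation is not implemented.
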