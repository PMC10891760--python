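# Methods

## Problem and objective

The package reconstructs a 5D cardiac CINE series — complex 3D volumes
`m_{i,j}` indexed by respiratory phase `i = 1..Nr` and cardiac phase
`j = 1..Nc` — from undersampled multicoil Cartesian k-space `y` by solving

    m̂ = argmin_m  ½ ‖E m − y‖₂² + λ ‖Φ m‖₁ .

`E` applies, per frame and coil, the coil sensitivity map, an **orthonormal**
3D DFT and the frame's binary sampling mask.  The data-fidelity norm runs
over sampled k-space entries only; since `E`'s range includes the sampling
matrix, unsampled entries are identically zero on both sides.  `Φ` is
temporal total variation (tTV): non-circular forward differences along the
cardiac axis and, when `Nr ≥ 2`, the respiratory axis, with equal unit
weights by default (a per-axis weight pair is exposed in the configuration).
Non-circular differences were chosen over periodic ones because they keep
each partition's dependencies to a single neighbour on each side, which is
what makes the device decomposition below exact.

Coil maps are stored already normalized (`Σ_c |S_c|² ≤ 1` everywhere, `= 1`
where the generator's profiles overlap, i.e. the whole grid).  Together with
the orthonormal DFT this pins the operator norms — `‖E‖² ≤ 1` and
`‖Φ‖² ≤ 4(w_c² + w_r²) = 8` — so the gradient's Lipschitz constant is
available in closed form rather than estimated from data.

## Solver

NESTA-style accelerated first-order iteration on the Huber-smoothed
objective `f(m) = ½‖Em − y‖² + λ f_μ(Φm)`, where `f_μ` sums
`h_μ(z) = |z|²/2μ` for `|z| ≤ μ` and `|z| − μ/2` otherwise (the standard
complex Huber smoothing of the l1 norm; its gradient is `z/μ` inside the
knee and `z/|z|` outside, never exceeding unit magnitude).  Within a stage,
with `L = ‖E‖² + λ‖Φ‖²/μ = 1 + 8λ/μ`:

    g_k = ∇f(x_k)
    y_k = x_k − g_k / L
    z_k = x_init − (1/L) Σ_{i≤k} α_i g_i ,  α_i = (i+1)/2
    x_{k+1} = τ_k z_k + (1 − τ_k) y_k ,      τ_k = 2/(k+3)

The stage solution is the final `y_k`.  Stages implement μ-continuation:
μ₀ = 0.9·max|Φ m⁰|∞ evaluated at the zero-filled initialization
`m⁰ = Eᴴ y`, decaying geometrically to `mu_final` (default μ₀·10⁻³, i.e.
decade steps over the default 4 stages).  Each stage warm-starts from the
previous solution and resets the accumulated-gradient sum.  The default λ is
data-scaled, `0.01·max|Eᴴ y|`, keeping the two objective terms commensurate
when no λ is supplied.

**Stopping.**  Each stage records `f(x_k)` per iteration and halts at the
iteration cap (default 100) or, once at least τ = 7 values exist, when the
progress quotient `qp = (f̄ − f_k)/f̄` (`f̄` = mean of the last τ values)
falls to the tolerance `tol` (default 1e-5).  An identically zero objective
reports `qp = 0`, so degenerate all-zero problems halt as soon as the rule
activates.  Iterates are not forced monotone; only endpoint decrease per
stage is asserted by the tests.  Any non-finite objective aborts with a
diagnostic naming stage, iteration and (when partitioned) device.

## Partitioned execution

`partition_cardiac` splits the `Nc` cardiac phases into consecutive ranges,
one per device, proportional to abstract capacity weights with
largest-remainder rounding (equal weights reduce to `floor(Nc/d)` plus one
extra phase for the lowest-indexed devices, matching the convention that the
first devices carry the heavier load).  Every device keeps at least one
phase; an explicit manual split overrides the rule for capacity policies the
proportional rule cannot express (e.g. a 13/7 split over a 24 GiB/16 GiB
pair).  A device is resident for `(assigned + ghost phases) × Nr` 3D frames;
end devices carry one ghost cardiac phase, interior devices two.

Each device evaluates its gradient on its assigned frames *extended* by the
ghost phases.  Implementation detail: the device's local k-space is the
extended slice with ghost columns zero-masked, so one fused
objective/gradient evaluation yields (a) the fidelity term over assigned
frames only and (b) the tTV term over every temporal difference touching the
device's frames; the gradient is then restricted to assigned slots.  Because
Λ = Φᴴ f_μ′(Φm) at a frame involves only the adjacent phases, the restricted
gradient is bitwise identical to the corresponding slice of the global
gradient — verified to 1e-10 (observed: exact) by the audit tests.

Synchronization follows a fixed protocol per stage: an initial constants
exchange (S.0) shares the maxima that fix μ₀ and the default λ, so local
schedules coincide with the global ones; a stage barrier (S.1) ensures no
payload crosses stages; each iteration, devices publish boundary frames into
per-dependency channels (S.2) and retrieve ghosts (S.3) just before the
gradient step; a device that converges early publishes its final stage
solution (S.4) and notifies dependents (S.5), which keep iterating against
that payload.  Channels hold one payload each, replaced atomically under a
per-channel mutex (last writer wins); retrieval never blocks — absent a new
update the consumer reuses what it has.

Execution modes: `lockstep` advances devices round-robin in device order and
is bit-reproducible; `concurrent` runs one thread per device with barriers
between the publish and retrieve phases of each iteration (so both modes
produce identical iterates and iteration counts — confirmed bitwise by the
tests); `single` is the unpartitioned degenerate case.  With
`local_stopping` each device applies the progress-quotient rule to its own
local objective — the duplicated boundary l1 terms are harmless because the
local objective is only a stopping statistic.  With it disabled, the
stopping statistic is the global objective of the assembled iterate, forcing
identical iteration counts everywhere; in that mode the partitioned
reconstruction reproduces the single-device result exactly (the tests assert
< 1e-9 relative; observed difference is zero).  Constants and output
assembly reduce in ascending device order for reproducibility.

The exchange is pinned to the single gradient evaluation per iteration at
`x_k`; the auxiliary `y_k`/`z_k` sequences never touch ghost data, so no
additional exchange point is needed.

## Synthetic data

The generator emulates a free-breathing acquisition categorized into 20
cardiac and 4 respiratory phases (80 volumes) with 16 coils at 2 mm
resolution; the desk-scale default used throughout the tests is a 32×32×8
grid with 4 coils, which exercises every code path at a fraction of the
cost.  Components:

* **Phantom** — a deterministic analytic torso (soft-edged ellipsoid plus a
  spine rod) containing a two-compartment heart whose radii contract
  sinusoidally over the cardiac cycle (peak contraction at mid-cycle,
  default fractional contraction 0.3) and whose centre translates
  sinusoidally along z over the respiratory cycle (default 2 voxels peak to
  peak), under a smooth complex phase ramp.  Soft (sigmoid) edges temper
  Gibbs ringing.
* **Coils** — Gaussian magnitude profiles centred around the FOV with
  per-coil linear phase ramps, normalized to exact unit sum-of-squares.
* **Masks** — readout axis fully sampled; each frame's (ky, kz) plane gets a
  fully sampled central disc (default 4 % of the plane) plus random samples
  drawn without replacement with probability decaying in k-space radius
  (Gaussian density), with an exact per-frame sample budget `round(NyNz/AF)`
  so the sampled fraction tracks 1/AF to rounding.  Patterns are seeded per
  (seed, i, j), so frames differ but runs reproduce.  This is a generic
  variable-density Cartesian pattern standing in for spiral-like Cartesian
  trajectories; any Cartesian variable-density mask exercises the same
  reconstruction path and needs no gridding.
* **Noise** — complex Gaussian noise on sampled entries scaled so that
  10·log₁₀(signal power / noise power) hits the requested SNR, with signal
  power measured over sampled k-space entries (a convention measurable from
  the container alone).  An all-zero signal requires an explicit reference
  power.

What the phantom does **not** model: anatomical realism and tissue contrast,
through-plane motion irregularity, arrhythmia/binning errors, off-resonance
and eddy-current artefacts, or noise correlation between coils.  Passing
tests therefore demonstrate the correctness and internal consistency of the
operators, solver and decomposition — not clinical image quality on real
data.

## Numerical choices

* complex128 throughout; the partitioned-vs-global equivalence leaves no
  room for reduced precision.
* Orthonormal DFT scaling (`norm="ortho"`), so `‖E‖ ≤ 1` by construction.
* The one-sided tTV boundary (no wrap) is also the reason end devices have
  exactly one dependency.
* Progress quotient with `f̄ = 0` is defined as 0 (halt).
* `build_schedule` with a single stage requires `mu0 == mu_final`; the
  reconstruction entry points run a single stage directly at the target
  smoothing.
* SSIM: per-frame 3D Gaussian windows (σ = 1.5, 11-voxel support truncated
  symmetrically on volumes smaller than 11), K1 = 0.01, K2 = 0.03,
  population window statistics, data range = the reference's magnitude
  peak-to-peak, averaged over the interior (padding-free) region and then
  over frames.  Complex images are compared by magnitude, the standard MRI
  reporting convention.  PSNR uses the reference's peak magnitude; identical
  inputs report +inf.

## Test problem sizes

The suite keeps every check at desk scale: operator identities on 4³–8³
randomized instances; partitioned-gradient audits on an 8×8×4 grid with
20×4 phases for 2–4 devices; the exact two-device equivalence run at
32×32×8, 4 coils, AF 4; and the local-optimization quality battery at
24×24×8 with 12×4 phases, AF 4, covering 2–4 devices and SNR ∈ {24, 18, 6}
dB against the single-device reference.  End-to-end runs use a stopping
tolerance of 1e-3, which engages the progress-quotient rule within the
100-iteration stage cap at these sizes.

## Known limitations

* Devices are simulated workers (threads in `concurrent` mode); the package
  validates the decomposition and synchronization scheme, not hardware
  kernels, transfer bandwidth or wall-clock scaling.
* Cartesian encoding only; no non-Cartesian trajectories or gridding, no
  spatial-TV/wavelet/low-rank priors, no sensitivity-map estimation.
* The per-iteration ghost exchange assumes the iteration cost dominates the
  (simulated) communication; no staleness/relaxation strategies are
  implemented beyond the early-finish reuse.
* No fault tolerance: a diverging device aborts the whole run.
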