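# Methods

This note documents the models implemented in `hippocan`, the parameter
choices that matter, what the synthetic data does and does not emulate, and
the numerical decisions behind the defaults.

## Head-direction encoding

Head-direction cells form a ring of `n_cells = 36` uniformly spaced
preferred angles θ_i. The encoding is purely feedforward,
`s_i = v·cos(θ_i − θ_head)`: each cell's signal is the velocity projection
onto its preferred direction. Signals are deliberately not rectified — cells
opposing the heading carry negative modulation, and rectification happens
downstream in the stripe plate's transfer function. A population-vector
decoder (`decode_ring`) inverts the encoding exactly and serves as a test
oracle; it is not part of the processing path.

## Stripe-cell continuous attractor

A ring of `n = 120` rate neurons with the all-inhibitory
difference-of-Gaussians kernel `W₀(x) = e^(−γx²) − e^(−βx²)`,
`β = 3/λ²`, `γ = 1.035β`, kernel wavelength parameter `λ = 20` cells.
Forward Euler with `τ = 5 ms`, `dt = 1 ms` (`dt ≤ τ/5` is enforced; the
update is a convex blend, so rates stay non-negative).

Two properties of this kernel on a 1-D ring deviate from naive expectation
and are handled explicitly:

* **Amplitude normalization (`w_amp = 10`).** Summing the unit-amplitude
  kernel along a single row of cells leaves the uniform state linearly
  stable (peak Fourier gain ≈ 0.16): no pattern ever forms. On a 2-D sheet
  the same kernel integrates over a plane and is marginally supercritical.
  The 1-D plate therefore scales the kernel by `w_amp = 10`, putting the
  most unstable ring mode at gain ≈ 1.55. Formation from uniform(0, 0.01)
  noise then completes in ≈ 150–250 ms, comfortably inside the 500 ms
  target.
* **Realized period.** The fastest-growing wavelength of this kernel is
  ≈ 1.5 λ, not λ: for λ = 20 on 120 cells the realized stripe period is 30
  cells (ring mode 4). `StripePlate.pattern_period` computes the discrete
  most-unstable mode from the kernel's ring spectrum, and all period checks,
  phase readout and calibration use that realized period.

Velocity coupling uses the offset `k = 1` cell and drive gain `α = 0.35`.
This operating point was chosen by sweeping the velocity response: the
phase-flow rate is linear in the drive to ≈ 1% above a small pinning
threshold, and the resulting physical stripe spacing after calibration is
L ≈ 0.22–0.26 m, a realistic band spacing for a room-sized arena. Phase is
read out as the argument of the population vector at the realized period and unwrapped by nearest-branch continuation (valid
while per-sample motion stays below half a period; guaranteed at ≤ 0.5 m/s).

**Calibration** regresses true displacement along the plate orientation on
the unwrapped phase over a 120 s random roam in a 1 m × 1 m arena
(ordinary least squares; `scipy.stats.linregress`). Typical results:
r ≈ 0.9998 (seed-to-seed range ≈ 0.9995–0.9999), maximum residual
8–17 mm. The residual is a slow, mean-reverting random walk caused by
lattice-discreteness ripple in the pattern's velocity response; it sets the
floor on 1-D path-integration accuracy.

## Grid assembly and tuning

Three plates with orientations 0°/60°/120° and a shared calibrated gain are
superposed by a rectified sum of their band responses; a band oriented at
angle a varies along a+90°, so the corresponding wave directions are
30°/90°/150° (`φ_l = −π/6 + l·π/3`). For decoding, grid cells follow the
von Mises tuning with defaults `n_max = 10 Hz`, `κ = 3`, and spike counts
are Poisson with a 1 s observation window. Cell phase offsets tile one unit
cell of the hexagonal lattice (primitive vectors of length 2λ/√3) on a
regular `cells_per_side × cells_per_side` grid.

## Maximum-likelihood decoding

Single-scale decoding is the closed-form population-vector solution; the
estimate is defined modulo the hexagonal lattice and is exact (to floating
precision) for noise-free rates whenever no per-direction phase wraps.

Multi-scale fusion runs coarse to fine with precision weights λ_m⁻²
(equal cell counts per scale; the weighted-average and recursive forms are
algebraically identical and both are exposed). One subtlety: the three wave
directions are linearly dependent (k₂ = k₁ + k₃), so per-direction phases
wrapped independently are generally *not* off by a lattice translate —
a naive "nearest lattice branch" search can be wrong by λ·2/3. Each finer
scale's offset is therefore computed per direction, wrapping
`μ_l − k⃗_l·x⃗_running` into (−λ_m/2, λ_m/2] — i.e. the offset is taken
relative to the running estimate, which is also the cheapest biologically
plausible rule. A dense-lattice evaluation of the log posterior
(`posterior_oracle`) provides the independent ground truth the decoders are
tested against. Undecodable inputs (zero counts, flat posterior) and
branch-ambiguous offsets (|offset| near λ_m/2) are flagged, never silently
guessed.

The decoder is unique only within the coarsest unit cell; arenas larger
than λ₀ are out of scope. In the pipeline the coarse absolute estimate
comes from the unwrapped plate phases (path integration), passed to the
decoder as a branch-selecting prior, matching the coarse-to-fine procedure.

## Boundary cells

The arena perimeter is split into equal segments (desk default 0.25 m,
full scale 1 m) with a binary wall-sensing band of 0.15–0.2 m. On the first
visit of a region the plate rates are occupancy-averaged over the visit and
stored as `W_id = ⟨rate_i⟩ / N` (first-visit learning; the remembered
snapshot is the reference, revisit updates off by default). On a revisit
the memory is injected additively (`+ Σ_d W_id B_d`, intensity `c = 20`)
for a limited `injection_s = 0.3 s` per band entry. With these defaults a
quarter-period phase offset corrects to < 10% within 200–500 ms.

Three practical rules keep correction productive, all motivated by the
mechanism's intrinsic error floor (the reference is only as precise as the
region geometry):

* only the nearest active region injects (two corner memories would pull
  the pattern toward conflicting phases);
* learning skips samples taken while an injection is deforming the pattern;
* injection is time-limited so that sliding along a wall does not pin the
  estimate to the remembered entry point.

Correction is applied only to plates whose physical period exceeds twice
the segment length; drift beyond half a period aliases and is flagged, not
silently corrected. In the experiments each run begins with a scripted
wall-following familiarization lap so the memories are laid down while
accumulated drift is still small — the exploration-then-correction
structure of the model; memories learned late in a drifting run would
otherwise embed the drift they are meant to cancel.

## Theta-rhythm drive dither

Running several grid scales from identical plates requires scaling the
velocity drive by L_base/λ_m, which for coarse scales pushes the drive
below the attractor's lattice-pinning threshold (≈ 0.005 in drive units):
the pattern sticks and integration fails. The plates in the multi-scale
pipeline therefore receive a zero-mean square-wave drive modulation
(amplitude 0.1, 20 Hz) in the same ±e_i channel as the velocity — a
theta-rhythm-like oscillation that sweeps the pattern back and forth
through its linear response regime, linearizing the net flow for
arbitrarily small drives. The dither period divides the trajectory sampling
interval, so phase samples are taken at a fixed dither phase and the
wiggle cancels. A residual state-dependent ratchet bias of order 0.05
cells/s remains; it is bounded in practice by the boundary corrections and
is one reason the uncorrected path integrator drifts slightly faster than
raw odometry. The single-plate calibration runs without dither (its drives
are well above threshold).

## Synthetic data and the odometry error model

Trajectories are random roams in a bounded rectangular arena: per-step
speeds uniform in (0, 0.5) m/s, heading increments uniform in (−π/2, π/2),
dt = 0.1 s, heading resampled away from walls so the speed distribution is
untouched. The odometry model applies i.i.d. Gaussian noise per step —
multiplicative on speed, additive on heading — plus optional systematic
encoder-scale and gyro-drift terms (off by default). Desk-scale noise
defaults (20% speed, 0.25 rad heading) are deliberately large so that
dead-reckoning drift becomes visible within a 1000 s run; real encoders
drift more slowly over longer times. A constant heading bias is *not* a
good drift model in a bounded arena (its position error is bounded by
geometry), and a growing gyro drift produces mid-path excursions that no
boundary correction can cancel; white noise gives the diffusive,
unbounded-in-time error growth the comparison needs.

What the synthetic setting does not emulate: wheel slip correlated with
floor material, heading errors correlated across steps, sensor latency,
non-rectangular arenas, and any visual or landmark input. Passing tests
show the mechanisms work under the stated noise model, not that the stack
is field-ready on a physical robot.

## Experiment sizes

Desk-scale defaults: 4 m × 4 m arena, 400–1000 s runs, 3 scales from
λ₀ = 4 m at ratio 1.5, 30²–50² grid cells per scale, 10–20 seeds per
study; the full-scale settings (10 m × 10 m, 5000 s, λ₀ = 10 m, 200²
cells) are available behind `ExperimentConfig.full_scale()` /
`--full-scale`. The multi-scale decoding study uses 200 Poisson trials per
configuration at 50² and 100² cells; the noise study perturbs the
activation values with 0/10/20% of peak rate over 50 repeats.

## Known limitations

* The stripe attractor's meters-per-cell gain exists only after
  calibration; it is a network property (of k, α, τ, the kernel), not a
  free parameter.
* Boundary correction's error floor is the region geometry (segment length
  plus sensing band) and the drift accumulated before first learning; the
  corrected-error envelope plateaus near that floor rather than at zero.
* Scales coarser than the arena cannot be corrected more precisely than
  the wall-sensing geometry allows, and arenas larger than the coarsest
  period (or without walls) are outside the model's validity, by design.
* All dynamics are rate-based; no spiking, no synaptic plasticity beyond
  the one-shot boundary memory.
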