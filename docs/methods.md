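# Methods

## State representation and operators

A voxel is idealized as the dephasing interval ψ ∈ [−π, π] with uniform
density. Magnetization is carried as configuration states per compartment:
`fplus[n] = F̃ₙ`, `fminus[n] = F̃₋ₙ*` and `z[n] = Z̃ₙ` for n = 0..order_max,
so `fminus[0] == conj(fplus[0])` is an invariant of every operator. Three
operators act per repetition:

* **RF transition** (3×3, same at every order) mixes {F̃ₙ, F̃₋ₙ*, Z̃ₙ} of
  each pool; both pools see the same flip and phase (per-pool flip angles
  are out of scope). In MT mode the bound pool has no transverse states
  and an RF event multiplies every Z̃ₙᵇ by exp(−W̄τ_rf).
* **Relaxation–exchange** over an interval Δt is exp(Λ·Δt) with the
  coupled generators given in the README. The exponentials are evaluated
  with scipy's dense Padé `expm` once per unique (model, Δt) inside each
  engine call and reused across pulses (all supported sequences have
  uniform timing). Rates are assembled in s⁻¹ (the unit exchange rates are
  tabulated in); times are milliseconds throughout and the ms→s conversion
  happens exactly once, at the `expm` call. The longitudinal recovery term
  (Ξ_L − I)Λ_L⁻¹ C is computed through the augmented exponential
  `expm([[Λ_L, C], [0, 0]]·Δt)`, which is exact and needs no special case
  when Λ_L is singular (R1 = 0 and no exchange).
* **Shift** increments transverse orders; it is integer bookkeeping only.
  The pool-b frequency offset δb lives inside Λ_T (where the coupled
  transverse generator places it), not in the shift. F̃₋ₙ* pairs evolve
  under the conjugate of the (M⁺a, M⁺b) block, which keeps the order-0
  conjugate symmetry exact for δb ≠ 0.

State arrays are allocated at order_max = n_pulses + 1 by default
(lossless); a smaller order_max truncates with a `RuntimeWarning`, never
silently.

## Lineshape and pulsed saturation

The super-Lorentzian absorption lineshape is evaluated by adaptive
quadrature (relative tolerance 1e-8) over fiber orientation u ∈ [0, 1]
with the singular point u = 1/√3 declared to the integrator. The function
diverges at zero offset; following standard practice the band |Δ| < 1 kHz
is bridged by a cubic spline through quadrature samples outside the band.
The interpolated value at Δ = 0 is inherently layout-dependent (reasonable
knot layouts span roughly 12.5–17.7 µs for T2b = 12 µs); this package uses
mirrored knots every 250 Hz from 1.5 to 50 kHz, a layout with a guard band
between the excluded region and the first knot, which reproduces the
conventional on-resonance value G(0) = 15.1 µs for T2b = 12 µs to 0.4%.
Off the excluded band the quadrature value is used directly. A Gaussian
lineshape is available as an alternative formula.

Pulsed saturation uses the mean-square-B1 convention
W̄ = (π γ² / τ_rf) ∫B1²dt · G(Δ), so the applied factor
exp(−W̄ τ_rf) = exp(−π γ² E G) depends only on pulse energy E, matching
how multislice protocols tabulate their pulses. γ is fixed at
267.5221 rad s⁻¹ µT⁻¹. Hard-pulse energies are E = B1²·α/(γB1) with
B1 = 13.5 µT by default. The saturation factor is applied to Z̃ₙᵇ at
*every* order (the RF block acts per order); only Z̃₀ᵇ is ever
macroscopically populated in the simulated sequences, so this choice is
inert in practice.

## Sequence engines

`simulate_train` applies, per pulse: RF (+saturation) → `sample_delay` ms
of relaxation–exchange → record demodulated F̃₀ᵃ → remainder of the
interval → optional diffusion attenuation → shift. SPGR samples at TE ≈ 0
by default (a TE is imposed via `sample_delay`, used for the
phantom-style fits at TE = 2.9 ms); bSSFP is evaluated at TE = TR/2.
RF-spoiling uses the quadratic schedule φⱼ = Φ₀ j(j+1)/2 with the receiver
demodulated by the transmitter phase. A `perfect_spoiling` option zeroes
all transverse states at the end of each interval; this is the transient
construction that converges exactly to the ideally-spoiled steady-state
solver, whereas a quadratic increment such as Φ₀ = 117° only approaches it
(to ~1% for the tissues shipped as presets).

The balanced-SSFP off-resonance profile is obtained from a single
transient run by the standard device of simulating with one dephasing
cycle per TR and reading the converged states back through
M⁺(ψ) = Σ F̃ₙ e^{inψ} (per-TR off-resonance phase is indistinguishable
from gradient dephasing), with an extra e^{iψ/2} for the half-interval to
the echo. Trains run for 5×T1 before the profile is read.

CPMG uses 90°·b1 excitation about x and 180°·b1 refocusing about y, with
b1 scaling applied to all pulses (a transmit-field error scales every
flip); echo amplitudes are F̃₀ at k·esp, and the *total* echo is
|F̃₀ᵃ + F̃₀ᵇ| since both water pools are visible. With ideal pulses and a
single pool this reduces to pure exp(−t/T2) with no stimulated pathways.

The variable-flip fingerprinting-style train is 256 pulses at TR = 12 ms
after a perfect inversion of the free pool (bound-pool saturation energy
433 ms µT²); small-pulse energies are 54.3·α² ms µT². Flip amplitudes form
a stepped sinusoidal lobe with 16 distinct levels including an exact zero
block (free recovery); a slow amplitude ramp keeps the 16 levels distinct.
The exact lobe shape is a free parameter of the generator and nothing
downstream depends on it. Gradient area is constant every TR, including
zero-flip intervals.

### Multislice TSE timing

From the centre slice's point of view, another slice's echo train is a
train of zero-flip pulses whose full RF energy saturates the bound pool at
offset (slice distance) × (2.78 kHz for the 180° protocol, 3.13 kHz for
120°; the 120° protocol's first refocusing pulse is 160°). The TR is
divided into n_slices equal slots, one slice train per slot in odd-even
interleaved order, the slot remainder being free relaxation — the uniform
slice packing scanners use when TR exceeds the minimum. (A compact
saturation block placed in the dead time after the centre train was tried
first and rejected: with TR = 5 s and T1obs ≈ 0.78 s the subsequent free
recovery washes the saturation out, and tying the centre slice's position
to the interleave order makes attenuation non-monotone in slice count.)
Three TR periods are simulated and the third period's echo train is
reported; the mean over the 25 echoes is the "signal" compared across
slice counts. Residual transverse coherence is dropped at each centre
excitation (TR ≫ T2a and crushed). Direct slice cross-talk is not modeled
(a tissue without a bound pool is provably unaffected by slice count).

## Diffusion

Isotropic diffusion attenuates each order by the constant-gradient
b-factors: transverse b = Δk²Δt(n² + n·kk + kk²/3) for an interval moving
order n → n+kk (the familiar ((n+½)² + 1/12)Δk²Δt at kk = 1), longitudinal
b = Δk²Δt·n². Both compartments share one diffusion coefficient by
default (compartment-specific coefficients would be a model extension,
not supported here). The per-interval gradient moment defaults to one
cycle across a 1.5 mm voxel (Δk = 2π/1.5 rad/mm); it is configuration,
chosen, not asserted, since protocols rarely publish the spoiler moment.

## Steady-state solvers

Ideally-spoiled SPGR solves the 2-vector fixed point
Z = Ξ_L S(α) Z + r with S = cos α·I (both pools rotated) or
S = diag(cos α, e^{−W̄τ_rf}) (MT), signal = sin α·Z_a; the single-pool
limit is the Ernst formula. bSSFP composes one two-pulse period (RF with
alternating 0/π phase, free evolution with precession ψ and relaxation–
exchange) as an affine map on the full order-0 state vector, solves
x = Px + d, and reads the echo at TR/2. These solvers share the propagator
primitives with the transient engine but none of its sequencing; their
correctness is established by (i) closed-form limits (Ernst, classical
bSSFP, an independently derived scalar fixed point for the on-resonance
two-pool MT case) and (ii) agreement with converged transients to 0.1%.

## Isochromat reference path

`simulate_isochromats` integrates the coupled equations directly for N
isochromats on the midpoint grid ψⱼ = −π + (j+½)·2π/N (no double-counted
endpoint; the arithmetic mean annihilates e^{inψ} exactly for 0 < |n| < N)
and averages M⁺ᵃ. For any train of P pulses and N ≥ P the ensemble mean
equals the phase-graph signal at the double-precision floor (~1e-16 RMS
here); undersampled ensembles are orders of magnitude off. This is the
package's brute-force oracle, not a performance path.

## NNLS T2 spectroscopy

Spectra solve min‖Ax − y‖ s.t. x ≥ 0 with A_ij = exp(−t_i/T2_j) on a
120-point log grid from 5 ms to 2 s (plain NNLS, no regularization; the
fraction estimate moves < 0.005 between 80 and 200 grid points). The
spectrum is split at the amplitude minimum between its two largest local
maxima; the estimated small-pool fraction is the fractional area of the
smaller-area peak and its T2 the amplitude-weighted geometric mean within
that peak (the estimator behind a reported "short-component T2" is rarely
specified; this one is stable under grid refinement). A single-peak
spectrum reports fraction 0 and an undefined short T2.

## MT fitting

`fit_epgx_mt` fits (ka, T1a, T1b, f, G0) to magnitude signals of two
RF-spoiling increments simultaneously, with T2a, diffusion and overall
scale fixed at measured values, by bound-constrained trust-region least
squares from 3 perturbed starts (first start deterministic; early stop on
an essentially exact fit). Simulated magnitudes are divided by (1−f)
because the bound pool is invisible to the receiver. Consistency with a
separately measured apparent T1 is enforced as a penalty residual
(T1obs(θ) − T1obs,meas)/5 ms, using the bi-exponential closed form

    T1obs⁻¹ = (s − √(s² − 4(R1aR1b + R1a kb + R1b ka)))/2,  s = R1a+ka+R1b+kb

(the smaller-magnitude eigenvalue of Λ_L; verified against numerical
eigenvalues to 1e-10 over random models). On noiseless self-generated
data the fit recovers all five parameters to well under 2%; a single-pool
control fit (T1 free) leaves residuals concentrated immediately after the
inversion, which is the characteristic signature of the bound pool's
faster apparent recovery.

The synthetic-signal generator adds complex white Gaussian noise with
per-channel σ = mean(|signal|)/SNR, deterministic per seed. Magnitude
(Rician) bias is ignored; at SNR ≥ 50 it is below the tolerances used
anywhere in the package. The generator emulates clean phantom-style
acquisitions — single voxel, perfect B1 calibration except where scaled
explicitly, no drift or motion — so passing tests demonstrate
correctness of the signal model and estimators, not robustness to
artefacts of in-vivo data.

## Exchange-rate conventions

For the myelin preset (f = 0.2, ka = 2 s⁻¹) the bound-water mean residence
time is 100 ms under τ_b = f/ka and 125 ms under τ_b = f/(ka(1−f)) = 1/kb;
both conventions appear in the literature and both are exposed
(`residence_time_b`). The package reports ka itself everywhere to avoid
the ambiguity.

## Problem sizes and numerical tolerances

Transient-vs-steady-state checks run 1000-pulse trains (5×T1 at TR = 5 ms)
and 64-point ψ grids; profile agreement is measured relative to the
profile maximum because pass-band nulls make pointwise relative error
ill-posed. The isochromat equivalence check uses 200 pulses/200
isochromats. The multislice engine runs 3 TR periods of up to 15×26
pulses. CPMG analyses use 50 echoes. Matrix-exponential and closed-form
identities are asserted at 1e-10–1e-12; physics-level consistency
(transient vs direct steady state) at 0.1%.

## Known limitations

* Two compartments only; no mixed BM+MT or ≥3-pool systems.
* Pulses are instantaneous rotations plus lumped saturation; no
  within-pulse integration of the coupled equations, no slice profiles
  (protocol pulse energies stand in for waveforms), so long-saturation
  experiments (z-spectrum CEST) are out of scope.
* Uniform inter-pulse timing with a single unbalanced gradient direction;
  sequences needing non-uniform timing would require the continuous-
  Fourier generalization.
* One shared diffusion coefficient across compartments, treated
  independently per pool.
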