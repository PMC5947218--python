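"""Sequence engines: assemble operators into signal series.

The central entry point is :func:`simulate_train`, which walks a
:class:`~epgx.models.PulseTrain` through RF / relaxation-exchange / shift
operator applications for single-pool, Bloch-McConnell (``bm``) or
magnetization-transfer (``mt``) tissue. On top of it sit generators for
RF-spoiled gradient echo (SPGR), balanced SSFP, CPMG multi-echo trains,
variable-flip-angle fingerprinting-style trains, and a multislice
turbo-spin-echo engine in which other slices act on the bound pool as
off-resonant saturation only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .models import (
    EPGXState,
    PulseTrain,
    SignalSeries,
    SinglePoolModel,
    TwoPoolBMModel,
    TwoPoolMTModel,
    mode_for_model,
)
from .operators import (
    GAMMA_RAD_PER_S_PER_UT,
    hard_pulse_energy,
    lineshape_value,
    relaxation_exchange,
    rf_transition,
    saturation_exponent,
    shift,
)

__all__ = [
    "DiffusionSpec",
    "simulate_train",
    "spgr_sequence",
    "bssfp_sequence",
    "bssfp_transient_profile",
    "quadratic_phase_schedule",
    "cpmg_sequence",
    "simulate_cpmg",
    "CPMGEchoes",
    "mrf_train",
    "multislice_tse",
    "apply_diffusion",
]


@dataclass
class DiffusionSpec:
    """Isotropic diffusion attenuation, applied identically to both pools.

    ``d`` is the apparent diffusion coefficient (mm^2/s) and
    ``gradient_moment`` the dephasing per unit length accrued in one
    interval (rad/mm, i.e. 2*pi/voxel-length for one cycle per voxel).
    """

    d: float
    gradient_moment: float = 2.0 * np.pi / 1.5  # one cycle across a 1.5 mm voxel
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("diffusion coefficient must be nonnegative")


def _diffusion_factors(
    n_orders: int, spec: DiffusionSpec, dt_ms: float, dephasing_cycles: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-order attenuation for one interval (constant-gradient b-factors).

    During an interval over which the order moves n -> n + kk the transverse
    b-factor is dk^2*dt*(n^2 + n*kk + kk^2/3) (which is ((n+1/2)^2 + 1/12)
    *dk^2*dt for kk=1); longitudinal states keep fixed order, b = dk^2*dt*n^2.
    """
    n = np.arange(n_orders, dtype=float)
    kk = float(dephasing_cycles)
    bscale = spec.gradient_moment**2 * (dt_ms * 1e-3)  # rad^2 s / mm^2
    b_plus = bscale * (n * n + n * kk + kk * kk / 3.0)
    nm = -n  # F~(-n)* states start at order -n
    b_minus = bscale * (nm * nm + nm * kk + kk * kk / 3.0)
    b_long = bscale * n * n
    return (
        np.exp(-spec.d * b_plus),
        np.exp(-spec.d * b_minus),
        np.exp(-spec.d * b_long),
    )


def apply_diffusion(
    state: EPGXState, spec: DiffusionSpec, interval_ms: float, dephasing_cycles: int = 1
) -> EPGXState:
    """Attenuate configuration states by diffusion over one interval (in place)."""
    if not spec.enabled or spec.d == 0:
        return state
    att_p, att_m, att_l = _diffusion_factors(
        state.order_max + 1, spec, interval_ms, dephasing_cycles
    )
    state.fplus_a *= att_p
    state.fminus_a *= att_m
    state.z_a *= att_l
    if state.mode == "bm":
        state.fplus_b *= att_p
        state.fminus_b *= att_m
    if state.z_b is not None:
        state.z_b *= att_l
    return state


def _apply_rf_free(state: EPGXState, t: np.ndarray, pool: str = "a") -> None:
    if pool == "a":
        fp, fm, z = state.fplus_a, state.fminus_a, state.z_a
    else:
        fp, fm, z = state.fplus_b, state.fminus_b, state.z_b
    new_fp = t[0, 0] * fp + t[0, 1] * fm + t[0, 2] * z
    new_fm = t[1, 0] * fp + t[1, 1] * fm + t[1, 2] * z
    new_z = t[2, 0] * fp + t[2, 1] * fm + t[2, 2] * z
    if pool == "a":
        state.fplus_a, state.fminus_a, state.z_a = new_fp, new_fm, new_z
    else:
        state.fplus_b, state.fminus_b, state.z_b = new_fp, new_fm, new_z


def _apply_relax(state: EPGXState, prop) -> None:
    """Relaxation-exchange over one precomputed interval (no shift)."""
    if state.mode == "single":
        e2 = prop.xi_t[0, 0]
        e1 = prop.xi_l[0, 0]
        state.fplus_a *= e2
        state.fminus_a *= e2
        state.z_a *= e1
        state.z_a[0] += prop.recovery[0]
    elif state.mode == "mt":
        e2 = prop.xi_t[0, 0]
        state.fplus_a *= e2
        state.fminus_a *= e2
        za = prop.xi_l[0, 0] * state.z_a + prop.xi_l[0, 1] * state.z_b
        zb = prop.xi_l[1, 0] * state.z_a + prop.xi_l[1, 1] * state.z_b
        state.z_a, state.z_b = za, zb
        state.z_a[0] += prop.recovery[0]
        state.z_b[0] += prop.recovery[1]
    else:  # bm
        xp = prop.xi_t_plus  # acts on (M+a, M+b) pairs
        xm = np.conj(xp)  # F~(-n)* pairs evolve under the conjugate block
        fpa = xp[0, 0] * state.fplus_a + xp[0, 1] * state.fplus_b
        fpb = xp[1, 0] * state.fplus_a + xp[1, 1] * state.fplus_b
        fma = xm[0, 0] * state.fminus_a + xm[0, 1] * state.fminus_b
        fmb = xm[1, 0] * state.fminus_a + xm[1, 1] * state.fminus_b
        state.fplus_a, state.fplus_b = fpa, fpb
        state.fminus_a, state.fminus_b = fma, fmb
        za = prop.xi_l[0, 0] * state.z_a + prop.xi_l[0, 1] * state.z_b
        zb = prop.xi_l[1, 0] * state.z_a + prop.xi_l[1, 1] * state.z_b
        state.z_a, state.z_b = za, zb
        state.z_a[0] += prop.recovery[0]
        state.z_b[0] += prop.recovery[1]


def _wsat_exponents(model, train: PulseTrain) -> np.ndarray:
    """Per-pulse bound-pool saturation exponents Wbar*tau_rf (MT mode)."""
    w = np.zeros(len(train))
    for j in range(len(train)):
        e = train.energies[j]
        if e == 0:
            continue
        off = train.offsets[j]
        if off == 0.0 and model.g0 is not None:
            g = model.g0
        else:
            g = lineshape_value(off, model.t2b_us, model.lineshape)
        w[j] = saturation_exponent(e, g)
    return w


def simulate_train(
    model,
    train: PulseTrain,
    mode: Optional[str] = None,
    diffusion: Optional[DiffusionSpec] = None,
    order_max: Optional[int] = None,
    sample_delay: float = 0.0,
    perfect_spoiling: bool = False,
    demodulate: bool = True,
    record_z: bool = False,
    return_state: bool = False,
):
    """Simulate a pulse train and return the demodulated F~0a series.

    Per pulse: apply the RF transition block (with bound-pool saturation in
    MT mode), record F~0a after ``sample_delay`` ms of relaxation-exchange
    (demodulated by the pulse phase when ``demodulate``), complete the
    interval, apply diffusion attenuation, and shift ``dephasing_cycles``
    times. With ``perfect_spoiling`` all transverse states are zeroed at
    the end of every interval (an idealized spoiler; the construction the
    ideally-spoiled steady-state solver assumes).

    Returns a :class:`SignalSeries`; with ``return_state=True`` a
    ``(series, final_state)`` tuple.
    """
    mode = mode or mode_for_model(model)
    n_pulses = len(train)
    if order_max is None:
        order_max = n_pulses + 1
    if not 0.0 <= sample_delay <= train.tr:
        raise ValueError("sample_delay must lie within the pulse interval")

    state = EPGXState.equilibrium(model, order_max, mode)
    prop_sample = relaxation_exchange(model, sample_delay, mode)
    prop_rest = relaxation_exchange(model, train.tr - sample_delay, mode)

    wsat = _wsat_exponents(model, train) if mode == "mt" else None

    sig = np.empty(n_pulses, dtype=complex)
    times = sample_delay + train.tr * np.arange(n_pulses)
    z0a = np.empty(n_pulses) if record_z else None
    z0b = np.empty(n_pulses) if record_z and mode != "single" else None
    warned = False

    for j in range(n_pulses):
        t = rf_transition(train.flips[j], train.phases[j])
        _apply_rf_free(state, t, "a")
        if mode == "bm":
            _apply_rf_free(state, t, "b")
        elif mode == "mt" and wsat[j] > 0:
            state.z_b = state.z_b * np.exp(-wsat[j])

        if sample_delay > 0:
            _apply_relax(state, prop_sample)
        demod = np.exp(-1j * train.phases[j]) if demodulate else 1.0
        sig[j] = state.fplus_a[0] * demod
        if not np.isfinite(sig[j]):
            raise FloatingPointError(f"non-finite signal at pulse index {j}")
        if record_z:
            z0a[j] = state.z_a[0].real
            if z0b is not None:
                z0b[j] = state.z_b[0].real

        _apply_relax(state, prop_rest)
        if diffusion is not None:
            apply_diffusion(state, diffusion, train.tr, train.dephasing_cycles)
        if train.dephasing_cycles:
            if not warned and abs(state.fplus_a[-train.dephasing_cycles]) > 0:
                warnings.warn(
                    "configuration states reached order_max; truncating",
                    RuntimeWarning,
                )
                warned = True
            shift(state, train.dephasing_cycles, warn_on_overflow=False)
        if perfect_spoiling:
            state.fplus_a[:] = 0
            state.fminus_a[:] = 0
            if mode == "bm":
                state.fplus_b[:] = 0
                state.fminus_b[:] = 0

    series = SignalSeries(times, sig, z0a, z0b)
    if return_state:
        return series, state
    return series


def bssfp_transient_profile(
    model,
    tr: float,
    alpha: float,
    psi: np.ndarray,
    mode: Optional[str] = None,
    n_pulses: Optional[int] = None,
    b1_max_ut: float = 13.5,
):
    """Off-resonance profile of bSSFP from a converged transient simulation.

    Because the balanced sequence accrues the same per-TR phase psi for
    every off-resonance isochromat, simulating with one dephasing cycle per
    TR and reading the configuration states back through the Fourier sum
    M+(psi) = sum_n F~n e^{i n psi} yields the whole off-resonance profile
    in a single run. The train is run for 5*T1, the next (phase-0) pulse is
    applied, and the echo is evaluated at TE = TR/2 (an extra e^{i psi/2}
    of precession on top of the half-interval relaxation).
    """
    mode = mode or mode_for_model(model)
    psi = np.asarray(psi, dtype=float)
    t1ref = model.t1 if isinstance(model, SinglePoolModel) else max(model.t1a, model.t1b)
    if n_pulses is None:
        n_pulses = int(np.ceil(5.0 * t1ref / tr))
    n_pulses += n_pulses % 2  # end just before a phase-0 pulse
    train = bssfp_sequence(tr, alpha, n_pulses, b1_max_ut)
    train = replace(train, dephasing_cycles=1)
    _, state = simulate_train(model, train, mode=mode, return_state=True)

    t = rf_transition(alpha, 0.0)
    _apply_rf_free(state, t, "a")
    if mode == "bm":
        _apply_rf_free(state, t, "b")
    elif mode == "mt":
        g0 = model.g0 if model.g0 is not None else lineshape_value(
            0.0, model.t2b_us, model.lineshape
        )
        w = saturation_exponent(hard_pulse_energy(alpha, b1_max_ut), g0)
        state.z_b = state.z_b * np.exp(-w)
    half = relaxation_exchange(model, tr / 2.0, mode)
    _apply_relax(state, half)
    from .isochromat import states_to_profile

    mplus, _ = states_to_profile(state, psi)
    return mplus * np.exp(1j * psi / 2.0)


def quadratic_phase_schedule(phi0: float, n_pulses: int) -> np.ndarray:
    """RF-spoiling phases phi_j = phi0 * j*(j+1)/2 (rad)."""
    j = np.arange(n_pulses, dtype=float)
    return phi0 * j * (j + 1) / 2.0


def spgr_sequence(
    tr: float,
    alpha: float,
    phi0: float,
    n_pulses: int,
    b1_max_ut: float = 13.5,
) -> PulseTrain:
    """RF-spoiled gradient-echo train: constant flip, quadratic phase.

    Pulse energies assume rectangular (hard) pulses at amplitude
    ``b1_max_ut``; they matter only for MT-mode saturation.
    """
    flips = np.full(n_pulses, alpha)
    phases = quadratic_phase_schedule(phi0, n_pulses)
    energies = np.full(n_pulses, hard_pulse_energy(alpha, b1_max_ut))
    durations = np.full(
        n_pulses, abs(alpha) / (GAMMA_RAD_PER_S_PER_UT * b1_max_ut) * 1e3
    )
    return PulseTrain(
        flips=flips,
        phases=phases,
        tr=tr,
        energies=energies,
        durations=durations,
        dephasing_cycles=1,
        spoil_increment=phi0,
    )


def bssfp_sequence(
    tr: float, alpha: float, n_pulses: int, b1_max_ut: float = 13.5
) -> PulseTrain:
    """Balanced SSFP train: constant flip, 0/pi alternating phase, no net
    gradient dephasing per TR."""
    flips = np.full(n_pulses, alpha)
    phases = np.where(np.arange(n_pulses) % 2 == 0, 0.0, np.pi)
    energies = np.full(n_pulses, hard_pulse_energy(alpha, b1_max_ut))
    return PulseTrain(
        flips=flips,
        phases=phases,
        tr=tr,
        energies=energies,
        dephasing_cycles=0,
    )


def cpmg_sequence(n_echoes: int, esp: float, b1_scale: float = 1.0) -> PulseTrain:
    """CPMG description: 90*b1 excitation about x, 180*b1 refocusing about y.

    Returned as a train with interval esp/2 (excitation, then refocusing
    pulses separated by esp with echoes midway); use :func:`simulate_cpmg`
    to obtain echo amplitudes.
    """
    if n_echoes < 1:
        raise ValueError("n_echoes must be >= 1")
    if esp <= 0:
        raise ValueError("echo spacing must be positive")
    flips = np.concatenate([[np.pi / 2], np.full(n_echoes, np.pi)]) * b1_scale
    phases = np.concatenate([[0.0], np.full(n_echoes, np.pi / 2)])
    return PulseTrain(flips=flips, phases=phases, tr=esp / 2.0, dephasing_cycles=1)


@dataclass
class CPMGEchoes:
    """Echo amplitudes of a multi-echo spin-echo train.

    ``total`` is what a receiver sees (both water pools contribute);
    per-compartment complex amplitudes are kept for inspection.
    """

    times: np.ndarray
    f0_a: np.ndarray
    f0_b: Optional[np.ndarray]

    @property
    def total(self) -> np.ndarray:
        if self.f0_b is None:
            return np.abs(self.f0_a)
        return np.abs(self.f0_a + self.f0_b)


def simulate_cpmg(
    model,
    n_echoes: int = 50,
    esp: float = 5.0,
    b1_scale: float = 1.0,
    mode: Optional[str] = None,
    order_max: Optional[int] = None,
) -> CPMGEchoes:
    """Simulate a CPMG echo train and return echo amplitudes at t = k*esp.

    Half-interval relaxation-exchange and unit dephasing are applied either
    side of each refocusing pulse; the echo amplitude is F~0 at the echo
    time. With ideal 180s and a single pool this reduces exactly to
    m0*exp(-t/T2).
    """
    mode = mode or mode_for_model(model)
    if order_max is None:
        order_max = 2 * n_echoes + 3
    state = EPGXState.equilibrium(model, order_max, mode)
    half = relaxation_exchange(model, esp / 2.0, mode)
    exc = rf_transition(np.pi / 2 * b1_scale, 0.0)
    ref = rf_transition(np.pi * b1_scale, np.pi / 2)

    def rf(t):
        _apply_rf_free(state, t, "a")
        if mode == "bm":
            _apply_rf_free(state, t, "b")

    rf(exc)
    f0a = np.empty(n_echoes, dtype=complex)
    f0b = np.empty(n_echoes, dtype=complex) if mode == "bm" else None
    for k in range(n_echoes):
        _apply_relax(state, half)
        shift(state, 1, warn_on_overflow=False)
        rf(ref)
        _apply_relax(state, half)
        shift(state, 1, warn_on_overflow=False)
        f0a[k] = state.fplus_a[0]
        if f0b is not None:
            f0b[k] = state.fplus_b[0]
    times = esp * np.arange(1, n_echoes + 1)
    return CPMGEchoes(times, f0a, f0b)


def mrf_train(
    n_pulses: int = 256,
    tr: float = 12.0,
    flip_max: float = np.deg2rad(60.0),
    n_levels: int = 16,
    inversion: bool = True,
    phi0: Optional[float] = np.deg2rad(117.0),
    inversion_energy: float = 433.0,
    energy_per_rad2: float = 54.3,
) -> PulseTrain:
    """Fingerprinting-style variable-flip train after an inversion pulse.

    Flip amplitudes follow a stepped sinusoidal lobe pattern with
    ``n_levels`` distinct values including zero (zero-flip intervals allow
    free recovery; gradient area is constant every TR regardless). Pulse
    energies are ``energy_per_rad2 * alpha^2`` ms*uT^2; the inversion is a
    perfect 180 on the free pool with energy ``inversion_energy`` deposited
    in the bound pool. With ``phi0`` set, quadratic RF spoiling phases are
    applied (SPGR variant, unit dephasing); with ``phi0=None`` phases
    alternate 0/pi (bSSFP variant, balanced).
    """
    block = n_pulses // n_levels
    k = np.arange(n_levels)
    # sinusoidal lobe with a slow amplitude ramp so all levels are distinct;
    # k = 0 gives an exact zero-flip block for free recovery
    levels = np.sin(np.pi * k / n_levels) * (0.6 + 0.4 * k / (n_levels - 1))
    flips = flip_max * np.repeat(levels, block)
    if len(flips) < n_pulses:
        flips = np.concatenate([flips, np.zeros(n_pulses - len(flips))])
    if phi0 is not None:
        phases = quadratic_phase_schedule(phi0, n_pulses)
        cycles = 1
        spoil = phi0
    else:
        phases = np.where(np.arange(n_pulses) % 2 == 0, 0.0, np.pi)
        cycles = 1  # constant gradient area every TR
        spoil = None
    energies = energy_per_rad2 * flips**2
    if inversion:
        flips = np.concatenate([[np.pi], flips])
        phases = np.concatenate([[0.0], phases])
        energies = np.concatenate([[inversion_energy], energies])
    return PulseTrain(
        flips=flips,
        phases=phases,
        tr=tr,
        energies=energies,
        dephasing_cycles=cycles,
        spoil_increment=spoil,
    )


# Pulse energies (ms*uT^2) for the multislice TSE protocols; keys are
# refocusing flip angle in degrees.
TSE_PULSE_ENERGIES = {
    180: {"excitation": 32.7, "first_refocus": 213.1, "refocus": 213.1,
          "first_refocus_deg": 180.0, "refocus_deg": 180.0,
          "slice_offset_hz": 2780.0},
    120: {"excitation": 36.7, "first_refocus": 189.4, "refocus": 106.5,
          "first_refocus_deg": 160.0, "refocus_deg": 120.0,
          "slice_offset_hz": 3130.0},
}


def multislice_tse(
    model,
    refocus_deg: int = 180,
    n_slices: int = 1,
    n_echoes: int = 25,
    echo_spacing: float = 7.7,
    tr: float = 5000.0,
    slice_offset_hz: Optional[float] = None,
    n_periods: int = 3,
    mode: Optional[str] = None,
) -> np.ndarray:
    """Echo amplitudes of the centre slice of a multislice TSE acquisition.

    From the centre slice's point of view, acquisition of every other slice
    is a train of pulses with zero flip angle on the free pool but full RF
    energy deposited off-resonance, so the bound pool is still saturated
    (offset = slice-position difference x ``slice_offset_hz``). The TR is
    divided into ``n_slices`` equal slots, one slice train per slot in
    odd-even interleaved order with the slot remainder as free relaxation
    (the uniform slice packing scanners use when TR exceeds the minimum).
    ``n_periods`` TR periods are run to reach a driven equilibrium and the
    centre-slice echo amplitudes |F~0a| of the last period are returned.
    """
    if n_slices % 2 == 0:
        raise ValueError("n_slices must be odd")
    if refocus_deg not in TSE_PULSE_ENERGIES:
        raise ValueError(f"refocus_deg must be one of {sorted(TSE_PULSE_ENERGIES)}")
    mode = mode or mode_for_model(model)
    cfg = TSE_PULSE_ENERGIES[refocus_deg]
    if slice_offset_hz is None:
        slice_offset_hz = cfg["slice_offset_hz"]

    centre = (n_slices - 1) // 2
    order = list(range(0, n_slices, 2)) + list(range(1, n_slices, 2))  # odd-even

    # Per-slice pulse description: (flip, phase, energy) for exc + n_echoes.
    exc = (np.pi / 2, 0.0, cfg["excitation"])
    first_ref = (np.deg2rad(cfg["first_refocus_deg"]), np.pi / 2, cfg["first_refocus"])
    ref = (np.deg2rad(cfg["refocus_deg"]), np.pi / 2, cfg["refocus"])
    slice_pulses = [exc, first_ref] + [ref] * (n_echoes - 1)

    n_per_slice = len(slice_pulses)
    flips, phases, energies, offsets = [], [], [], []
    for s in order:
        off = (s - centre) * slice_offset_hz
        for flip, phase, energy in slice_pulses:
            if s == centre:
                flips.append(flip)
                phases.append(phase)
                offsets.append(0.0)
            else:
                flips.append(0.0)
                phases.append(0.0)
                offsets.append(off)
            energies.append(energy)
    flips = np.array(flips)
    phases = np.array(phases)
    energies = np.array(energies)
    offsets = np.array(offsets)

    wsat = None
    if mode == "mt":
        dummy = PulseTrain(flips=flips, phases=phases, tr=echo_spacing,
                           energies=energies, offsets=offsets)
        wsat = _wsat_exponents(model, dummy)

    order_max = 2 * n_per_slice + 3
    state = EPGXState.equilibrium(model, order_max, mode)
    half = relaxation_exchange(model, echo_spacing / 2.0, mode)
    # each slice train occupies esp/2 (exc -> first refocus) + n_echoes*esp
    # within its TR/n_slices slot; the slot remainder is free relaxation
    slot = tr / n_slices
    train_dur = echo_spacing / 2.0 + n_echoes * echo_spacing
    if train_dur > slot:
        raise ValueError("slice trains do not fit within TR")
    rest = relaxation_exchange(model, slot - train_dur, mode)
    centre_pos = order.index(centre)
    echoes = np.empty(n_echoes)
    for _period in range(n_periods):
        for p, _s in enumerate(order):
            base = p * n_per_slice
            is_centre = p == centre_pos
            if is_centre:
                # fresh excitation: transverse coherence from the previous
                # TR is long dead (TR >> T2a) and crushed; drop it
                state.fplus_a[:] = 0
                state.fminus_a[:] = 0
                if mode == "bm":
                    state.fplus_b[:] = 0
                    state.fminus_b[:] = 0

            def pulse(idx):
                if flips[idx] != 0.0:
                    t = rf_transition(flips[idx], phases[idx])
                    _apply_rf_free(state, t, "a")
                    if mode == "bm":
                        _apply_rf_free(state, t, "b")
                if wsat is not None and wsat[idx] > 0:
                    state.z_b = state.z_b * np.exp(-wsat[idx])

            # excitation, then esp/2 to the first refocusing pulse
            pulse(base)
            _apply_relax(state, half)
            if is_centre:
                shift(state, 1, warn_on_overflow=False)
            for k in range(n_echoes):
                pulse(base + 1 + k)
                _apply_relax(state, half)
                if is_centre:
                    shift(state, 1, warn_on_overflow=False)
                    echoes[k] = abs(state.fplus_a[0])
                _apply_relax(state, half)
                if is_centre:
                    shift(state, 1, warn_on_overflow=False)
            _apply_relax(state, rest)  # slot remainder
    return echoes
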