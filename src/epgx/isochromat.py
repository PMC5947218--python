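"""Brute-force reference path: direct Bloch-McConnell integration over a
dephasing ensemble, and Fourier reconstruction of intravoxel profiles.

An idealized voxel is the interval psi in [-pi, pi] of gradient-induced
dephasing with uniform magnetization density. The phase-graph calculation
is the Fourier-series description of that same physics, so for any train
of P pulses an ensemble of N >= P evenly spaced isochromats averages to the
identical signal (to double precision); this module provides that check and
the profile <-> states transforms.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .models import EPGXState, PulseTrain, SignalSeries, mode_for_model
from .operators import relaxation_exchange, rf_transition
from .sequences import _wsat_exponents

__all__ = ["isochromat_angles", "simulate_isochromats", "states_to_profile", "profile_to_states"]


def isochromat_angles(n_iso: int) -> np.ndarray:
    """Midpoint grid psi_j = -pi + (j + 1/2)*2*pi/N over [-pi, pi].

    The midpoint rule avoids double-counting the equivalent endpoints +-pi
    and makes the arithmetic ensemble mean annihilate e^{i*n*psi} exactly
    for every order 0 < |n| < N.
    """
    if n_iso < 1:
        raise ValueError("n_iso must be >= 1")
    j = np.arange(n_iso)
    return -np.pi + (j + 0.5) * 2.0 * np.pi / n_iso


def simulate_isochromats(
    model,
    train: PulseTrain,
    n_iso: int,
    mode: Optional[str] = None,
    demodulate: bool = True,
) -> SignalSeries:
    """Voxel-averaged signal from direct per-isochromat evolution.

    Each isochromat carries (M+, Mz) per compartment; between pulses it
    precesses by its own dephasing angle (times ``dephasing_cycles``) and
    relaxes/exchanges via the same matrix-exponential propagators the
    phase-graph engine uses; pulses act as the identical RF transition.
    The signal is the arithmetic ensemble mean of M+a, demodulated by the
    pulse phase.
    """
    mode = mode or mode_for_model(model)
    psi = isochromat_angles(n_iso)
    grad_phase = np.exp(1j * psi * train.dephasing_cycles)

    prop = relaxation_exchange(model, train.tr, mode)
    wsat = _wsat_exponents(model, train) if mode == "mt" else None

    from .models import derived_rates

    rates = derived_rates(model)
    mp_a = np.zeros(n_iso, dtype=complex)
    mz_a = np.full(n_iso, rates.m0a, dtype=complex)
    if mode == "bm":
        mp_b = np.zeros(n_iso, dtype=complex)
    if mode in ("bm", "mt"):
        mz_b = np.full(n_iso, rates.m0b, dtype=complex)

    n_pulses = len(train)
    sig = np.empty(n_pulses, dtype=complex)
    times = train.tr * np.arange(n_pulses)
    for j in range(n_pulses):
        t = rf_transition(train.flips[j], train.phases[j])

        def rotate(mp, mz):
            new_mp = t[0, 0] * mp + t[0, 1] * np.conj(mp) + t[0, 2] * mz
            new_mz = t[2, 0] * mp + t[2, 1] * np.conj(mp) + t[2, 2] * mz
            return new_mp, new_mz

        mp_a, mz_a = rotate(mp_a, mz_a)
        if mode == "bm":
            mp_b, mz_b = rotate(mp_b, mz_b)
        elif mode == "mt" and wsat[j] > 0:
            mz_b = mz_b * np.exp(-wsat[j])

        demod = np.exp(-1j * train.phases[j]) if demodulate else 1.0
        sig[j] = np.mean(mp_a) * demod

        # free precession (gradient) + relaxation/exchange
        if mode == "single":
            mp_a = mp_a * grad_phase * prop.xi_t[0, 0]
            mz_a = mz_a * prop.xi_l[0, 0] + prop.recovery[0]
        elif mode == "mt":
            mp_a = mp_a * grad_phase * prop.xi_t[0, 0]
            za = prop.xi_l[0, 0] * mz_a + prop.xi_l[0, 1] * mz_b + prop.recovery[0]
            zb = prop.xi_l[1, 0] * mz_a + prop.xi_l[1, 1] * mz_b + prop.recovery[1]
            mz_a, mz_b = za, zb
        else:
            xp = prop.xi_t_plus
            pa = xp[0, 0] * mp_a + xp[0, 1] * mp_b
            pb = xp[1, 0] * mp_a + xp[1, 1] * mp_b
            mp_a, mp_b = pa * grad_phase, pb * grad_phase
            za = prop.xi_l[0, 0] * mz_a + prop.xi_l[0, 1] * mz_b + prop.recovery[0]
            zb = prop.xi_l[1, 0] * mz_a + prop.xi_l[1, 1] * mz_b + prop.recovery[1]
            mz_a, mz_b = za, zb
    return SignalSeries(times, sig)


def _coeffs(state: EPGXState, pool: str) -> Tuple[np.ndarray, np.ndarray]:
    """Full two-sided Fourier coefficients (F~n for n=-N..N, Z~n likewise)."""
    if pool == "a":
        fp, fm, z = state.fplus_a, state.fminus_a, state.z_a
    else:
        fp, fm, z = state.fplus_b, state.fminus_b, state.z_b
    n = state.order_max
    f_two = np.zeros(2 * n + 1, dtype=complex)
    z_two = np.zeros(2 * n + 1, dtype=complex)
    f_two[n:] = fp  # F~0..F~N
    f_two[:n] = np.conj(fm[1:][::-1])  # F~(-k) = conj(F~(-k)*)
    z_two[n:] = z
    z_two[:n] = np.conj(z[1:][::-1])  # Mz real => Z~(-k) = conj(Z~k)
    return f_two, z_two


def states_to_profile(
    state: EPGXState, psi: np.ndarray, pool: str = "a"
) -> Tuple[np.ndarray, np.ndarray]:
    """Evaluate M+(psi) and Mz(psi) from configuration states.

    Direct evaluation of the Fourier sums M+(psi) = sum_n F~n e^{i n psi},
    Mz(psi) = sum_n Z~n e^{i n psi} at arbitrary dephasing angles.
    """
    psi = np.asarray(psi, dtype=float)
    f_two, z_two = _coeffs(state, pool)
    n = state.order_max
    orders = np.arange(-n, n + 1)
    basis = np.exp(1j * np.outer(psi, orders))
    return basis @ f_two, basis @ z_two


def profile_to_states(
    mplus: np.ndarray, mz: np.ndarray, order_max: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover (F~n, F~(-n)*, Z~n) for n = 0..order_max from profiles.

    ``mplus``/``mz`` must be sampled on the uniform full-period grid
    psi_k = -pi + 2*pi*k/N; N must resolve all retained orders
    (N >= 2*order_max + 1), otherwise an aliasing error is raised.
    """
    mplus = np.asarray(mplus, dtype=complex)
    n_grid = len(mplus)
    if n_grid < 2 * order_max + 1:
        raise ValueError("psi grid too small to resolve the retained orders (aliasing)")
    psi = -np.pi + 2.0 * np.pi * np.arange(n_grid) / n_grid
    orders = np.arange(-order_max, order_max + 1)
    basis = np.exp(-1j * np.outer(orders, psi)) / n_grid
    f_two = basis @ mplus
    z_two = basis @ np.asarray(mz, dtype=complex)
    n = order_max
    fp = f_two[n:]
    fm = np.concatenate([[np.conj(f_two[n])], np.conj(f_two[:n][::-1])])
    z = z_two[n:]
    return fp, fm, z
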