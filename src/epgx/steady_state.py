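"""Direct (non-iterative) steady states for ideally spoiled gradient echo
and balanced SSFP under single-pool, exchange, and MT models.

The solvers build one repetition period out of the same relaxation-exchange
propagators as the transient engine and solve the affine fixed point
x = P x + d linearly. The ideally-spoiled SPGR solution assumes transverse
magnetization is destroyed every TR (only longitudinal states survive); the
bSSFP solution keeps the full order-0 state vector and composes a two-pulse
period to handle the alternating RF phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import derived_rates, mode_for_model
from .operators import (
    hard_pulse_energy,
    lineshape_value,
    relaxation_exchange,
    rf_transition,
    saturation_exponent,
)

__all__ = ["SteadyStateResult", "spgr_ideal_spoiled_ss", "bssfp_ss"]


@dataclass
class SteadyStateResult:
    """Steady-state signal (complex demodulated F~0a) and longitudinal state."""

    signal: complex
    mz: np.ndarray
    psi: Optional[float] = None

    @property
    def magnitude(self) -> float:
        return abs(self.signal)


def _mt_wsat(model, alpha: float, b1_max_ut: float) -> float:
    energy = hard_pulse_energy(alpha, b1_max_ut)
    g0 = model.g0 if model.g0 is not None else lineshape_value(0.0, model.t2b_us, model.lineshape)
    return saturation_exponent(energy, g0)


def spgr_ideal_spoiled_ss(
    model,
    tr: float,
    alpha: float,
    mode: Optional[str] = None,
    b1_max_ut: float = 13.5,
) -> SteadyStateResult:
    """Ideally spoiled SPGR steady state.

    Solves the longitudinal fixed point Z = Xi_L S(alpha) Z + r with
    S = cos(alpha)*I for coupled transverse-visible pools (both pools are
    rotated) and S = diag(cos(alpha), exp(-Wbar*tau_rf)) for MT (the bound
    pool is directly saturated instead of rotated). The echo signal is
    sin(alpha) * Z_a of the pre-pulse steady state (TE ~ 0); in the
    single-pool limit this is the Ernst formula.
    """
    if not 0 < alpha < np.pi:
        raise ValueError("alpha must lie in (0, pi)")
    mode = mode or mode_for_model(model)
    prop = relaxation_exchange(model, tr, mode)
    if mode == "single":
        xi = prop.xi_l[0, 0]
        z = prop.recovery[0] / (1.0 - xi * np.cos(alpha))
        return SteadyStateResult(signal=np.sin(alpha) * z, mz=np.array([z]))
    if mode == "bm":
        s = np.cos(alpha) * np.eye(2)
    elif mode == "mt":
        s = np.diag([np.cos(alpha), np.exp(-_mt_wsat(model, alpha, b1_max_ut))])
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    a = np.eye(2) - prop.xi_l @ s
    if abs(np.linalg.det(a)) < 1e-300:
        raise np.linalg.LinAlgError("singular steady-state system (non-physical parameters)")
    z = np.linalg.solve(a, prop.recovery)
    return SteadyStateResult(signal=np.sin(alpha) * z[0], mz=z)


def _rf_matrix_order0(model, alpha, phi, mode, b1_max_ut):
    """RF action on the order-0 state vector used by the bSSFP solver."""
    t = rf_transition(alpha, phi)
    if mode == "single":
        return t
    if mode == "bm":
        out = np.zeros((6, 6), dtype=complex)
        out[:3, :3] = t
        out[3:, 3:] = t
        return out
    out = np.zeros((4, 4), dtype=complex)
    out[:3, :3] = t
    out[3, 3] = np.exp(-_mt_wsat(model, alpha, b1_max_ut))
    return out


def _evolution_affine(model, dt, psi_frac_phase, mode):
    """Affine map (matrix, offset) for free evolution over ``dt`` ms with
    transverse precession phase ``psi_frac_phase`` (rad) on top of any
    pool-b chemical shift already inside the propagator."""
    prop = relaxation_exchange(model, dt, mode)
    ph = np.exp(1j * psi_frac_phase)
    if mode == "single":
        m = np.diag([prop.xi_t[0, 0] * ph, np.conj(prop.xi_t[0, 0] * ph), prop.xi_l[0, 0]])
        d = np.array([0, 0, prop.recovery[0]], dtype=complex)
        return m, d
    if mode == "mt":
        m = np.zeros((4, 4), dtype=complex)
        m[0, 0] = prop.xi_t[0, 0] * ph
        m[1, 1] = np.conj(prop.xi_t[0, 0] * ph)
        m[2:, 2:] = prop.xi_l
        d = np.array([0, 0, prop.recovery[0], prop.recovery[1]], dtype=complex)
        return m, d
    # bm basis: [M+a, M-a, Mza, M+b, M-b, Mzb]
    m = np.zeros((6, 6), dtype=complex)
    xt = prop.xi_t  # on [M+a, M-a, M+b, M-b]
    idx = {0: 0, 1: 1, 3: 2, 4: 3}  # state index -> xi_t index
    for i_s, i_x in idx.items():
        for j_s, j_x in idx.items():
            m[i_s, j_s] = xt[i_x, j_x]
    phases = np.array([ph, np.conj(ph), 1, ph, np.conj(ph), 1])
    m = np.diag(phases) @ m
    m[2, 2] = prop.xi_l[0, 0]
    m[2, 5] = prop.xi_l[0, 1]
    m[5, 2] = prop.xi_l[1, 0]
    m[5, 5] = prop.xi_l[1, 1]
    d = np.zeros(6, dtype=complex)
    d[2] = prop.recovery[0]
    d[5] = prop.recovery[1]
    return m, d


def bssfp_ss(
    model,
    tr: float,
    alpha: float,
    psi: float = 0.0,
    mode: Optional[str] = None,
    b1_max_ut: float = 13.5,
) -> SteadyStateResult:
    """Balanced-SSFP steady state at off-resonance dephasing ``psi`` (rad/TR).

    Composes one two-pulse period (alternating 0/pi RF phase): RF, then
    free evolution (relaxation-exchange plus precession by psi), twice;
    solves the affine fixed point; and evaluates the echo at TE = TR/2
    after the phase-0 pulse, demodulated by that pulse's phase.
    """
    if not -np.pi <= psi <= np.pi:
        raise ValueError("psi must lie in [-pi, pi]")
    mode = mode or mode_for_model(model)
    e_full, d_full = _evolution_affine(model, tr, psi, mode)
    r0 = _rf_matrix_order0(model, alpha, 0.0, mode, b1_max_ut)
    r1 = _rf_matrix_order0(model, alpha, np.pi, mode, b1_max_ut)
    # period starting just before a phase-0 pulse
    m = e_full @ r1 @ e_full @ r0
    d = e_full @ r1 @ d_full + d_full
    n = m.shape[0]
    try:
        x = np.linalg.solve(np.eye(n) - m, d)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular bSSFP steady-state system") from err
    # echo: phase-0 pulse then half-interval evolution
    e_half, d_half = _evolution_affine(model, tr / 2.0, psi / 2.0, mode)
    x_echo = e_half @ (r0 @ x) + d_half
    mz_idx = {"single": [2], "mt": [2, 3], "bm": [2, 5]}[mode]
    return SteadyStateResult(signal=x_echo[0], mz=x_echo[mz_idx].real, psi=psi)
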