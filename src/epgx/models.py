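"""Tissue models, pulse trains, and configuration-state containers.

Unit conventions used throughout the package:

* times (T1, T2, TR, echo spacing, pulse durations) in **milliseconds**;
* exchange rates ``ka``/``kb`` in **s^-1** (as conventionally tabulated);
* the bound-pool lineshape T2 in **microseconds**;
* frequencies (off-resonance, irradiation offsets) in **Hz**;
* angles in **radians**;
* RF pulse energies (time integral of B1^2) in **ms*uT^2**.

``derived_rates`` is the single place where relaxation times are inverted
into rates; propagator construction converts ms -> s exactly once when the
matrix exponential is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SinglePoolModel",
    "TwoPoolBMModel",
    "TwoPoolMTModel",
    "PulseTrain",
    "EPGXState",
    "SignalSeries",
    "RateBundle",
    "derived_rates",
    "t1_observed",
    "residence_time_b",
]


@dataclass
class SinglePoolModel:
    """Classic single-compartment tissue (Bloch equations only).

    Parameters
    ----------
    t1, t2 : float
        Longitudinal / transverse relaxation times (ms).
    m0 : float
        Equilibrium magnetization (arbitrary units).
    """

    t1: float
    t2: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("relaxation times must be positive")


@dataclass
class TwoPoolBMModel:
    """Two compartments coupled by the Bloch-McConnell equations.

    Compartment *a* is the larger one by convention; ``f`` is the fractional
    equilibrium magnetization of compartment *b* (M0b = f*m0). ``ka`` is the
    forward exchange rate a->b; the reverse rate follows from detailed
    balance, ka*M0a = kb*M0b. ``delta_b`` is the chemical-shift / frequency
    offset of compartment b relative to a (Hz).
    """

    t1a: float
    t1b: float
    t2a: float
    t2b: float
    ka: float
    f: float
    delta_b: float = 0.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t1a", "t1b", "t2a", "t2b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.f < 1.0:
            raise ValueError("f must satisfy 0 <= f < 1")
        if self.ka < 0:
            raise ValueError("ka must be nonnegative")
        if self.f == 0.0 and self.ka > 0:
            raise ValueError("f=0 with ka>0 leaves the reverse rate undefined")


_LINESHAPES = ("super_lorentzian", "gaussian")


@dataclass
class TwoPoolMTModel:
    """Two-pool magnetization-transfer tissue (semisolid bound pool).

    The bound pool (*b*) carries no transverse magnetization anywhere in the
    formalism; its very short T2 (``t2b_us``, microseconds) enters only
    through the absorption lineshape G(omega_z) that sets the RF saturation
    rate. There is consequently no frequency offset parameter for pool b.

    ``g0`` optionally caches/overrides the lineshape value at zero offset
    (microseconds); when unset it is computed from the lineshape.
    """

    t1a: float
    t1b: float
    t2a: float
    t2b_us: float
    ka: float
    f: float
    lineshape: str = "super_lorentzian"
    g0: Optional[float] = None
    m0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t1a", "t1b", "t2a", "t2b_us"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.f < 1.0:
            raise ValueError("f must satisfy 0 <= f < 1")
        if self.ka < 0:
            raise ValueError("ka must be nonnegative")
        if self.f == 0.0 and self.ka > 0:
            raise ValueError("f=0 with ka>0 leaves the reverse rate undefined")
        if self.lineshape not in _LINESHAPES:
            raise ValueError(f"lineshape must be one of {_LINESHAPES}")


@dataclass
class RateBundle:
    """Relaxation/exchange rates in s^-1 plus equilibrium pool sizes."""

    r1a: float
    r1b: float
    r2a: float
    r2b: float
    ka: float
    kb: float
    m0a: float
    m0b: float


def derived_rates(model) -> RateBundle:
    """Convert a tissue model into rates (s^-1) and pool magnetizations.

    The reverse exchange rate is fixed by detailed balance,
    ``kb = ka*(1-f)/f``, so that ka*M0a = kb*M0b at thermal equilibrium.
    """
    if isinstance(model, SinglePoolModel):
        return RateBundle(
            r1a=1e3 / model.t1,
            r1b=0.0,
            r2a=1e3 / model.t2,
            r2b=0.0,
            ka=0.0,
            kb=0.0,
            m0a=model.m0,
            m0b=0.0,
        )
    if isinstance(model, TwoPoolBMModel):
        r2b = 1e3 / model.t2b
    elif isinstance(model, TwoPoolMTModel):
        r2b = 0.0  # bound pool has no transverse states
    else:
        raise TypeError(f"unsupported model type: {type(model).__name__}")
    f = model.f
    kb = model.ka * (1.0 - f) / f if f > 0 else 0.0
    return RateBundle(
        r1a=1e3 / model.t1a,
        r1b=1e3 / model.t1b,
        r2a=1e3 / model.t2a,
        r2b=r2b,
        ka=model.ka,
        kb=kb,
        m0a=(1.0 - f) * model.m0,
        m0b=f * model.m0,
    )


def t1_observed(model) -> float:
    """Apparent mono-exponential T1 (ms) of a coupled two-pool system.

    Longitudinal evolution of the coupled system is bi-exponential with
    rates given by the eigenvalues of the relaxation-exchange matrix; an
    inversion-recovery experiment predominantly observes the slower rate
    (the smaller-magnitude eigenvalue). This evaluates that rate in closed
    form:

        R1obs = (s - sqrt(s^2 - 4*(R1a*R1b + R1a*kb + R1b*ka))) / 2,
        s = R1a + ka + R1b + kb

    and returns 1/R1obs in ms.
    """
    if isinstance(model, SinglePoolModel):
        return model.t1
    r = derived_rates(model)
    s = r.r1a + r.ka + r.r1b + r.kb
    disc = s * s - 4.0 * (r.r1a * r.r1b + r.r1a * r.kb + r.r1b * r.ka)
    rate = 0.5 * (s - math.sqrt(disc))  # s^-1
    return 1e3 / rate


def residence_time_b(model, convention: str = "f/ka") -> float:
    """Mean residence time (ms) of magnetization in compartment b.

    Two conventions circulate in the exchange literature:

    * ``"f/ka"``    : tau_b = f/ka           (= 1/kb * f/(1-f) ... = M0b/(ka*M0... )
    * ``"f/ka(1-f)"``: tau_b = f/(ka*(1-f))  (= 1/kb exactly)

    For the myelin parameters (f=0.2, ka=2 s^-1) these give 100 ms and
    125 ms respectively. The default reports f/ka; prefer quoting ``ka``
    itself to avoid ambiguity.
    """
    if model.ka == 0:
        return math.inf
    if convention == "f/ka":
        return 1e3 * model.f / model.ka
    if convention == "f/ka(1-f)":
        return 1e3 * model.f / (model.ka * (1.0 - model.f))
    raise ValueError("convention must be 'f/ka' or 'f/ka(1-f)'")


@dataclass
class PulseTrain:
    """A pulse sequence as seen by the simulator.

    Per-pulse arrays (all the same length): flip angles and phases (rad),
    pulse energies (ms*uT^2, used only for bound-pool saturation in MT
    mode), pulse durations (ms, metadata), and irradiation frequency
    offsets (Hz; 0 = on-resonance). ``tr`` is the uniform inter-pulse
    interval (ms) and ``dephasing_cycles`` the gradient dephasing per
    interval in units of 2*pi (0 balanced, 1 standard unbalanced).
    """

    flips: np.ndarray
    phases: np.ndarray
    tr: float
    energies: Optional[np.ndarray] = None
    durations: Optional[np.ndarray] = None
    offsets: Optional[np.ndarray] = None
    dephasing_cycles: int = 1
    spoil_increment: Optional[float] = None

    def __post_init__(self) -> None:
        self.flips = np.asarray(self.flips, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        n = len(self.flips)
        if len(self.phases) != n:
            raise ValueError("flips and phases must have equal length")
        if self.energies is None:
            self.energies = np.zeros(n)
        else:
            self.energies = np.asarray(self.energies, dtype=float)
        if self.durations is None:
            self.durations = np.zeros(n)
        else:
            self.durations = np.asarray(self.durations, dtype=float)
        if self.offsets is None:
            self.offsets = np.zeros(n)
        else:
            self.offsets = np.asarray(self.offsets, dtype=float)
        for name in ("energies", "durations", "offsets"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must match flips in length")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if np.any(self.energies < 0):
            raise ValueError("pulse energies must be nonnegative")
        if self.dephasing_cycles < 0:
            raise ValueError("dephasing_cycles must be nonnegative")

    def __len__(self) -> int:
        return len(self.flips)


_MODES = ("single", "bm", "mt")


def mode_for_model(model) -> str:
    if isinstance(model, SinglePoolModel):
        return "single"
    if isinstance(model, TwoPoolBMModel):
        return "bm"
    if isinstance(model, TwoPoolMTModel):
        return "mt"
    raise TypeError(f"unsupported model type: {type(model).__name__}")


@dataclass
class EPGXState:
    """Ordered configuration states for one or two compartments.

    Arrays hold orders n = 0..order_max: ``fplus_*[n]`` stores F~n,
    ``fminus_*[n]`` stores F~(-n)* (so ``fminus_*[0] == conj(fplus_*[0])``
    throughout any simulation), and ``z_*[n]`` stores Z~n. In ``mt`` mode
    the bound pool has longitudinal states only and the transverse b arrays
    are absent (None).
    """

    order_max: int
    mode: str
    fplus_a: np.ndarray
    fminus_a: np.ndarray
    z_a: np.ndarray
    fplus_b: Optional[np.ndarray] = None
    fminus_b: Optional[np.ndarray] = None
    z_b: Optional[np.ndarray] = None

    @classmethod
    def equilibrium(cls, model, order_max: int, mode: Optional[str] = None) -> "EPGXState":
        """Thermal-equilibrium state: Z~0a = (1-f)*m0, Z~0b = f*m0."""
        mode = mode or mode_for_model(model)
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        n = order_max + 1
        zeros = lambda: np.zeros(n, dtype=complex)  # noqa: E731
        st = cls(order_max, mode, zeros(), zeros(), zeros())
        rates = derived_rates(model)
        st.z_a[0] = rates.m0a
        if mode == "bm":
            st.fplus_b = zeros()
            st.fminus_b = zeros()
            st.z_b = zeros()
            st.z_b[0] = rates.m0b
        elif mode == "mt":
            st.z_b = zeros()
            st.z_b[0] = rates.m0b
        return st

    def copy(self) -> "EPGXState":
        return EPGXState(
            self.order_max,
            self.mode,
            self.fplus_a.copy(),
            self.fminus_a.copy(),
            self.z_a.copy(),
            None if self.fplus_b is None else self.fplus_b.copy(),
            None if self.fminus_b is None else self.fminus_b.copy(),
            None if self.z_b is None else self.z_b.copy(),
        )


@dataclass
class SignalSeries:
    """Demodulated F~0a samples (complex) at acquisition times (ms)."""

    times: np.ndarray
    signal: np.ndarray
    z0_a: Optional[np.ndarray] = None
    z0_b: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=complex)
        if len(self.times) != len(self.signal):
            raise ValueError("times and signal must have equal length")

    def magnitude(self) -> np.ndarray:
        return np.abs(self.signal)

    def __len__(self) -> int:
        return len(self.signal)
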