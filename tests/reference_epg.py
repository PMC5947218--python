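"""Independent textbook single-pool EPG implementation used as a test
oracle.

Deliberately written as a naive dictionary-of-orders implementation with
explicit per-state arithmetic (no shared code with the package engine):
states are {n: (Fplus_n, Fminus_n, Z_n)} where Fminus_n stores F(-n)*.
"""

from __future__ import annotations

import cmath
import math


def rf_matrix(alpha: float, phi: float):
    ca2 = math.cos(alpha / 2) ** 2
    sa2 = math.sin(alpha / 2) ** 2
    sa = math.sin(alpha)
    ca = math.cos(alpha)
    eip = cmath.exp(1j * phi)
    return [
        [ca2, eip * eip * sa2, -1j * eip * sa],
        [eip.conjugate() ** 2 * sa2, ca2, 1j * eip.conjugate() * sa],
        [-0.5j * eip.conjugate() * sa, 0.5j * eip * sa, ca],
    ]


class ReferenceEPG:
    def __init__(self, t1_ms: float, t2_ms: float, m0: float = 1.0):
        self.t1 = t1_ms
        self.t2 = t2_ms
        self.m0 = m0
        self.states = {0: [0j, 0j, complex(m0)]}

    def rf(self, alpha: float, phi: float):
        t = rf_matrix(alpha, phi)
        for n, (fp, fm, z) in list(self.states.items()):
            self.states[n] = [
                t[0][0] * fp + t[0][1] * fm + t[0][2] * z,
                t[1][0] * fp + t[1][1] * fm + t[1][2] * z,
                t[2][0] * fp + t[2][1] * fm + t[2][2] * z,
            ]

    def relax(self, dt_ms: float):
        e1 = math.exp(-dt_ms / self.t1)
        e2 = math.exp(-dt_ms / self.t2)
        for n, s in self.states.items():
            s[0] *= e2
            s[1] *= e2
            s[2] *= e1
        self.states[0][2] += self.m0 * (1 - e1)

    def shift(self):
        new = {}
        orders = sorted(self.states)
        for n in orders:
            fp, fm, z = self.states[n]
            new.setdefault(n + 1, [0j, 0j, 0j])[0] = fp
            if n - 1 >= 0:
                new.setdefault(n - 1, [0j, 0j, 0j])[1] = fm
            new.setdefault(n, [0j, 0j, 0j])[2] = z
        # fresh F0 comes from the conjugate of the former F(-1)*
        if 0 not in new:
            new[0] = [0j, 0j, 0j]
        new[0][0] = new[0][1].conjugate()
        self.states = new

    def f0(self) -> complex:
        return self.states.get(0, [0j, 0j, 0j])[0]

    def run_spgr(self, tr_ms, alpha, phi0, n_pulses):
        """Signal immediately after each pulse, demodulated by pulse phase."""
        out = []
        for j in range(n_pulses):
            phi = phi0 * j * (j + 1) / 2
            self.rf(alpha, phi)
            out.append(self.f0() * cmath.exp(-1j * phi))
            self.relax(tr_ms)
            self.shift()
        return out

    def run_cpmg(self, n_echoes, esp):
        """|F0| at each echo time for ideal CPMG (90x / 180y)."""
        self.rf(math.pi / 2, 0.0)
        out = []
        for _ in range(n_echoes):
            self.relax(esp / 2)
            self.shift()
            self.rf(math.pi, math.pi / 2)
            self.relax(esp / 2)
            self.shift()
            out.append(abs(self.f0()))
        return out
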