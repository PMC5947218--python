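# epgx — extended phase graphs for two-compartment spin systems

Quantitative MRI increasingly relies on simulating the *transient* signal
of long pulse trains (turbo spin echo, MR fingerprinting, variable-flip
relaxometry). The extended phase graph (EPG) algorithm does this
efficiently for a single tissue compartment, but real tissues — white
matter above all — behave as coupled two-pool systems: free water
exchanging with a second water pool (Bloch–McConnell) or with a semisolid
"bound" proton pool (magnetization transfer, MT). `epgx` implements the
two-compartment extension of the phase-graph algorithm for both cases, for
people who need sequence-level predictions or fitting models that account
for exchange and MT.

## The model

Intravoxel magnetization under a repeated RF/gradient block is expanded in
configuration states F̃ₙ (transverse) and Z̃ₙ (longitudinal); the receiver
sees F̃₀. For two pools *a* (free, fraction 1−f) and *b* (fraction f), each
state becomes a pair that evolves between pulses under combined
relaxation–exchange generators

    ΛT = [[−R2a−ka, kb], [ka, −R2b−kb ∓ 2πi δb]]     (transverse pairs)
    ΛL = [[−R1a−ka, kb], [ka, −R1b−kb]]              (longitudinal pairs)

with kb = ka(1−f)/f fixed by detailed balance and δb the pool-b frequency
offset. The per-interval propagators exp(ΛT Δt), exp(ΛL Δt) are dense
matrix exponentials (relaxation and exchange do not commute); longitudinal
recovery feeds only the order-0 states. RF pulses mix {F̃ₙ, F̃₋ₙ*, Z̃ₙ}
identically at every order; the gradient shift operator increments
transverse orders and is pure bookkeeping. In the MT variant the bound
pool keeps only Z̃ₙᵇ states and an RF pulse of energy E = ∫B1²dt saturates
them by exp(−π γ² E G(Δ)), where G is the absorption lineshape
(super-Lorentzian by default, spline-bridged across ±1 kHz around its
on-resonance singularity).

On top of the engine sit: direct steady-state solvers for ideally spoiled
gradient echo and balanced SSFP; an isochromat-ensemble reference path
(exactly equal to the phase-graph result once the ensemble resolves all
orders); CPMG simulation with nonnegative-least-squares T2 spectroscopy;
a multislice turbo-spin-echo engine where other slices act as off-resonant
bound-pool saturation; and constrained fitting of the MT model to
transient variable-flip data.

## Worked example

Exchange biases the NNLS myelin-water fraction. Simulate a 50-echo CPMG
train (5 ms spacing, 10% transmit overdrive) for a myelin-water exchange
tissue with true f = 0.2 and ka = 2 s⁻¹, then analyse it the standard way:

```python
import numpy as np
from epgx import get_preset, simulate_cpmg
from epgx.relaxometry import nnls_t2_spectrum

model = get_preset("myelin_bm")           # T1 1000/500, T2 100/20 ms, ka=2, f=0.2
echoes = simulate_cpmg(model, n_echoes=50, esp=5.0, b1_scale=1.1)
spec = nnls_t2_spectrum(echoes.total, echoes.times)
print(f"f_hat = {spec.f_hat:.3f}, T2b_hat = {spec.t2b_hat:.1f} ms")
```

This prints

```
f_hat = 0.133, T2b_hat = 20.0 ms
```

i.e. the short-T2 peak sits at the right T2 (20 ms) but its area
underestimates the true pool fraction by a third — exchange drains the
apparent myelin-water fraction even though the fit looks clean. Setting
`ka=0` in the model recovers `f_hat = 0.200`.

The same machinery runs from the shell:

```bash
epgx cpmg --model myelin_bm --b1 1.1 --out echoes.csv
epgx simulate --model wm_mt --sequence spgr --tr 5 --flip 10 --phi0 117 \
    --npulses 1000 --out signal.csv
epgx multislice --model wm_mt --refocus 180 --nslices 15 --out tse.csv
epgx figure fig4 --outdir figures/
```

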