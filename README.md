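# poreblock

Kinetics of pore-blocker release from K+ channels, computed from the ion
occupancy of the selectivity filter.

Quaternary-ammonium blockers (TPrA, TBA) bind in the aqueous cavity of K+
channels directly below the selectivity filter. Release of the positively
charged blocker is accelerated by electrostatic repulsion from a K+ ion in
S4, the filter binding site adjacent to the cavity. `poreblock` implements
the quantitative chain from single-channel electrophysiology to that
mechanism, for experimentalists and modellers working on channel block:

1. **`poreblock.ionflux`** — a 5-state cyclic Markov model of K+ hopping
   through the filter ("soft knock-on") with Eyring voltage factors and
   activity-coupled entry steps. Solving the master equation gives the
   voltage-dependent site occupancy **P(S4, V)** for the open channel and for
   the blocked channel, where the bound blocker switches off the
   cavity-exchange transitions (k12 = k21 = k32 = 0).
2. **`poreblock.blockrelease`** — the two-parameter release model

       koff(V) = a·(1 − P(S4,V)) + c·P(S4,V) = a + b·P(S4,V)

   with fitting, confidence bands, prediction under asymmetric ionic
   conditions, the barrier change ΔΔG = −ln(1 + b/a)·kT, and the
   thermodynamic-cycle / z·F·V energetics bookkeeping.
3. **`poreblock.simchan`** — a synthetic-recording generator: exact
   stochastic simulation of O/F/M/S/B gating, rendered through a 1-kHz
   4-pole Bessel filter at 5-kHz sampling with Gaussian baseline noise.
4. **`poreblock.betafit`** — extended-beta-style amplitude-histogram
   analysis: blocking rates faster than the filter bandwidth
   (kOB, kBO ≈ 10⁴–7·10⁵ s⁻¹) are recovered from the excess noise they
   leave in the histogram, by simplex fitting of simulation-matched
   histograms with common random numbers.

A CLI (`poreblock simulate / histogram / fit-gating / extract-koff /
occupancy / fit-release / predict / energetics / validate / run`) exposes
each stage and an end-to-end pipeline over plain-text formats (CSV + JSON
sidecars, YAML configs).

## Worked example

```python
import numpy as np
from poreblock.ionflux import (
    kcv_like_scheme, apply_block, occupancy_vs_voltage, symmetric_kcl_conditions)
from poreblock.blockrelease import BlockerReleaseModel, delta_delta_G

scheme = kcv_like_scheme()                    # documented synthetic parameter set
cond = symmetric_kcl_conditions(kcl_mM=100)   # K+ activity 77 mM, both sides
blocked = apply_block(scheme)                 # blocker: k12 = k21 = k32 = 0
grid = np.array([-160.0, -80.0, 0.0, 80.0, 160.0])
prof = occupancy_vs_voltage(blocked, cond, grid)
for v, p2, ps4 in zip(grid, prof.state("2"), prof.site("S4")):
    print(f"{v:+6.0f} mV   P2 = {p2:.2e}   P(S4) = {ps4:.3f}")

model = BlockerReleaseModel(a=31_400.0, b=378_600.0)
print(f"koff at P(S4)=0.5 : {model.koff(0.5):,.0f} /s")
ddg_kt, ddg_kj = delta_delta_G(model)
print(f"ddG = {ddg_kt:.2f} kT = {ddg_kj:.2f} kJ/mol")
```

prints

```
  -160 mV   P2 = 0.00e+00   P(S4) = 0.339
   -80 mV   P2 = 0.00e+00   P(S4) = 0.545
    +0 mV   P2 = 1.89e-16   P(S4) = 0.757
   +80 mV   P2 = 7.65e-17   P(S4) = 0.902
  +160 mV   P2 = 8.27e-17   P(S4) = 0.969
koff at P(S4)=0.5 : 220,700 /s
ddG = -2.57 kT = -6.37 kJ/mol
```

Reading this: in the blocked channel, state 2 (cavity ion present, filter
inner sites empty) is never populated — the blocker has taken the cavity
site — and the S4 occupancy rises monotonically with voltage as K+ is pushed
outward through the filter. With release rates a = 31,400 s⁻¹ (S4 empty) and
c = a + b = 410,000 s⁻¹ (S4 occupied), a half-occupied S4 releases the
blocker at 220,700 s⁻¹, and the ion lowers the release barrier by 2.6 kT
(−6.4 kJ/mol).

The full simulation → histogram-fit → koff(V) → release-fit loop runs from a
config file:

```
poreblock run --config examples/pipeline.yaml --out scratch/demo
```

which generates noisy filtered recordings with known ground truth
(kBO(V) = a + b·P(S4,V)), re-extracts the hidden rates from amplitude
histograms, and refits (a, b) — `summary.json` reports the recovered
parameters next to the generating truth.

## Layout

```
src/poreblock/
  ionflux.py       filter hopping model, steady states, site occupancies
  blockrelease.py  release model, fitting, prediction, energetics
  simchan.py       gating simulation + acquisition-chain rendering
  betafit.py       amplitude histograms, simplex fitting, koff assembly
  io.py            plain-text formats and validation
  pipeline.py      end-to-end runner with manifest
  cli.py           command-line interface
docs/methods.md    model assumptions, defaults, numerical choices
```
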