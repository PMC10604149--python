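# cuttleflow

Liquid–gas interface dynamics in cuttlebone-inspired dual channels.

Cuttlefish regulate buoyancy by pumping water in and out of the cuttlebone,
a chambered shell supported by corrugated ("wavy") vertical pillars. Near
the ventral membrane the pillars are straight and parallel; elsewhere they
are wavy and maze-like. `cuttleflow` is a toolkit for studying how that
geometry shapes the motion of an air–water interface in paired millimetric
channels: when two nominally identical channels drain towards a common
head, do their fronts move together or separate — and how fast?

The package is aimed at researchers in biomimetic fluid dynamics who work
with paired interface-displacement time series and top-view video of
channel filling, or who want a seeded stochastic simulator of the
experiment.

## The model and the statistic

**Capillary rise.** A wetting column in a gap of width `w` obeys the
momentum balance `ρ d(z ż)/dt = 2σcosθ/w − (μ z/w²) ż`: linear growth
`z = U₀t` while inertia balances surface tension, then the Washburn law
`z = √(4σcosθ·w·t/μ)` once viscosity takes over, with crossover time
`t_c = ρw²/μ`. The log–log growth exponent of a measured trace therefore
falls between 0.5 and 1.

**Pressure budget.** Lowering the bath by `ΔH` drives the interface with
`ρgΔH` (tens of Pa) plus the capillary pull `2γ/R`; the viscous drop
`μLU/h²` and contact-line drop `~μU/h` are orders of magnitude smaller, so
they cannot differentiate the two fronts — separation must come from
geometry and irregularity.

**Front separation.** For fronts `S₁(t), S₂(t)` the separation
`D(t) = |S₁ − S₂|` grows roughly exponentially, `D ~ exp(λt)`, because a
Darcy-law front speeds up as its remaining liquid column shortens: a lead
is self-amplifying. The local exponent λ is the 7-sample, degree-4
sliding-window slope of `log D(t)`; each experiment is summarised by the
75th percentile of its local exponents (λ₇₅), and λ₇₅ is compared across
hydrostatic heads and wall amplitudes.

**Simulator.** Each front advances by
`dS/dt = [h(S)²/12μ]·(ρgΔH + 2σcosθ/h(S))/(L − S + L_ref)·ξ(t)` with
sinusoidal wall profile `h(x)` and multiplicative lognormal roughness noise
ξ, reproducing the observed phenomenology: wavier channels fill faster and
separate faster, stronger heads separate faster, straight channels separate
slowest. Synthetic traces can be rendered as binary image stacks and
re-tracked, closing the video → trace → λ₇₅ loop.

## Worked example

```python
import numpy as np
from cuttleflow import (WATER, SimulationConfig, analyze_trace,
                        dual_channel_geometry, pressure_budget,
                        simulate_dual_channel)

# pressure budget at the strongest head, mid-range speed
b = pressure_budget(WATER, height_difference=1.33e-2, radius_of_curvature=0.375e-3,
                    filled_length=3.9e-2, speed=1e-3, gap=0.75e-3)
print(f"hydrostatic {b.hydrostatic:.1f} Pa, viscous {b.viscous:.3f} Pa, "
      f"contact line {b.contact_line:.2e} Pa")

# one stochastic run in the 0.188 mm amplitude preset and its summary
pair = dual_channel_geometry(0.188e-3)
trace = simulate_dual_channel(*pair, WATER, SimulationConfig(head_height=1.33e-2, seed=3))
print(analyze_trace(trace, floor=25e-6))
```

prints

```
hydrostatic 130.1 Pa, viscous 0.069 Pa, contact line 1.33e-03 Pa
{'lambda_q75': 340.29274939586526, 'n_exponents': 122, 'crossings': 13}
```

The driving pressure exceeds the dynamic drops by three to five orders of
magnitude. The simulated run yields 122 local exponents whose 75th
percentile, ~340 s⁻¹ on the simulation's timescale, is the run's separation
summary; this particular noise realisation also produced 13 front
crossings before the fronts separated for good.

The same pipeline is scriptable from the shell:

```
cuttleflow simulate --head 1.33cm --amplitude 0.188mm --seed 3 --out run.csv
cuttleflow analyze --in run.csv --floor 25um
cuttleflow ensemble --reps 20 --seed 0 --out grid.tsv
cuttleflow report --in grid.tsv --out-dir report/
```

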