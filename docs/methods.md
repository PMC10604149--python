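# Methods

`cuttleflow` models the motion of air–water interfaces in paired millimetric
channels with corrugated ("wavy") walls — an idealisation of the parallel
pillar structure in the siphuncular zone of cuttlebone — and quantifies how
fast the two fronts separate. This note records the models, the numerical
choices, the synthetic-data design, and the limits of what the tests show.

## Pressure scales and dimensionless numbers

The working fluid is water (`rho = 997 kg/m^3`, `mu = 1e-3 Pa s`,
`sigma = 0.072 N/m`, contact angle `theta = 0`, all config-overridable).
Lowering the liquid bath a height `dH` below the channel sets the gauge
pressure at the channel head to `-(rho g dH + 2 sigma / R)`; atmosphere is
the zero of gauge pressure throughout, so no nominal 101 325 Pa appears
anywhere. Four pressure components are computed (`core_physics`):

| component      | expression        | scale at nominal conditions |
|----------------|-------------------|-----------------------------|
| hydrostatic    | `rho g dH`        | 56–130 Pa (`dH` 0.57–1.33 cm) |
| capillary      | `2 sigma / R`     | ~384 Pa at `R = h/2 = 0.375 mm` |
| viscous        | `mu L U / h^2`    | 1e-2–1e-1 Pa |
| contact line   | `~ mu U / h`      | 1e-3–1e-2 Pa |

The contact-line proportionality constant is order one and not fixed by the
scaling argument; it is exposed as a coefficient defaulting to 1. The
hierarchy hydrostatic >> viscous >> contact-line (ratio < 1e-2 across the
whole operating window `U` 0.2–2 mm/s, `h = 0.75 mm`, `L <= 3.9 cm`) is
asserted as a property test: the dynamic drops cannot differentiate the two
fronts, so front separation must come from geometry and irregularity, not
from the pressure budget.

The Reynolds number `rho U L / mu` is ~3e-2 for cuttlebone conditions
(300 um/s through ~100 um channels). For the artificial channels the formula
gives 0.15–1.5 over `U` = 0.2–2 mm/s at `L = 0.75 mm`; only the low-speed
end matches the order-1e-1 estimate sometimes quoted for such channels. Both
readings are left visible: the function computes the formula exactly and the
acceptance checks pin the `U = 0.2 mm/s` value, the one on which both
readings agree.

## Capillary rise

A column of height `z(t)` rising in a gap of width `w` obeys

    rho d(z zdot)/dt = 2 sigma cos(theta) / w - (mu z / w^2) zdot.

The viscous coefficient is used exactly as written above (bare `mu z / w^2`);
a `poiseuille_factor` (default 1) lets users insert the plane-Poiseuille 12.
With the momentum variable `y = z zdot` the equation is linear in `y` and
the `z = 0` onset is regular: the implementation integrates `(y, ∫y dt)`
with LSODA at `atol = 1e-12`, `rtol = 1e-10` and recovers
`z = sqrt(z0^2 + 2 ∫y dt)`. The closed form of the linear `y` equation is
deliberately kept out of the implementation and used only as the independent
oracle in the tests, which require agreement to better than 1e-7 relative.

Regimes: early (`t << t_c = rho w^2 / mu`) the inertia–capillarity balance
gives `z = U0 t`, `U0 = sqrt(2 sigma cos(theta) / (rho w))`; late
(`t >> t_c`) the viscous balance gives the Washburn law
`z = sqrt(4 sigma cos(theta) w t / mu)`. The log–log growth exponent
therefore lies in [0.5, 1.0], which `fit_rise_exponent` checks over any
fractional time window. `t_c` is the only timescale the two balances share
and is used to place the asymptotic test windows (`t_c/100` and `200 t_c`).

## Separation statistic

For a dual trace `S1(t), S2(t)` on a uniform grid the separation is
`D = |S1 - S2|`; the absolute value removes any bias towards one channel.
Samples with `D` below a floor (one spatial-resolution unit, 25 um for
rendered data) are masked: `log D` is undefined at crossings and
sub-resolution separations are noise. The local Lyapunov exponent is the
sliding-window slope of `log D`: a centred least-squares polynomial of
degree 4 over 7 samples (Savitzky–Golay style), differentiated at the window
centre, with both axes centred per window for conditioning. Windows touching
a masked sample are skipped entirely — no truncated edge windows — so a
fully valid series of `N` samples yields exactly `N - 6` exponents, and
`N` in 156–306 lands in the 150–300 exponents a single experiment produces.
Per-experiment summaries take the 0.75 quantile (linear interpolation
between order statistics, stated because conventions differ); a
`positive_only` option restricts to positive exponents for the alternative
reading of "upper values". Trends of the per-experiment summary against
head or amplitude are ordinary least-squares slopes; raw exponents are never
pooled across experiments.

## Synthetic dual-channel simulator

The simulator stands in for the bench experiments. Each front advances by a
Darcy-law speed

    dS/dt = [h(S)^2 / (12 mu)] (rho g dH + 2 sigma cos(theta)/h(S))
            / (L - S + L_ref) * xi(t),

with `h(x) = h0 + A sin(2 pi x / wavelength + phase)` inside the three
channel segments and `h0` in the inter-segment gaps. The parallel-plate
permeability `h^2/12` is the natural mobility prefactor (any constant
cancels in trend comparisons). The capillary term pulls harder where the
walls constrict; setting `sigma = 0` disables it. `L_ref = 14 mm`, the
hydraulic length of the rectangular head, keeps the speed finite at arrival.
The shrinking liquid column `L - S + L_ref` is the lead-amplifying feedback:
with noise off and an initial offset, `D(t)` grows monotonically, which is
asserted directly as the positive-exponent mechanism.

Defaults and why:

* geometry: length 39 mm, width 0.75 mm, three segments with 1 mm gaps;
  amplitude presets 0, 0.0625, 0.188, 0.25 mm; heads 0.57, 1.14, 1.33 cm —
  the fabricated conditions.
* corrugation wavelength 2.6 mm (15 periods over the channel). The period
  must be resolvable by the 7-sample differentiation window at the sampling
  rate that keeps the exponent count in the 150–300 band: at 2.6 mm a front
  crosses one period in ~20 output samples at every head, whereas half that
  wavelength leaves ~10 samples/period, and the window's high-frequency
  attenuation then grows with front speed and distorts cross-condition
  comparisons. Config-overridable; the physical wavelength is not known.
* wall phase: both channels are cast side by side from one mold, so the
  corrugations are nominally in register (equal phases). Separation is then
  seeded by noise and amplified by the wall-slope velocity gradient
  (local rate ~ `2 v A k / h0`, alternating sign along the channel) and by
  the column feedback — the two mechanisms whose rates scale with amplitude
  and with speed, producing the observed trends. A `phase_offset` parameter
  dials in deliberately misregistered walls.
* roughness: `xi` is lognormal with median 1 and log-scale 0.3, redrawn once
  per output sample per channel and held across that sample's internal
  substeps. It stands in for surface roughness and small shape errors;
  multiplicative noise cannot make a front retreat, which additive noise
  could. Both channels' factors are always drawn, so the random stream is
  aligned across runs that share a seed.
* time stepping: output samples every 0.4 ms (a traverse then yields
  ~215–290 samples, matching the experimental exponent counts); each output
  step is subdivided so no front advances more than 1/20 of a corrugation
  period per substep, and advanced by an explicit midpoint rule. Against the
  separable closed form for a straight channel the trajectory is accurate to
  ~2e-6 relative.
* runs end when both fronts arrive (clamped at the outlet), or at the 0.5 s
  duration cap.

Ensembles sweep (head, amplitude, replicate). Per-run seeds derive from a
stable hash of the base seed and the replicate index, so the same replicate
shares one noise realisation across every condition — a common-random-numbers
blocked design under which condition comparisons are paired; means are
unbiased and cross-condition differences carry no independent-draw noise.
`paired=False` hashes the condition into the seed for fully independent
runs. Failed cells are recorded in an `error` column, never fatal.

The traverse times are not calibrated to the experimental 21–140 s — those
depend on unmeasured hydraulic resistances — so simulated exponents are in
1/s on the simulation's own timescale and only their ordering across
conditions is meaningful. With 20 replicates the mean 75th-percentile
exponent increases strictly with head at fixed amplitude and with amplitude
at fixed head; the hardest comparison (1.14 vs 1.33 cm, a ~6% driving
contrast against the constant capillary term) passes for the large majority
of base seeds but remains a sign test on a stochastic quantity.

## Rendering and tracking

`render_frames` draws each time sample as a binary top view: channel
interiors light when dry, dark when wet (`x < S`), walls dark, two channels
stacked with margins. `track_fronts` row-averages each channel's region of
interest, normalises to the frame's intensity range (guarding against
illumination drift; uniform frames fall back to the stack range), takes the
last column whose wetness clears the 0.5 threshold, refines to sub-pixel by
linear interpolation between the straddling columns, and median-filters over
time (width 3). A dry reading after the front has advanced is treated as a
dropout frame: the previous position is carried forward and the frame
flagged; more than 20% flagged frames is a tracking failure. The default
regions of interest are the central strip that stays inside the walls at
every corrugation phase (half-width 0.45 `h_min`), which makes the wetness
profile near-binary for every amplitude preset. Round trip
`track(render(trace))` recovers every front position within 1 pixel
(measured ~0.5 px worst case), the resolution claim under which the
separation floor of one pixel is justified.

## What the synthetic data do not show

The simulator is one-dimensional: fronts are scalar positions, so fingering
morphology, bubble/droplet breakup and meniscus shape are out of scope, as
is any porous-network coupling between more than two channels. Roughness is
white in time rather than frozen into the walls, and the wall corrugation
period and registration are free parameters, not measurements. Passing
trend tests therefore show that the Darcy feedback plus wall-modulation
mechanism reproduces the direction of the experimental trends under the
stated noise model — not that the simulator predicts experimental exponent
magnitudes, which are hardware-bound.

## Problem sizes

Tests and the acceptance script use the condition grid at 20 replicates per
cell (140 runs, ~2000 internal steps each), 150–600-point integration grids
for the rise equation, and 20-frame image stacks at 25 um/px for the round
trip. These sizes keep every property measurable at desk scale while
matching the per-experiment sample counts of the study design.
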