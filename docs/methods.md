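# Model and methods

`purkinje_ca` simulates a single mouse cardiac Purkinje cell as a cylindrical
reaction–diffusion system coupled to a membrane ionic model, with stochastic
ryanodine-receptor (RyR) gating and an optional store-overload spontaneous
Ca²⁺-release ("CPVT") pathway. This note records the model structure, the
parameter choices that matter, the numerical scheme, and what the package's
tests do and do not demonstrate.

## Geometry and state

The cell is a cylinder of length 129 µm and diameter 8 µm (default), cut into
10 axial discs and 81 concentric layers of equal radial thickness. Cytosolic
free [Ca²⁺] lives on this (disc, layer) grid; layer 0 is the sub-SR core,
layer 80 the sub-sarcolemmal (sub-SL) shell. Purkinje cells lack T-tubules:
all sarcolemmal Ca²⁺ enters at the outermost layer and must diffuse inward,
which is what makes the Ca²⁺ transient wave-like (radial wavelets plus
longitudinal cell-wide waves) rather than spatially synchronous.

Each disc carries a two-compartment sarcoplasmic reticulum: a junctional SR
(JSR, release pool, volume fraction 2×10⁻⁴ of the disc) and a network SR
(NSR, uptake pool, 3.5×10⁻²). The JSR is deliberately small — a conduit
whose depletion terminates Ca²⁺-induced Ca²⁺ release (CICR) crisply — while
the NSR is the bulk store. Adjacent discs' NSR compartments exchange Ca²⁺
axially (conductance 1 µm³/ms), reflecting the continuity of the SR network;
this matters only for spontaneous release events, which can drain more than
one disc's store.

Membrane state (voltage, eleven Hodgkin–Huxley gates, bulk Na⁺ and K⁺) is a
single compartment; Ca²⁺-sensing currents read the sub-SL layer mean.

## Transport

Diffusion is finite-volume and flux-form (hence mass-conserving to solver
precision) with no-flux boundaries at the sarcolemma and the cell ends.
Radial diffusion is integrated implicitly (backward Euler; the tridiagonal
matrix depends only on the time step, so its LU factors are precomputed),
because at 81 layers the explicit radial stability bound would be ~1 µs.
Longitudinal diffusion between discs is explicit; its stability bound at the
12.9 µm disc spacing is far above any admissible step and is checked.

The longitudinal coefficient is 70% of the radial one (slower cell-wide wave
propagation along the fibre axis). The radial coefficient defaults to
0.8 µm²/ms. These are *effective* coefficients: cytosolic buffering is not
modelled as explicit buffer species but folded into the effective diffusion
coefficients and flux magnitudes, so the dynamic field is free Ca²⁺. This
keeps the radial solve linear and prefactorable; the cost is that
buffer-saturation effects (concentration-dependent effective diffusivity)
are absent.

SERCA pumps from each disc's core region (innermost 9 layers) into that
disc's NSR with Hill kinetics (vmax 40 µM·µm³/ms per disc, K½ 1.35 µM, Hill
coefficient 6). The steep, high-K½ form concentrates uptake at
transient-peak concentrations, which is how the model reconciles a fast
time-to-peak (~24 ms) with a slow decay (~200 ms): clearance is strong above
~1 µM and weak below. It should be read as a lumped clearance curve, not a
literal pump stoichiometry. A small passive NSR→cytosol leak (10⁻⁴ µm³/ms
per disc) balances diastolic uptake. JSR refills from NSR with a 500 ms time
constant — slow on the CICR time scale, so a release event sees an
essentially fixed JSR content.

## RyR gating

Each disc has N = 10 two-state RyR channels. The opening rate is
k_open·(1 + (K_m/Ca_subSR)⁴)⁻¹ with k_open = 1.8 ms⁻¹; closing is k_close =
1.0 ms⁻¹. K_m falls sigmoidally with JSR content from 3.76 µM (empty) to
0.25 µM (overloaded) — a fuller store sensitizes the channel, which is the
store-overload mechanism in miniature. Channel counts are updated by a
per-step Monte-Carlo draw: at most one transition per step, with aggregate
probabilities proportional to N·dt; when those would exceed one the step is
subcycled. The ensemble mean of this scheme converges to the mean-field
open-probability ODE (tested at N = 10, 100, 1000).

N, k_open and k_close are not constrained by any printed source; they were
calibrated jointly so that (a) the quiescent opening rate reproduces the
observed ~9 sparks per 100 µm·s at the diastolic working point, (b) single
openings last ~1 ms (the spark detection floor), and (c) CICR triggers
within a few ms once sub-SR Ca²⁺ reaches ~1 µM. Release flux is
g_rel·P_open·([Ca]_JSR − [Ca]_subSR) with g_rel = 1.0 µm³/ms per disc,
deposited uniformly over the core region.

## Spontaneous release (CPVT)

With the CPVT flag on, each macro step draws Y ~ U[0,1] per disc and fires a
leak on disc i when Y·[Ca]_JSR,i exceeds 594 µM — calibrated so the trigger
probability is exactly 1% per evaluation at 600 µM and, because Y ≤ 1,
exactly zero below 594 µM: leaks are a genuine overload phenomenon. The
firing disc gets an open probability Z from a lognormal law (µ = −1.3,
σ = 0.5, clipped at 1) that then decays as Z·exp(−Δt/125 ms); Monte-Carlo
gating is suspended on that disc until the value falls below 1% of Z. Only
one disc leaks at a time; ties go to the largest product.

While a leak is active the stuck-open cluster drains the *network* SR
directly (conductance g_scr = 8 µm³/ms), not just its tiny JSR. Without this
pathway a sustained 125-ms event is throttled by the slow JSR refill and
releases too little Ca²⁺ to move the membrane; with it, an event plus the
axial NSR coupling releases a few-µM (cell-averaged) Ca²⁺ wave over a few
hundred ms — the substrate for delayed afterdepolarizations (DADs).

The exponential form of the 125-ms sustain and the 1%-of-Z deactivation
floor are assumptions (the sustain's functional form is not specified
anywhere); both are configuration parameters.

## Membrane currents

The current set is Hodgkin–Huxley throughout: fast Na⁺ (I_Na, Luo–Rudy-style
kinetics), late Na⁺ (I_NaL, slow 600-ms inactivation), a small transient
outward K⁺ current, L-type Ca²⁺ (I_CaL, ohmic driving term, voltage- and
Ca²⁺-dependent inactivation sensing sub-SL Ca²⁺), low-threshold T-type Ca²⁺
(I_CaT, activation midpoint −53 mV), inward rectifier (I_K1, steep
rectification engaging below ~−68 mV), a rapidly activating delayed
rectifier K⁺ current (labelled I_Ks; it deactivates below −45 mV and carries
most of phase-1/2 repolarization, as the dominant non-inactivating K⁺
current in mouse does), Na⁺/K⁺ pump, Na⁺–Ca²⁺ exchanger (NCX, with an
allosteric cytosolic-Ca²⁺ activation factor, K½ 0.5 µM) and small Na⁺/Ca²⁺
background leaks. Bulk Na⁺ and K⁺ are integrated (slow drift only).

Conductances are free parameters calibrated against the reference working
point of the control model paced at 1 Hz: dV/dt_max ≈ 223 mV/ms, APD50 ≈
9.3 ms, APD70 ≈ 19.4 ms, APD90 ≈ 67.2 ms, average-Ca²⁺ transient amplitude
≈ 0.92 µM, time-to-peak ≈ 24 ms, decay time ≈ 208 ms, peak I_CaL ≈ −7 pA/pF.
The AP shape is built from: a fast I_Na upstroke; rapid partial
repolarization by the fast delayed rectifier; a low-voltage plateau between
−40 and −60 mV carried by the I_CaT window current (the signature Purkinje
feature); and a final collapse once I_CaT inactivates and I_K1 engages. The
NCX tail current during the Ca²⁺ transient co-determines APD90, which is
why the AP and Ca²⁺ calibrations are not separable.

Charge–mass consistency is enforced by construction: the summed
Ca²⁺-carrying current (I_CaL + I_CaT + I_Cab at 2e⁻/ion, NCX at 1 net
e⁻/ion) is converted to a molar flux and deposited in the sub-SL layer each
step.

β-adrenergic stimulation (isoproterenol) is a static modifier set:
I_CaT ×2.15, I_CaL ×2.0, I_NaK ×1.35, I_Ks ×1.8, SERCA ×1.2, I_K1 ×0.8.
Channel blockade multiplies a channel by (1 − fraction) and composes with
the isoproterenol stack.

## Numerics

Operator splitting per step: membrane currents and gates (Rush–Larsen for
gates, forward Euler for V, Na⁺, K⁺) → sarcolemmal Ca²⁺ source → per-disc
release/uptake/leak/refill → leak-trigger evaluation → diffusion. Two-level
fixed stepping: 0.005 ms around stimuli and wherever |dV/dt| exceeds
1 mV/ms, 0.02 ms otherwise; all times live on the fine-step integer grid, so
a run is bit-reproducible for a given configuration and seed. A single RNG
stream serves all stochastic draws in fixed disc order. Numerical blow-up
(V outside ±250 mV or non-finite state) aborts with a diagnostic.

Degenerate-input conventions: boundary Monte-Carlo events (opening at
n_open = N, closing at 0) are no-ops; SERCA cannot remove more Ca²⁺ than a
core region holds in a step; concentrations are floored at zero after
deposits; a leak carried across protocol stages keeps a monotonic clock.

## Protocols and scaling

The experimental protocols pace to steady state for minutes. The package's
desk-scale defaults are 15 s of 1 Hz prepacing before AP/Ca measurements and
2 s before burst pacing (5 s burst at 5 Hz, 15 s observation), with
full-length protocols available through configuration. The default initial
state is the stored 1 Hz paced quasi-steady state, so short prepacing
suffices to wash out transients. Replicate batches derive disjoint seeds
from a base seed and run sequentially; results are independent of any
worker-pool arrangement by construction.

## Analysis conventions

APD_x is measured from the instant of maximum upstroke slope to x%
repolarization of (peak − diastolic), with linear interpolation. "Decay
time" of the Ca²⁺ transient is time from peak to 90% return toward the
pre-stimulus baseline — distinct from the fitted monoexponential constant,
which is also reported. A DAD is a local depolarization ≥ 2 mV above the
running diastolic baseline that does not elicit an AP; a triggered AP is a
non-paced upstroke with dV/dt > 10 mV/ms (both thresholds configurable;
neither is externally specified). Sparks are supra-baseline excursions of
per-disc RyR flux lasting ≥ 1 ms: in the low-variability regime directly
against the median baseline; in the high-variability (isoproterenol) regime
by the iterative two-pass mean + 2·SD rule on the absolute first differences
of the flux, with events required to stay elevated above their pre-event
level ("sustained" rule) — the first difference is used because the
detection statistic is the *change* in flux. Spark frequency is events per
(100 µm × s). All detector parameters are echoed into output metadata.

## What the synthetic fixtures do and do not show

The fixture generators (α-function transients, voltage traces with Gaussian
DAD humps and stylized upstrokes, rectangular flux pulses with Gaussian
noise) exercise the analysis code against closed-form ground truth. They
contain none of the correlated noise, drift, or wave-shaped flux of real
simulations, so detector tests on fixtures validate the algorithms, not the
biological calibration; the integrative tests on simulated traces do the
latter.

## Known limitations

- The two-phase sub-SL Ca²⁺ rise of the calibrated control beat (fast
  sarcolemmal phase, slower SR phase) does not form two separate local
  maxima: the sustained T-type window influx that the model needs for its
  late-plateau APD fills in the trough between the phases.
- Triggered activity requires both the NCX depolarizing foot and the
  T-type avalanche. Full elimination of triggered activity needs ~30–40%
  T-type blockade in some seeds (rather than exactly 20%), and NCX blockade
  silences triggered activity from ~80% rather than 90% — the long (120 s)
  Ca-overload equilibration that compensates NCX loss experimentally is
  outside the scaled protocol length.
- Isoproterenol spark frequencies run 10–30% above the baseline-to-iso
  ratio implied by the reference working points, because the iterative
  detector also counts flux steps inside sustained release events.
- Single membrane compartment (no axial voltage gradients), no explicit
  buffers, no mitochondria, no β-adrenergic kinetics (static scalings), and
  a two-state RyR without explicit adaptation — termination relies on local
  JSR depletion.
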