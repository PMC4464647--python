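# Methods

## Scope and conventions

The package analyzes whole-cell voltage-clamp recordings of Cl⁻ currents and
their companion assays. Outward current is positive, depolarization is
positive, voltages are in mV, currents in pA, concentrations in mM, and
temperatures in K (default 295 K, the middle of the usual 18–23 °C
room-temperature range; with the shipped recipes this default reproduces
both reference Cl⁻ equilibrium potentials, −20 and −28.5 mV, within 0.5 mV).
Every command potential is corrected for the liquid junction potential as
`Vm = Vout − Vlj` before analysis.

## Solutions

Recipes are lists of (salt, mM) with fixed dissociation stoichiometry
(NaCl→Na⁺+Cl⁻, CaCl₂→Ca²⁺+2Cl⁻, …). Glucose, mannitol, HEPES, EGTA, and ATP
salts are carried as metadata but treated as non-transported: HEPES is
zwitterionic at recording pH, EGTA and ATP are bulky, slow, and present at
low millimolar levels, and their partial ionization is rarely specified on a
recipe. This is overridable by extending the dissociation table.

The junction potential uses the generalized Henderson equation over all
transported ions of both solutions, weighted by limiting molar conductivities
per mole of ion (equivalently the classical z²·mobility weighting) — the
full multivalent form, not a single-salt shortcut, because Ca²⁺ and Mg²⁺
appear at few-mM levels on both sides. The sign convention (bath minus
pipette) is pinned by two checks: a single-salt 10:1 dilution junction
reduces to the Lewis–Sargent closed form (−12.1 mV for 150→15 mM NaCl, the
dilute side negative because Cl⁻ outruns Na⁺), and the CsAsp-rich pipette
against the NaCl bath gives Vlj = +12.6 mV, so a +80 mV command step is
analyzed at +67.4 mV. Mobilities ship as an editable CSV
(`data/mobilities.csv`); values for inorganic ions are the standard
limiting conductivities, and organic ions (aspartate⁻ 22.05, NMDG⁺ 24.3
S·cm²·mol⁻¹) use the relative-mobility tables common to junction-potential
calculators, since such values vary between sources.

No activity-coefficient corrections are applied; osmolality is metadata only.

## Current extraction

Step onsets are detected from the command trace itself (first sample
deviating >1 mV from holding), so synthetic and instrument-exported files are
read identically; a step at the holding level itself (e.g. the 0 mV level of
a −100…+120 mV family) leaves no edge and is resolved from the protocol
timing. The *instantaneous* current is the mean over a ±0.2 ms window around
1 ms after onset — at 2.5 kHz sampling a single-sample read would rest on
2–3 samples, and the first 0.4 ms is blanked as capacitative transient. The
*steady-state* current is the mean over the final 5% of the step (a window
mean, not a point sample, was chosen for noise robustness). Ramp series are
reduced to one current per ramp at chosen membrane potentials by
interpolation along the corrected ramp.

## GHK permeability and Boltzmann activation

The constant-field current equation is linear in the whole-cell permeability
P, which the package exploits twice: the instantaneous-I–V fit is the exact
least-squares solution `P̂ = Σ I_k g_k / Σ g_k²` (g_k the per-unit-P GHK
shape), and the steady-state inversion `P(V) = I_ss/g(V)` is algebraic. The
removable singularity at V = 0 is evaluated by series expansion below
|V| = 0.01 mV (`expm1` keeps the quotient stable elsewhere); the two branches
agree to 1e-9 relative. Permeability carries m³/s units internally
(mM ≡ mol/m³ makes `P·shape` come out in amperes), but all reported
activation curves are normalized, so the absolute unit never reaches output.

A point exactly at the reversal potential carries no permeability
information; zero current there inverts to P = 0 and non-zero current is
flagged as inconsistent. Negative inverted P values (noise near reversal)
are retained for fitting — flooring them would bias the fit — and floored at
0 only in reports.

The Boltzmann fit is a 4-parameter nonlinear least squares (P_min, P_max,
V½, dV) with dV > 0. Permeabilities are rescaled to order 1 internally
(they are ~1e-17 m³/s, nine orders of magnitude from the voltage parameters,
which otherwise defeats the optimizer's trust-region scaling).
Initialization: V½ at the half-range crossing of P, dV = 10 mV, plateaus
from the curve extremes, with up to five deterministically jittered restarts.
Normalization to [0, 1] uses the *fitted* plateaus, not the raw extremes.
Cohorts are summarized by fitting per cell and averaging V½ (the
fit-the-average-curve mode is available through the pipeline's per-cell
tables).

QC: cells whose instantaneous I–V reverses more than 15 mV positive of the
calculated E_Cl are excluded as insufficiently Cl⁻-selective (threshold
configurable); every exclusion is logged with the measured shift. The
reversal estimate itself is a local linear interpolation between the
bracketing sign change.

## Pharmacology

Residual current is fitted with the Hill equation with floor fixed at 0 and
ceiling at 1 by default — with the ~6 dose points typical of these
experiments a 4-free-parameter Hill is not identifiable, and saturating block
is the observed behavior; a free-floor variant exists. The Hill coefficient
is free within [0.3, 4], and IC50 is optimized on a log scale. Free
concentration = nominal × free fraction (0.2 in serum-containing media for
strongly serum-bound compounds, 1.0 serum-free).

## Assays

**%RWD.** The denominator is `c(t) − w(0)`: the pointwise form `c(t) − w(t)`
sometimes seen in print divides by zero exactly when the wound closes
completely, contradicting the very 100%-closure readouts it is used to
report, so the initial-wound form (the instrument vendor's definition) is
the default and the pointwise variant is kept behind a flag.

**ΔΔCt.** Group-mean ΔCt difference, fold = 2^−ΔΔCt, with the s.e.m. of the
fold propagated by the delta method (`fold·ln2·se(ΔΔCt)`); pairing of
technical replicates across groups is not assumed.

**Fura-2.** Peak search is limited to a configurable 120 s post-stimulus
window (an unbounded search would pick up later spontaneous transients);
baseline is the 30 s mean before the stimulus.

## Synthetic generator

The generator's defaults encode the studied conditions: step protocols
−100…+120 mV in 20 mV, 2 s steps from 0 mV holding, sampled at 2.5 kHz;
ramps −100…+100 mV over 1 s every 15 s; the shipped pipette/bath recipes
(155/50.68 mM Cl⁻, E_Cl = −28.4 mV; the 0-Ca²⁺/hypotonic pair gives
−20 mV); cell-line presets with V½ = 61 (Capan-1-like), 58 (AsPC-1-like),
30 mV (BxPC-3-like) and a barely-conducting normal-duct control; an NS3728
block preset with IC50 = 1.3 µM at +48 mV; a 320-fold expression ratio for
the qPCR preset.

Quantities no recording can pin down were chosen once as plausible
conventions and are stated as such: CaCC activation τ = 200 ms (slow enough
that the 1 ms read isolates the pre-step gate), a resting open fraction
g_min = 0.25 of the voltage gate at 1 µM Ca²⁺ (high intracellular Ca²⁺ holds
ANO1 partly open at all voltages, which is what makes instantaneous I–V
curves large and GHK-shaped), Boltzmann slope dV = 12 mV, a Ca²⁺ gate with
EC50 = 0.4 µM and Hill n = 2 (only the 0 and 1 µM operating points are
asserted anywhere), VRAC onset lognormal(median 120 s, σ = 0.5) with
τ = 30 s and inactivation (V½ = +40 mV, dV = 20 mV, floor 0.3), ohmic leak
0.05 nS, and a Hill coefficient of 1 for the inhibitor preset. Contaminated
cells add a 5 nS non-selective conductance, enough to drag the instantaneous
reversal well past the QC gate. Noise is additive Gaussian on current
samples — no 1/f, seal drift, or series-resistance artifacts — and response
noise σ = 0.05 on normalized dose–response points. qPCR tables default to 4
experiments × 3 technical replicates per group with σ_Ct = 0.2 and a stable
reference gene.

What passing recovery tests therefore shows: the analysis chain is unbiased
and correctly plumbed under GHK + Boltzmann assumptions with Gaussian noise.
What they do not show: robustness to rundown, seal instability, imperfect
series-resistance compensation, or channels that deviate from constant-field
permeation — real recordings need the QC tools, not just the fits.

Each simulation draws from a single seeded `numpy` generator and returns a
ground-truth ledger (realized per-cell parameters, contamination labels,
seed); identical spec + seed reproduces outputs byte for byte.

## Problem sizes

The shipped recovery runs use 10-cell cohorts (12 steps × 2.2 s × 2.5 kHz
per cell), 50 dose–response replicates of 6 doses × 3–8 cells, and 12 Ct
rows per qPCR group — the cohort sizes of the emulated experiments; the full
test suite and the acceptance script each run in well under a minute.

## Known limitations

Single-ion GHK only (no multi-ion permeation or anion substitution
analysis); no kinetic model fitting of activation time constants; junction
potentials assume the Henderson free-diffusion boundary (no agar-bridge or
dilution-potential corrections beyond it); Boltzmann and Hill standard errors
are curvature-based (no bootstrap); the ABF instrument format is not read
directly — recordings enter as long-format CSV plus a JSON metadata sidecar.
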