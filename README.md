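# wholecell

Analysis tools for whole-cell patch-clamp recordings of chloride currents —
the kind of data produced when characterizing Ca²⁺-activated (CaCC/ANO1) and
volume-regulated (VRAC) Cl⁻ channels in epithelial and cancer cell lines —
plus the small companion assays that usually travel with such a study
(inhibitor dose–response, qPCR fold change, scratch-wound closure, Fura-2
Ca²⁺ imaging).

## What it computes

**Electrophysiology.** The single-ion Goldman–Hodgkin–Katz current equation

```
I = P · z²F²V/(RT) · (C_o − C_i·e^{zFV/RT}) / (1 − e^{zFV/RT})
```

is linear in the whole-cell permeability `P`, so the package fits `P` to
instantaneous I–V curves in closed form and inverts the equation exactly at
each voltage to turn steady-state currents into a permeability–voltage curve
P(V). Voltage-dependent activation is summarized by the Boltzmann curve

```
P(V) = P_max + (P_min − P_max) / (1 + e^{(V − V½)/dV})
```

whose half-activation voltage `V½` and slope factor `dV` are the quantities
of interest; fitted curves are normalized to `P_min = 0, P_max = 1`.
Supporting calculations: per-ion concentrations from salt recipes, Nernst
equilibrium potentials, generalized-Henderson liquid junction potentials
(applied as `Vm = Vout − Vlj`), reversal potentials, a reversal-based QC
filter that drops cells with poor Cl⁻ selectivity, and percent inhibition
with cohort mean ± s.e.m.

**Pharmacology.** Hill dose–response fits (`IC50`, Hill coefficient) of
normalized residual currents, and nominal→free concentration conversion for
serum-bound inhibitors.

**Assays.** Relative wound density `%RWD(t) = 100·(w(t) − w(0))/(c(t) − w(0))`,
ΔΔCt fold change `2^−ΔΔCt` with delta-method s.e.m., and baseline-subtracted
Fura-2 peak responses.

**Synthetic data.** A first-class generator (`wholecell.synthetic`) produces
every input above with known ground truth — GHK-rectifying gated currents
with Boltzmann steady states, Ca²⁺ dependence, swelling-activated ramp series
with cell-variable onset and inactivation at positive potentials, Hill-type
block, lognormal expression ratios, sigmoidal wound closure — so the whole
pipeline is testable without instrument data.

## Worked example

Simulate a 10-cell cohort at the `capan1` preset (V½ = 61 mV, 5% inter-cell
parameter CV), then run the full analysis chain — junction correction,
instantaneous-I–V QC, GHK inversion, per-cell Boltzmann fits:

```
$ wholecell simulate --preset capan1 --n-cells 10 --seed 1 --out sim
wrote 10 cells to sim/sweeps.csv (Vlj 12.57 mV)

$ wholecell fit-boltzmann sim/sweeps.csv --out boltzmann.json
mean V1/2 = 60.9 +- 1.1 mV (n=10); wrote boltzmann.json
```

The recovered cohort mean (60.9 ± 1.1 mV) agrees with the generating value
of 61 mV; `boltzmann.json` holds the per-cell `V½`, `dV`, reversal
potentials, and any QC exclusions with their reasons. The junction potential
(12.57 mV for the CsAsp-rich pipette against the NaCl bath) is computed from
the shipped solution recipes and mobility table, so the +80 mV command step
is analyzed at Vm = +67.4 mV.

Dose–response works the same way:

```
$ wholecell simulate --kind dose --seed 1 --out dose
$ wholecell dose-response dose/dose_response.csv --out hill.json
IC50 = 1.34 uM (n_H = 1.00); wrote hill.json
```

The same operations are available as plain functions (`wholecell.biophysics`,
`wholecell.pharmacology`, …) for notebook use; `wholecell.pipeline` chains
them.

## Layout

- `src/wholecell/solutions.py` — recipes, Nernst, Henderson Vlj
- `src/wholecell/protocols.py` — step/ramp protocols, sweep I/O, current extraction
- `src/wholecell/biophysics.py` — GHK, permeability inversion, Boltzmann, QC
- `src/wholecell/pharmacology.py` — Hill fits, free concentration
- `src/wholecell/assays.py` — %RWD, ΔΔCt, Fura-2 peaks
- `src/wholecell/synthetic.py` — ground-truth generators and presets
- `src/wholecell/pipeline.py`, `cli.py` — orchestration and the `wholecell` CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
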