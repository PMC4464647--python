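"""Synthetic whole-cell recordings and assay data with known ground truth.

Every input the analysis consumes can be generated here with the statistical
structure the analysis assumes, so the full pipeline is testable end to end
and parameter recovery is a measurable property.

Generative models
-----------------
*Ca2+-activated current* (step protocols): the membrane carries a GHK
chloride permeability gated multiplicatively by

* a Boltzmann voltage gate with resting open fraction ``g_min`` that relaxes
  exponentially (time constant ``tau_activation_s``) toward its steady state
  after each step - this produces GHK-shaped instantaneous I-V curves and
  slow activation at depolarized potentials;
* a Hill function of pipette free Ca2+ (no current without Ca2+);

plus an ohmic leak (reversal 0 mV) and additive Gaussian sample noise.
Contaminated cells get an extra non-selective ohmic conductance, which drags
the instantaneous reversal potential positive of the Cl- equilibrium - the
phenotype the reversal-QC filter is meant to catch.

*Volume-regulated current* (repeated ramps): activation rises with a
cell-specific random delay after the hypotonic switch (onset lognormal across
cells), multiplied by a voltage-dependent inactivation that sags at positive
potentials; an inhibitor window scales the gated current by the block
fraction and washes out afterwards.

*Assays*: qPCR Ct values are ``base - log2(expression) + N(0, sigma)`` with a
stable reference gene; wound density closes logistically toward the monolayer
density; Fura-2 traces are a baseline plus a double-exponential transient of
stated amplitude.

All draws come from one ``numpy.random.default_rng(seed)`` per simulation, so
identical spec + seed gives byte-identical outputs; each generator returns a
ground-truth ledger with the realized per-cell parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np

from .assays import FuraTrace, QpcrSample, WoundTimeSeries
from .biophysics import GHKContext, ghk_current
from .pharmacology import DoseResponse, hill_response
from .protocols import RampProtocol, StepProtocol, Sweep, SweepRecording

__all__ = [
    "CaccModelParams", "VracModelParams", "CohortSpec",
    "CACC_PRESETS", "VRAC_PRESET", "NS3728_PRESET", "EXPRESSION_RATIOS",
    "simulate_step_sweeps", "simulate_step_cohort", "simulate_ramp_series",
    "simulate_dose_response", "simulate_qpcr", "simulate_wound",
    "simulate_fura", "simulate_assays", "max_gated_current",
]


@dataclass(frozen=True)
class CaccModelParams:
    """Ground-truth parameters of the Ca2+- and voltage-gated Cl- current."""

    p_max_m3s: float = 2.0e-17      # whole-cell permeability at full activation
    v_half_mv: float = 61.0         # Boltzmann half-activation voltage
    dv_mv: float = 12.0             # Boltzmann slope factor
    g_min: float = 0.25             # resting open fraction of the voltage gate
    ca_ec50_um: float = 0.4         # Ca2+ gate half-activation
    ca_hill: float = 2.0            # Ca2+ gate Hill coefficient
    tau_activation_s: float = 0.2   # voltage-gate relaxation time constant
    leak_ns: float = 0.05           # ohmic leak, reversal at 0 mV
    noise_sd_pa: float = 5.0        # additive Gaussian sample noise

    def __post_init__(self) -> None:
        if min(self.p_max_m3s, self.dv_mv, self.ca_ec50_um, self.ca_hill,
               self.tau_activation_s) <= 0:
            raise ValueError("model scales and slopes must be positive")
        if not 0 <= self.g_min < 1:
            raise ValueError("g_min must lie in [0, 1)")

    def ca_gate(self, free_ca_um: float) -> float:
        """Open fraction contributed by intracellular Ca2+ (0 at 0 Ca2+)."""
        if free_ca_um <= 0:
            return 0.0
        return free_ca_um ** self.ca_hill / (
            free_ca_um ** self.ca_hill + self.ca_ec50_um ** self.ca_hill)

    def gate_steady(self, vm_mv) -> np.ndarray:
        """Steady-state voltage-gate open fraction g_inf(V)."""
        act = 1.0 / (1.0 + np.exp(-(np.asarray(vm_mv, float) - self.v_half_mv)
                                  / self.dv_mv))
        return self.g_min + (1.0 - self.g_min) * act


@dataclass(frozen=True)
class VracModelParams:
    """Ground-truth parameters of the swelling-activated Cl- current."""

    p_max_m3s: float = 1.5e-17
    onset_median_s: float = 120.0   # cell-random delay after the hypotonic switch
    onset_sigma: float = 0.5        # lognormal sigma of the onset across cells
    activation_tau_s: float = 30.0
    inact_v_half_mv: float = 40.0   # inactivation midpoint at positive potentials
    inact_dv_mv: float = 20.0
    h_min: float = 0.3              # residual open fraction at strong depolarization
    leak_ns: float = 0.05
    noise_sd_pa: float = 5.0

    def inactivation(self, vm_mv) -> np.ndarray:
        """Voltage-dependent steady inactivation h_inf(V); flattens as dV -> inf."""
        vm = np.asarray(vm_mv, float)
        if not np.isfinite(self.inact_dv_mv):
            return np.full_like(vm, self.h_min + (1.0 - self.h_min) / 2.0)
        return self.h_min + (1.0 - self.h_min) / (
            1.0 + np.exp((vm - self.inact_v_half_mv) / self.inact_dv_mv))


@dataclass(frozen=True)
class CohortSpec:
    """How many cells to draw and how much they differ."""

    n_cells: int = 10
    param_cv: float = 0.05          # inter-cell CV applied to model parameters
    n_contaminated: int = 0         # cells with an extra non-selective leak
    contamination_ns: float = 5.0
    block_fraction: float = 0.0     # fraction of the gated current blocked
    inhibitor: str = ""
    inhibitor_free_um: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("cohort needs at least one cell")
        if self.param_cv < 0:
            raise ValueError("parameter CV must be non-negative")
        if not 0 <= self.block_fraction <= 1:
            raise ValueError("block fraction must lie in [0, 1]")
        if self.n_contaminated > self.n_cells:
            raise ValueError("more contaminated cells than cells")


# presets bundling the activation parameters of the studied cell lines; p_max
# magnitudes mirror the relative current sizes (largest in Capan-1, barely
# detectable in the normal-duct HPDE control)
CACC_PRESETS: dict[str, CaccModelParams] = {
    "capan1": CaccModelParams(p_max_m3s=2.5e-17, v_half_mv=61.0),
    "aspc1": CaccModelParams(p_max_m3s=1.5e-17, v_half_mv=58.0),
    "bxpc3": CaccModelParams(p_max_m3s=1.8e-17, v_half_mv=30.0),
    "hpde": CaccModelParams(p_max_m3s=5.0e-19, v_half_mv=61.0),
    "ano1_hek": CaccModelParams(p_max_m3s=2.0e-17, v_half_mv=61.0),
}

VRAC_PRESET = VracModelParams()

#: NS3728 block of the Ca2+-activated current in ANO1-expressing cells
NS3728_PRESET = {"ic50_um": 1.3, "hill_n": 1.0, "vm_mv": 48.0}

#: target-gene expression relative to the normal-duct control line
EXPRESSION_RATIOS = {"panc1": 2.3, "bxpc3": 320.0, "capan1": 1450.0}


def _draw_positive(rng: np.random.Generator, nominal: float, cv: float) -> float:
    """Lognormal draw with the given mean CV (exact for small CV)."""
    if cv == 0 or nominal == 0:
        return nominal
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return float(nominal * rng.lognormal(-sigma**2 / 2.0, sigma))


def _draw_cell_params(rng: np.random.Generator, model: CaccModelParams,
                      cv: float) -> CaccModelParams:
    return replace(
        model,
        p_max_m3s=_draw_positive(rng, model.p_max_m3s, cv),
        v_half_mv=float(rng.normal(model.v_half_mv, cv * abs(model.v_half_mv))),
        dv_mv=_draw_positive(rng, model.dv_mv, cv),
        tau_activation_s=_draw_positive(rng, model.tau_activation_s, cv),
    )


def max_gated_current(model: CaccModelParams, protocol: StepProtocol,
                      ctx: GHKContext, vlj_mv: float = 0.0,
                      free_ca_um: float = 1.0) -> float:
    """Largest |steady-state gated current| over the protocol, noiseless (pA)."""
    vm = protocol.levels() - vlj_mv
    i = ghk_current(model.p_max_m3s, vm, ctx) * model.gate_steady(vm) \
        * model.ca_gate(free_ca_um)
    return float(np.max(np.abs(i)))


def simulate_step_sweeps(
    model: CaccModelParams,
    protocol: StepProtocol,
    ctx: GHKContext,
    rng: np.random.Generator,
    cell_id: str = "cell_000",
    vlj_mv: float = 0.0,
    free_ca_um: float = 1.0,
    sampling_rate_hz: float = 2500.0,
    extra_leak_ns: float = 0.0,
    block_fraction: float = 0.0,
    capacitance_pf: float = 25.0,
) -> SweepRecording:
    """Simulate one cell's step-protocol recording (one sweep per level).

    The command trace holds at the protocol holding level, steps for the step
    duration, and returns to holding; the gate relaxes exponentially toward
    its steady state at the local membrane potential.  ``block_fraction``
    scales the gated (not leak) current, emulating an inhibitor.
    """
    dt = 1.0 / sampling_rate_hz
    vm_hold = protocol.holding_mv - vlj_mv
    ca = model.ca_gate(free_ca_um)
    m0 = float(model.gate_steady(vm_hold))
    total_leak = model.leak_ns + extra_leak_ns
    sweeps = []
    for level in protocol.levels():
        n_pre = int(round(protocol.pre_hold_s * sampling_rate_hz))
        n_step = int(round(protocol.step_duration_s * sampling_rate_hz))
        n_post = int(round(protocol.post_hold_s * sampling_rate_hz))
        n = n_pre + n_step + n_post
        t = np.arange(n) * dt
        v_out = np.full(n, protocol.holding_mv)
        v_out[n_pre:n_pre + n_step] = level
        vm = v_out - vlj_mv

        gate = np.full(n, m0)
        m_inf = float(model.gate_steady(level - vlj_mv))
        t_step = (np.arange(n_step) + 1) * dt
        gate[n_pre:n_pre + n_step] = m_inf - (m_inf - m0) * np.exp(
            -t_step / model.tau_activation_s)
        if n_post:
            m_end = gate[n_pre + n_step - 1]
            t_post = (np.arange(n_post) + 1) * dt
            gate[n_pre + n_step:] = m0 - (m0 - m_end) * np.exp(
                -t_post / model.tau_activation_s)

        i = (1.0 - block_fraction) * ghk_current(model.p_max_m3s, vm, ctx) \
            * gate * ca + total_leak * vm
        if model.noise_sd_pa > 0:
            i = i + rng.normal(0.0, model.noise_sd_pa, size=n)
        sweeps.append(Sweep(t, v_out, i))
    return SweepRecording(
        cell_id=cell_id, sampling_rate_hz=sampling_rate_hz, sweeps=sweeps,
        capacitance_pf=capacitance_pf, vlj_mv=vlj_mv,
        holding_mv=protocol.holding_mv,
    )


def simulate_step_cohort(
    model: CaccModelParams,
    protocol: StepProtocol,
    ctx: GHKContext,
    cohort: CohortSpec,
    seed: int,
    vlj_mv: float = 0.0,
    free_ca_um: float = 1.0,
) -> tuple[list[SweepRecording], dict]:
    """Simulate a cohort of cells with inter-cell parameter dispersion.

    The last ``cohort.n_contaminated`` cells receive an extra non-selective
    ohmic conductance.  Returns the recordings and a ground-truth ledger with
    the realized per-cell parameters and contamination labels.
    """
    rng = np.random.default_rng(seed)
    recordings = []
    ledger: dict = {"seed": seed, "model": asdict(model),
                    "cohort": asdict(cohort), "vlj_mv": vlj_mv,
                    "free_ca_um": free_ca_um, "cells": []}
    for k in range(cohort.n_cells):
        cell = _draw_cell_params(rng, model, cohort.param_cv)
        contaminated = k >= cohort.n_cells - cohort.n_contaminated
        extra = cohort.contamination_ns if contaminated else 0.0
        cell_id = f"cell_{k:03d}"
        rec = simulate_step_sweeps(
            cell, protocol, ctx, rng, cell_id=cell_id, vlj_mv=vlj_mv,
            free_ca_um=free_ca_um, extra_leak_ns=extra,
            block_fraction=cohort.block_fraction,
        )
        recordings.append(rec)
        entry = asdict(cell)
        entry.update(cell_id=cell_id, contaminated=contaminated,
                     extra_leak_ns=extra)
        ledger["cells"].append(entry)
    return recordings, ledger


def simulate_ramp_series(
    model: VracModelParams,
    ramp: RampProtocol,
    ctx: GHKContext,
    seed: int,
    total_duration_s: float = 900.0,
    switch_time_s: float = 60.0,
    inhibitor_window_s: tuple[float, float] | None = None,
    block_fraction: float = 0.0,
    cell_id: str = "cell_000",
    vlj_mv: float = 0.0,
    sampling_rate_hz: float = 2500.0,
) -> tuple[SweepRecording, dict]:
    """Simulate a repeated-ramp recording through a hypotonic challenge.

    Activation a(t) rises as a delayed exponential after ``switch_time_s``
    (the cell's own onset delay is a lognormal draw), is multiplied by the
    voltage-dependent inactivation h_inf(V), and is scaled by
    ``1 - block_fraction`` inside the inhibitor window (washout restores the
    current).  One sweep per ramp, ramps every ``repeat_interval_s``.
    """
    if not 0 <= switch_time_s <= total_duration_s:
        raise ValueError("switch time must lie within the recorded series")
    rng = np.random.default_rng(seed)
    onset_delay = float(rng.lognormal(math.log(model.onset_median_s),
                                      model.onset_sigma))
    onset = switch_time_s + onset_delay
    dt = 1.0 / sampling_rate_hz
    # endpoint included so the full command span is sampled
    n_ramp = int(round(ramp.ramp_duration_s * sampling_rate_hz)) + 1
    slope = (ramp.stop_mv - ramp.start_mv) / ramp.ramp_duration_s
    sweeps = []
    n_sweeps = int(total_duration_s // ramp.repeat_interval_s)
    for k in range(n_sweeps):
        t0 = k * ramp.repeat_interval_s
        t = t0 + np.arange(n_ramp) * dt
        v_out = ramp.start_mv + slope * (t - t0)
        vm = v_out - vlj_mv
        a = np.where(t > onset, 1.0 - np.exp(-np.maximum(t - onset, 0.0)
                                             / model.activation_tau_s), 0.0)
        block = np.ones_like(t)
        if inhibitor_window_s is not None:
            w0, w1 = inhibitor_window_s
            block = np.where((t >= w0) & (t <= w1), 1.0 - block_fraction, 1.0)
        i = ghk_current(model.p_max_m3s, vm, ctx) * a * model.inactivation(vm) \
            * block + model.leak_ns * vm
        if model.noise_sd_pa > 0:
            i = i + rng.normal(0.0, model.noise_sd_pa, size=i.size)
        sweeps.append(Sweep(t, v_out, i))
    recording = SweepRecording(cell_id=cell_id, sampling_rate_hz=sampling_rate_hz,
                               sweeps=sweeps, vlj_mv=vlj_mv,
                               holding_mv=ramp.holding_mv)
    ledger = {"seed": seed, "model": asdict(model), "onset_s": onset,
              "switch_time_s": switch_time_s, "vlj_mv": vlj_mv,
              "block_fraction": block_fraction,
              "inhibitor_window_s": inhibitor_window_s}
    return recording, ledger


def simulate_dose_response(
    ic50_um: float,
    hill_n: float,
    concentrations_um,
    seed: int,
    n_cells_per_dose: tuple[int, int] = (3, 8),
    noise_sd: float = 0.05,
    inhibitor: str = "NS3728",
    vm_mv: float = 48.0,
    floor: float = 0.0,
    ceiling: float = 1.0,
) -> tuple[DoseResponse, dict]:
    """Per-dose mean normalized residual currents around a Hill ground truth.

    Each dose is measured in ``n_cells_per_dose`` (uniform draw, inclusive)
    cells with independent Gaussian response noise; the dose-response table
    carries the per-dose means and cell counts, mirroring how cohort
    dose-response figures are assembled.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_um, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    lo, hi = n_cells_per_dose
    means, counts = [], []
    for c in conc:
        n = int(rng.integers(lo, hi + 1))
        r = hill_response(c, ic50_um, hill_n, floor, ceiling) \
            + rng.normal(0.0, noise_sd, size=n)
        means.append(float(np.mean(r)))
        counts.append(n)
    dr = DoseResponse(inhibitor=inhibitor, vm_mv=vm_mv, conc_um=conc,
                      response=np.array(means), n_cells=np.array(counts))
    ledger = {"seed": seed, "ic50_um": ic50_um, "hill_n": hill_n,
              "floor": floor, "ceiling": ceiling, "noise_sd": noise_sd,
              "n_cells": counts}
    return dr, ledger


def simulate_qpcr(
    expression_ratio: float,
    seed: int,
    sigma_ct: float = 0.0,
    n_experiments: int = 4,
    n_replicates: int = 3,
    base_ct_target: float = 24.0,
    ct_reference: float = 17.0,
    control_group: str = "control",
    test_group: str = "test",
) -> list[QpcrSample]:
    """Synthetic Ct tables for a target gene expressed at ``expression_ratio``.

    ``Ct = base - log2(expression) + N(0, sigma_ct)`` for the target; the
    reference gene is stable.  Each group gets ``n_experiments`` independent
    experiments of ``n_replicates`` technical replicates.
    """
    if expression_ratio <= 0:
        raise ValueError("expression ratio must be positive")
    rng = np.random.default_rng(seed)
    samples = []
    for group, expr in ((control_group, 1.0), (test_group, expression_ratio)):
        ct_t = base_ct_target - math.log2(expr)
        for _ in range(n_experiments * n_replicates):
            samples.append(QpcrSample(
                group=group,
                ct_target=ct_t + float(rng.normal(0.0, sigma_ct)) if sigma_ct else ct_t,
                ct_reference=ct_reference + (float(rng.normal(0.0, sigma_ct))
                                             if sigma_ct else 0.0),
            ))
    return samples


def simulate_wound(
    seed: int,
    times_h=None,
    closure_rate_per_h: float = 0.15,
    t_half_h: float = 25.0,
    w0_pct: float = 5.0,
    c_pct: float = 90.0,
    final_closure: float = 1.0,
    noise_sd_pct: float = 0.0,
) -> WoundTimeSeries:
    """Sigmoidal wound closure toward the monolayer density.

    w(t) rises logistically from w(0) toward ``final_closure`` of the cell
    region density; rate 0 leaves the wound empty (%RWD stays 0).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 61.0, 2.0) if times_h is None else np.asarray(times_h, float)
    if closure_rate_per_h == 0:
        w = np.full_like(t, w0_pct)
    else:
        logistic = 1.0 / (1.0 + np.exp(-closure_rate_per_h * (t - t_half_h)))
        l0 = 1.0 / (1.0 + np.exp(closure_rate_per_h * t_half_h))
        frac = (logistic - l0) / (1.0 - l0)
        w = w0_pct + (c_pct - w0_pct) * final_closure * frac
    c = np.full_like(t, c_pct)
    if noise_sd_pct > 0:
        w = w + rng.normal(0.0, noise_sd_pct, size=t.size)
        c = c + rng.normal(0.0, noise_sd_pct, size=t.size)
        w[0] = w0_pct  # wounding time defines the reference density
    return WoundTimeSeries(times_h=t, w_pct=np.clip(w, 0, 100),
                           c_pct=np.clip(c, 0, 100))


def simulate_fura(
    seed: int,
    amplitude: float = 0.46,
    baseline: float = 0.8,
    stimulus_time_s: float = 60.0,
    duration_s: float = 240.0,
    dt_s: float = 1.0,
    tau_rise_s: float = 2.0,
    tau_decay_s: float = 25.0,
    noise_sd: float = 0.0,
) -> FuraTrace:
    """Fura-2 ratio trace: baseline plus a double-exponential Ca2+ transient.

    The transient is normalized so its peak equals ``amplitude`` exactly in
    the noiseless case.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    s = np.zeros_like(t)
    post = t >= stimulus_time_s
    tp = t[post] - stimulus_time_s
    shape = np.exp(-tp / tau_decay_s) - np.exp(-tp / tau_rise_s)
    peak = shape.max() if shape.size and shape.max() > 0 else 1.0
    s[post] = amplitude * shape / peak
    ratio = baseline + s
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, size=t.size)
    return FuraTrace(time_s=t, ratio=np.maximum(ratio, 1e-6),
                     stimulus_time_s=stimulus_time_s)


def simulate_assays(expression_ratio: float, wound_rate_per_h: float,
                    fura_amplitude: float, seed: int, sigma_ct: float = 0.0,
                    wound_noise_pct: float = 0.0, fura_noise: float = 0.0,
                    ) -> tuple[list[QpcrSample], WoundTimeSeries, FuraTrace]:
    """Bundle generator for the three companion assays with one master seed."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    qpcr = simulate_qpcr(expression_ratio, seed=int(seeds[0]), sigma_ct=sigma_ct)
    wound = simulate_wound(seed=int(seeds[1]),
                           closure_rate_per_h=wound_rate_per_h,
                           noise_sd_pct=wound_noise_pct)
    fura = simulate_fura(seed=int(seeds[2]), amplitude=fura_amplitude,
                         noise_sd=fura_noise)
    return qpcr, wound, fura
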