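"""End-to-end analysis pipelines chaining the module operations.

The canonical chloride-current analysis for one cohort of step recordings:

1. compute the liquid junction potential from the actual solution recipes and
   correct every command level, ``Vm = Vout - Vlj``;
2. read the *instantaneous* I-V (1 ms after each step), estimate its reversal
   potential, and exclude cells reversing far positive of the Cl- equilibrium
   potential (imperfectly selective or leaky cells);
3. read the *steady-state* I-V, invert the GHK equation per voltage for the
   whole-cell permeability P(V);
4. fit a Boltzmann activation curve per cell and summarize V1/2 across the
   cohort (per-cell fits first, then averaged).

`recover_vhalf_cohort` runs that chain on the synthetic generator so the
recovery of known activation parameters can be measured; `run_pipeline` runs
it on sweep files on disk and writes a report bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biophysics import (
    GHKContext,
    fit_boltzmann,
    fit_ghk_permeability,
    invert_permeability,
    qc_reversal_filter,
    reversal_potential,
    PermeabilityCurve,
    InconsistentPointError,
)
from .pharmacology import fit_hill
from .protocols import (
    StepProtocol,
    SweepRecording,
    correct_membrane_potential,
    instantaneous_current,
    read_sweeps_csv,
    steady_state_current,
)
from .solutions import (
    SolutionComposition,
    ion_concentrations,
    junction_potential_henderson,
    load_mobility_table,
    load_reference_solution,
    nernst_potential,
)
from .synthetic import (
    CACC_PRESETS,
    CohortSpec,
    NS3728_PRESET,
    max_gated_current,
    simulate_dose_response,
    simulate_step_cohort,
)

__all__ = [
    "CellAnalysis", "CohortResult", "analyze_step_recording",
    "analyze_step_cohort", "recover_vhalf_cohort", "recover_ic50",
    "chloride_context", "run_pipeline",
]


@dataclass
class CellAnalysis:
    """Per-cell results of the step-protocol analysis."""

    cell_id: str
    vrev_instantaneous_mv: float
    p_instantaneous: float
    r_squared_instantaneous: float
    curve: PermeabilityCurve
    v_half_mv: float | None = None
    dv_mv: float | None = None
    p_min: float | None = None
    p_max: float | None = None
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class CohortResult:
    cells: list[CellAnalysis]
    e_cl_mv: float
    vlj_mv: float
    mean_v_half_mv: float = float("nan")
    sem_v_half_mv: float = float("nan")
    n_included: int = 0
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def included_cells(self) -> list[CellAnalysis]:
        return [c for c in self.cells if not c.excluded]


def chloride_context(pipette: SolutionComposition, bath: SolutionComposition,
                     temperature_k: float | None = None) -> GHKContext:
    """GHK context for Cl- from the two solution recipes."""
    co = ion_concentrations(bath).get("Cl", 0.0)
    ci = ion_concentrations(pipette).get("Cl", 0.0)
    t = temperature_k if temperature_k is not None else bath.temperature_k
    return GHKContext(co_mm=co, ci_mm=ci, z=-1, temperature_k=t)


def analyze_step_recording(recording: SweepRecording, protocol: StepProtocol,
                           ctx: GHKContext) -> CellAnalysis:
    """Instantaneous GHK fit + reversal, steady-state P(V) inversion, Boltzmann."""
    levels = protocol.levels()
    vm = correct_membrane_potential(levels, recording.vlj_mv)
    hint = (protocol.pre_hold_s, protocol.step_duration_s)
    i_inst = np.array([instantaneous_current(recording, lv, timing_hint=hint)
                       for lv in levels])
    i_ss = np.array([steady_state_current(recording, lv, timing_hint=hint)
                     for lv in levels])

    vrev = reversal_potential(vm, i_inst)
    ghk_fit = fit_ghk_permeability(vm, i_inst, ctx)

    p_points = []
    v_points = []
    for v, i in zip(vm, i_ss):
        try:
            p_points.append(invert_permeability(v, i, ctx))
            v_points.append(v)
        except InconsistentPointError:
            continue  # point at the reversal potential carries no P information
    curve = PermeabilityCurve(np.array(v_points), np.array(p_points))

    return CellAnalysis(
        cell_id=recording.cell_id,
        vrev_instantaneous_mv=vrev,
        p_instantaneous=ghk_fit.p_hat,
        r_squared_instantaneous=ghk_fit.r_squared,
        curve=curve,
    )


def analyze_step_cohort(recordings: list[SweepRecording], protocol: StepProtocol,
                        ctx: GHKContext, vlj_mv: float,
                        qc_max_shift_mv: float = 15.0) -> CohortResult:
    """Run the full per-cell chain and summarize V1/2 over QC-passing cells."""
    e_cl = ctx.vrev_mv
    cells = [analyze_step_recording(rec, protocol, ctx) for rec in recordings]
    reversals = {c.cell_id: c.vrev_instantaneous_mv for c in cells}
    included_ids, excluded = qc_reversal_filter(reversals, e_cl, qc_max_shift_mv)
    reasons = dict(excluded)

    v_halves = []
    for cell in cells:
        if cell.cell_id in reasons:
            cell.excluded = True
            cell.exclusion_reason = reasons[cell.cell_id]
            continue
        fit, _normalized = fit_boltzmann(cell.curve)
        cell.v_half_mv = fit.v_half_mv
        cell.dv_mv = fit.dv_mv
        cell.p_min = fit.p_min
        cell.p_max = fit.p_max
        v_halves.append(fit.v_half_mv)

    result = CohortResult(cells=cells, e_cl_mv=e_cl, vlj_mv=vlj_mv,
                          excluded=excluded, n_included=len(v_halves))
    if v_halves:
        arr = np.asarray(v_halves)
        result.mean_v_half_mv = float(arr.mean())
        result.sem_v_half_mv = (float(arr.std(ddof=1) / np.sqrt(arr.size))
                                if arr.size > 1 else 0.0)
    return result


def recover_vhalf_cohort(preset: str, seed: int, n_cells: int = 10,
                         param_cv: float = 0.05,
                         noise_frac_of_max: float = 0.02,
                         n_contaminated: int = 0) -> CohortResult:
    """Simulate a cohort at a cell-line preset and run the full recovery chain.

    Noise is set to ``noise_frac_of_max`` of the largest noiseless gated
    current under the protocol.  Solutions are the packaged 1-uM-Ca pipette
    and standard bath; the junction potential is computed from them with the
    packaged mobility table on both the generating and the analysis side.
    """
    from dataclasses import replace

    model = CACC_PRESETS[preset]
    pipette = load_reference_solution("pipette_ca_1um")
    bath = load_reference_solution("bath_standard")
    vlj = junction_potential_henderson(pipette, bath)
    ctx = chloride_context(pipette, bath)
    protocol = StepProtocol()
    noise = noise_frac_of_max * max_gated_current(model, protocol, ctx, vlj)
    model = replace(model, noise_sd_pa=noise)
    cohort = CohortSpec(n_cells=n_cells, param_cv=param_cv,
                        n_contaminated=n_contaminated)
    recordings, _truth = simulate_step_cohort(
        model, protocol, ctx, cohort, seed=seed, vlj_mv=vlj,
        free_ca_um=pipette.free_ca_um or 0.0)
    return analyze_step_cohort(recordings, protocol, ctx, vlj)


def recover_ic50(seed: int, n_seeds: int = 50,
                 ic50_um: float = NS3728_PRESET["ic50_um"],
                 hill_n: float = NS3728_PRESET["hill_n"],
                 noise_sd: float = 0.05) -> dict:
    """Median recovered IC50 over repeated simulated dose-response cohorts.

    Six log-spaced free concentrations spanning 0.1-30 uM, 3-8 cells per
    dose, Gaussian response noise; each replicate gets an independent
    sub-seed derived from ``seed``.
    """
    conc = np.geomspace(0.1, 30.0, 6)
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=n_seeds)
    estimates = []
    for s in sub_seeds:
        dr, _truth = simulate_dose_response(ic50_um, hill_n, conc, seed=int(s),
                                            noise_sd=noise_sd,
                                            vm_mv=NS3728_PRESET["vm_mv"])
        estimates.append(fit_hill(dr).ic50_um)
    estimates = np.array(estimates)
    return {"median_ic50_um": float(np.median(estimates)),
            "mean_ic50_um": float(estimates.mean()),
            "n_fits": int(estimates.size),
            "true_ic50_um": ic50_um}


# ---------------------------------------------------------------------------
# file-driven pipeline


@dataclass
class RunConfig:
    """Configuration of a file-driven analysis run."""

    sweeps_csv: str
    pipette_solution: str = "pipette_ca_1um"  # packaged key or JSON path
    bath_solution: str = "bath_standard"
    mobility_table: str | None = None  # None = packaged table
    temperature_k: float = 295.0
    qc_max_shift_mv: float = 15.0
    vlj_mode: str = "computed"  # or "supplied"
    vlj_mv: float = 0.0
    protocol: StepProtocol = field(default_factory=StepProtocol)
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 273.0 <= self.temperature_k <= 320.0:
            raise ValueError("temperature outside the plausible 273-320 K range")
        if self.vlj_mode not in ("computed", "supplied"):
            raise ValueError("vlj_mode must be 'computed' or 'supplied'")


def _load_solution(spec: str) -> SolutionComposition:
    path = Path(spec)
    if path.suffix == ".json" and path.exists():
        return SolutionComposition.from_file(path)
    return load_reference_solution(spec)


def run_pipeline(config: RunConfig) -> dict:
    """Run the cohort analysis on sweep files and write a report bundle.

    Writes ``summary.json``, ``cells.csv``, ``permeability.csv``, a
    line-delimited ``log.jsonl`` recording every QC exclusion, and a
    ``manifest.json`` with a hash of the configuration; identical config and
    inputs give identical reports.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    pipette = _load_solution(config.pipette_solution)
    bath = _load_solution(config.bath_solution)
    mobility = load_mobility_table(config.mobility_table)

    if config.vlj_mode == "computed":
        vlj = junction_potential_henderson(pipette, bath, mobility,
                                           config.temperature_k)
    else:
        vlj = config.vlj_mv

    ctx = chloride_context(pipette, bath, config.temperature_k)
    recordings = read_sweeps_csv(config.sweeps_csv)
    for rec in recordings:
        rec.vlj_mv = vlj

    result = analyze_step_cohort(recordings, config.protocol, ctx, vlj,
                                 config.qc_max_shift_mv)

    rows, p_rows, log_lines = [], [], []
    for cell in result.cells:
        rows.append({
            "cell_id": cell.cell_id,
            "vrev_mv": cell.vrev_instantaneous_mv,
            "p_instantaneous_m3s": cell.p_instantaneous,
            "r2_instantaneous": cell.r_squared_instantaneous,
            "v_half_mv": cell.v_half_mv,
            "dv_mv": cell.dv_mv,
            "excluded": cell.excluded,
            "exclusion_reason": cell.exclusion_reason,
        })
        for v, p in zip(cell.curve.v_mv, cell.curve.p):
            # negative inverted P (noise near reversal) floored for reporting
            p_rows.append({"cell_id": cell.cell_id, "vm_mv": v,
                           "p_m3s": max(p, 0.0)})
        if cell.excluded:
            log_lines.append(json.dumps({
                "event": "qc_exclusion", "cell_id": cell.cell_id,
                "reason": cell.exclusion_reason}))

    summary = {
        "n_cells": len(result.cells),
        "n_included": result.n_included,
        "e_cl_mv": result.e_cl_mv,
        "vlj_mv": result.vlj_mv,
        "mean_v_half_mv": result.mean_v_half_mv,
        "sem_v_half_mv": result.sem_v_half_mv,
        "nernst_e_cl_mv": nernst_potential(-1, ctx.co_mm, ctx.ci_mm,
                                           ctx.temperature_k),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    pd.DataFrame(rows).to_csv(outdir / "cells.csv", index=False)
    pd.DataFrame(p_rows).to_csv(outdir / "permeability.csv", index=False)
    (outdir / "log.jsonl").write_text("\n".join(log_lines) + ("\n" if log_lines else ""))

    config_repr = json.dumps({
        "sweeps_csv": config.sweeps_csv,
        "pipette_solution": config.pipette_solution,
        "bath_solution": config.bath_solution,
        "temperature_k": config.temperature_k,
        "qc_max_shift_mv": config.qc_max_shift_mv,
        "vlj_mode": config.vlj_mode,
        "vlj_mv": config.vlj_mv,
        "seed": config.seed,
    }, sort_keys=True)
    manifest = {
        "config_hash": hashlib.sha256(config_repr.encode()).hexdigest(),
        "package_version": __version__,
        "seed": config.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary
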