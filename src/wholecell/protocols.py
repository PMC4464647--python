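"""Voltage protocols, sweep containers, and current-extraction rules.

Sign conventions follow the usual whole-cell bookkeeping: outward current is
positive, depolarization is positive, and every command level is corrected for
the liquid junction potential as ``Vm = Vout - Vlj`` before analysis.

Measurement rules implemented here:

* the *instantaneous* current is read ~1 ms after a voltage step, before the
  time-dependent gate has moved, as a short window mean (the 2.5 kHz sampling
  leaves only 2-3 samples inside the first millisecond, so a single-sample
  read would be needlessly noisy); samples inside the capacitative-transient
  blanking window right at the step edge are excluded;
* the *steady-state* current is the mean over the final fraction of the step;
* ramp series are reduced to a per-ramp time course of the current at chosen
  membrane potentials by interpolation along each ramp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StepProtocol",
    "RampProtocol",
    "Sweep",
    "SweepRecording",
    "correct_membrane_potential",
    "instantaneous_current",
    "steady_state_current",
    "ramp_timecourse",
    "current_density",
    "read_sweeps_csv",
    "write_sweeps_csv",
    "StepLevelError",
]


class StepLevelError(ValueError):
    """Requested step level is not present in the recording."""


@dataclass(frozen=True)
class StepProtocol:
    """Family of rectangular voltage steps from a common holding potential."""

    start_mv: float = -100.0
    stop_mv: float = 120.0
    increment_mv: float = 20.0
    step_duration_s: float = 2.0
    holding_mv: float = 0.0
    pre_hold_s: float = 0.1
    post_hold_s: float = 0.1

    def __post_init__(self) -> None:
        if self.increment_mv <= 0:
            raise ValueError("step increment must be positive")
        if self.stop_mv < self.start_mv:
            raise ValueError("stop level must not be below start level")
        if self.step_duration_s <= 0:
            raise ValueError("step duration must be positive")

    def levels(self) -> np.ndarray:
        """Command levels (Vout, mV) of the step family."""
        n = int(round((self.stop_mv - self.start_mv) / self.increment_mv)) + 1
        return self.start_mv + self.increment_mv * np.arange(n)


@dataclass(frozen=True)
class RampProtocol:
    """Repeated voltage ramps run continuously at a fixed interval."""

    start_mv: float = -100.0
    stop_mv: float = 100.0
    ramp_duration_s: float = 1.0
    repeat_interval_s: float = 15.0
    holding_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.ramp_duration_s <= 0:
            raise ValueError("ramp duration must be positive")
        if self.repeat_interval_s < self.ramp_duration_s:
            raise ValueError("repeat interval cannot be shorter than the ramp")


@dataclass
class Sweep:
    """One acquisition episode: time (s), command voltage (mV), current (pA)."""

    time_s: np.ndarray
    v_out_mv: np.ndarray
    i_pa: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.v_out_mv = np.asarray(self.v_out_mv, dtype=float)
        self.i_pa = np.asarray(self.i_pa, dtype=float)
        if not (self.time_s.shape == self.v_out_mv.shape == self.i_pa.shape):
            raise ValueError("sweep arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("sweep time must be strictly increasing")


@dataclass
class SweepRecording:
    """All sweeps of one cell under one protocol, plus recording metadata."""

    cell_id: str
    sampling_rate_hz: float
    sweeps: list[Sweep]
    pipette_solution: str = ""
    bath_solution: str = ""
    capacitance_pf: float | None = None
    vlj_mv: float = 0.0
    holding_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")


def correct_membrane_potential(v_out_mv, vlj_mv: float):
    """Junction-corrected membrane potential, Vm = Vout - Vlj (mV)."""
    out = np.asarray(v_out_mv, dtype=float) - vlj_mv
    return out if out.ndim else float(out)


def _find_step(sweep: Sweep, level_mv: float, holding_mv: float,
               tol_mv: float = 1.0,
               timing_hint: tuple[float, float] | None = None) -> tuple[int, int]:
    """Locate the [onset, offset) sample range of a step at ``level_mv`` (Vout).

    Onset is detected from the command trace itself - the first sample
    deviating by more than 1 mV from holding - so synthetic and real files are
    read identically.  A step at the holding level itself leaves no edge in
    the command trace; such sweeps are resolved through ``timing_hint``
    (onset time, duration in seconds), normally the protocol timing.
    """
    dev = np.abs(sweep.v_out_mv - holding_mv) > tol_mv
    if not np.any(dev):
        if abs(level_mv - holding_mv) <= tol_mv and timing_hint is not None:
            t_rel = sweep.time_s - sweep.time_s[0]
            onset_t, duration = timing_hint
            inside = (t_rel >= onset_t) & (t_rel < onset_t + duration)
            if np.any(inside):
                idx = np.nonzero(inside)[0]
                return int(idx[0]), int(idx[-1]) + 1
        raise StepLevelError(
            f"no step found in sweep (command stays at holding {holding_mv:g} mV)"
        )
    onset = int(np.argmax(dev))
    at_level = np.abs(sweep.v_out_mv - level_mv) <= tol_mv
    if not at_level[onset]:
        raise StepLevelError(
            f"step level {level_mv:g} mV absent from this sweep "
            f"(found {sweep.v_out_mv[onset]:g} mV)"
        )
    off = onset + int(np.argmax(~at_level[onset:])) if not at_level[onset:].all() \
        else sweep.v_out_mv.size
    return onset, off


def _sweep_for_level(recording: SweepRecording, level_mv: float,
                     timing_hint: tuple[float, float] | None = None,
                     ) -> tuple[Sweep, int, int]:
    for sweep in recording.sweeps:
        try:
            onset, off = _find_step(sweep, level_mv, recording.holding_mv,
                                    timing_hint=timing_hint)
        except StepLevelError:
            continue
        return sweep, onset, off
    raise StepLevelError(
        f"step level {level_mv:g} mV not present in recording {recording.cell_id!r}"
    )


def instantaneous_current(recording: SweepRecording, step_level_mv: float,
                          delay_s: float = 1e-3, half_window_s: float = 0.2e-3,
                          blank_s: float = 0.4e-3,
                          timing_hint: tuple[float, float] | None = None) -> float:
    """Current ~1 ms after the step onset (pA), mean over a +-0.2 ms window.

    ``step_level_mv`` is the command (Vout) level.  Samples within ``blank_s``
    of the onset are excluded as capacitative transient.  ``timing_hint``
    (onset time, duration) disambiguates a step at the holding level.
    """
    sweep, onset, off = _sweep_for_level(recording, step_level_mv, timing_hint)
    t0 = sweep.time_s[onset]
    t_end = sweep.time_s[off - 1]
    if t0 + delay_s > t_end:
        raise ValueError(
            f"delay {delay_s:g} s exceeds the step duration ({t_end - t0:g} s)"
        )
    t_rel = sweep.time_s - t0
    sel = (np.abs(t_rel - delay_s) <= half_window_s + 1e-12) & (t_rel >= blank_s)
    sel[:onset] = False
    sel[off:] = False
    if not np.any(sel):  # very low sampling rate: nearest usable sample
        idx = np.nonzero((t_rel >= blank_s) & (np.arange(t_rel.size) >= onset)
                         & (np.arange(t_rel.size) < off))[0]
        sel[idx[np.argmin(np.abs(t_rel[idx] - delay_s))]] = True
    return float(sweep.i_pa[sel].mean())


def steady_state_current(recording: SweepRecording, step_level_mv: float,
                         window_fraction: float = 0.05,
                         timing_hint: tuple[float, float] | None = None) -> float:
    """Mean current over the terminal ``window_fraction`` of the step (pA)."""
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    sweep, onset, off = _sweep_for_level(recording, step_level_mv, timing_hint)
    n = off - onset
    start = off - max(int(round(window_fraction * n)), 1)
    return float(sweep.i_pa[start:off].mean())


def ramp_timecourse(recording: SweepRecording, targets_mv,
                    ) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Per-ramp current at chosen *membrane* potentials, one point per sweep.

    Each sweep must contain one voltage ramp.  Targets are junction-corrected
    membrane potentials (mV); the command trace is corrected with the
    recording's Vlj before interpolation.  Returns
    ``{target: (acquisition times, currents)}``.
    """
    targets = np.atleast_1d(np.asarray(targets_mv, dtype=float))
    out: dict[float, tuple[list, list]] = {float(t): ([], []) for t in targets}
    for sweep in recording.sweeps:
        vm = correct_membrane_potential(sweep.v_out_mv, recording.vlj_mv)
        span = np.abs(vm - vm[0]) > 1.0
        if not np.any(span):
            continue
        a = int(np.argmax(span))
        b = vm.size - int(np.argmax(span[::-1]))
        vm_ramp, i_ramp, t_ramp = vm[a:b], sweep.i_pa[a:b], sweep.time_s[a:b]
        order = np.argsort(vm_ramp)
        vm_sorted, i_sorted = vm_ramp[order], i_ramp[order]
        for t in targets:
            if t < vm_ramp.min() or t > vm_ramp.max():
                raise ValueError(
                    f"target {t:g} mV outside the corrected ramp span "
                    f"[{vm_ramp.min():.1f}, {vm_ramp.max():.1f}] mV"
                )
            out[float(t)][0].append(float(t_ramp[0]))
            out[float(t)][1].append(float(np.interp(t, vm_sorted, i_sorted)))
    return {t: (np.array(ts), np.array(cs)) for t, (ts, cs) in out.items()}


def current_density(i_pa: float, capacitance_pf: float | None) -> float:
    """Capacitance-normalized current, pA/pF."""
    if capacitance_pf is None:
        raise ValueError("recording has no capacitance; cannot form a density")
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    return i_pa / capacitance_pf


# ---------------------------------------------------------------------------
# file I/O: long-format CSV plus a JSON metadata sidecar


def write_sweeps_csv(recordings: list[SweepRecording], csv_path: str | Path) -> Path:
    """Write recordings as long CSV (cell_id, sweep, time_s, v_out_mv, i_pa).

    A ``<name>.meta.json`` sidecar holds per-cell metadata.  Returns the CSV
    path.
    """
    csv_path = Path(csv_path)
    frames = []
    meta = {}
    for rec in recordings:
        for k, sweep in enumerate(rec.sweeps):
            frames.append(pd.DataFrame({
                "cell_id": rec.cell_id, "sweep": k, "time_s": sweep.time_s,
                "v_out_mv": sweep.v_out_mv, "i_pa": sweep.i_pa,
            }))
        meta[rec.cell_id] = {
            "sampling_rate_hz": rec.sampling_rate_hz,
            "pipette_solution": rec.pipette_solution,
            "bath_solution": rec.bath_solution,
            "capacitance_pf": rec.capacitance_pf,
            "vlj_mv": rec.vlj_mv,
            "holding_mv": rec.holding_mv,
        }
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False,
                                                float_format="%.6g")
    csv_path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return csv_path


def read_sweeps_csv(csv_path: str | Path) -> list[SweepRecording]:
    """Read recordings written by :func:`write_sweeps_csv`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    recordings = []
    for cell_id, cell_df in df.groupby("cell_id", sort=False):
        sweeps = [
            Sweep(g["time_s"].to_numpy(), g["v_out_mv"].to_numpy(),
                  g["i_pa"].to_numpy())
            for _, g in cell_df.groupby("sweep", sort=True)
        ]
        m = meta.get(str(cell_id), {})
        recordings.append(SweepRecording(
            cell_id=str(cell_id),
            sampling_rate_hz=m.get("sampling_rate_hz", 2500.0),
            sweeps=sweeps,
            pipette_solution=m.get("pipette_solution", ""),
            bath_solution=m.get("bath_solution", ""),
            capacitance_pf=m.get("capacitance_pf"),
            vlj_mv=m.get("vlj_mv", 0.0),
            holding_mv=m.get("holding_mv", 0.0),
        ))
    return recordings
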