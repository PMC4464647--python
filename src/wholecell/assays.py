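"""Companion assay quantifications: wound closure, qPCR fold change, Ca2+ imaging.

Three small, self-contained reductions that accompany the electrophysiology:

* scratch-wound **relative wound density**, the fraction of the initial wound
  that has filled in relative to the surrounding monolayer,
  ``%RWD(t) = 100 (w(t) - w(0)) / (c(t) - w(0))`` - see the note on the
  denominator in the docstring of :func:`relative_wound_density`;
* the **ddCt** relative-expression method for qPCR,
  ``fold = 2^-(dCt_test - dCt_control)`` with ``dCt = Ct_target - Ct_ref``;
* the **peak delta-ratio** of a Fura-2 340/380 nm trace after a stimulus,
  baseline-subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WoundTimeSeries", "QpcrSample", "FuraTrace",
           "relative_wound_density", "ddct_fold_change", "peak_delta_ratio"]


@dataclass
class WoundTimeSeries:
    """Wound-region density w(t) and cell-region density c(t), both in %."""

    times_h: np.ndarray
    w_pct: np.ndarray
    c_pct: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.w_pct = np.asarray(self.w_pct, dtype=float)
        self.c_pct = np.asarray(self.c_pct, dtype=float)
        if not (self.times_h.shape == self.w_pct.shape == self.c_pct.shape):
            raise ValueError("wound series arrays differ in length")
        if np.any((self.w_pct < 0) | (self.w_pct > 100)) or \
           np.any((self.c_pct < 0) | (self.c_pct > 100)):
            raise ValueError("densities must lie in [0, 100] %")


@dataclass(frozen=True)
class QpcrSample:
    """One qPCR well: group label and Ct values of target and reference gene."""

    group: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if not 0 < ct < 45:
                raise ValueError(f"Ct value {ct:g} outside the plausible (0, 45) range")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass
class FuraTrace:
    """Fura-2 340/380 fluorescence ratio over time with a stimulus marker."""

    time_s: np.ndarray
    ratio: np.ndarray
    stimulus_time_s: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time_s.shape != self.ratio.shape:
            raise ValueError("trace arrays differ in length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("trace time must be strictly increasing")


def relative_wound_density(series: WoundTimeSeries,
                           denominator: str = "initial") -> np.ndarray:
    """Percent relative wound density over time.

    ``denominator="initial"`` (default) computes
    ``100 (w(t) - w(0)) / (c(t) - w(0))``, which is 0 at the moment of
    wounding and exactly 100 when the wound is as dense as the monolayer.
    ``denominator="pointwise"`` uses ``c(t) - w(t)`` instead; that variant is
    singular exactly at full closure, so it is kept only for comparison with
    reports that print it.  Degenerate denominators yield NaN for that point.
    """
    w, c = series.w_pct, series.c_pct
    w0 = w[0]
    if denominator == "initial":
        den = c - w0
    elif denominator == "pointwise":
        den = c - w
    else:
        raise ValueError("denominator must be 'initial' or 'pointwise'")
    out = np.full_like(w, np.nan, dtype=float)
    ok = den > 1e-9
    out[ok] = 100.0 * (w[ok] - w0) / den[ok]
    return out


def ddct_fold_change(samples: list[QpcrSample], control_group: str,
                     ) -> tuple[float, float]:
    """ddCt fold change of the non-control group relative to ``control_group``.

    Per sample dCt = Ct_target - Ct_reference; ddCt is the difference of group
    mean dCt values; fold = 2^-ddCt.  The s.e.m. of the fold is propagated
    from the two group variances by the delta method
    (``sem_fold = fold * ln2 * se(ddCt)``).
    """
    control = [s.dct for s in samples if s.group == control_group]
    treated = [s.dct for s in samples if s.group != control_group]
    if not control or not treated:
        raise ValueError("need at least one sample in each of control and test groups")
    control = np.asarray(control)
    treated = np.asarray(treated)
    ddct = treated.mean() - control.mean()
    fold = float(2.0 ** (-ddct))
    var = 0.0
    if control.size > 1:
        var += control.var(ddof=1) / control.size
    if treated.size > 1:
        var += treated.var(ddof=1) / treated.size
    sem_fold = fold * np.log(2.0) * float(np.sqrt(var))
    return fold, sem_fold


def peak_delta_ratio(trace: FuraTrace, baseline_window_s: float = 30.0,
                     search_window_s: float = 120.0) -> float:
    """Maximum stimulus-induced rise of the Fura-2 ratio above baseline.

    Baseline is the mean ratio over the ``baseline_window_s`` seconds directly
    preceding the stimulus; the peak is searched within ``search_window_s``
    after it.
    """
    t, r = trace.time_s, trace.ratio
    t0 = trace.stimulus_time_s
    base_sel = (t >= t0 - baseline_window_s) & (t < t0)
    if not np.any(base_sel):
        raise ValueError("baseline window contains no samples before the stimulus")
    post_sel = (t >= t0) & (t <= t0 + search_window_s)
    if not np.any(post_sel):
        raise ValueError("no samples inside the post-stimulus search window")
    return float(r[post_sel].max() - r[base_sel].mean())
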