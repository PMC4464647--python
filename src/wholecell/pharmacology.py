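"""Hill dose-response fitting and nominal-to-free inhibitor concentration.

Residual current after an inhibitor is modelled with the Hill equation

    response(c) = floor + (ceiling - floor) / (1 + (c / IC50)^n)

on the normalized 0-1 scale (1 = untreated current).  With the few dose
points typical of patch-clamp pharmacology, a 4-free-parameter Hill is not
identifiable, so the floor is fixed to 0 and the ceiling to 1 by default
(full block at saturation); a free-floor variant is available.

Strongly serum-bound inhibitors act at their free, not nominal, bath
concentration; :func:`free_concentration` applies the free fraction (default
0.2 in serum-containing media, 1.0 serum-free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DoseResponse", "HillFit", "fit_hill", "free_concentration",
           "hill_response", "FREE_FRACTION_SERUM", "FREE_FRACTION_SERUM_FREE"]

#: free fraction of a strongly serum-bound inhibitor in serum-containing media
FREE_FRACTION_SERUM = 0.2
FREE_FRACTION_SERUM_FREE = 1.0

HILL_N_BOUNDS = (0.3, 4.0)


@dataclass
class DoseResponse:
    """Normalized residual current vs free inhibitor concentration at one Vm."""

    inhibitor: str
    vm_mv: float
    conc_um: np.ndarray
    response: np.ndarray
    n_cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conc_um = np.asarray(self.conc_um, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc_um.shape != self.response.shape:
            raise ValueError("concentration and response arrays differ in length")
        if np.any(self.conc_um < 0):
            raise ValueError("concentrations must be non-negative")
        if self.n_cells is not None:
            self.n_cells = np.asarray(self.n_cells, dtype=int)


@dataclass
class HillFit:
    ic50_um: float
    hill_n: float
    floor: float = 0.0
    ceiling: float = 1.0
    se: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ic50_um <= 0 or self.hill_n <= 0:
            raise ValueError("IC50 and Hill coefficient must be positive")
        if not 0 <= self.floor <= self.ceiling <= 1 + 1e-9:
            raise ValueError("need 0 <= floor <= ceiling <= 1")


def hill_response(conc_um, ic50_um, hill_n, floor=0.0, ceiling=1.0):
    """Residual current fraction at concentration ``conc_um``."""
    c = np.asarray(conc_um, dtype=float)
    out = floor + (ceiling - floor) / (1.0 + (c / ic50_um) ** hill_n)
    return out if out.ndim else float(out)


def fit_hill(dr: DoseResponse, free_floor: bool = False) -> HillFit:
    """Least-squares Hill fit; IC50 is optimized on a log scale for stability.

    Requires at least 4 distinct concentrations with responses on both sides
    of the half-block level.
    """
    c, r = dr.conc_um, dr.response
    pos = c > 0
    c, r = c[pos], r[pos]
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct positive concentrations")

    lo, hi = HILL_N_BOUNDS
    # initial IC50: concentration whose response is nearest half block
    mid = (r.max() + r.min()) / 2.0
    log_ic50_0 = float(np.log(c[np.argmin(np.abs(r - mid))]))

    if free_floor:
        def model(logc, log_ic50, n, floor):
            return hill_response(np.exp(logc), np.exp(log_ic50), n, floor, 1.0)
        p0 = [log_ic50_0, 1.0, max(float(r.min()), 0.0)]
        bounds = ([np.log(c.min()) - 10, lo, 0.0], [np.log(c.max()) + 10, hi, 1.0])
    else:
        def model(logc, log_ic50, n):
            return hill_response(np.exp(logc), np.exp(log_ic50), n, 0.0, 1.0)
        p0 = [log_ic50_0, 1.0]
        bounds = ([np.log(c.min()) - 10, lo], [np.log(c.max()) + 10, hi])

    try:
        popt, pcov = curve_fit(model, np.log(c), r, p0=p0, bounds=bounds,
                               maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"Hill fit did not converge: {err}") from err
    perr = np.sqrt(np.diag(pcov))
    ic50 = float(np.exp(popt[0]))
    se = {"ic50_um": ic50 * float(perr[0]),  # delta method from log scale
          "hill_n": float(perr[1])}
    floor = float(popt[2]) if free_floor else 0.0
    if free_floor:
        se["floor"] = float(perr[2])
    return HillFit(ic50_um=ic50, hill_n=float(popt[1]), floor=floor,
                   ceiling=1.0, se=se)


def free_concentration(nominal_um: float, free_fraction: float) -> float:
    """Free inhibitor concentration (uM) given the unbound fraction."""
    if not 0 < free_fraction <= 1:
        raise ValueError("free fraction must lie in (0, 1]")
    if nominal_um < 0:
        raise ValueError("nominal concentration must be non-negative")
    return nominal_um * free_fraction
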