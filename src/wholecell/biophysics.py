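"""GHK current analysis: permeability fitting, Boltzmann activation, QC, inhibition.

The constant-field (Goldman-Hodgkin-Katz) current equation for a single ion

    I = P * z^2 F^2 V / (R T) * (Co - Ci exp(zFV/RT)) / (1 - exp(zFV/RT))

is linear in the whole-cell permeability ``P``, which makes both the
instantaneous-I-V fit (one shared P) and the per-voltage steady-state
inversion (one P per voltage) exact least-squares/algebraic operations.
Voltage dependence of activation is then summarized by fitting a Boltzmann
curve P(V) = Pmax + (Pmin - Pmax)/(1 + exp((V - V1/2)/dV)) to the inverted
permeabilities and normalizing to the fitted Pmin = 0, Pmax = 1.

Units: voltages mV, currents pA, concentrations mM, permeability m^3/s
(mM == mol/m^3, so ``P * shape`` lands directly in amperes; a 1e12 factor
converts to pA).  Reported activation curves are normalized, so the absolute
permeability unit never reaches a figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .solutions import DEFAULT_TEMPERATURE_K, FARADAY, GAS_CONSTANT, nernst_potential

__all__ = [
    "GHKContext",
    "PermeabilityCurve",
    "BoltzmannFit",
    "GhkPermeabilityFit",
    "ghk_current",
    "ghk_shape",
    "fit_ghk_permeability",
    "invert_permeability",
    "fit_boltzmann",
    "boltzmann",
    "reversal_potential",
    "qc_reversal_filter",
    "percent_inhibition",
    "summarize_inhibition",
    "InconsistentPointError",
]

# below this |V| (mV) the exp form is replaced by its series expansion
_V_SERIES_MV = 0.01


class InconsistentPointError(ValueError):
    """Non-zero current at the reversal potential cannot be inverted to a P."""


@dataclass(frozen=True)
class GHKContext:
    """Ion valence, its bath/pipette concentrations (mM) and temperature."""

    co_mm: float
    ci_mm: float
    z: int = -1
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.co_mm <= 0 or self.ci_mm <= 0:
            raise ValueError("GHK needs positive concentrations on both sides")
        if self.z == 0:
            raise ValueError("valence must be non-zero")

    @property
    def vrev_mv(self) -> float:
        """Nernst potential of the ion in this context, mV."""
        return nernst_potential(self.z, self.co_mm, self.ci_mm, self.temperature_k)


def ghk_shape(v_mv, ctx: GHKContext):
    """GHK current per unit permeability (pA per m^3/s) at membrane voltage v_mv.

    The removable singularity at V = 0 is evaluated by series expansion for
    |V| < 0.01 mV; elsewhere ``expm1`` keeps the quotient stable.
    """
    v_mv = np.asarray(v_mv, dtype=float)
    z, co, ci = ctx.z, ctx.co_mm, ctx.ci_mm
    rt = GAS_CONSTANT * ctx.temperature_k
    u = z * FARADAY * (v_mv * 1e-3) / rt  # dimensionless voltage

    small = np.abs(v_mv) < _V_SERIES_MV
    u_safe = np.where(small, 1.0, u)
    # I/P = zF * u * (Ci - (Co - Ci)/expm1(u));  series below |u| ~ 4e-7
    exact = z * FARADAY * u_safe * (ci - (co - ci) / np.expm1(u_safe))
    series = z * FARADAY * ((ci - co) + u * (ci + co) / 2.0 - u**2 * (co - ci) / 12.0)
    out = 1e12 * np.where(small, series, exact)
    return out if out.ndim else float(out)


def ghk_current(p, v_mv, ctx: GHKContext):
    """GHK current (pA) for permeability ``p`` (m^3/s) at voltage ``v_mv`` (mV)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("permeability must be non-negative")
    out = p * ghk_shape(v_mv, ctx)
    return out if out.ndim else float(out)


@dataclass
class GhkPermeabilityFit:
    """Single-parameter GHK fit of an instantaneous I-V relationship."""

    p_hat: float
    p_se: float
    r_squared: float
    residuals_pa: np.ndarray


def fit_ghk_permeability(v_mv, i_pa, ctx: GHKContext) -> GhkPermeabilityFit:
    """Least-squares permeability from an (V, I) relation, closed form.

    The GHK equation is linear in P, so the optimum is
    ``P = sum(I_k g_k) / sum(g_k^2)`` with ``g_k`` the per-unit-P GHK shape.
    """
    v = np.asarray(v_mv, dtype=float)
    i = np.asarray(i_pa, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 voltage points to fit a permeability")
    g = ghk_shape(v, ctx)
    gg = float(np.dot(g, g))
    if gg == 0.0:
        raise ValueError("all GHK shape values are zero; voltages degenerate")
    p_hat = float(np.dot(i, g)) / gg
    resid = i - p_hat * g
    dof = max(v.size - 1, 1)
    sigma2 = float(np.dot(resid, resid)) / dof
    ss_tot = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    return GhkPermeabilityFit(p_hat=p_hat, p_se=float(np.sqrt(sigma2 / gg)),
                              r_squared=r2, residuals_pa=resid)


def invert_permeability(v_mv: float, i_pa: float, ctx: GHKContext,
                        shape_tol: float = 1e-3) -> float:
    """Solve the GHK equation for P at a single (V, I) point.

    Exact since the equation is linear in P.  At the reversal potential the
    shape vanishes: a non-zero current there is flagged as inconsistent, a
    zero current gives P = 0.  ``shape_tol`` is in pA per unit P relative to
    the shape at the far end of the curve.
    """
    g = float(ghk_shape(v_mv, ctx))
    scale = abs(float(ghk_shape(ctx.vrev_mv + 100.0, ctx)))
    if abs(g) < shape_tol * scale:
        if abs(i_pa) < 1e-9:
            return 0.0
        raise InconsistentPointError(
            f"current {i_pa:g} pA at the reversal potential (V = {v_mv:g} mV) "
            "cannot be attributed to the modelled ion"
        )
    return float(i_pa) / g


@dataclass
class PermeabilityCurve:
    """P(V) points for one cell, optionally normalized to fitted [0, 1]."""

    v_mv: np.ndarray
    p: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.v_mv = np.asarray(self.v_mv, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.v_mv.shape != self.p.shape:
            raise ValueError("voltage and permeability arrays differ in length")
        if np.any(np.diff(self.v_mv) <= 0):
            raise ValueError("voltages must be strictly increasing")


def boltzmann(v_mv, p_min, p_max, v_half, dv):
    """Two-state Boltzmann activation curve (rises toward p_max at positive V)."""
    v_mv = np.asarray(v_mv, dtype=float)
    return p_max + (p_min - p_max) / (1.0 + np.exp((v_mv - v_half) / dv))


@dataclass
class BoltzmannFit:
    p_min: float
    p_max: float
    v_half_mv: float
    dv_mv: float
    se: dict = field(default_factory=dict)
    residual_norm: float = float("nan")

    def normalize(self, curve: PermeabilityCurve) -> PermeabilityCurve:
        """Scale a curve to the fitted Pmin = 0, Pmax = 1."""
        span = self.p_max - self.p_min
        if span <= 0:
            raise ValueError("cannot normalize: fitted Pmax <= Pmin")
        return PermeabilityCurve(curve.v_mv, (curve.p - self.p_min) / span,
                                 normalized=True)


def fit_boltzmann(curve: PermeabilityCurve, n_restarts: int = 5,
                  ) -> tuple[BoltzmannFit, PermeabilityCurve]:
    """Fit the 4-parameter Boltzmann curve to P(V); return fit and normalized curve.

    Initialization: V1/2 at the voltage where P crosses half of its observed
    range, dV = 10 mV, Pmin/Pmax from the curve extremes; on failure the start
    is jittered for a bounded number of deterministic restarts.
    """
    v, p_raw = curve.v_mv, curve.p
    if v.size < 5:
        raise ValueError("need at least 5 points spanning the inflection")
    # whole-cell permeabilities are ~1e-17 m^3/s; rescale to O(1) so the
    # optimizer's trust region treats plateau and voltage parameters alike
    scale = float(np.max(np.abs(p_raw))) or 1.0
    p = p_raw / scale
    p_lo, p_hi = float(p.min()), float(p.max())
    half = (p_lo + p_hi) / 2.0
    above = np.nonzero(p >= half)[0]
    v_half0 = float(v[above[0]]) if above.size else float(np.median(v))
    span = p_hi - p_lo if p_hi > p_lo else max(abs(p_hi), 1.0)
    x0 = np.array([p_lo, p_hi, v_half0, 10.0])
    lower = [p_lo - 2 * span, p_lo - 2 * span, v.min() - 200.0, 1e-3]
    upper = [p_hi + 2 * span, p_hi + 2 * span, v.max() + 200.0, 500.0]

    rng = np.random.default_rng(0)  # jitter is deterministic by design
    last_err: Exception | None = None
    for attempt in range(n_restarts):
        start = x0 if attempt == 0 else x0 * (1 + 0.2 * rng.standard_normal(4))
        start = np.clip(start, lower, upper)
        try:
            popt, pcov = curve_fit(boltzmann, v, p, p0=start,
                                   bounds=(lower, upper), maxfev=20000)
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
            continue
        p_min, p_max, v_half, dv = popt
        if p_max < p_min:  # relabel the two plateaus
            p_min, p_max = p_max, p_min
        perr = np.sqrt(np.diag(pcov))
        resid = (p - boltzmann(v, *popt)) * scale
        fit = BoltzmannFit(
            p_min=float(p_min) * scale, p_max=float(p_max) * scale,
            v_half_mv=float(v_half), dv_mv=float(dv),
            se={"p_min": float(perr[0]) * scale, "p_max": float(perr[1]) * scale,
                "v_half_mv": float(perr[2]), "dv_mv": float(perr[3])},
            residual_norm=float(np.linalg.norm(resid)),
        )
        return fit, fit.normalize(curve)
    raise RuntimeError(
        f"Boltzmann fit failed after {n_restarts} restarts: {last_err}"
    )


def reversal_potential(v_mv, i_pa) -> float:
    """Zero-current voltage by linear interpolation between bracketing points."""
    v = np.asarray(v_mv, dtype=float)
    i = np.asarray(i_pa, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    exact = np.nonzero(i == 0.0)[0]
    if exact.size:
        return float(v[exact[0]])
    sign_change = np.nonzero(np.diff(np.sign(i)) != 0)[0]
    if not sign_change.size:
        raise ValueError("current does not change sign across the voltage range")
    k = sign_change[0]
    frac = -i[k] / (i[k + 1] - i[k])
    return float(v[k] + frac * (v[k + 1] - v[k]))


def qc_reversal_filter(reversals: dict[str, float], e_cl_mv: float,
                       max_positive_shift_mv: float = 15.0,
                       ) -> tuple[list[str], list[tuple[str, str]]]:
    """Exclude cells whose I-V reverses far positive of the Cl- equilibrium.

    ``reversals`` maps cell id to the instantaneous-I-V reversal estimate.
    Returns (included ids, excluded (id, reason) pairs); exclusions carry the
    measured shift so the run log can record why a cell was dropped.
    """
    included: list[str] = []
    excluded: list[tuple[str, str]] = []
    for cell_id, vrev in reversals.items():
        shift = vrev - e_cl_mv
        if shift > max_positive_shift_mv:
            excluded.append((
                cell_id,
                f"reversal {vrev:+.1f} mV is {shift:.1f} mV positive of "
                f"E_Cl = {e_cl_mv:+.1f} mV (limit {max_positive_shift_mv:g} mV)",
            ))
        else:
            included.append(cell_id)
    return included, excluded


def percent_inhibition(i_control_pa: float, i_treated_pa: float) -> float:
    """Percent block of a current by an inhibitor: 100 (1 - I_treated/I_control)."""
    if i_control_pa == 0:
        raise ValueError("control current is zero; inhibition undefined")
    return 100.0 * (1.0 - i_treated_pa / i_control_pa)


def summarize_inhibition(pairs) -> tuple[float, float]:
    """Mean +- s.e.m. percent inhibition over paired (control, treated) currents."""
    values = np.array([percent_inhibition(c, t) for c, t in pairs], dtype=float)
    if values.size == 0:
        raise ValueError("no current pairs supplied")
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return float(values.mean()), sem
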