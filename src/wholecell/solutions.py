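"""Recording solutions: ion concentrations, Nernst potentials, junction potentials.

A :class:`SolutionComposition` is a recipe of salts (in mM) as a solution would
be written on a whiteboard in a patch-clamp rig.  Salts dissociate with fixed
stoichiometry into transported ions; buffers, chelators, sugars and ATP salts
are carried along as metadata but excluded from charge transport.  From the
per-ion concentration maps the module computes Nernst equilibrium potentials
and generalized-Henderson liquid junction potentials (Vlj), the latter in the
convention used to correct command potentials, ``Vm = Vout - Vlj`` (Vlj =
potential of the bath relative to the pipette).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from scipy.constants import R as GAS_CONSTANT  # J / (mol K)
from scipy.constants import physical_constants

FARADAY = physical_constants["Faraday constant"][0]  # C / mol

#: default recording temperature, K ("room temperature", mid-range of 18-23 C)
DEFAULT_TEMPERATURE_K = 295.0

# Fixed dissociation stoichiometry: salt formula -> [(ion, charge, count), ...].
SALT_DISSOCIATION: dict[str, list[tuple[str, int, int]]] = {
    "NaCl": [("Na", 1, 1), ("Cl", -1, 1)],
    "KCl": [("K", 1, 1), ("Cl", -1, 1)],
    "CsCl": [("Cs", 1, 1), ("Cl", -1, 1)],
    "CaCl2": [("Ca", 2, 1), ("Cl", -1, 2)],
    "MgCl2": [("Mg", 2, 1), ("Cl", -1, 2)],
    "CsAsp": [("Cs", 1, 1), ("Asp", -1, 1)],
    "NMDG-Cl": [("NMDG", 1, 1), ("Cl", -1, 1)],
}

# Species carried in recipes but treated as non-transported (neutral, chelator,
# zwitterionic buffer, or bulky ATP salt); overridable by extending
# SALT_DISSOCIATION before building the ion map.
NEUTRAL_SPECIES = frozenset(
    {"glucose", "mannitol", "HEPES", "EGTA", "Na2ATP", "NaATP", "MgATP", "sucrose"}
)


class UnknownSaltError(ValueError):
    """A salt formula is neither in the dissociation table nor a neutral species."""


class MissingMobilityError(KeyError):
    """An ion present in a solution has no entry in the mobility table."""


@dataclass(frozen=True)
class IonSpecies:
    """One transported ion and its limiting molar conductivity.

    ``limiting_molar_conductivity`` is per mole of ion (S cm^2 mol^-1), not per
    equivalent; divalents therefore carry values near twice the familiar
    equivalent conductances.
    """

    name: str
    charge: int
    limiting_molar_conductivity: float

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"ion {self.name!r} must carry a non-zero charge")
        if self.limiting_molar_conductivity <= 0:
            raise ValueError(f"ion {self.name!r} needs a positive conductivity")


@dataclass
class SolutionComposition:
    """A pipette or bath solution as a list of (salt formula, mM) pairs."""

    name: str
    salts: list[tuple[str, float]]
    pH: float | None = None
    osmolality_mosm_kg: float | None = None
    temperature_k: float = DEFAULT_TEMPERATURE_K
    #: free Ca2+ set by the chelator system, uM; metadata for the simulator
    free_ca_um: float | None = None
    neutral: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for formula, conc in self.salts:
            if conc < 0:
                raise ValueError(f"negative concentration for {formula!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SolutionComposition":
        """Read a solution recipe from JSON (``{"name":..., "salts": [[salt, mM], ...]}``)."""
        data = json.loads(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SolutionComposition":
        return cls(
            name=data["name"],
            salts=[(str(s), float(c)) for s, c in data["salts"]],
            pH=data.get("pH"),
            osmolality_mosm_kg=data.get("osmolality_mosm_kg"),
            temperature_k=data.get("temperature_k", DEFAULT_TEMPERATURE_K),
            free_ca_um=data.get("free_ca_um"),
            neutral=dict(data.get("neutral", {})),
        )


def ion_concentrations(solution: SolutionComposition) -> dict[str, float]:
    """Expand a salt recipe into the per-ion concentration map (mM).

    Neutral species are skipped; an unknown salt raises
    :class:`UnknownSaltError` naming it.
    """
    ions: dict[str, float] = {}
    for formula, conc in solution.salts:
        if formula in NEUTRAL_SPECIES:
            continue
        try:
            parts = SALT_DISSOCIATION[formula]
        except KeyError:
            raise UnknownSaltError(
                f"no dissociation rule for salt {formula!r} in solution {solution.name!r}"
            ) from None
        for ion, _charge, count in parts:
            ions[ion] = ions.get(ion, 0.0) + count * conc
    return ions


def ion_charges(solution: SolutionComposition) -> dict[str, int]:
    """Charge of every transported ion appearing in the solution."""
    charges: dict[str, int] = {}
    for formula, _conc in solution.salts:
        for ion, charge, _count in SALT_DISSOCIATION.get(formula, []):
            charges[ion] = charge
    return charges


def nernst_potential(z: int, co_mm: float, ci_mm: float,
                     temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Equilibrium potential (RT/zF) ln(Co/Ci), in mV.

    Parameters are the ion valence and its outside/inside concentrations in mM.
    """
    if z == 0:
        raise ValueError("valence must be non-zero")
    if co_mm <= 0 or ci_mm <= 0:
        raise ValueError("concentrations must be positive for a Nernst potential")
    return 1e3 * GAS_CONSTANT * temperature_k / (z * FARADAY) * math.log(co_mm / ci_mm)


def load_mobility_table(path: str | Path | None = None) -> dict[str, IonSpecies]:
    """Load the limiting-molar-conductivity table (CSV: ion,charge,lambda).

    Without a path, the packaged table of standard values is used.  The file is
    deliberately editable data, not code: organic-anion mobilities differ
    between published junction-potential tables.
    """
    if path is None:
        source = resources.files("wholecell").joinpath("data/mobilities.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, IonSpecies] = {}
    for row in csv.DictReader(text.splitlines()):
        table[row["ion"]] = IonSpecies(
            name=row["ion"],
            charge=int(row["charge"]),
            limiting_molar_conductivity=float(row["lambda_s_cm2_per_mol"]),
        )
    return table


def junction_potential_henderson(
    pipette: SolutionComposition,
    bath: SolutionComposition,
    mobility_table: dict[str, IonSpecies] | None = None,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Liquid junction potential Vlj (mV) of the bath relative to the pipette.

    Generalized Henderson equation over all transported ions of both solutions,

    ``Vlj = (RT/F) * [sum_i sgn(z_i) l_i dc_i / sum_i |z_i| l_i dc_i]
            * ln(sum_i |z_i| l_i c_i(pip) / sum_i |z_i| l_i c_i(bath))``

    with ``dc_i = c_i(bath) - c_i(pip)`` and ``l_i`` the limiting molar
    conductivity (the |z| weighting is the z^2 u_i mobility weighting written
    in terms of per-mole conductivities).  The result is applied to command
    potentials as ``Vm = Vout - Vlj``.
    """
    if mobility_table is None:
        mobility_table = load_mobility_table()
    pip_ions = ion_concentrations(pipette)
    bath_ions = ion_concentrations(bath)
    names = sorted(set(pip_ions) | set(bath_ions))
    if not names:
        return 0.0

    num = den = s_pip = s_bath = 0.0
    for name in names:
        try:
            species = mobility_table[name]
        except KeyError:
            raise MissingMobilityError(
                f"no mobility entry for ion {name!r}; add it to the mobility table"
            ) from None
        lam = species.limiting_molar_conductivity
        z = species.charge
        cp = pip_ions.get(name, 0.0)
        cb = bath_ions.get(name, 0.0)
        dc = cb - cp
        num += math.copysign(1.0, z) * lam * dc
        den += abs(z) * lam * dc
        s_pip += abs(z) * lam * cp
        s_bath += abs(z) * lam * cb

    if s_pip <= 0 or s_bath <= 0:
        raise ValueError("both solutions need at least one transported ion")
    log_term = math.log(s_pip / s_bath)
    if den == 0.0:
        # identical ionic strength-conductance profile on both sides
        return 0.0
    return 1e3 * GAS_CONSTANT * temperature_k / FARADAY * (num / den) * log_term


def load_reference_solution(key: str) -> SolutionComposition:
    """Load one of the packaged recording-solution recipes by key.

    Keys: ``pipette_ca_1um``, ``pipette_ca_0``, ``bath_standard``,
    ``bath_isotonic``, ``bath_hypotonic``, ``bath_krebs``.
    """
    source = resources.files("wholecell").joinpath(f"data/solutions/{key}.json")
    try:
        text = source.read_text()
    except FileNotFoundError:
        raise KeyError(f"no packaged solution named {key!r}") from None
    return SolutionComposition.from_dict(json.loads(text))
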