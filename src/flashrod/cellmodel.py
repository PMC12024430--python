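"""Cell-water composition, pulse geometry, dose arithmetic and unit bridges.

The irradiation geometry is a Dirac (zero-duration) pulse of N monoenergetic
low-LET protons travelling parallel to the axis of a water cylinder of radius
R_o and length L.  Every proton deposits LET x L of energy inside the
cylinder, so the absorbed dose is strictly linear in N and LET and the
per-pulse fluence is N / (pi R_o^2).

Radiation-chemical yields G (molecules per 100 eV) convert to concentrations
through C = rho * D * G with 1 molecule/100 eV = 0.103364 umol/J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "CellComposition",
    "PulseSpec",
    "DoseReport",
    "DEFAULT_HANDOFF_YIELDS",
    "G_TO_UMOL_PER_J",
    "pulse_dose",
    "g_to_concentration",
    "concentration_to_g",
    "direct_radical_concentration",
    "initial_state",
]

#: 1 molecule per 100 eV expressed in umol/J (1e8 / (N_A * e))
G_TO_UMOL_PER_J = 0.103364

EV_TO_J = 1.602176634e-19
KEV_TO_J = 1.602176634e-16

#: reference pulse intensity for the direct-ionization radical pool
_REFERENCE_N = 20
#: direct-effect carbon radical concentration at the N=20 reference pulse, M
_REFERENCE_R_DIRECT = 2.5e-6

#: hand-off yields for homogeneous-mode runs, molecules/100 eV at ~1 ns.
#: Literature-informed early-time water radiolysis yields for low LET; the
#: hydroxyl and electron entries are the two calibration degrees of freedom
#: (see pipeline.calibrate_initial_yields).  Electroneutrality holds by
#: construction: G(H3O+) = G(e_aq) + G(OH-).
DEFAULT_HANDOFF_YIELDS: dict[str, float] = {
    "e_aq": 4.0,
    "OH_r": 4.8,
    "H_r": 0.62,
    "H2": 0.40,
    "H2O2": 0.50,
    "H3O_p": 4.5,
    "OH_m": 0.5,
}


@dataclass(frozen=True)
class CellComposition:
    """Resting solute concentrations of the cell-water model, molar.

    ``rh`` is the generic oxidizable-substrate pool (proteins, lipids,
    nucleic acids lumped into one species); 0.5 M is the documented
    heterogeneity variant.  ``r_direct_reference`` is the carbon-radical
    pool created by direct ionization of RH at the reference N=20 pulse.
    """

    o2: float = 30e-6
    rh: float = 1.0
    gsh: float = 6.5e-3
    ah: float = 1e-3
    no: float = 1e-6
    toh: float = 2e-4
    r_direct_reference: float = _REFERENCE_R_DIRECT

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValueError(f"negative concentration for {name}")

    def as_dict(self) -> dict[str, float]:
        return {
            "O2": self.o2,
            "RH": self.rh,
            "GSH": self.gsh,
            "AH_m": self.ah,
            "NO_r": self.no,
            "TOH": self.toh,
        }

    def with_rh(self, rh: float) -> "CellComposition":
        return replace(self, rh=rh)


@dataclass(frozen=True)
class PulseSpec:
    """One instantaneous pulse: N protons, LET keV/um, cylinder R_o x L um."""

    N: int = 20
    LET: float = 0.3
    R_o: float = 0.1
    L: float = 1.0
    rho: float = 1.0  # kg/L
    label_energy: str = "300 MeV protons"

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if min(self.LET, self.R_o, self.L, self.rho) <= 0:
            raise ValueError("LET, R_o, L and rho must be > 0")

    @property
    def fluence(self) -> float:
        """Protons per um^2, N / (pi R_o^2)."""
        return self.N / (math.pi * self.R_o**2)

    @property
    def volume_l(self) -> float:
        """Cylinder volume in litres (1 um^3 = 1e-15 L)."""
        return math.pi * self.R_o**2 * self.L * 1e-15

    def with_n(self, N: int) -> "PulseSpec":
        return replace(self, N=N)


@dataclass(frozen=True)
class DoseReport:
    dose: float  # Gy
    energy_deposited_ev: float
    mass_kg: float


def pulse_dose(pulse: PulseSpec) -> DoseReport:
    """Absorbed dose of one pulse: N tracks each depositing LET x L.

    The energy goes into the cylinder mass rho * pi * R_o^2 * L, so the track
    length cancels and dose = N * LET * 1.602e-16 / (rho * pi * R_o^2) with
    LET in keV/um and R_o in um.
    """
    energy_kev = pulse.N * pulse.LET * pulse.L  # keV
    mass_kg = pulse.rho * math.pi * pulse.R_o**2 * pulse.L * 1e-15  # kg (rho kg/L)
    dose = energy_kev * KEV_TO_J / mass_kg
    return DoseReport(dose=dose, energy_deposited_ev=energy_kev * 1e3, mass_kg=mass_kg)


def g_to_concentration(G: float, dose: float, rho: float = 1.0) -> float:
    """Convert a yield (molecules/100 eV) to molar via C = rho * D * G."""
    return rho * dose * G * G_TO_UMOL_PER_J * 1e-6


def concentration_to_g(conc: float, dose: float, rho: float = 1.0) -> float:
    """Inverse of :func:`g_to_concentration` (undefined at zero dose)."""
    return conc * 1e6 / (rho * dose * G_TO_UMOL_PER_J)


def eq8_depleted_oxygen(N: int, LET: float, G_minus_o2: float) -> float:
    """Depleted-oxygen concentration in mM from the compact dose relation.

    [-O2] ~= 5.3e-4 * N * LET * G(-O2); the constant is the geometry factor
    rho * dose_per(N*LET) * 0.103364 rounded to two figures, so this agrees
    with composing pulse_dose and g_to_concentration to within ~1%.
    """
    return 5.3e-4 * N * LET * G_minus_o2


def direct_radical_concentration(
    pulse: PulseSpec, composition: CellComposition | None = None
) -> float:
    """Direct-ionization R pool, molar: 2.5 uM at N=20 scaled with dose."""
    composition = composition or CellComposition()
    reference = pulse_dose(replace(pulse, N=_REFERENCE_N)).dose
    if reference == 0:
        return 0.0
    return composition.r_direct_reference * pulse_dose(pulse).dose / reference


def initial_state(
    composition: CellComposition,
    pulse: PulseSpec,
    yields0: dict[str, float] | None = None,
    charge_tolerance: float = 1e-9,
    species_charges: dict[str, int] | None = None,
) -> dict[str, float]:
    """Homogeneous-stage initial concentrations, molar, keyed by species.

    Combines the resting solutes, the radiolytic products at their hand-off
    yields converted through the pulse dose, and the direct-effect carbon
    radical pool.  The radiolytic yields must be electroneutral; the check
    uses the bundled primary-species charges unless ``species_charges``
    supplies others.
    """
    yields0 = DEFAULT_HANDOFF_YIELDS if yields0 is None else yields0
    charges = species_charges or {
        "e_aq": -1, "OH_r": 0, "H_r": 0, "H2": 0, "H2O2": 0,
        "H3O_p": 1, "OH_m": -1, "O2_rm": -1,
    }
    imbalance = sum(charges.get(name, 0) * G for name, G in yields0.items())
    if abs(imbalance) > charge_tolerance * max(1.0, sum(map(abs, yields0.values()))):
        raise ValueError(f"radiolytic hand-off yields not electroneutral: {imbalance:+.3g}")

    dose = pulse_dose(pulse).dose
    state = dict(composition.as_dict())
    for name, G in yields0.items():
        state[name] = state.get(name, 0.0) + g_to_concentration(G, dose, pulse.rho)
    state["R_r"] = state.get("R_r", 0.0) + direct_radical_concentration(pulse, composition)
    return state
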