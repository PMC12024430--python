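"""Deterministic homogeneous kinetics with exact per-reaction flux accounting.

The reaction network is turned into mass-action rate equations and integrated
with a stiff implicit solver jointly with the vector of cumulative reaction
extents xi_r(t), so that the species balance

    c_s(t) - c_s(t0) = sum_r S_{s,r} xi_r(t)

holds to integrator tolerance at every output time (ledger closure).  The
extents, converted to G units through the run's dose, are the per-reaction
contributions plotted in flux-decomposition figures.

Rate-law convention for self-reactions: for 2A -> P the printed k is the rate
constant of the elementary event, rate = k [A]^2, hence d[A]/dt = -2 k [A]^2.
Conventions in the literature differ by this factor of two; the stoichiometric
matrix carries the -2.

Diffusion scaling: reactions classified diffusion_influenced respond to a
global ``diffusion_scale`` s through the Collins-Kimball relation
1/k = 1/k_act + 1/(s k_diff).  By default the printed constant is taken as
fully diffusion limited (k_act -> infinity, encounter radius from Smoluchowski
inversion), so k scales linearly with s; an explicit activation-controlled
component can be supplied per reaction label to soften the scaling.
Activation-controlled reactions are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .cellmodel import PulseSpec, concentration_to_g, pulse_dose
from .scheme import ReactionScheme

__all__ = [
    "RateSystem",
    "YieldTimeSeries",
    "FluxLedger",
    "IntegrationError",
    "build_rate_system",
    "integrate",
    "log_time_grid",
    "oxygen_depletion_curve",
    "flux_decomposition",
    "peroxyl_termination_fractions",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the last time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


def log_time_grid(t0: float = 1e-9, t_end: float = 1.0, points_per_decade: int = 60) -> np.ndarray:
    """Logarithmic output grid from t0 to t_end (inclusive)."""
    n = int(np.ceil(np.log10(t_end / t0) * points_per_decade)) + 1
    return np.logspace(np.log10(t0), np.log10(t_end), n)


class RateSystem:
    """Mass-action rate equations compiled from a reaction scheme."""

    def __init__(self, scheme: ReactionScheme, k_eff: np.ndarray, diffusion_scale: float):
        self.scheme = scheme
        self.diffusion_scale = diffusion_scale
        self.species_names = scheme.species_names
        self.reaction_labels = [r.label for r in scheme.reactions]
        self.k = np.asarray(k_eff, dtype=float)
        self.S = scheme.stoichiometric_matrix()
        n_r = len(scheme.reactions)
        self._i1 = np.empty(n_r, dtype=int)
        self._i2 = np.empty(n_r, dtype=int)
        for j, rxn in enumerate(scheme.reactions):
            self._i1[j] = scheme.index(rxn.reactants[0])
            self._i2[j] = scheme.index(rxn.reactants[1]) if len(rxn.reactants) == 2 else -1

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_labels)

    def rates(self, conc: np.ndarray) -> np.ndarray:
        c = np.maximum(conc, 0.0)
        r = self.k * c[self._i1]
        bi = self._i2 >= 0
        r[bi] *= c[self._i2[bi]]
        return r

    def rhs(self, conc: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(conc)

    def rate_jacobian(self, conc: np.ndarray) -> np.ndarray:
        """d(rates)/d(conc), shape (n_reactions, n_species)."""
        c = np.maximum(conc, 0.0)
        J = np.zeros((self.n_reactions, self.n_species))
        rows = np.arange(self.n_reactions)
        bi = self._i2 >= 0
        # unimolecular: d(k c1)/dc1 = k
        J[rows[~bi], self._i1[~bi]] = self.k[~bi]
        # bimolecular: d(k c1 c2)/dc1 = k c2 and vice versa (adds 2kc for self)
        np.add.at(J, (rows[bi], self._i1[bi]), self.k[bi] * c[self._i2[bi]])
        np.add.at(J, (rows[bi], self._i2[bi]), self.k[bi] * c[self._i1[bi]])
        return J


def build_rate_system(
    scheme: ReactionScheme,
    diffusion_scale: float = 1.0,
    activation_rates: dict[str, float] | None = None,
) -> RateSystem:
    """Compile a scheme into a rate system at a given diffusion scale.

    ``activation_rates`` optionally maps reaction labels to intrinsic
    activation-controlled constants k_act (M^-1 s^-1) for diffusion-influenced
    reactions whose printed k is not fully diffusion limited.
    """
    activation_rates = activation_rates or {}
    k_eff = np.empty(len(scheme.reactions))
    for j, rxn in enumerate(scheme.reactions):
        if rxn.kinetic_class != "diffusion_influenced" or diffusion_scale == 1.0:
            k_eff[j] = rxn.k
            continue
        k_act = activation_rates.get(rxn.label, np.inf)
        if not np.isfinite(k_act):
            # fully diffusion limited: 1/k = 1/(s k_diff) with k_diff = printed k
            k_eff[j] = diffusion_scale * rxn.k
        else:
            if k_act <= rxn.k:
                raise ValueError(f"{rxn.label}: k_act must exceed the observed k")
            k_diff = 1.0 / (1.0 / rxn.k - 1.0 / k_act)
            k_eff[j] = 1.0 / (1.0 / k_act + 1.0 / (diffusion_scale * k_diff))
    return RateSystem(scheme, k_eff, diffusion_scale)


@dataclass
class YieldTimeSeries:
    """Concentrations (M) on a time grid with yield-unit conversion."""

    times: np.ndarray
    species_names: list[str]
    conc: np.ndarray  # (n_times, n_species)
    dose: float  # Gy
    rho: float = 1.0
    se: np.ndarray | None = None  # optional, same shape as conc

    def __getitem__(self, species: str) -> np.ndarray:
        return self.conc[:, self.species_names.index(species)]

    def g_values(self, species: str) -> np.ndarray:
        """Yields in molecules/100 eV (relative to zero, not to t0)."""
        return concentration_to_g(self[species], self.dose, self.rho)

    def at_time(self, t: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.times - t)))
        return dict(zip(self.species_names, self.conc[i]))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.conc, columns=self.species_names)
        df.insert(0, "time_s", self.times)
        return df


@dataclass
class FluxLedger:
    """Cumulative extents xi_r(t) in M per reaction, with G conversion."""

    times: np.ndarray
    reaction_labels: list[str]
    xi: np.ndarray  # (n_times, n_reactions)
    S: np.ndarray  # (n_species, n_reactions)
    species_names: list[str]
    dose: float
    rho: float = 1.0

    def extent(self, label: str) -> np.ndarray:
        return self.xi[:, self.reaction_labels.index(label)]

    def extent_g(self, label: str) -> np.ndarray:
        return concentration_to_g(self.extent(label), self.dose, self.rho)

    def closure_residual(self, series: YieldTimeSeries, species: str) -> np.ndarray:
        """|c_s(t) - c_s(t0) - sum_r S_sr xi_r(t)| in M at each time."""
        i = self.species_names.index(species)
        predicted = series.conc[0, i] + self.xi @ self.S[i]
        return np.abs(series.conc[:, i] - predicted)


def integrate(
    system: RateSystem,
    state0: dict[str, float] | np.ndarray,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-18,
    dose: float | None = None,
    rho: float = 1.0,
) -> tuple[YieldTimeSeries, FluxLedger]:
    """Stiff integration of the augmented system [conc; extents].

    ``state0`` may be a dict keyed by species name (missing species start at
    zero).  ``dose`` (Gy) sets the concentration<->G conversion of the outputs
    and defaults to 1 Gy when not given.  Small negative excursions are
    clipped at zero; excursions beyond 1e3*atol abort.
    """
    if t_grid is None:
        t_grid = log_time_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    n_s, n_r = system.n_species, system.n_reactions
    if isinstance(state0, dict):
        c0 = np.zeros(n_s)
        for name, conc in state0.items():
            c0[system.species_names.index(name)] = conc
    else:
        c0 = np.asarray(state0, dtype=float)
    if np.any(c0 < 0):
        raise ValueError("negative initial concentrations")

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        r = system.rates(y[:n_s])
        return np.concatenate([system.S @ r, r])

    def jac(_t: float, y: np.ndarray) -> np.ndarray:
        Jr = system.rate_jacobian(y[:n_s])
        J = np.zeros((n_s + n_r, n_s + n_r))
        J[:n_s, :n_s] = system.S @ Jr
        J[n_s:, :n_s] = Jr
        return J

    y0 = np.concatenate([c0, np.zeros(n_r)])
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        method="BDF",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t_grid[0]
        raise IntegrationError(f"stiff solver failed: {sol.message}", last_time=last)

    conc = sol.y[:n_s].T.copy()
    worst = conc.min()
    # undershoot is governed by rtol on ~uM species, not atol; floor the guard
    if worst < -max(1e3 * atol, 1e-11):
        raise IntegrationError(
            f"negative concentration {worst:.3e} M beyond guard band", last_time=sol.t[-1]
        )
    conc = np.clip(conc, 0.0, None)
    dose = 1.0 if dose is None else dose
    series = YieldTimeSeries(sol.t, list(system.species_names), conc, dose=dose, rho=rho)
    ledger = FluxLedger(
        sol.t,
        list(system.reaction_labels),
        sol.y[n_s:].T.copy(),
        system.S,
        list(system.species_names),
        dose=dose,
        rho=rho,
    )
    return series, ledger


def oxygen_depletion_curve(
    series: YieldTimeSeries, ledger: FluxLedger, pulse: PulseSpec
) -> pd.DataFrame:
    """Net oxygen depletion over time: G(-O2) and [-O2].

    G(-O2)(t) = ([O2](t0) - [O2](t)) / (rho * D * 0.103364 umol/J); the
    concentration column is the same depletion re-expressed in molar, which
    coincides with the compact N*LET form of the dose relation.
    """
    dose = pulse_dose(pulse).dose
    o2 = series["O2"]
    depleted = o2[0] - o2
    g_minus = (
        np.zeros_like(depleted)
        if dose == 0
        else np.array([concentration_to_g(d, dose, pulse.rho) for d in depleted])
    )
    return pd.DataFrame(
        {"time_s": series.times, "g_minus_o2": g_minus, "depleted_o2_m": depleted}
    )


def flux_decomposition(ledger: FluxLedger, species: str) -> pd.DataFrame:
    """Signed per-reaction contributions to a species' net yield change.

    Returns one row per reaction touching the species with its stoichiometric
    coefficient, the final signed contribution in G units and in molar, and a
    formation/consumption tag.  The signed contributions sum to the net
    change of the species (ledger closure).
    """
    if species not in ledger.species_names:
        raise KeyError(f"unknown species {species!r}")
    i = ledger.species_names.index(species)
    rows = []
    for j, label in enumerate(ledger.reaction_labels):
        s = ledger.S[i, j]
        if s == 0:
            continue
        contrib_m = s * ledger.xi[-1, j]
        rows.append(
            {
                "reaction": label,
                "stoichiometry": s,
                "role": "formation" if s > 0 else "consumption",
                "delta_m": contrib_m,
                "delta_g": concentration_to_g(contrib_m, ledger.dose, ledger.rho),
            }
        )
    return pd.DataFrame(rows).sort_values("delta_g", ascending=False, ignore_index=True)


def peroxyl_termination_fractions(ledger: FluxLedger) -> pd.Series:
    """Fraction of peroxyl-radical (ROO) removal per terminating reaction.

    Chain transfer to the substrate (R10, ROO + RH -> ROOH + R) regenerates a
    carbon radical that mostly re-forms ROO, so it propagates rather than
    terminates the peroxidation chain; it is excluded from the normalization.
    The remaining consumption channels (antioxidant H-donation, radical
    cross/self recombination) are genuine chain breakers.
    """
    dec = flux_decomposition(ledger, "ROO_r")
    cons = dec[(dec.role == "consumption") & (dec.reaction != "R10")]
    total = -cons["delta_m"].sum()
    if total <= 0:
        return pd.Series(dtype=float)
    return (-cons.set_index("reaction")["delta_m"] / total).sort_values(ascending=False)
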