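"""Chemical reaction scheme: species registry, reactions, conservation audits.

The bundled scheme couples the antioxidant/peroxidation chemistry of an
aerated cell-water model (generic oxidizable substrate RH, glutathione,
ascorbate, nitric oxide, alpha-tocopherol, dissolved O2) to a standard
pure-water radiolysis core (hydrated electron, H atom, hydroxyl radical,
peroxide, water ions).  Every reaction is an elementary uni- or bimolecular
step; H+ co-substrates are treated as an implicit buffered pool at pH 7, and
HO2./O2.- are lumped into the superoxide anion (pKa 4.8 << 7).

Conservation audits are machine-checkable: each named moiety map (glutathione
backbone, ascorbate skeleton, R carbon, NO nitrogen, tocopherol chromanol)
must lie in the left null space of the stoichiometric matrix, and each
reaction must balance elementary charge once implicit protons are credited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionScheme",
    "ValidationReport",
    "SchemeParseError",
    "builtin_cell_scheme",
    "load_scheme",
    "save_scheme",
    "validate_scheme",
]

CATEGORIES = ("primary_radiolytic", "cellular_solute", "product")
KINETIC_CLASSES = ("diffusion_influenced", "activation_controlled")

#: conventional partition between diffusion-influenced and activation-
#: controlled bimolecular steps (Collins-Kimball picture), M^-1 s^-1
DIFFUSION_CLASS_THRESHOLD = 1.0e9


class SchemeParseError(ValueError):
    """Malformed scheme file; message names the offending line."""


@dataclass(frozen=True)
class Species:
    """A chemical species tracked by the model.

    ``diffusion_coefficient`` is in m^2/s and is used only by the stochastic
    spur stage and by diffusion-scaling of rate constants; ``None`` marks a
    terminal sink that never reacts further and therefore needs no mobility.
    """

    name: str
    charge: int
    diffusion_coefficient: float | None
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.diffusion_coefficient is not None and self.diffusion_coefficient <= 0:
            raise ValueError(f"diffusion coefficient must be > 0 for {self.name}")

    @property
    def terminal(self) -> bool:
        return self.diffusion_coefficient is None


@dataclass(frozen=True)
class Reaction:
    """An elementary reaction with at most two mobile reactants.

    ``k`` is in M^-1 s^-1 for bimolecular steps and s^-1 for unimolecular
    ones.  ``implicit_protons`` counts buffered H+ consumed on the reactant
    side (negative values mean H+ released); it enters only the charge audit.
    """

    label: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float
    kinetic_class: str
    implicit_protons: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (1 <= len(self.reactants) <= 2):
            raise ValueError(f"{self.label}: needs 1 or 2 reactants")
        if self.k <= 0:
            raise ValueError(f"{self.label}: rate constant must be > 0")
        if self.kinetic_class not in KINETIC_CLASSES:
            raise ValueError(f"{self.label}: unknown kinetic class {self.kinetic_class!r}")

    @property
    def unimolecular(self) -> bool:
        return len(self.reactants) == 1

    @property
    def self_reaction(self) -> bool:
        return len(self.reactants) == 2 and self.reactants[0] == self.reactants[1]

    def net_stoichiometry(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for s in self.reactants:
            net[s] = net.get(s, 0) - 1
        for s in self.products:
            net[s] = net.get(s, 0) + 1
        return {s: n for s, n in net.items() if n != 0}


@dataclass
class ValidationReport:
    moiety_violations: list[tuple[str, str]] = field(default_factory=list)
    charge_violations: list[str] = field(default_factory=list)
    orphan_species: list[tuple[str, str]] = field(default_factory=list)
    duplicate_labels: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.moiety_violations
            or self.charge_violations
            or self.orphan_species
            or self.duplicate_labels
        )


class ReactionScheme:
    """Ordered registry of species and reactions plus named moiety maps."""

    def __init__(
        self,
        species: Iterable[Species],
        reactions: Iterable[Reaction],
        moiety_maps: Mapping[str, Mapping[str, int]] | None = None,
    ) -> None:
        self.species: dict[str, Species] = {}
        for sp in species:
            if sp.name in self.species:
                raise ValueError(f"duplicate species {sp.name!r}")
            self.species[sp.name] = sp
        self.reactions: list[Reaction] = list(reactions)
        self.moiety_maps: dict[str, dict[str, int]] = {
            name: dict(mm) for name, mm in (moiety_maps or {}).items()
        }
        self._index = {sp: i for i, sp in enumerate(self.species)}

    # -- lookups ---------------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return list(self.species)

    def index(self, name: str) -> int:
        return self._index[name]

    def reaction(self, label: str) -> Reaction:
        for r in self.reactions:
            if r.label == label:
                return r
        raise KeyError(f"no reaction labelled {label!r}")

    def __contains__(self, label: str) -> bool:
        return any(r.label == label for r in self.reactions)

    def __len__(self) -> int:
        return len(self.reactions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionScheme):
            return NotImplemented
        return (
            self.species == other.species
            and self.reactions == other.reactions
            and self.moiety_maps == other.moiety_maps
        )

    # -- linear algebra --------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometry S, shape (n_species, n_reactions)."""
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for name, n in rxn.net_stoichiometry().items():
                S[self._index[name], j] = n
        return S

    def moiety_vector(self, moiety: str) -> np.ndarray:
        v = np.zeros(len(self.species))
        for name, count in self.moiety_maps[moiety].items():
            v[self._index[name]] = count
        return v

    def with_reaction_replaced(self, label: str, new: Reaction) -> "ReactionScheme":
        """Copy of the scheme with one reaction swapped (audit fixtures)."""
        reactions = [new if r.label == label else r for r in self.reactions]
        return ReactionScheme(self.species.values(), reactions, self.moiety_maps)


def validate_scheme(scheme: ReactionScheme) -> ValidationReport:
    """Audit moiety conservation, charge balance and referential integrity.

    Violations are reported as data, never raised.
    """
    report = ValidationReport()

    seen: set[str] = set()
    for rxn in scheme.reactions:
        if rxn.label in seen:
            report.duplicate_labels.append(rxn.label)
        seen.add(rxn.label)
        for name in (*rxn.reactants, *rxn.products):
            if name not in scheme.species:
                report.orphan_species.append((rxn.label, name))

    for rxn in scheme.reactions:
        if any(n not in scheme.species for n in (*rxn.reactants, *rxn.products)):
            continue  # orphan already reported; balances unverifiable
        q_in = sum(scheme.species[n].charge for n in rxn.reactants) + rxn.implicit_protons
        q_out = sum(scheme.species[n].charge for n in rxn.products)
        if q_in != q_out:
            report.charge_violations.append(rxn.label)
        for moiety, mm in scheme.moiety_maps.items():
            balance = sum(n * mm.get(name, 0) for name, n in rxn.net_stoichiometry().items())
            if balance != 0:
                report.moiety_violations.append((rxn.label, moiety))

    return report


# ---------------------------------------------------------------------------
# serialization: TSV dialect with [species] / [reactions] / [moieties] blocks
# ---------------------------------------------------------------------------

def _parse_float(text: str, where: str) -> float:
    try:
        value = float(text)
    except ValueError as exc:
        raise SchemeParseError(f"{where}: bad number {text!r}") from exc
    if not math.isfinite(value):
        raise SchemeParseError(f"{where}: non-finite number {text!r}")
    return value


def load_scheme(path: str | Path) -> ReactionScheme:
    """Parse a scheme file in the documented TSV dialect.

    Raises :class:`SchemeParseError` naming the line for malformed rows, and
    ``ValueError`` listing orphans if a reaction references an undeclared
    species.
    """
    species: list[Species] = []
    reactions: list[Reaction] = []
    moieties: dict[str, dict[str, int]] = {}
    block = None
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            block = line[1:-1]
            if block not in ("species", "reactions", "moieties"):
                raise SchemeParseError(f"line {lineno}: unknown block {block!r}")
            continue
        where = f"line {lineno}"
        cols = line.split("\t")
        if block == "species":
            if len(cols) != 4:
                raise SchemeParseError(f"{where}: species rows need 4 columns, got {len(cols)}")
            name, charge, dcol, category = cols
            D = None if dcol == "-" else _parse_float(dcol, where)
            try:
                species.append(Species(name, int(charge), D, category))
            except ValueError as exc:
                raise SchemeParseError(f"{where}: {exc}") from exc
        elif block == "reactions":
            if len(cols) != 8:
                raise SchemeParseError(f"{where}: reaction rows need 8 columns, got {len(cols)}")
            label, r1, r2, prods, kcol, kclass, protons, prov = cols
            reactants = (r1,) if r2 == "-" else (r1, r2)
            products = () if prods == "-" else tuple(prods.split("+"))
            try:
                reactions.append(
                    Reaction(
                        label,
                        reactants,
                        products,
                        _parse_float(kcol, where),
                        kclass,
                        int(protons),
                        prov,
                    )
                )
            except ValueError as exc:
                raise SchemeParseError(f"{where}: {exc}") from exc
        elif block == "moieties":
            if len(cols) != 2:
                raise SchemeParseError(f"{where}: moiety rows need 2 columns, got {len(cols)}")
            name, pairs = cols
            try:
                moieties[name] = {
                    sp: int(count)
                    for sp, count in (pair.split("=") for pair in pairs.split(","))
                }
            except ValueError as exc:
                raise SchemeParseError(f"{where}: bad moiety map") from exc
        else:
            raise SchemeParseError(f"{where}: data outside any block")

    scheme = ReactionScheme(species, reactions, moieties)
    report = validate_scheme(scheme)
    if report.orphan_species:
        raise ValueError(f"unregistered species referenced: {report.orphan_species}")
    return scheme


def save_scheme(scheme: ReactionScheme, path: str | Path) -> None:
    """Write a scheme in the TSV dialect; round-trips through load_scheme."""
    lines = ["[species]"]
    for sp in scheme.species.values():
        dcol = "-" if sp.diffusion_coefficient is None else repr(sp.diffusion_coefficient)
        lines.append(f"{sp.name}\t{sp.charge}\t{dcol}\t{sp.category}")
    lines.append("[reactions]")
    for rxn in scheme.reactions:
        r2 = rxn.reactants[1] if len(rxn.reactants) == 2 else "-"
        prods = "+".join(rxn.products) if rxn.products else "-"
        lines.append(
            f"{rxn.label}\t{rxn.reactants[0]}\t{r2}\t{prods}\t{rxn.k!r}"
            f"\t{rxn.kinetic_class}\t{rxn.implicit_protons}\t{rxn.provenance}"
        )
    lines.append("[moieties]")
    for name, mm in scheme.moiety_maps.items():
        pairs = ",".join(f"{sp}={count}" for sp, count in mm.items())
        lines.append(f"{name}\t{pairs}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def builtin_cell_scheme() -> ReactionScheme:
    """The bundled aerated cell-water scheme (cell chemistry + water core)."""
    with resources.as_file(
        resources.files("flashrod.data").joinpath("cell_scheme.tsv")
    ) as path:
        return load_scheme(path)
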