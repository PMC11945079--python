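"""Domain types for mass-action equilibrium models.

A system is described by three components — metal M, proton H, ligand L —
and a list of species, each a stoichiometric combination (m, h, l) with a
base-10 cumulative formation constant:

    beta_mhl = [M_m H_h L_l] / ([M]^m [H]^h [L]^l)

Negative ``h`` denotes hydroxo/hydrolysis species (protons removed from
water); hydroxide itself is generated internally as the species
(0, -1, 0) with log beta = -pKw and must not appear in the species list.
All constants are conditional at the stated medium/ionic strength; no
activity corrections are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidConditionError, InvalidModelError

#: component order used throughout: metal, proton, ligand
COMPONENTS = ("M", "H", "L")


@dataclass(frozen=True)
class SpeciesDef:
    """One equilibrium species.

    Parameters
    ----------
    m, h, l : int
        Stoichiometric counts of metal, proton and ligand. ``h`` may be
        negative (hydrolysis); ``m`` and ``l`` are non-negative.
    log_beta : float
        Base-10 cumulative formation constant, mol/L concentration scale.
    label : str
        Free-text name used in results and distribution tables.
    """

    m: int
    h: int
    l: int
    log_beta: float
    label: str = ""

    def __post_init__(self):
        if self.m < 0 or self.l < 0:
            raise InvalidModelError(
                f"species {self.label!r}: m and l must be >= 0, got ({self.m}, {self.l})"
            )
        if (self.m, self.h, self.l) == (0, 0, 0):
            raise InvalidModelError("species with stoichiometry (0, 0, 0) is not allowed")
        if (self.m, self.h, self.l) in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            raise InvalidModelError(
                f"({self.m}, {self.h}, {self.l}) is a bare free component, not a species"
            )
        if not math.isfinite(self.log_beta):
            raise InvalidModelError(f"species {self.label!r}: log_beta must be finite")
        if not self.label:
            object.__setattr__(self, "label", default_label(self.m, self.h, self.l))

    @property
    def stoichiometry(self) -> tuple[int, int, int]:
        return (self.m, self.h, self.l)


def default_label(m: int, h: int, l: int, metal: str = "M", ligand: str = "L") -> str:
    """Systematic label like ``MH2L`` or ``MH-2`` for unnamed species."""
    parts = []
    if m:
        parts.append(metal if m == 1 else f"{metal}{m}")
    if h:
        parts.append(f"H{h}" if h != 1 else "H")
    if l:
        parts.append(ligand if l == 1 else f"{ligand}{l}")
    return "".join(parts)


@dataclass(frozen=True)
class EquilibriumModel:
    """A component system (metal, proton, ligand) plus its species list.

    ``pKw`` is the autoprotolysis constant of the working medium
    (-log10 Kw); temperature and ionic strength are metadata only, the
    constants being conditional.
    """

    species: tuple[SpeciesDef, ...]
    pKw: float
    medium: str = ""
    temperature_C: float = 25.0
    ionic_strength_M: float = 0.1

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        if not (math.isfinite(self.pKw) and self.pKw > 0):
            raise InvalidModelError(f"pKw must be a positive finite real, got {self.pKw}")
        seen: dict[tuple[int, int, int], str] = {}
        labels: set[str] = set()
        for sp in self.species:
            if sp.stoichiometry == (0, -1, 0):
                raise InvalidModelError(
                    "hydroxide (0, -1, 0) is generated internally from pKw; "
                    "do not list it as a species"
                )
            if sp.stoichiometry in seen:
                raise InvalidModelError(
                    f"duplicate stoichiometry {sp.stoichiometry}: "
                    f"{seen[sp.stoichiometry]!r} and {sp.label!r}"
                )
            if sp.label in labels:
                raise InvalidModelError(f"duplicate species label {sp.label!r}")
            seen[sp.stoichiometry] = sp.label
            labels.add(sp.label)

    def __getitem__(self, label: str) -> SpeciesDef:
        for sp in self.species:
            if sp.label == label:
                return sp
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sp.label for sp in self.species)

    def has_metal_species(self) -> bool:
        return any(sp.m > 0 for sp in self.species)

    def replace_log_beta(self, updates: dict[str, float]) -> "EquilibriumModel":
        """Return a copy with the listed species' log beta values replaced."""
        unknown = set(updates) - set(self.labels)
        if unknown:
            raise KeyError(f"unknown species labels: {sorted(unknown)}")
        new = tuple(
            SpeciesDef(sp.m, sp.h, sp.l, updates.get(sp.label, sp.log_beta), sp.label)
            for sp in self.species
        )
        return EquilibriumModel(new, self.pKw, self.medium, self.temperature_C,
                                self.ionic_strength_M)


@dataclass(frozen=True)
class Conditions:
    """Analytical totals at one solution condition.

    ``T_H`` is the total analytical proton excess relative to the fully
    deprotonated ligand reference (negative = excess strong base). When
    ``fixed_pH`` is set, ``T_H`` is ignored and [H] is clamped to
    ``10**(-fixed_pH)``.
    """

    C_M: float = 0.0
    C_L: float = 0.0
    T_H: float = 0.0
    fixed_pH: float | None = None

    def __post_init__(self):
        if self.C_M < 0 or self.C_L < 0:
            raise InvalidConditionError(
                f"totals must be non-negative, got C_M={self.C_M}, C_L={self.C_L}"
            )
        for name in ("C_M", "C_L", "T_H"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidConditionError(f"{name} must be finite")
        if self.fixed_pH is not None and not math.isfinite(self.fixed_pH):
            raise InvalidConditionError("fixed_pH must be finite")
        if self.C_M == 0 and self.C_L == 0 and self.T_H == 0 and self.fixed_pH is None:
            raise InvalidConditionError(
                "nothing to solve: all totals zero and no fixed_pH"
            )


@dataclass
class SpeciationResult:
    """Free and per-species concentrations at one condition.

    ``residuals`` maps each solved component to its relative mass-balance
    error (relative to the larger of the component total and 1e-12).
    """

    free: dict[str, float]
    species_conc: dict[str, float]
    residuals: dict[str, float]
    iterations: int = 0
    conditions: Conditions | None = None

    @property
    def pH(self) -> float:
        return -math.log10(self.free["H"])

    def metal_fraction(self, model: EquilibriumModel, label: str) -> float:
        """Fraction of total metal bound in one species (m-weighted)."""
        sp = model[label]
        total = self.free.get("M", 0.0) + sum(
            s.m * self.species_conc[s.label] for s in model.species
        )
        if total <= 0:
            raise InvalidConditionError("no metal in the system")
        return sp.m * self.species_conc[label] / total

    def ligand_fraction(self, model: EquilibriumModel, label: str) -> float:
        """Fraction of total ligand bound in one species (l-weighted)."""
        sp = model[label]
        total = self.free.get("L", 0.0) + sum(
            s.l * self.species_conc[s.label] for s in model.species
        )
        if total <= 0:
            raise InvalidConditionError("no ligand in the system")
        return sp.l * self.species_conc[label] / total
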