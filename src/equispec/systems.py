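"""Built-in equilibrium models for the tripodal 3,4-HOPO chelator study.

Four systems are provided, built from published conditional constants:

``kemppr_gd``
    Gd(III) with the hexadentate tripodal tris(3,4-hydroxypyridinone)
    ligand KEMPPr(3,4-HP)3 in 50% w/w DMSO/water (I = 0.1 M KCl, 25 C):
    six ligand protonation steps, four Gd complexes (GdH4L, GdH2L, GdHL,
    GdL), two Gd hydrolysis species and pKw = 14.95.
``kemppr_ligand_only``
    The same ligand without metal (acid-base model only).
``h3l2_gd``
    The comparison tripodal ligand H3L2 with Gd(III), aqueous constants.
``ntp_prhp3_gd``
    The comparison ligand NTP(PrHP)3 with Gd(III), aqueous constants,
    including the 1:2 metal-to-ligand species GdH5L2 and GdH3L2.

Stepwise protonation constants are stored as printed and converted to
cumulative log beta on construction.
"""

from __future__ import annotations

from .errors import InvalidModelError
from .model import EquilibriumModel, SpeciesDef
from .speciation import stepwise_to_cumulative

__all__ = ["builtin_model", "BUILTIN_MODELS"]

_PKW_WATER = 13.997  # 25 C, I -> 0 reference value for the aqueous systems

_KEMPPR_STEPWISE = [11.5, 10.97, 9.87, 3.96, 3.19, 3.04]
_H3L2_STEPWISE = [9.93, 9.75, 9.18, 4.26, 3.11, 2.77]
_NTP_STEPWISE = [9.95, 9.84, 9.09, 6.77, 3.81, 3.14, 2.76]

_GD_HYDROLYSIS = [
    SpeciesDef(1, -2, 0, -15.17, "Gd(OH)2"),
    SpeciesDef(1, -3, 0, -24.06, "Gd(OH)3"),
]


def _protonation_species(stepwise: list[float]) -> list[SpeciesDef]:
    return [
        SpeciesDef(0, i + 1, 1, beta, f"H{i + 1}L" if i else "HL")
        for i, beta in enumerate(stepwise_to_cumulative(stepwise))
    ]


def _kemppr_ligand_only() -> EquilibriumModel:
    return EquilibriumModel(
        species=tuple(_protonation_species(_KEMPPR_STEPWISE)),
        pKw=14.95,
        medium="50% w/w DMSO/water, I = 0.1 M KCl",
        temperature_C=25.0,
        ionic_strength_M=0.1,
    )


def _kemppr_gd() -> EquilibriumModel:
    species = _protonation_species(_KEMPPR_STEPWISE) + [
        SpeciesDef(1, 4, 1, 41.35, "GdH4L"),
        SpeciesDef(1, 2, 1, 35.17, "GdH2L"),
        SpeciesDef(1, 1, 1, 31.30, "GdHL"),
        SpeciesDef(1, 0, 1, 26.59, "GdL"),
    ] + _GD_HYDROLYSIS
    return EquilibriumModel(
        species=tuple(species),
        pKw=14.95,
        medium="50% w/w DMSO/water, I = 0.1 M KCl",
        temperature_C=25.0,
        ionic_strength_M=0.1,
    )


def _h3l2_gd() -> EquilibriumModel:
    species = _protonation_species(_H3L2_STEPWISE) + [
        SpeciesDef(1, 4, 1, 37.74, "GdH4L"),
        SpeciesDef(1, 2, 1, 30.03, "GdH2L"),
        SpeciesDef(1, 0, 1, 21.22, "GdL"),
    ]
    return EquilibriumModel(
        species=tuple(species),
        pKw=_PKW_WATER,
        medium="water, I = 0.1 M",
        temperature_C=25.0,
        ionic_strength_M=0.1,
    )


def _ntp_prhp3_gd() -> EquilibriumModel:
    species = _protonation_species(_NTP_STEPWISE) + [
        SpeciesDef(1, 5, 1, 42.8, "GdH5L"),
        SpeciesDef(1, 4, 1, 39.46, "GdH4L"),
        SpeciesDef(1, 3, 1, 35.69, "GdH3L"),
        SpeciesDef(1, 2, 1, 31.16, "GdH2L"),
        SpeciesDef(1, 1, 1, 26.35, "GdHL"),
        SpeciesDef(1, 5, 2, 65.3, "GdH5L2"),
        SpeciesDef(1, 3, 2, 52.3, "GdH3L2"),
    ]
    return EquilibriumModel(
        species=tuple(species),
        pKw=_PKW_WATER,
        medium="water, I = 0.1 M",
        temperature_C=25.0,
        ionic_strength_M=0.1,
    )


BUILTIN_MODELS = {
    "kemppr_gd": _kemppr_gd,
    "kemppr_ligand_only": _kemppr_ligand_only,
    "h3l2_gd": _h3l2_gd,
    "ntp_prhp3_gd": _ntp_prhp3_gd,
}


def builtin_model(name: str) -> EquilibriumModel:
    """Return one of the built-in study systems by name."""
    try:
        return BUILTIN_MODELS[name]()
    except KeyError:
        raise InvalidModelError(
            f"unknown model {name!r}; choices: {sorted(BUILTIN_MODELS)}"
        ) from None
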