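"""Synthetic potentiometric titration curves.

Emulates the pH-metric protocol used for the chelator study: an initial
20 mL solution of ligand (3.2e-4 M), with or without equimolar Gd(III),
plus a strong-acid excess, titrated with 0.1 M KOH. The readout is the
glass-electrode EMF through a Nernst response

    E = E0 + slope * pH        (slope ~ -59.16 mV per pH unit at 25 C)

with independent Gaussian noise on the EMF and on the delivered titrant
volume. Curves carry their generation metadata (seed, noise levels) so
every simulation is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCurveError, InvalidConditionError, SolverFailureError
from .model import Conditions, EquilibriumModel, SpeciesDef
from .speciation import solve_speciation

__all__ = [
    "TitrationProtocol",
    "Electrode",
    "TitrationCurve",
    "total_proton_at",
    "default_volumes",
    "simulate_curve",
    "simulate_calibration_curve",
]


@dataclass(frozen=True)
class TitrationProtocol:
    """Composition and dosing plan of one titration.

    ``C_acid0`` is the initial strong-acid excess over the fully
    protonated ligand reference; ``ligand_protons`` counts the
    dissociable protons the ligand carries as dissolved (3 for the
    neutral H3L form), which enter the proton balance on top of the
    strong acid. Volumes are the nominal burette readings in mL.
    """

    C_L0: float = 0.0
    C_M0: float = 0.0
    C_acid0: float = 2e-3
    C_titrant: float = 0.1
    V0: float = 20.0
    ligand_protons: int = 3
    volumes: tuple[float, ...] = ()

    def __post_init__(self):
        if self.V0 <= 0 or self.C_titrant <= 0:
            raise InvalidConditionError("V0 and C_titrant must be positive")
        if self.C_L0 < 0 or self.C_M0 < 0:
            raise InvalidConditionError("initial concentrations must be >= 0")
        v = np.asarray(self.volumes, dtype=float)
        if v.size:
            if v[0] < 0 or np.any(np.diff(v) <= 0):
                raise InvalidConditionError(
                    "volumes must start >= 0 and be strictly increasing"
                )
        object.__setattr__(self, "volumes", tuple(float(x) for x in v))

    def conditions_at(self, v: float) -> Conditions:
        """Diluted analytical totals after adding ``v`` mL of titrant."""
        d = self.V0 + v
        C_L = self.C_L0 * self.V0 / d
        C_M = self.C_M0 * self.V0 / d
        T_H = total_proton_at(self, v) + self.ligand_protons * C_L
        return Conditions(C_M=C_M, C_L=C_L, T_H=T_H)


def total_proton_at(protocol: TitrationProtocol, v: float) -> float:
    """Strong-acid proton excess (mol/L) after ``v`` mL of base.

    T_H(v) = (C_acid0*V0 - C_titrant*v) / (V0 + v); the same dilution
    factor applies to the ligand and metal totals.
    """
    if v < 0:
        raise InvalidConditionError("titrant volume must be >= 0")
    return (protocol.C_acid0 * protocol.V0 - protocol.C_titrant * v) / (protocol.V0 + v)


@dataclass(frozen=True)
class Electrode:
    """Glass-electrode Nernst response ``E = E0 + slope * pH``.

    ``slope`` is dE/dpH in mV per pH unit and is negative for a real
    electrode (-59.16 mV at 25 C for ideal Nernstian response); ``E0``
    is the cell standard potential in mV. pH here is -log10 of the
    proton concentration on the working medium's concentration scale.
    """

    E0: float = 400.0
    slope: float = -59.16

    def __post_init__(self):
        if self.slope == 0 or not math.isfinite(self.slope):
            raise InvalidConditionError("electrode slope must be finite and nonzero")

    def emf(self, pH: float | np.ndarray) -> float | np.ndarray:
        return self.E0 + self.slope * pH

    def pH(self, E: float | np.ndarray) -> float | np.ndarray:
        return (E - self.E0) / self.slope


@dataclass(frozen=True)
class TitrationCurve:
    """An ordered (volume, EMF) series with provenance metadata."""

    v: tuple[float, ...]
    E: tuple[float, ...]
    pH: tuple[float, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float)
        E = np.asarray(self.E, dtype=float)
        if v.size != E.size or v.size == 0:
            raise DegenerateCurveError("curve needs matching non-empty v and E arrays")
        if np.any(np.diff(v) <= 0):
            raise DegenerateCurveError("volumes must be strictly increasing")
        if not np.all(np.isfinite(E)):
            raise DegenerateCurveError("EMF values must be finite")
        object.__setattr__(self, "v", tuple(float(x) for x in v))
        object.__setattr__(self, "E", tuple(float(x) for x in E))
        if self.pH is not None:
            object.__setattr__(self, "pH", tuple(float(x) for x in self.pH))

    def __len__(self) -> int:
        return len(self.v)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.v), np.asarray(self.E)


def default_volumes(
    model: EquilibriumModel,
    protocol: TitrationProtocol,
    pH_end: float,
    n_points: int = 80,
) -> tuple[float, ...]:
    """Equally spaced titrant volumes from 0 up to the volume where the
    noiseless curve reaches ``pH_end`` (located by bisection on the exact
    speciation)."""

    def ph_at(v):
        return solve_speciation(model, protocol.conditions_at(v)).pH

    v_hi = 0.05
    while ph_at(v_hi) < pH_end:
        v_hi *= 1.6
        if v_hi > 50 * protocol.V0:
            raise InvalidConditionError(
                f"pH {pH_end} not reachable with this titrant/protocol"
            )
    lo, hi = 0.0, v_hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ph_at(mid) < pH_end:
            lo = mid
        else:
            hi = mid
    return tuple(np.linspace(0.0, hi, n_points))


def simulate_curve(
    model: EquilibriumModel,
    protocol: TitrationProtocol,
    electrode: Electrode = Electrode(),
    sigma_E: float = 0.1,
    sigma_v: float = 0.002,
    seed: int = 0,
) -> TitrationCurve:
    """Simulate one titration curve.

    For each nominal volume the actually delivered volume is perturbed by
    N(0, sigma_v^2), the speciation is solved at the diluted totals, and
    the emitted EMF is the Nernst response plus N(0, sigma_E^2) noise.
    The recorded volumes are the nominal burette readings, as in a real
    experiment; ``sigma_E = sigma_v = 0`` gives the exact noiseless curve.
    Deterministic for a given seed.
    """
    if not protocol.volumes:
        raise InvalidConditionError("protocol has no titrant volumes")
    rng = np.random.default_rng(seed)
    vs = np.asarray(protocol.volumes)
    v_true = vs + rng.normal(0.0, sigma_v, size=vs.size) if sigma_v > 0 else vs
    v_true = np.maximum(v_true, 0.0)
    e_noise = rng.normal(0.0, sigma_E, size=vs.size) if sigma_E > 0 else 0.0

    emf = np.empty(vs.size)
    ph = np.empty(vs.size)
    warm = None
    for i, vt in enumerate(v_true):
        try:
            res = solve_speciation(model, protocol.conditions_at(float(vt)), x0=warm)
        except SolverFailureError as exc:
            raise SolverFailureError(
                f"speciation failed at titration point {i} (v = {vt:.4f} mL): {exc}"
            ) from exc
        warm = {k: math.log10(c) for k, c in res.free.items() if c > 0}
        ph[i] = res.pH
        emf[i] = electrode.emf(res.pH)
    emf = emf + e_noise
    return TitrationCurve(
        v=tuple(vs),
        E=tuple(emf),
        pH=tuple(electrode.pH(emf)),
        meta={"seed": seed, "sigma_E": sigma_E, "sigma_v": sigma_v,
              "V0": protocol.V0, "C_titrant": protocol.C_titrant},
    )


# water-scale carbonate protonation constants used for the synthetic
# titrant-impurity fixture (log K: 10.33 for HCO3-, 6.35 for H2CO3)
_CARBONATE_LOGBETA = (10.33, 16.68)


def simulate_calibration_curve(
    protocol: TitrationProtocol,
    electrode: Electrode = Electrode(),
    pKw: float = 14.95,
    carbonate_fraction: float = 0.0,
    sigma_E: float = 0.0,
    sigma_v: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Strong acid - strong base calibration curve, optionally with a
    synthetic carbonate impurity in the titrant.

    ``carbonate_fraction`` is the mole fraction of the titrant's base
    content delivered as CO3(2-) instead of OH- (0.02 = 2% carbonate).
    The impurity is modelled as a diprotic carbonate with water-scale
    protonation constants; it buffers near the alkaline end and splits
    the Gran end-points, which is what the carbonate quality-control
    check measures.
    """
    if not (0.0 <= carbonate_fraction < 0.5):
        raise InvalidConditionError("carbonate_fraction must be in [0, 0.5)")
    if not protocol.volumes:
        raise InvalidConditionError("protocol has no titrant volumes")

    # carbonate rides in the ligand slot of the component system
    species = [
        SpeciesDef(0, 1, 1, _CARBONATE_LOGBETA[0], "HCO3"),
        SpeciesDef(0, 2, 1, _CARBONATE_LOGBETA[1], "H2CO3"),
    ] if carbonate_fraction > 0 else []
    model = EquilibriumModel(species=tuple(species), pKw=pKw,
                             medium="calibration")

    rng = np.random.default_rng(seed)
    vs = np.asarray(protocol.volumes)
    v_true = vs + rng.normal(0.0, sigma_v, size=vs.size) if sigma_v > 0 else vs
    v_true = np.maximum(v_true, 0.0)
    e_noise = rng.normal(0.0, sigma_E, size=vs.size) if sigma_E > 0 else 0.0

    f = carbonate_fraction
    emf = np.empty(vs.size)
    warm = None
    for i, vt in enumerate(v_true):
        d = protocol.V0 + vt
        # each mole of CO3 replaces one mole of OH in the titrant
        T_H = (protocol.C_acid0 * protocol.V0 - (1 - f) * protocol.C_titrant * vt) / d
        C_CO3 = f * protocol.C_titrant * vt / d
        cond = Conditions(C_M=0.0, C_L=C_CO3, T_H=T_H) if C_CO3 > 0 else \
            Conditions(C_M=0.0, C_L=0.0, T_H=T_H if T_H != 0 else 1e-300)
        res = solve_speciation(model, cond, x0=warm)
        warm = {k: math.log10(c) for k, c in res.free.items() if c > 0}
        emf[i] = electrode.emf(res.pH)
    emf = emf + e_noise
    return TitrationCurve(
        v=tuple(vs), E=tuple(emf), pH=tuple(electrode.pH(emf)),
        meta={"seed": seed, "sigma_E": sigma_E, "sigma_v": sigma_v,
              "V0": protocol.V0, "C_titrant": protocol.C_titrant,
              "carbonate_fraction": f, "pKw": pKw},
    )
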