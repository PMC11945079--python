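"""Gran's-method analysis of strong acid - strong base calibration titrations.

Before a ligand titration the glass electrode is calibrated against an
HCl/KOH titration in the working medium. Gran's linearization turns the
sigmoidal EMF curve into two straight lines:

    acid side:  (V0 + v) * [H]  = C_t * (Ve - v)   -> x-intercept Ve
    base side:  (V0 + v) * [OH] = C_t * (v - Ve)   -> x-intercept Ve

with [H] proportional to 10**(-E/slope) through the Nernst response.
Alternating the intercept location with a regression of E on the pH
implied by the intercepts recovers both the standard potential E0 and
the actual Nernst slope. The separation of the acid- and base-side
end-points measures carbonate contamination of the titrant; runs with
more than 1% carbonate (relative to total base) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCurveError, InvalidConditionError
from .titration import Electrode, TitrationCurve, TitrationProtocol

__all__ = ["GranResult", "gran_transform", "calibrate_electrode", "carbonate_check"]


@dataclass(frozen=True)
class GranResult:
    """Outcome of a Gran calibration."""

    E0: float
    slope: float
    Ve_acid: float
    Ve_base: float
    carbonate_percent: float
    accepted: bool
    n_acid: int = 0
    n_base: int = 0

    @property
    def electrode(self) -> Electrode:
        return Electrode(E0=self.E0, slope=self.slope)


def gran_transform(
    curve: TitrationCurve,
    slope_guess: float,
    side: str,
    V0: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gran linearization of a titration curve.

    Returns (v, F) with F = (V0+v) * 10**(-E/slope) on the acid side and
    F = (V0+v) * 10**(E/slope) on the base side; both are straight lines
    in v for ideal Nernstian data, with x-intercept at the equivalence
    volume. The unknown E0 only scales F and does not move the intercept.
    """
    if side not in ("acid", "base"):
        raise InvalidConditionError(f"side must be 'acid' or 'base', got {side!r}")
    v, E = curve.arrays()
    if v.size == 0:
        raise DegenerateCurveError("empty curve")
    if np.ptp(E) == 0:
        raise DegenerateCurveError("EMF has zero range; not a titration curve")
    sign = -1.0 if side == "acid" else 1.0
    # shift the exponent by its maximum for numerical range only; a common
    # factor does not affect the straight line's intercept
    expo = sign * E / slope_guess
    F = (V0 + v) * 10.0 ** (expo - expo.max())
    return v, F


def _line_intercept(v: np.ndarray, F: np.ndarray) -> float:
    """x-intercept of the least-squares line through (v, F)."""
    A = np.vstack([v, np.ones_like(v)]).T
    slope, icept = np.linalg.lstsq(A, F, rcond=None)[0]
    if slope == 0:
        raise DegenerateCurveError("Gran line is flat; no equivalence point")
    return -icept / slope


def calibrate_electrode(
    curve: TitrationCurve,
    protocol: TitrationProtocol,
    pKw: float = 14.95,
    slope_guess: float = -59.16,
    max_rounds: int = 100,
    tol_Ve: float = 1e-6,
) -> GranResult:
    """Recover E0, Nernst slope and equivalence volumes from a strong
    acid - strong base calibration curve.

    Alternates (a) Gran-intercept location of the acid- and base-side
    equivalence volumes using the current slope with (b) regression of
    E on the pH implied by those intercepts, until the equivalence
    volumes move by less than ``tol_Ve`` mL. ``pKw`` converts base-side
    hydroxide excess to pH for the regression.

    Fit windows: acid side v <= 0.8*Ve, base side v >= 1.2*Ve, the
    standard practice that keeps the poorly-poised region around the
    end-point out of the straight-line fits.
    """
    v, E = curve.arrays()
    if np.ptp(E) == 0:
        raise DegenerateCurveError("EMF has zero range; not a titration curve")
    V0, C_t = protocol.V0, protocol.C_titrant

    # coarse end-point: steepest EMF step
    dE = np.abs(np.diff(E) / np.diff(v))
    Ve = float(0.5 * (v[np.argmax(dE)] + v[np.argmax(dE) + 1]))
    slope = slope_guess

    Ve_acid = Ve_base = Ve
    for _ in range(max_rounds):
        acid = v <= 0.8 * Ve_acid
        base = v >= 1.2 * Ve_base
        if acid.sum() < 2 or base.sum() < 2:
            raise DegenerateCurveError(
                "no equivalence bracket: need >= 2 points on each side of Ve"
            )
        _, Fa = gran_transform(curve, slope, "acid", V0)
        _, Fb = gran_transform(curve, slope, "base", V0)
        new_Ve_acid = _line_intercept(v[acid], Fa[acid])
        new_Ve_base = _line_intercept(v[base], Fb[base])
        if new_Ve_acid <= 0 or new_Ve_base <= 0:
            raise DegenerateCurveError("Gran intercept is non-positive")

        # implied pH at the window points from the stoichiometric excess
        pH_a = -np.log10(C_t * (new_Ve_acid - v[acid]) / (V0 + v[acid]))
        pH_b = pKw + np.log10(C_t * (v[base] - new_Ve_base) / (V0 + v[base]))
        ph = np.concatenate([pH_a, pH_b])
        emf = np.concatenate([E[acid], E[base]])
        A = np.vstack([ph, np.ones_like(ph)]).T
        slope_new, E0_new = np.linalg.lstsq(A, emf, rcond=None)[0]

        moved = max(abs(new_Ve_acid - Ve_acid), abs(new_Ve_base - Ve_base))
        Ve_acid, Ve_base, slope, E0 = new_Ve_acid, new_Ve_base, slope_new, E0_new
        if moved < tol_Ve:
            break

    carb = 100.0 * (Ve_base - Ve_acid) / Ve_base
    carb = max(carb, 0.0)
    return GranResult(
        E0=float(E0), slope=float(slope),
        Ve_acid=float(Ve_acid), Ve_base=float(Ve_base),
        carbonate_percent=float(carb),
        accepted=carb <= 1.0,
        n_acid=int(acid.sum()), n_base=int(base.sum()),
    )


def carbonate_check(result: GranResult, threshold_percent: float = 1.0) -> bool:
    """Titrant quality-control rule: accept the calibration only if the
    carbonate content (from the split of the two Gran end-points) is at
    most ``threshold_percent`` of the total base."""
    if result.Ve_acid is None or result.Ve_base is None or \
            not (result.Ve_acid > 0 and result.Ve_base > 0):
        raise InvalidConditionError("both equivalence volumes are required")
    return result.carbonate_percent <= threshold_percent
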