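"""Weighted nonlinear least-squares refinement of formation constants.

This is the model-fitting stage of the potentiometric workflow: given one
or more titration curves, a species model, and a calibrated electrode,
refine the cumulative log beta values of a chosen subset of species by
Levenberg-Marquardt minimisation of

    S(theta) = sum_i w_i * (E_obs,i - E_calc,i(theta))^2

where every E_calc requires an inner mass-balance solve and the weights
follow the standard potentiometric error propagation

    w_i = 1 / (sigma_E^2 + (dE/dv)_i^2 * sigma_v^2)

which down-weights the steep, buffer-poor regions where a small burette
error produces a large EMF error. The parameter Jacobian is computed
analytically through the implicit-function theorem on the mass-balance
system, so each iteration costs one speciation solve per point plus one
small linear solve per free parameter.

Organised as a model/results pair: :class:`TitrationRefinement` holds the
data and configuration, ``fit()`` runs the optimisation and returns a
:class:`RefinementResults` with estimates, standard errors and a
``summary()`` table. :func:`refine_constants` is the functional wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateCurveError,
    InvalidConditionError,
    InvalidModelError,
    SolverFailureError,
)
from .model import EquilibriumModel
from .speciation import solve_speciation
from .titration import Electrode, TitrationCurve, TitrationProtocol

__all__ = [
    "RefinementSpec",
    "RefinementResults",
    "TitrationRefinement",
    "refine_constants",
    "ph_window_filter",
    "point_weights",
    "format_estimate",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class RefinementSpec:
    """Configuration of one refinement run.

    ``free_params`` are the species labels whose log beta is adjusted;
    every other species is held fixed. ``initial_guesses`` may override
    the model's stored values as starting points. ``max_pH`` drops
    points above a cutoff before fitting (the precipitation rule).
    """

    free_params: tuple[str, ...]
    initial_guesses: dict[str, float] = field(default_factory=dict)
    sigma_E: float = 0.1
    sigma_v: float = 0.002
    max_pH: float | None = None
    convergence_tol: float = 1e-8
    max_iter: int = 100
    residual: str = "emf"  # or "pH"

    def __post_init__(self):
        object.__setattr__(self, "free_params", tuple(self.free_params))
        if not self.free_params:
            raise InvalidModelError("free_params must be non-empty")
        if len(set(self.free_params)) != len(self.free_params):
            raise InvalidModelError("free_params contains duplicates")
        if self.sigma_E <= 0 or self.sigma_v < 0:
            raise InvalidModelError("sigma_E must be > 0 and sigma_v >= 0")
        if self.residual not in ("emf", "pH"):
            raise InvalidModelError("residual mode must be 'emf' or 'pH'")


def ph_window_filter(
    curve: TitrationCurve,
    electrode: Electrode,
    max_pH: float,
) -> TitrationCurve:
    """Drop all points above a pH cutoff (order preserved).

    Used to exclude regions invalidated by precipitation: for the Gd
    runs of the study system, points above pH 6 are discarded.
    """
    v, E = curve.arrays()
    ph = electrode.pH(E)
    keep = ph <= max_pH
    if not keep.any():
        raise DegenerateCurveError(f"no points at or below pH {max_pH}")
    return TitrationCurve(
        v=tuple(v[keep]), E=tuple(E[keep]),
        pH=tuple(ph[keep]), meta=dict(curve.meta),
    )


def point_weights(
    curve: TitrationCurve,
    sigma_E: float,
    sigma_v: float,
) -> np.ndarray:
    """Per-point weights 1/(sigma_E^2 + (dE/dv)^2 sigma_v^2).

    The local curve slope dE/dv is estimated by central differences
    (one-sided at the ends); with sigma_v = 0 the weights are uniform.
    """
    v, E = curve.arrays()
    if v.size < 3:
        raise DegenerateCurveError("need >= 3 points to estimate dE/dv")
    if np.any(np.diff(v) == 0):
        raise DegenerateCurveError("duplicate titrant volumes")
    dEdv = np.gradient(E, v)
    return 1.0 / (sigma_E**2 + dEdv**2 * sigma_v**2)


@dataclass
class RefinementResults:
    """Refined constants with uncertainties and fit diagnostics."""

    params: dict[str, float]
    bse: dict[str, float]
    wssq: float
    n_points: int
    converged: bool
    iterations: int
    model: EquilibriumModel
    cov: np.ndarray | None = None
    sigma_scale: float = 1.0

    def __getitem__(self, label: str) -> float:
        return self.params[label]

    def summary(self) -> str:
        """Plain-text report in the last-digit parenthetical convention
        (26.59(8) means 26.59 with standard deviation 0.08)."""
        lines = [
            "Formation-constant refinement",
            "=" * 46,
            f"{'species':<14}{'log beta':>12}{'std dev':>10}{'':>10}",
            "-" * 46,
        ]
        for lab in self.params:
            sd = self.bse[lab]
            lines.append(
                f"{lab:<14}{self.params[lab]:>12.4f}{sd:>10.4f}"
                f"{format_estimate(self.params[lab], sd):>10}"
            )
        lines += [
            "-" * 46,
            f"points {self.n_points}   weighted ssq {self.wssq:.6g}",
            f"converged {self.converged} in {self.iterations} iterations",
        ]
        return "\n".join(lines)


def format_estimate(value: float, sd: float) -> str:
    """Format an estimate in the compact last-digit convention."""
    if not (math.isfinite(sd) and sd > 0):
        return f"{value:.2f}(-)"
    if sd >= 2.0:
        return f"{value:.0f}({sd:.0f})"
    ndec = max(0, -int(math.floor(math.log10(sd))))
    digit = round(sd * 10**ndec)
    if digit == 10:  # 0.096 -> 0.1, not (10)
        ndec -= 1
        digit = 1
    return f"{value:.{ndec}f}({digit})"


class TitrationRefinement:
    """Weighted least-squares model for formation-constant refinement.

    Parameters
    ----------
    model
        The species model; the ``free_params`` entries of ``spec`` name
        which of its log beta values are refined.
    curves, protocols
        One or more observed titration curves with their matching
        protocols (same length, same order).
    electrode
        Calibrated Nernst response used to map pH <-> EMF.
    spec
        Refinement configuration (free parameters, noise model used for
        weighting, pH cutoff, convergence settings).
    """

    def __init__(
        self,
        model: EquilibriumModel,
        curves: list[TitrationCurve],
        protocols: list[TitrationProtocol],
        electrode: Electrode,
        spec: RefinementSpec,
    ):
        if len(curves) != len(protocols) or not curves:
            raise InvalidConditionError(
                "need equal, non-empty lists of curves and protocols"
            )
        unknown = set(spec.free_params) - set(model.labels)
        if unknown:
            raise InvalidModelError(f"free_params not in model: {sorted(unknown)}")
        self.model = model
        self.electrode = electrode
        self.spec = spec
        self.curves = []
        self.protocols = list(protocols)
        self.weights = []
        for curve in curves:
            if spec.max_pH is not None:
                curve = ph_window_filter(curve, electrode, spec.max_pH)
            self.curves.append(curve)
            self.weights.append(point_weights(curve, spec.sigma_E, spec.sigma_v))
        self.n_points = sum(len(c) for c in self.curves)

    # -- residuals and analytic parameter Jacobian ---------------------

    def _eval(self, theta: np.ndarray, with_jac: bool):
        """Residual vector (and Jacobian) at parameter vector theta."""
        labels = self.spec.free_params
        model = self.model.replace_log_beta(dict(zip(labels, theta)))
        nu_all = np.array(
            [[sp.m, sp.h, sp.l] for sp in model.species] + [[0, -1, 0]], float
        )
        free_idx = [model.labels.index(lab) for lab in labels]

        r = np.empty(self.n_points)
        J = np.empty((self.n_points, len(labels))) if with_jac else None
        pos = 0
        for curve, protocol in zip(self.curves, self.protocols):
            warm = None
            for v_i, E_obs in zip(*curve.arrays()):
                cond = protocol.conditions_at(float(v_i))
                res = solve_speciation(model, cond, x0=warm)
                warm = {k: math.log10(cv) for k, cv in res.free.items() if cv > 0}
                ph = res.pH
                if self.spec.residual == "emf":
                    r[pos] = E_obs - self.electrode.emf(ph)
                else:
                    r[pos] = self.electrode.pH(E_obs) - ph
                if with_jac:
                    J[pos] = self._dpH_dtheta(model, nu_all, free_idx, res, cond)
                    if self.spec.residual == "emf":
                        J[pos] *= self.electrode.slope
                    # residual = obs - calc, so flip sign of d calc/d theta
                    J[pos] = -J[pos]
                pos += 1
        return (r, J) if with_jac else r

    @staticmethod
    def _dpH_dtheta(model, nu_all, free_idx, res, cond):
        """d pH / d log beta_k via the implicit-function theorem.

        At the solved point, F(x, beta) = 0 defines the log free
        concentrations x; dx/dbeta_k = -Jx^{-1} dF/dbeta_k with
        dF_j/dlog beta_k = ln10 * nu_{k,j} * c_k, and pH = -x_H.
        """
        comps = ["M", "H", "L"]
        active = [j for j, name in enumerate(comps)
                  if (name == "H") or
                  (name == "M" and cond.C_M > 0) or
                  (name == "L" and cond.C_L > 0)]
        h_pos = active.index(1)
        freevec = np.array([res.free[comps[j]] for j in active])
        c = np.array([res.species_conc[lab] for lab in model.labels]
                     + [res.species_conc["OH"]])
        nu_a = nu_all[:, active]
        Jx = _LN10 * (np.diag(freevec) + (nu_a.T * c) @ nu_a)
        out = np.empty(len(free_idx))
        for col, k in enumerate(free_idx):
            b = _LN10 * c[k] * nu_a[k]
            try:
                dx = np.linalg.solve(Jx, -b)
            except np.linalg.LinAlgError:
                dx = np.linalg.lstsq(Jx, -b, rcond=None)[0]
            out[col] = -dx[h_pos]  # pH = -log10[H]
        return out

    # -- Levenberg-Marquardt -------------------------------------------

    def fit(self) -> RefinementResults:
        """Run the Levenberg-Marquardt refinement.

        Damping schedule: lambda starts at 1e-3, is multiplied by 10 on
        a rejected step and divided by 10 on an accepted one; iteration
        stops when the relative decrease of the weighted sum of squares
        falls below the spec's convergence tolerance. Standard errors
        come from the weighted covariance at the optimum scaled by the
        reduced chi-square.
        """
        labels = self.spec.free_params
        theta = np.array([
            self.spec.initial_guesses.get(lab, self.model[lab].log_beta)
            for lab in labels
        ])
        w = np.concatenate(self.weights)

        r, J = self._eval(theta, with_jac=True)
        S = float(w @ r**2)
        lam = 1e-3
        converged = False
        it = 0
        for it in range(1, self.spec.max_iter + 1):
            A = (J.T * w) @ J
            g = (J.T * w) @ r
            accepted = False
            for _ in range(25):
                D = np.diag(np.maximum(np.diag(A), 1e-30))
                try:
                    delta = np.linalg.solve(A + lam * D, -g)
                except np.linalg.LinAlgError:
                    delta = np.linalg.lstsq(A + lam * D, -g, rcond=None)[0]
                try:
                    r_new = self._eval(theta + delta, with_jac=False)
                    S_new = float(w @ r_new**2)
                except SolverFailureError:
                    S_new = math.inf
                if S_new <= S:
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break
            theta = theta + delta
            rel_drop = (S - S_new) / max(S, 1e-300)
            S = S_new
            lam = max(lam / 10.0, 1e-12)
            r, J = self._eval(theta, with_jac=True)
            if rel_drop < self.spec.convergence_tol:
                converged = True
                break

        A = (J.T * w) @ J
        dof = max(self.n_points - len(labels), 1)
        s2 = S / dof
        try:
            cov = np.linalg.inv(A) * s2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(A) * s2
        bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        # a parameter the data never constrains shows up as a (near-)
        # singular normal matrix: flag it through an infinite std error
        with np.errstate(invalid="ignore"):
            ill = ~np.isfinite(bse) | (np.diag(A) <= 1e-30)
        bse[ill] = math.inf

        return RefinementResults(
            params=dict(zip(labels, (float(t) for t in theta))),
            bse=dict(zip(labels, (float(b) for b in bse))),
            wssq=S,
            n_points=self.n_points,
            converged=converged,
            iterations=it,
            model=self.model.replace_log_beta(dict(zip(labels, theta))),
            cov=cov,
            sigma_scale=math.sqrt(s2),
        )


def refine_constants(
    model: EquilibriumModel,
    curves: list[TitrationCurve],
    protocols: list[TitrationProtocol],
    electrode: Electrode,
    spec: RefinementSpec,
) -> RefinementResults:
    """Functional wrapper around :class:`TitrationRefinement`."""
    return TitrationRefinement(model, curves, protocols, electrode, spec).fit()
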