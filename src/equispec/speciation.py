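"""Mass-balance speciation solver and derived equilibrium quantities.

Given analytical totals (C_M, T_H, C_L) and a set of species with
cumulative constants beta, the free concentrations solve

    C_M = [M] + sum_s m_s c_s
    T_H = [H] - Kw/[H] + sum_s h_s c_s
    C_L = [L] + sum_s l_s c_s

with c_s = 10**(log beta_s + m_s log[M] + h_s log[H] + l_s log[L]).
The system is solved by a damped Newton iteration in log10 free
concentrations, which keeps every concentration positive and conditions
the Jacobian across the ~20 orders of magnitude the species span.

Derived operations: species distribution diagrams versus pH, the pM
(-log10 free metal) chelation-strength index, prevalence and crossover
pH boundaries, and the stepwise <-> cumulative constant conversions.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    InvalidConditionError,
    InvalidModelError,
    NoCrossoverError,
    SolverFailureError,
    ThresholdNotReachedError,
)
from .model import Conditions, EquilibriumModel, SpeciationResult

__all__ = [
    "stepwise_to_cumulative",
    "cumulative_to_stepwise",
    "solve_speciation",
    "species_distribution",
    "compute_pM",
    "prevalence_pH",
    "crossover_pH",
    "statistical_separation",
]

# damped-Newton settings: step clamp in log10 units, iteration cap, and the
# relative residual tolerance (relative to max(total, 1e-12) per component)
_STEP_CLAMP = 1.0
_MAX_ITER = 200
_REL_TOL = 1e-11
_EXP_CAP = 300.0  # cap on decadic exponents to avoid overflow far from the root


def stepwise_to_cumulative(stepwise_logK: Sequence[float]) -> list[float]:
    """Convert stepwise protonation constants log K_i to cumulative log beta.

    K_i = [H_iL]/([H_{i-1}L][H]), so log beta(H_iL) is the prefix sum
    of the first i stepwise constants.
    """
    ks = list(stepwise_logK)
    if not ks:
        raise InvalidModelError("stepwise constant list is empty")
    if not all(math.isfinite(k) for k in ks):
        raise InvalidModelError("stepwise constants must be finite")
    out, acc = [], 0.0
    for k in ks:
        acc += k
        out.append(acc)
    return out


def cumulative_to_stepwise(cumulative_logbeta: Sequence[float]) -> list[float]:
    """Inverse of :func:`stepwise_to_cumulative` (first differences)."""
    bs = list(cumulative_logbeta)
    if not bs:
        raise InvalidModelError("cumulative constant list is empty")
    if not all(math.isfinite(b) for b in bs):
        raise InvalidModelError("cumulative constants must be finite")
    return [bs[0]] + [b - a for a, b in zip(bs, bs[1:])]


def statistical_separation(n_sites: int, step_index: int) -> float:
    """log10 of the statistical ratio K_i/K_{i+1} for n equivalent sites.

    For n independent equivalent protonation sites the stepwise constants
    scale as K_i = K_intrinsic * (n - i + 1)/i, so successive constants are
    separated by log10((n-i+1)(i+1) / (i(n-i))) even with identical site
    chemistry (0.602 for n = 2, 0.477 for n = 3).
    """
    if n_sites < 2 or not (1 <= step_index < n_sites):
        raise InvalidModelError(
            f"need n_sites >= 2 and 1 <= step_index < n_sites, "
            f"got n_sites={n_sites}, step_index={step_index}"
        )
    i, n = step_index, n_sites
    return math.log10((n - i + 1) * (i + 1) / (i * (n - i)))


def _build_arrays(model: EquilibriumModel):
    """Stoichiometry matrix and log beta vector, hydroxide appended last."""
    nu = np.array([[sp.m, sp.h, sp.l] for sp in model.species] + [[0, -1, 0]],
                  dtype=float)
    logbeta = np.array([sp.log_beta for sp in model.species] + [-model.pKw])
    return nu, logbeta


def _species_conc(nu, logbeta, logfree):
    # absent components carry logfree = -inf but only multiply zero
    # stoichiometries here (dead species are filtered upstream), so the
    # -inf is masked to keep 0 * -inf out of the matmul
    lf = np.where(np.isfinite(logfree), logfree, 0.0)
    expo = np.clip(logbeta + nu @ lf, -_EXP_CAP, _EXP_CAP)
    return 10.0 ** expo


def solve_speciation(
    model: EquilibriumModel,
    cond: Conditions,
    x0: dict[str, float] | None = None,
) -> SpeciationResult:
    """Solve the nonlinear mass-balance system for the free concentrations.

    Parameters
    ----------
    model, cond
        The equilibrium model and the analytical totals. With
        ``cond.fixed_pH`` set, [H] is clamped and only the metal/ligand
        balances are solved. Components with zero total are dropped from
        the system (their free concentration is exactly zero).
    x0
        Optional warm start: mapping component -> log10 free concentration
        (used when scanning titration curves or pH grids).

    Returns
    -------
    SpeciationResult
        Free concentrations, per-species concentrations and the relative
        mass-balance residuals actually achieved.

    Raises
    ------
    SolverFailureError
        If the damped Newton iteration does not converge; the error
        carries the worst relative residual reached.
    """
    nu, logbeta = _build_arrays(model)
    totals = np.array([cond.C_M, cond.T_H, cond.C_L])

    active = [False, cond.fixed_pH is None, False]
    active[0] = cond.C_M > 0
    active[2] = cond.C_L > 0
    act = np.array(active)

    logfree = np.full(3, -np.inf)
    if cond.fixed_pH is not None:
        logfree[1] = -cond.fixed_pH

    # drop species containing an absent component (their concentration is 0)
    present = np.ones(3, dtype=bool)
    present[0], present[2] = cond.C_M > 0, cond.C_L > 0
    live = ~np.any((nu[:, ~present] != 0) & (nu[:, ~present] > 0), axis=1) \
        if (~present).any() else np.ones(len(nu), dtype=bool)
    # hydrolysis-type species with negative h only need H, which always exists
    nu_l, logbeta_l = nu[live], logbeta[live]

    idx = np.flatnonzero(act)
    if idx.size == 0:
        # nothing to iterate: fixed pH, no metal, no ligand
        c = _species_conc(nu_l, logbeta_l, logfree)
        return _pack_result(model, cond, nu, logbeta, logfree, live, c, 0)

    # initial guess: half of each total; [H] from the dominant acid/base side
    x = np.empty(idx.size)
    for k, j in enumerate(idx):
        if j == 1:
            x[k] = _init_logH(cond, model.pKw)
        else:
            x[k] = math.log10(0.5 * totals[j])
    if x0 is not None:
        for k, j in enumerate(idx):
            name = ("M", "H", "L")[j]
            if name in x0 and math.isfinite(x0[name]):
                x[k] = x0[name]

    # tolerance scale floored at 1e-9 so that degenerate totals (e.g. a
    # proton balance at exact equivalence) still demand <= 1e-20 absolute,
    # which float64 cancellation can deliver, while any reportable total
    # converges far beyond the 1e-8 relative contract
    scale = np.maximum(np.abs(totals), 1e-9)
    tol = _REL_TOL * scale

    def residuals(xv):
        logfree[idx] = xv
        c = _species_conc(nu_l, logbeta_l, logfree)
        f = np.zeros(3)
        f[idx] += 10.0 ** xv          # free-component terms
        f += nu_l.T @ c               # species terms (incl. internal OH for H)
        return f - totals, c

    def scalar_solve(xv, k):
        """Solve component k's own balance with the others held fixed.

        Each single-component balance is strictly monotone increasing in
        its own log10 free concentration (all stoichiometric coefficients
        enter squared in the derivative), so expanding-bracket bisection
        always finds the unique root.
        """
        j = idx[k]

        def g(val):
            xt = xv.copy()
            xt[k] = val
            ft, _ = residuals(xt)
            return ft[j]

        lo = hi = xv[k]
        glo = ghi = g(lo)
        span = 1.0
        while glo > 0 and lo > -280:
            lo -= span
            span *= 2.0
            glo = g(lo)
        span = 1.0
        while ghi < 0 and hi < 10:
            hi += span
            span *= 2.0
            ghi = g(hi)
        if glo > 0 or ghi < 0:
            return xv[k]
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if g(mid) < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def newton(x):
        """Damped Newton in log10 space; returns (x, f, c, iters, ok)."""
        f, c = residuals(x)
        for it in range(1, _MAX_ITER + 1):
            if np.all(np.abs(f[idx]) <= tol[idx]):
                return x, f, c, it, True
            # Jacobian in log10 space: ln10 * (diag(free) + nu^T diag(c) nu)
            J = math.log(10.0) * (
                np.diag(10.0 ** x)
                + (nu_l[:, idx].T * c) @ nu_l[:, idx]
            )
            try:
                dx = np.linalg.solve(J, -f[idx])
            except np.linalg.LinAlgError:
                dx = np.linalg.lstsq(J, -f[idx], rcond=None)[0]
            # damp by rescaling the whole vector: elementwise clipping
            # would bend the step off the narrow curved valleys these
            # systems have (e.g. the H3L manifold couples
            # d log[L] = -3 d log[H])
            biggest = np.max(np.abs(dx))
            if biggest > _STEP_CLAMP:
                dx = dx * (_STEP_CLAMP / biggest)
            # backtracking line search on the scaled residual 2-norm (a
            # max-norm would veto any step perturbing an exactly solved
            # component); accept unconditionally after 8 halvings
            norm0 = np.linalg.norm(f[idx] / scale[idx])
            step = 1.0
            while True:
                cand = x + step * dx
                f_new, c_new = residuals(cand)
                if (np.linalg.norm(f_new[idx] / scale[idx]) < norm0
                        or step <= 1.0 / 256):
                    break
                step *= 0.5
            x, f, c = cand, f_new, c_new
        return x, f, c, _MAX_ITER, False

    x, f, c, it, ok = newton(x)
    if not ok:
        # fall back: Gauss-Seidel sweeps over the monotone single-component
        # balances pull the iterate into Newton's basin from any start
        x2 = np.empty(idx.size)
        for k, j in enumerate(idx):
            x2[k] = _init_logH(cond, model.pKw) if j == 1 \
                else math.log10(0.5 * totals[j])
        prev = np.inf
        for _ in range(40):
            for k in range(idx.size):
                x2[k] = scalar_solve(x2, k)
            f2, _ = residuals(x2)
            worst = np.max(np.abs(f2[idx]) / scale[idx])
            if worst < 1e-6 or worst > 0.9 * prev:
                break  # good enough, or sweeps have stalled
            prev = worst
        x, f, c, it2, ok = newton(x2)
        it += it2
    if not ok:
        worst = float(np.max(np.abs(f[idx]) / scale[idx]))
        raise SolverFailureError(
            f"mass-balance solver did not converge in {_MAX_ITER} iterations "
            f"(worst relative residual {worst:.3e})",
            worst_residual=worst,
        )

    logfree[idx] = x
    return _pack_result(model, cond, nu, logbeta, logfree, live, c, it)


def _init_logH(cond: Conditions, pKw: float) -> float:
    """Start [H] from the strong-acid/strong-base limit of T_H."""
    floor = 10.0 ** (-pKw / 2.0)
    if cond.T_H > floor:
        return math.log10(cond.T_H)
    if cond.T_H < -floor:
        return -pKw - math.log10(-cond.T_H)
    return -pKw / 2.0


def _pack_result(model, cond, nu, logbeta, logfree, live, c_live, iterations):
    totals = np.array([cond.C_M, cond.T_H, cond.C_L])
    scale = np.maximum(np.abs(totals), 1e-12)
    c = np.zeros(len(nu))
    c[live] = c_live
    f = np.zeros(3)
    for j in range(3):
        if np.isfinite(logfree[j]):
            f[j] += 10.0 ** logfree[j]
    f += nu.T @ c - totals
    free = {}
    for j, name in enumerate(("M", "H", "L")):
        free[name] = float(10.0 ** logfree[j]) if np.isfinite(logfree[j]) else 0.0
    residuals = {}
    solved = {"M": cond.C_M > 0, "L": cond.C_L > 0, "H": cond.fixed_pH is None}
    for j, name in enumerate(("M", "H", "L")):
        if solved[name]:
            residuals[name] = float(abs(f[j]) / scale[j])
    species_conc = {sp.label: float(c[i]) for i, sp in enumerate(model.species)}
    species_conc["OH"] = float(c[-1])
    return SpeciationResult(free=free, species_conc=species_conc,
                            residuals=residuals, iterations=iterations,
                            conditions=cond)


def species_distribution(
    model: EquilibriumModel,
    cond_template: Conditions,
    pH_grid: Sequence[float],
    component: str = "auto",
) -> pd.DataFrame:
    """Species-fraction diagram versus pH.

    For each pH the mass balance is solved at the template totals with [H]
    clamped, and every species' concentration is expressed as a fraction of
    its component's analytical total (metal-containing species are counted
    m-weighted against C_M; pure protonation species l-weighted against
    C_L). Free M / free L appear as columns ``M`` and ``L``, so each
    component's columns sum to exactly 1.

    Returns a DataFrame indexed by pH with one column per species fraction.
    """
    grid = np.asarray(list(pH_grid), dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise InvalidConditionError("pH grid must be non-empty and strictly increasing")

    has_m = cond_template.C_M > 0
    has_l = cond_template.C_L > 0
    cols: dict[str, list[float]] = {}
    warm = None
    rows = []
    for ph in grid:
        cond = Conditions(C_M=cond_template.C_M, C_L=cond_template.C_L,
                          fixed_pH=float(ph))
        try:
            res = solve_speciation(model, cond, x0=warm)
        except SolverFailureError as exc:
            raise SolverFailureError(
                f"speciation failed at pH {ph:.3f}: {exc}") from exc
        warm = {"M": math.log10(res.free["M"]) if res.free["M"] > 0 else -math.inf,
                "L": math.log10(res.free["L"]) if res.free["L"] > 0 else -math.inf}
        row = {}
        if has_m:
            row["M"] = res.free["M"] / cond_template.C_M
        if has_l:
            row["L"] = res.free["L"] / cond_template.C_L
        for sp in model.species:
            cs = res.species_conc[sp.label]
            if sp.m > 0 and has_m:
                row[sp.label] = sp.m * cs / cond_template.C_M
            elif sp.l > 0 and has_l:
                row[sp.label] = sp.l * cs / cond_template.C_L
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(grid, name="pH"))
    return df.fillna(0.0)


def _component_fraction(model, cond_template, label, ph, warm=None):
    sp = model[label]
    cond = Conditions(C_M=cond_template.C_M, C_L=cond_template.C_L,
                      fixed_pH=float(ph))
    res = solve_speciation(model, cond, x0=warm)
    if sp.m > 0:
        return sp.m * res.species_conc[label] / cond_template.C_M, res
    return sp.l * res.species_conc[label] / cond_template.C_L, res


def compute_pM(
    model: EquilibriumModel,
    pH: float,
    C_L: float = 1e-5,
    C_M: float = 1e-6,
) -> float:
    """The pM chelation-strength index: -log10 of the free metal.

    Standard comparison conditions: total ligand 1e-5 M, ligand-to-metal
    ratio 10, fixed pH. Higher pM means less free (uncomplexed) metal and
    therefore a stronger effective chelator at that pH.
    """
    if C_L <= 0 or C_M <= 0:
        raise InvalidConditionError("compute_pM requires C_L > 0 and C_M > 0")
    cond = Conditions(C_M=C_M, C_L=C_L, fixed_pH=pH)
    res = solve_speciation(model, cond)
    return -math.log10(res.free["M"])


def prevalence_pH(
    model: EquilibriumModel,
    cond_template: Conditions,
    species_label: str,
    threshold: float = 0.5,
    bracket: tuple[float, float] = (2.0, 12.0),
    resolution: float = 0.01,
) -> float:
    """Lowest pH at which a species reaches a fraction of its component total.

    "Prevalent"/"dominant" in distribution-diagram language: the species
    holds at least ``threshold`` (default 50%) of the total of the
    component it is counted against. Located by coarse scan plus bisection
    to ``resolution`` pH units.
    """
    if not (0.0 < threshold < 1.0):
        raise InvalidConditionError("threshold must be in (0, 1)")
    model[species_label]  # raises KeyError early if unknown
    lo, hi = bracket
    grid = np.arange(lo, hi + 1e-9, 0.1)
    fracs = []
    warm = None
    for ph in grid:
        frac, res = _component_fraction(model, cond_template, species_label, ph, warm)
        warm = {k: math.log10(v) if v > 0 else -math.inf
                for k, v in res.free.items() if k in ("M", "L")}
        fracs.append(frac)
    fracs = np.asarray(fracs)
    above = np.flatnonzero(fracs >= threshold)
    if above.size == 0:
        raise ThresholdNotReachedError(
            f"{species_label!r} never reaches fraction {threshold} in "
            f"pH [{lo}, {hi}] (max {fracs.max():.4f})",
            max_fraction=float(fracs.max()),
        )
    i = above[0]
    if i == 0:
        return float(grid[0])
    a, b = grid[i - 1], grid[i]
    func = lambda ph: _component_fraction(model, cond_template, species_label, ph)[0] - threshold
    return float(brentq(func, a, b, xtol=resolution / 2.0))


def crossover_pH(
    model: EquilibriumModel,
    cond_template: Conditions,
    speciesA: str,
    speciesB: str,
    bracket: tuple[float, float] = (2.0, 12.0),
    resolution: float = 0.01,
) -> float:
    """pH at which two species' concentrations are equal.

    For adjacent protonation states H_iL / H_{i-1}L this is analytically
    the stepwise log K_i; computed here from the full speciation so it
    also applies to metal complexes.
    """
    spA, spB = model[speciesA], model[speciesB]
    shared = (spA.m > 0 and spB.m > 0) or (spA.l > 0 and spB.l > 0)
    if not shared:
        raise InvalidConditionError(
            f"{speciesA!r} and {speciesB!r} share no common component to compare"
        )

    def diff(ph):
        cond = Conditions(C_M=cond_template.C_M, C_L=cond_template.C_L,
                          fixed_pH=float(ph))
        res = solve_speciation(model, cond)
        ca, cb = res.species_conc[speciesA], res.species_conc[speciesB]
        if ca <= 0 and cb <= 0:
            return 0.0
        if ca <= 0:
            return -_EXP_CAP
        if cb <= 0:
            return _EXP_CAP
        return math.log10(ca) - math.log10(cb)

    lo, hi = bracket
    grid = np.arange(lo, hi + 1e-9, 0.1)
    vals = [diff(ph) for ph in grid]
    for a, b, fa, fb in zip(grid, grid[1:], vals, vals[1:]):
        if fa == 0.0:
            return float(a)
        if fa * fb < 0:
            return float(brentq(diff, a, b, xtol=resolution / 2.0))
    raise NoCrossoverError(
        f"concentrations of {speciesA!r} and {speciesB!r} never cross in "
        f"pH [{lo}, {hi}]"
    )
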