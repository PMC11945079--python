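"""Test helpers: a random-model generator and an independent brute-force
speciation oracle.

The oracle never calls the package's Newton solver: it evaluates the
mass-balance residuals directly from the mass-action law and locates the
free concentrations by nested grid search in log10 space. It is only
practical for <= 2 unknown components, which is exactly what it is used
for."""

import numpy as np

from equispec import Conditions, EquilibriumModel, SpeciesDef


def random_model_and_conditions(rng: np.random.Generator):
    """One random valid model plus random valid conditions."""
    n_sp = rng.integers(1, 5)
    seen = set()
    species = []
    while len(species) < n_sp:
        m = int(rng.integers(0, 2))
        h = int(rng.integers(-1, 4))
        l = int(rng.integers(0, 3))
        if (m, h, l) in seen or (m, h, l) == (0, 0, 0):
            continue
        if (m, h, l) in ((1, 0, 0), (0, 1, 0), (0, 0, 1), (0, -1, 0)):
            continue
        if m == 0 and h < 0:  # pointless pure-hydroxide duplicates
            continue
        seen.add((m, h, l))
        # scale log beta with the number of bound protons/components so
        # the constants stay in a chemically plausible window
        base = 3.0 * (m + max(h, 0) + l)
        species.append(SpeciesDef(m, h, l, float(base + rng.uniform(-3, 3)),
                                  f"sp{len(species)}"))
    model = EquilibriumModel(species=tuple(species),
                             pKw=float(rng.uniform(13.0, 15.0)))
    C_M = float(rng.uniform(1e-6, 1e-3)) if rng.random() < 0.7 else 0.0
    C_L = float(rng.uniform(1e-6, 1e-3)) if rng.random() < 0.8 else 0.0
    if rng.random() < 0.5:
        cond = Conditions(C_M=C_M, C_L=C_L, fixed_pH=float(rng.uniform(2, 12)))
    else:
        T_H = float(rng.uniform(-2e-3, 5e-3))
        if C_M == 0 and C_L == 0 and T_H == 0:
            T_H = 1e-4
        cond = Conditions(C_M=C_M, C_L=C_L, T_H=T_H)
    return model, cond


def mass_balance_residuals(model, cond, free):
    """Relative mass-balance residuals computed straight from the
    mass-action law (independent of the solver's internals)."""
    conc = {}
    for sp in model.species:
        log_c = sp.log_beta
        for count, comp in ((sp.m, "M"), (sp.h, "H"), (sp.l, "L")):
            if count != 0:
                log_c += count * np.log10(free[comp]) if free[comp] > 0 else -np.inf
        conc[sp.label] = 10.0 ** log_c if np.isfinite(log_c) else 0.0
    out = {}
    if cond.C_M > 0:
        tot = free["M"] + sum(sp.m * conc[sp.label] for sp in model.species)
        out["M"] = abs(tot - cond.C_M) / max(cond.C_M, 1e-12)
    if cond.C_L > 0:
        tot = free["L"] + sum(sp.l * conc[sp.label] for sp in model.species)
        out["L"] = abs(tot - cond.C_L) / max(cond.C_L, 1e-12)
    if cond.fixed_pH is None:
        tot = free["H"] - 10.0 ** (-model.pKw) / free["H"] + sum(
            sp.h * conc[sp.label] for sp in model.species)
        out["H"] = abs(tot - cond.T_H) / max(abs(cond.T_H), 1e-12)
    return out


def brute_force_two_unknowns(model, C_M, C_L, pH, step_final=1e-4):
    """Search oracle for the free metal and ligand at clamped pH.

    Works directly from the mass-action law, never calling the package
    solver: for each trial log10[M] on a grid, the ligand balance (which
    is strictly monotone in log10[L]) is solved by plain bisection, and
    the metal-balance misfit is evaluated; the log10[M] grid is then
    refined around the sign change down to ``step_final`` resolution.
    Returns (log10 free M, log10 free L)."""

    def totals_at(logm, logl):
        tot_m, tot_l = 10.0 ** logm, 10.0 ** logl
        for sp in model.species:
            c = 10.0 ** (sp.log_beta + sp.m * logm + sp.h * (-pH) + sp.l * logl)
            tot_m += sp.m * c
            tot_l += sp.l * c
        return tot_m, tot_l

    def logl_for(logm):
        lo, hi = np.log10(C_L) - 40.0, np.log10(C_L)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if totals_at(logm, mid)[1] < C_L:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def metal_misfit(logm):
        return totals_at(logm, logl_for(logm))[0] - C_M

    # the metal balance (with the ligand balance enforced) is increasing
    # in log[M]; bracket the sign change and bisect
    lo, hi = np.log10(C_M) - 40.0, np.log10(C_M)
    while hi - lo > step_final / 4:
        mid = 0.5 * (lo + hi)
        if metal_misfit(mid) < 0:
            lo = mid
        else:
            hi = mid
    lm = 0.5 * (lo + hi)
    return lm, logl_for(lm)
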