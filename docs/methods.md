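# Methods

## The equilibrium model

A solution is described by three components — a trivalent metal ion M
(here Gd³⁺), the proton H, and a polyprotic chelating ligand L (the
fully deprotonated form is the reference state) — and a list of species
M_mH_hL_l, each carrying a cumulative formation constant on the mol/L
concentration scale:

    β_mhl = [M_mH_hL_l] / ([M]^m [H]^h [L]^l)

Negative `h` denotes hydroxo species (protons removed from water);
hydroxide itself is generated internally as the species (0, −1, 0) with
log β = −pKw. All constants are *conditional* constants at the stated
medium, temperature and ionic strength; no activity-coefficient model
(Davies, SIT) is applied, and pH means −log₁₀ of the proton
*concentration* on that same scale. The mixed-solvent medium of the
built-in study system (50% w/w DMSO/water, I = 0.1 M KCl, 25 °C,
pKw = 14.95) is carried as metadata only.

Stepwise protonation constants K_i = [H_iL]/([H_{i−1}L][H]) relate to
the cumulative scale by prefix summation; both representations are
exposed and round-trip exactly.

### Built-in systems

Four models ship with the package (`builtin_model`): the tripodal
tris(3,4-hydroxypyridinone) chelator KEMPPr(3,4-HP)₃ with and without
Gd(III) (six protonation steps; GdH₄L, GdH₂L, GdHL, GdL; the
independently determined Gd hydrolysis species GdH₋₂ = −15.17 and
GdH₋₃ = −24.06; pKw 14.95), and the two comparison tripodal ligands
H₃L2 and NTP(PrHP)₃ with their aqueous constants, the latter including
the 1:2 metal-to-ligand species GdH₅L₂ and GdH₃L₂. The aqueous
comparison systems carry pKw = 13.997 (25 °C reference value); this
only enters through the proton balance, which is clamped in every
fixed-pH computation those systems are used for.

## Solving the mass balance

At given analytical totals (C_M, T_H, C_L) the free concentrations
satisfy

    C_M = [M] + Σ m_s c_s
    T_H = [H] − Kw/[H] + Σ h_s c_s
    C_L = [L] + Σ l_s c_s,        c_s = 10^(log β_s + m_s log[M] + h_s log[H] + l_s log[L])

T_H is the analytical proton excess relative to the L reference
(negative = excess base). The system is solved in log₁₀ free
concentrations — which enforces positivity and conditions the Jacobian
across the ~20 orders of magnitude the species span — by a damped
Newton iteration:

* Jacobian `ln10·(diag(free) + νᵀ diag(c) ν)`, symmetric positive
  definite on the active components;
* the step is damped by rescaling the whole vector to a maximum
  component of 1 log unit (elementwise clipping is deliberately
  avoided: it bends the step off the narrow curved valleys these
  systems have, e.g. the H₃L manifold couples d log[L] = −3 d log[H]);
* backtracking line search on the 2-norm of the scaled residuals, with
  unconditional acceptance after 8 halvings so the iteration cannot
  deadlock;
* initialisation at 50% of each total, [H] from the strong-acid /
  strong-base limit of T_H;
* if Newton fails to converge in 200 iterations, a Gauss–Seidel
  fallback solves the single-component balances one at a time by
  expanding-bracket bisection (each is strictly monotone in its own
  log free concentration), then Newton restarts from there.

Convergence demands residuals below 10⁻¹¹ relative to
max(|total|, 10⁻⁹); the result contract checked in tests is ≤ 10⁻⁸
relative to max(total, 10⁻¹²) per component. Components with zero total
are removed from the system (their free concentration is exactly zero),
so ligand-only titrations never solve a degenerate 0 = 0 metal balance.
With `fixed_pH` set, [H] is clamped and only the remaining balances are
solved. Decadic exponents are capped at ±300 to avoid overflow far from
the root; the cap is inactive at any solution.

Warm starts (the previous point's free concentrations) are used along
titration curves and pH grids; a stale warm start that strands Newton
triggers an automatic cold restart.

## Derived quantities

* **Species distributions.** Fractions are reported per component:
  metal-containing species are counted m-weighted against C_M, pure
  protonation species l-weighted against C_L; free M and free L appear
  as their own columns, so each component's columns sum to exactly 1.
* **pM** (here pGd) = −log₁₀[M] at the standard comparison conditions
  C_L = 10⁻⁵ M, C_L/C_M = 10, fixed pH. It is bounded below by
  −log₁₀ C_M, with equality when nothing binds. The model is used
  exactly as given: hydrolysis species contribute only if present in
  the queried model (for the study system their effect at pH ≤ 7 is
  < 0.1 pGd unit).
* **Prevalence pH**: the lowest pH at which a species holds ≥ 50% (or a
  chosen threshold) of its component's total, located by a 0.1-unit
  coarse scan and Brent bisection to 0.01 pH resolution in the default
  pH 2–12 bracket. **Crossover pH**: equal concentration of two species
  sharing a component; for adjacent protonation states this equals the
  stepwise log K and is used as an internal consistency check.
* **Statistical separation**: for n equivalent independent protonation
  sites K_i ∝ (n−i+1)/i, so successive stepwise constants differ by
  log₁₀[(n−i+1)(i+1)/(i(n−i))] — 0.602 for n = 2 and 0.477 for n = 3 —
  even with identical site chemistry. The general formula is
  implemented; nothing forces the two-site value onto a three-armed
  ligand.

## Synthetic titration curves

The generator emulates the study's pH-metric protocol: V₀ = 20 mL of
ligand solution (C_L = 3.2×10⁻⁴ M), with or without equimolar Gd(III),
plus a strong-acid excess, titrated with 0.1 M KOH. Per point, the
delivered volume is the nominal burette reading plus N(0, σ_v²), the
speciation is solved at the diluted totals, and the recorded EMF is the
Nernst response E = E₀ + slope·pH plus N(0, σ_E²). The *recorded*
volume is the nominal reading, as in a real experiment. Defaults:
σ_E = 0.1 mV, σ_v = 0.002 mL, E₀ = 400 mV, slope = −59.16 mV per pH
unit (ideal Nernstian at 25 °C; the calibration stage refines both and
the refiner never assumes them). All randomness flows from a single
integer seed; identical seeds give byte-identical curves.

Choices the protocol leaves open, fixed here once:

* the strong-acid excess is an explicit parameter, default
  C_acid0 = 2×10⁻³ M, which puts the start near pH 2.8 so the full
  protonation ladder is traversed;
* the ligand is dosed as its neutral H₃L form and therefore delivers
  three protons per ligand into the proton balance on top of the strong
  acid (`ligand_protons = 3`);
* 80 equally spaced volumes spanning from 0 to the volume where the
  noiseless curve reaches pH 11 (ligand-only) or pH 6 (metal runs — the
  window above pH 6 is excluded from metal refinements, mirroring the
  precipitation cutoff), located by bisection on the exact curve.

What the generator does **not** emulate: junction-potential drift,
electrode hysteresis, CO₂ ingress during a run, slow approach to
equilibrium, or actual precipitation (the pH-6 cutoff models the
*exclusion rule*, not the physics). Passing round-trip tests therefore
demonstrates the correctness and statistical calibration of the
estimator under the declared noise model, not robustness to every
systematic error of a real electrode.

## Gran calibration

Strong acid – strong base calibration curves are linearized as
F = (V₀+v)·10^(∓E/slope); acid and base branches are fitted in the
windows v ≤ 0.8·Ve and v ≥ 1.2·Ve (standard practice, keeping the
poorly poised end-point region out of the lines). The algorithm
alternates Gran-intercept location with a regression of E on the pH
implied by the intercepts until the equivalence volumes move by less
than 10⁻⁶ mL; on noiseless data it reproduces the generating E₀ and
slope to better than one part in 10⁶. The carbonate content of the
titrant is measured as 100·(Ve_base − Ve_acid)/Ve_base from the
end-point split; calibrations above 1% are rejected. The synthetic
carbonate impurity used in tests is a diprotic carbonate (log K 10.33 /
6.35, water-scale values) substituted mole-for-mole for titrant
hydroxide.

## Refinement (weighted nonlinear least squares)

Formation constants are refined by Levenberg–Marquardt on

    S(θ) = Σ w_i (E_obs,i − E_calc,i(θ))²,   w_i = 1/(σ_E² + (dE/dv)_i²·σ_v²)

with dE/dv estimated by central differences from the observed curve.
Residuals are in EMF (mV), matching potentiometric practice; a pH
residual mode exists for curves supplied as pH. Each E_calc requires an
inner speciation solve; the parameter Jacobian is analytic through the
implicit-function theorem (dx/dβ_k = −J⁻¹·ln10·ν_k·c_k at the solved
point), so an iteration costs one solve per point plus one small linear
solve per free parameter. Damping: λ starts at 10⁻³, ×10 on a rejected
step, ÷10 on an accepted one; convergence when the relative decrease of
S falls below 10⁻⁸ (configurable). Standard errors are the square roots
of the diagonal of (JᵀWJ)⁻¹ scaled by the reduced chi-square
S/(n−p); reports use the compact last-digit convention (26.59(8) means
sd 0.08). A parameter the data never constrain surfaces as an infinite
standard error (near-singular normal matrix), never as a silently
confident value.

Protonation and metal constants can be refined jointly or sequentially;
the default workflow mirrors the study: ligand-only curves fix the
protonation ladder, then metal runs refine the four Gd constants with
protonation fixed and points above pH 6 excluded.

### Statistical behaviour under the default noise model

Round-trip experiments (simulate → refine, three curves per replicate)
behave differently across the ladder:

* the Gd constants are well determined: log β(GdL) comes back within
  ~0.01–0.02 of the generating 26.59 per triplicate;
* log K1 = 11.5 is the least-determined constant. Its HL/L transition
  midpoint lies half a pH unit above the pH-11 end of the data window,
  and the burette noise is Berkson-type (the *true* delivered volume
  scatters around the *recorded* nominal one), which adds a small
  curvature-driven bias of order −0.03 on top of a per-replicate
  scatter of ~0.1. Averaged over 20 replicate seed sets the recovery
  stays within 0.05 of the generating value, but users refining
  constants that sit at the edge of their data window should expect
  exactly this inflation. No curvature correction is applied: the
  objective is kept in the standard weighted-NLS form above.

## Problem sizes and runtime

All tests and the acceptance script run on one CPU. Simulated curves
use 80 points; recovery experiments use 3 curves × 20 replicate seed
sets (≈ 1–2 minutes each for the metal and ligand studies); the
randomized mass-balance property suite uses 1,000 model/condition
draws; the brute-force oracle checks use nested monotone bisection at
10⁻⁴ log-unit resolution.

## Known limitations

* Mononuclear-in-metal species lists are assumed well posed by the
  user; there is no automatic model selection over candidate species
  sets.
* No activity corrections, no temperature dependence: constants are
  conditional at the stated medium.
* One metal, one ligand per system; no competition refinements.
* The carbonate QC fixture uses aqueous carbonate constants regardless
  of the model medium; it is a synthetic quality-control scenario, not
  a thermodynamic claim about DMSO/water mixtures.
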