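"""Mass-balance solver, distribution diagrams, pM, prevalence and
crossover boundaries: worked examples plus the core invariants
(conservation, oracle agreement, normalization, monotonicity)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equispec import (
    Conditions,
    EquilibriumModel,
    InvalidConditionError,
    NoCrossoverError,
    SpeciesDef,
    ThresholdNotReachedError,
    builtin_model,
    compute_pM,
    crossover_pH,
    prevalence_pH,
    solve_speciation,
    species_distribution,
)

from util import (
    brute_force_two_unknowns,
    mass_balance_residuals,
    random_model_and_conditions,
)


@pytest.fixture(scope="module")
def monoprotic():
    return EquilibriumModel(species=(SpeciesDef(0, 1, 1, 4.0, "HL"),), pKw=14.0)


class TestSolveSpeciation:
    def test_nothing_to_bind(self):
        model = EquilibriumModel(species=(), pKw=14.0)
        res = solve_speciation(model, Conditions(C_M=1e-6, fixed_pH=6.0))
        assert res.free["M"] == pytest.approx(1e-6, rel=1e-9)

    def test_monoprotic_symmetry_at_pK(self, monoprotic):
        res = solve_speciation(monoprotic, Conditions(C_L=1e-3, fixed_pH=4.0))
        assert res.species_conc["HL"] == pytest.approx(5e-4, rel=1e-8)
        assert res.free["L"] == pytest.approx(5e-4, rel=1e-8)

    def test_residual_contract(self, gd_model):
        cond = Conditions(C_M=1e-6, C_L=1e-5, fixed_pH=6.0)
        res = solve_speciation(gd_model, cond)
        assert all(r <= 1e-8 for r in res.residuals.values())

    def test_mass_action_reconstruction(self, gd_model):
        """Species concentrations are exactly the mass-action law applied
        to the free concentrations."""
        res = solve_speciation(gd_model, Conditions(C_M=1e-6, C_L=1e-5,
                                                    fixed_pH=6.0))
        for sp in gd_model.species:
            expected = 10.0 ** (
                sp.log_beta
                + sp.m * math.log10(res.free["M"])
                + sp.h * math.log10(res.free["H"])
                + sp.l * math.log10(res.free["L"])
            )
            assert res.species_conc[sp.label] == pytest.approx(expected, rel=1e-12)

    def test_negative_totals_rejected(self):
        with pytest.raises(InvalidConditionError):
            Conditions(C_M=-1e-6, fixed_pH=7.0)

    def test_deterministic(self, gd_model):
        c = Conditions(C_M=3.2e-4, C_L=3.2e-4, T_H=1e-3)
        r1 = solve_speciation(gd_model, c)
        r2 = solve_speciation(gd_model, c)
        assert r1.free == r2.free

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mass_conservation_randomized(self, seed):
        """Mass-balance residuals <= 1e-8 on randomized models/conditions,
        verified by an independent residual computation."""
        rng = np.random.default_rng(seed)
        model, cond = random_model_and_conditions(rng)
        res = solve_speciation(model, cond)
        for comp, rel in mass_balance_residuals(model, cond, res.free).items():
            assert rel <= 1e-8, (comp, model, cond)

    def test_brute_force_oracle_agreement(self, gd_model):
        """Newton solution matches an independent nested-grid search to
        1e-4 log units on two-unknown (fixed pH) systems."""
        cases = [
            (gd_model, 1e-6, 1e-5, 6.0),
            (gd_model, 3.2e-4, 3.2e-4, 4.5),
            (builtin_model("h3l2_gd"), 1e-6, 1e-5, 7.0),
        ]
        for model, C_M, C_L, ph in cases:
            res = solve_speciation(model, Conditions(C_M=C_M, C_L=C_L,
                                                     fixed_pH=ph))
            lm, ll = brute_force_two_unknowns(model, C_M, C_L, ph)
            assert math.log10(res.free["M"]) == pytest.approx(lm, abs=1e-4)
            assert math.log10(res.free["L"]) == pytest.approx(ll, abs=1e-4)


class TestComputePM:
    def test_no_binding_gives_total(self):
        model = EquilibriumModel(species=(SpeciesDef(0, 1, 1, 4.0, "HL"),),
                                 pKw=14.0)
        assert compute_pM(model, 7.0, C_L=1e-5, C_M=1e-6) == pytest.approx(6.0, abs=1e-9)

    @pytest.mark.parametrize("name, ph, expected", [
        ("kemppr_gd", 6.0, 13.2),
        ("h3l2_gd", 7.0, 14.3),
        ("ntp_prhp3_gd", 7.0, 12.3),
    ])
    def test_study_values(self, name, ph, expected):
        assert compute_pM(builtin_model(name), ph) == pytest.approx(expected, abs=0.1)

    def test_lower_bound(self, gd_model, h3l2_model, ntp_model):
        for model in (gd_model, h3l2_model, ntp_model):
            for ph in (3.0, 6.0, 9.0):
                assert compute_pM(model, ph) >= 6.0 - 1e-9

    def test_monotone_in_log_beta(self, gd_model, h3l2_model, ntp_model):
        """Strengthening any metal complex by +0.5 log units never
        decreases pM."""
        for model in (gd_model, h3l2_model, ntp_model):
            base = compute_pM(model, 6.5)
            for sp in model.species:
                if sp.m == 0 or sp.l == 0:
                    continue
                bumped = model.replace_log_beta({sp.label: sp.log_beta + 0.5})
                assert compute_pM(bumped, 6.5) >= base - 1e-9


class TestDistribution:
    def test_monoprotic_half_at_pK(self, monoprotic):
        df = species_distribution(monoprotic, Conditions(C_L=1e-3, fixed_pH=7),
                                  [3.0, 4.0, 5.0])
        assert df.loc[4.0, "HL"] == pytest.approx(0.5, abs=1e-9)

    def test_normalization(self, gd_model):
        cond = Conditions(C_M=3.2e-4, C_L=3.2e-4, fixed_pH=7)
        grid = np.arange(2.0, 6.01, 0.2)
        df = species_distribution(gd_model, cond, grid)
        metal_cols = ["M"] + [sp.label for sp in gd_model.species if sp.m > 0]
        ligand_cols = ["L"] + [sp.label for sp in gd_model.species
                               if sp.m == 0 and sp.l > 0]
        # ligand fractions must count the ligand bound in metal complexes
        lig_in_metal = [sp.label for sp in gd_model.species
                        if sp.m > 0 and sp.l > 0]
        msum = df[metal_cols].sum(axis=1)
        assert np.allclose(msum, 1.0, atol=1e-9)
        lsum = df[ligand_cols].sum(axis=1)
        # metal-bound ligand is assigned to the metal column set, so the
        # pure-ligand columns alone sum to < 1 where complexes form
        assert (lsum <= 1.0 + 1e-9).all()

    def test_h3l_dominates_mid_pH(self, lig_model):
        """Closed-form check: the neutral H3L form is essentially the only
        ligand species near pH 6.5."""
        cond = Conditions(C_L=3.2e-4, fixed_pH=7)
        df = species_distribution(lig_model, cond, [6.5])
        assert df.loc[6.5, "H3L"] > 0.99
        # independent Henderson-Hasselbalch style oracle
        betas = {0: 0.0}
        for i, sp in enumerate(sorted((s for s in lig_model.species),
                                      key=lambda s: s.h)):
            betas[sp.h] = sp.log_beta
        terms = {h: 10.0 ** (b - 6.5 * h) for h, b in betas.items()}
        frac = terms[3] / sum(terms.values())
        assert df.loc[6.5, "H3L"] == pytest.approx(frac, rel=1e-9)

    def test_gdl_most_abundant_at_5p5(self, gd_model):
        cond = Conditions(C_M=3.2e-4, C_L=3.2e-4, fixed_pH=7)
        df = species_distribution(gd_model, cond, [5.5])
        gd_cols = ["M"] + [sp.label for sp in gd_model.species if sp.m > 0]
        assert df.loc[5.5, gd_cols].idxmax() == "GdL"

    def test_bad_grid_rejected(self, gd_model):
        cond = Conditions(C_M=1e-4, C_L=1e-4, fixed_pH=7)
        with pytest.raises(InvalidConditionError):
            species_distribution(gd_model, cond, [5.0, 4.0])


class TestPrevalence:
    def test_monoprotic_deprotonated_half(self, monoprotic):
        # L takes over from HL exactly at pH = log K = 4... the free-L
        # "fraction" is the L column; use HL reaching 0.5 from the acid
        # side instead: its fraction passes 0.5 going *down* at pH 4, and
        # rises through 0.5 at low pH; the lowest crossing is found
        ph = prevalence_pH(monoprotic, Conditions(C_L=1e-3, fixed_pH=7),
                           "HL", threshold=0.5)
        assert ph <= 4.0  # reaches 50% well below the pK

    @pytest.mark.parametrize("name, expected", [
        ("kemppr_gd", 4.8),
        ("h3l2_gd", 4.5),
    ])
    def test_gdl_prevalence(self, name, expected):
        model = builtin_model(name)
        cond = Conditions(C_M=3.2e-4, C_L=3.2e-4, fixed_pH=7)
        ph = prevalence_pH(model, cond, "GdL")
        assert ph == pytest.approx(expected, abs=0.15)

    def test_threshold_never_reached(self, gd_model):
        cond = Conditions(C_M=3.2e-4, C_L=3.2e-4, fixed_pH=7)
        with pytest.raises(ThresholdNotReachedError) as exc:
            prevalence_pH(gd_model, cond, "GdH4L", threshold=0.9,
                          bracket=(2.0, 6.0))
        assert exc.value.max_fraction is not None
        assert exc.value.max_fraction < 0.9


class TestCrossover:
    def test_adjacent_protonation_equals_stepwise_logK(self, lig_model):
        """[H_iL] = [H_{i-1}L] exactly at pH = stepwise log K_i."""
        stepwise = [11.5, 10.97, 9.87, 3.96, 3.19, 3.04]
        cond = Conditions(C_L=3.2e-4, fixed_pH=7)
        labels = ["HL", "H2L", "H3L", "H4L", "H5L", "H6L"]
        for i, (lo, hi) in enumerate(zip(["L*"] + labels, labels)):
            if lo == "L*":
                continue  # free ligand is not a species entry
            ph = crossover_pH(lig_model, cond, hi, lo)
            assert ph == pytest.approx(stepwise[i], abs=0.01)

    def test_gdl_gdhl_crossover(self, gd_model):
        cond = Conditions(C_M=3.2e-4, C_L=3.2e-4, fixed_pH=7)
        ph = crossover_pH(gd_model, cond, "GdL", "GdHL")
        # analytically log beta(GdHL) - log beta(GdL) = 31.30 - 26.59
        assert ph == pytest.approx(4.71, abs=0.01)

    def test_no_crossover_raises(self, lig_model):
        # adjacent states H6L/H5L cross at log K6 = 3.04, far outside
        # the bracket, so their ratio keeps one sign throughout
        cond = Conditions(C_L=3.2e-4, fixed_pH=7)
        with pytest.raises(NoCrossoverError):
            crossover_pH(lig_model, cond, "H6L", "H5L", bracket=(6.0, 8.0))

    def test_disjoint_components_rejected(self, gd_model):
        cond = Conditions(C_M=3.2e-4, C_L=3.2e-4, fixed_pH=7)
        with pytest.raises(InvalidConditionError):
            crossover_pH(gd_model, cond, "Gd(OH)2", "H3L")
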