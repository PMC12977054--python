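"""Fixed-pH equilibrium solver, pM, and speciation curves."""

import math

import numpy as np
import pytest

from chelastab.errors import ChelastabError
from chelastab.speciation import (
    EquilibriumModel,
    Species,
    pM,
    read_model,
    solve_equilibrium,
    speciation_curve,
    write_model,
)


def quadratic_free_m(logk, cm, cl):
    """Closed-form free [M] for a single deprotonated ML species."""
    k = 10.0**logk
    b = 1.0 + k * (cl - cm)
    return (-b + math.sqrt(b * b + 4.0 * k * cm)) / (2.0 * k)


class TestSolveEquilibrium:
    def test_no_binding_free_metal_equals_total(self):
        res = solve_equilibrium(EquilibriumModel(()), 1e-6, 1e-5, 7.4)
        assert res.free_m == pytest.approx(1e-6, rel=1e-12)
        assert res.pm == pytest.approx(6.000, abs=1e-9)

    @pytest.mark.parametrize("logk", [4.0, 8.0, 12.0])
    @pytest.mark.parametrize("ph", [3.0, 7.4, 10.0])
    def test_single_ml_matches_quadratic_closed_form(self, logk, ph):
        model = EquilibriumModel((Species(1, 1, 0, logk),))
        res = solve_equilibrium(model, 1e-6, 1e-5, ph)
        expect = quadratic_free_m(logk, 1e-6, 1e-5)
        assert res.free_m == pytest.approx(expect, rel=1e-10)

    def test_mass_balances_close(self):
        model = EquilibriumModel.from_constants(
            14.0, ligand_logKH=(10.0, 8.5, 4.0), complex_logKH=(3.0,)
        )
        res = solve_equilibrium(model, 1e-6, 1e-5, 7.4)
        tm = res.free_m + sum(sp.m * c for sp, c in res.concentrations.items())
        tl = res.free_l + sum(sp.l * c for sp, c in res.concentrations.items())
        assert tm == pytest.approx(1e-6, rel=1e-10)
        assert tl == pytest.approx(1e-5, rel=1e-10)
        assert res.residual_m < 1e-10 and res.residual_l < 1e-10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ChelastabError):
            solve_equilibrium(EquilibriumModel(()), -1e-6, 1e-5, 7.4)
        with pytest.raises(ChelastabError):
            solve_equilibrium(EquilibriumModel(()), 1e-6, 1e-5, 15.0)

    def test_duplicate_stoichiometries_rejected(self):
        with pytest.raises(ChelastabError):
            EquilibriumModel((Species(1, 1, 0, 8.0), Species(1, 1, 0, 9.0)))


class TestPM:
    def test_no_complexation_baseline(self):
        assert pM(EquilibriumModel(())) == pytest.approx(6.000, abs=1e-9)

    def test_strong_binding_closed_form(self):
        """log K = 10, non-protonatable ligand: [M] ~ C_M / (K (C_L - C_M))."""
        val = pM(EquilibriumModel.from_constants(10.0))
        expect = -math.log10(quadratic_free_m(10.0, 1e-6, 1e-5))
        assert val == pytest.approx(expect, rel=1e-10)
        assert val == pytest.approx(10.954, abs=2e-3)

    def test_pm_never_below_total_metal_limit(self):
        for logk in (2.0, 8.0, 20.0):
            assert pM(EquilibriumModel.from_constants(logk)) >= 6.0 - 1e-9

    def test_ligand_protonation_lowers_pm(self):
        """Raising ligand basicity at fixed log K strictly lowers pM."""
        base = pM(EquilibriumModel.from_constants(12.0))
        weak = pM(EquilibriumModel.from_constants(12.0, ligand_logKH=(8.0,)))
        strong = pM(EquilibriumModel.from_constants(12.0, ligand_logKH=(10.0, 9.0)))
        assert base > weak > strong

    def test_pm_monotone_in_complex_logbeta(self):
        pms = [pM(EquilibriumModel.from_constants(lk)) for lk in (6.0, 9.0, 12.0, 15.0)]
        assert pms == sorted(pms)


class TestSpeciationCurve:
    def test_no_complex_model_all_free(self):
        curve = speciation_curve(EquilibriumModel(()), 1e-6, 1e-5, np.linspace(2, 12, 11))
        assert np.allclose(curve["M"], 1.0)

    def test_fractions_sum_to_one(self):
        model = EquilibriumModel.from_constants(
            12.0, ligand_logKH=(9.0, 6.0), complex_logKH=(2.5,)
        )
        curve = speciation_curve(model, 1e-6, 1e-5, np.linspace(2, 12, 41))
        cols = [c for c in curve.columns if c not in ("pH", "converged")]
        assert np.allclose(curve[cols].sum(axis=1), 1.0, atol=1e-9)
        assert curve["converged"].all()

    def test_half_bound_crossing_matches_conditional_constant(self):
        """The 50% bound point sits where K' (C_L - C_M/2) = 1.

        For ML with a monoprotic ligand, K'(pH) = K / (1 + 10^(logKH - pH)).
        """
        logk, logkh = 10.0, 9.0
        cm, cl = 1e-6, 1e-5
        model = EquilibriumModel.from_constants(logk, ligand_logKH=(logkh,))
        # pH where K' * (C_L - C_M/2) = 1
        kprime_needed = 1.0 / (cl - cm / 2)
        ph_star = logkh - math.log10(10.0**logk / kprime_needed - 1.0)
        curve = speciation_curve(model, cm, cl, np.linspace(ph_star - 2, ph_star + 2, 201))
        bound = 1.0 - curve["M"].values
        crossing = np.interp(0.5, bound, curve["pH"].values)
        assert crossing == pytest.approx(ph_star, abs=0.02)


class TestModelIO:
    def test_roundtrip(self, tmp_path):
        model = EquilibriumModel.from_constants(12.3, ligand_logKH=(9.1, 5.2))
        f = tmp_path / "model.txt"
        write_model(model, f)
        back = read_model(f)
        assert set(back.species) == set(model.species)

    def test_missing_header_rejected(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("1 1 0 8.0\n")
        with pytest.raises(ChelastabError):
            read_model(f)
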