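"""Deterministic rate systems: closed-form oracles, ledger closure,
diffusion scaling and flux decomposition."""

import numpy as np
import pytest

import flashrod as fr
from flashrod.kinetics import peroxyl_termination_fractions
from flashrod.scheme import Reaction, ReactionScheme, Species


def _ab_scheme(k=1e6):
    """Minimal A + B -> C scheme for closed-form comparisons."""
    species = [
        Species("A", 0, 1e-9, "product"),
        Species("B", 0, 1e-9, "product"),
        Species("C", 0, None, "product"),
    ]
    return ReactionScheme(species, [Reaction("X", ("A", "B"), ("C",), k, "activation_controlled")])


class TestIntegrate:
    def test_pseudo_first_order_decay_matches_closed_form(self):
        k, a0, b0 = 1e6, 1e-9, 1e-3  # B in vast excess
        system = fr.build_rate_system(_ab_scheme(k))
        grid = np.logspace(-6, -2, 60)
        series, _ = fr.integrate(system, {"A": a0, "B": b0}, grid, rtol=1e-10)
        expected = a0 * np.exp(-k * b0 * series.times)
        assert np.allclose(series["A"], expected, rtol=1e-6)

    def test_zero_radicals_stay_constant(self, scheme):
        system = fr.build_rate_system(scheme)
        comp = fr.CellComposition()
        series, ledger = fr.integrate(
            system, dict(comp.as_dict()), np.logspace(-9, -3, 30)
        )
        # resting solutes do not react with each other in this scheme
        for name in comp.as_dict():
            assert series[name] == pytest.approx(comp.as_dict()[name], rel=1e-6)
        assert np.abs(ledger.xi).max() < 1e-12

    def test_negative_initial_state_rejected(self, scheme):
        system = fr.build_rate_system(scheme)
        with pytest.raises(ValueError):
            fr.integrate(system, {"O2": -1e-6}, np.logspace(-9, -6, 5))

    def test_ledger_closure_for_oxygen(self, n20_run):
        series, ledger, _ = n20_run
        assert ledger.closure_residual(series, "O2").max() < 1e-9

    def test_ledger_closure_all_species(self, n20_run):
        series, ledger, _ = n20_run
        for name in series.species_names:
            assert ledger.closure_residual(series, name).max() < 1e-9, name

    def test_moiety_conservation_within_numerical_drift(self, scheme, n20_run):
        # linear invariants drift only by linear-solve roundoff accumulation
        series, _, _ = n20_run
        for moiety in scheme.moiety_maps:
            v = scheme.moiety_vector(moiety)
            total = series.conc @ v
            assert np.abs(total - total[0]).max() / total[0] < 1e-11, moiety


class TestDiffusionScaling:
    def test_unit_scale_keeps_printed_constants(self, scheme):
        system = fr.build_rate_system(scheme, diffusion_scale=1.0)
        printed = np.array([r.k for r in scheme.reactions])
        assert np.array_equal(system.k, printed)

    def test_fully_diffusion_limited_scales_linearly(self, scheme):
        system = fr.build_rate_system(scheme, diffusion_scale=0.01)
        r2 = scheme.reaction("(2)")
        j = system.reaction_labels.index("(2)")
        assert system.k[j] == pytest.approx(0.01 * r2.k)

    def test_activation_controlled_unaffected(self, scheme):
        system = fr.build_rate_system(scheme, diffusion_scale=0.01)
        for label in ("R10", "R23", "(1)", "(7)"):
            j = system.reaction_labels.index(label)
            assert system.k[j] == scheme.reaction(label).k

    def test_collins_kimball_with_explicit_activation_rate(self, scheme):
        # 1/k = 1/k_act + 1/(s k_diff), k_diff recovered from the printed k
        label, k_act, s = "(2)", 4e9, 0.01
        k_obs = scheme.reaction(label).k
        k_diff = 1 / (1 / k_obs - 1 / k_act)
        system = fr.build_rate_system(
            scheme, diffusion_scale=s, activation_rates={label: k_act}
        )
        j = system.reaction_labels.index(label)
        assert system.k[j] == pytest.approx(1 / (1 / k_act + 1 / (s * k_diff)))


class TestFluxDecomposition:
    def test_oxygen_sources_and_sinks_match_stoichiometry(self, n20_run):
        _, ledger, _ = n20_run
        dec = fr.flux_decomposition(ledger, "O2")
        sinks = set(dec[dec.role == "consumption"].reaction)
        sources = set(dec[dec.role == "formation"].reaction)
        assert sinks == {"(2)", "R3", "R4", "R18", "R23"}
        # W10 (hydroxyl + superoxide) is a water-core O2 source
        assert sources == {"R5", "R6", "R11", "R19", "W10"}

    def test_signed_contributions_close_the_balance(self, n20_run):
        series, ledger, _ = n20_run
        for species in ("O2", "ROO_r", "GSH"):
            dec = fr.flux_decomposition(ledger, species)
            net = series[species][-1] - series[species][0]
            assert dec.delta_m.sum() == pytest.approx(net, abs=1e-9)

    def test_unknown_species_raises(self, n20_run):
        _, ledger, _ = n20_run
        with pytest.raises(KeyError):
            fr.flux_decomposition(ledger, "unobtainium")

    def test_termination_fractions_exclude_chain_transfer(self, n20_run):
        _, ledger, _ = n20_run
        frac = peroxyl_termination_fractions(ledger)
        assert "R10" not in frac.index
        assert frac.sum() == pytest.approx(1.0)
        assert frac.idxmax() == "(7)"  # ascorbate H-donation dominates


class TestOxygenDepletionCurve:
    def test_starts_at_zero_and_bounded_by_pool(self, n20_run):
        series, ledger, pulse = n20_run
        table = fr.oxygen_depletion_curve(series, ledger, pulse)
        assert table.g_minus_o2.iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert (table.depleted_o2_m <= 30e-6 + 1e-12).all()
        assert table.depleted_o2_m.iloc[-1] > 0

    def test_g_and_concentration_columns_consistent(self, n20_run):
        series, ledger, pulse = n20_run
        table = fr.oxygen_depletion_curve(series, ledger, pulse)
        dose = fr.pulse_dose(pulse).dose
        back = fr.g_to_concentration(table.g_minus_o2.values, dose)
        assert np.allclose(back, table.depleted_o2_m.values, atol=1e-15)
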