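"""Spur-ensemble generation and independent-reaction-times chemistry."""

import math

import numpy as np
import pytest

import flashrod as fr
from flashrod.spur_irt import (
    SpurEnsemble,
    SpurParams,
    ensemble_yields,
    generate_ensembles,
    generate_tracks,
    irt_simulate,
    reaction_radius,
    sample_pair_reaction_time,
    sample_scavenging_time,
)


class TestReactionRadius:
    def test_hand_arithmetic(self):
        # k/(4 pi D N_A') with k=2e9, D=5e-9 -> ~0.053 nm
        assert reaction_radius(2e9, 5e-9) == pytest.approx(0.0529, rel=1e-2)

    def test_inverse_proportional_to_diffusion(self):
        assert reaction_radius(2e9, 1e-8) == pytest.approx(
            reaction_radius(2e9, 5e-9) / 2
        )

    def test_vanishes_with_rate(self):
        assert reaction_radius(0.0, 5e-9) == 0.0


class TestPairReactionTime:
    def test_contact_reacts_immediately(self):
        rng = np.random.default_rng(0)
        assert sample_pair_reaction_time(0.5, 0.5, 5e-9, rng) == 0.0

    def test_reaction_probability_is_r_over_r0(self):
        rng = np.random.default_rng(1)
        n = 100_000
        for ratio in (1.5, 2.0, 5.0):
            R = 0.25
            hits = sum(
                math.isfinite(sample_pair_reaction_time(ratio * R, R, 5e-9, rng))
                for _ in range(n)
            )
            w = 1.0 / ratio
            sigma = math.sqrt(w * (1 - w) / n)
            assert abs(hits / n - w) < 3 * sigma + 1e-12

    def test_median_time_scales_inversely_with_diffusion(self):
        # time quantiles of the conditional first-passage law go as 1/D
        rng1, rng2 = np.random.default_rng(2), np.random.default_rng(2)
        t1 = [sample_pair_reaction_time(1.0, 0.5, 5e-9, rng1) for _ in range(2000)]
        t2 = [sample_pair_reaction_time(1.0, 0.5, 5e-11, rng2) for _ in range(2000)]
        m1 = np.median([t for t in t1 if math.isfinite(t)])
        m2 = np.median([t for t in t2 if math.isfinite(t)])
        assert m2 / m1 == pytest.approx(100, rel=0.05)


class TestScavengingTime:
    def test_oxygen_scavenging_power_of_electron(self):
        # 1.9e10 x 30 uM = 5.7e5 s^-1 mean rate
        rng = np.random.default_rng(3)
        times = [sample_scavenging_time(1.9e10, 30e-6, rng) for _ in range(20000)]
        assert np.mean(times) == pytest.approx(1 / 5.7e5, rel=0.05)

    def test_substrate_capture_time_of_hydroxyl(self):
        rng = np.random.default_rng(4)
        times = [sample_scavenging_time(5e8, 1.0, rng) for _ in range(20000)]
        assert np.mean(times) == pytest.approx(2e-9, rel=0.05)

    def test_zero_concentration_never_reacts(self):
        rng = np.random.default_rng(5)
        assert sample_scavenging_time(1e10, 0.0, rng) == math.inf


class TestGenerateTracks:
    def test_empty_pulse_gives_empty_ensemble(self):
        ens = generate_tracks(fr.PulseSpec(N=0), SpurParams(), seed=0)
        assert len(ens) == 0

    def test_mean_spur_population(self):
        # 300 eV per track / 47.5 eV per spur ~ 6.3 spurs -> ~126 over 20
        # tracks; ~16 species per 100 eV -> ~950 particles on average
        params = SpurParams(seed=0)
        sizes = [
            len(generate_tracks(fr.PulseSpec(N=20), params, seed=s)) for s in range(40)
        ]
        per_100ev = sum(params.per_spur_yields.values())
        expected = 20 * 300 / 100 * per_100ev
        assert np.mean(sizes) == pytest.approx(expected, rel=0.05)

    def test_ensemble_mean_yields_match_generator(self):
        params = SpurParams(seed=1)
        counts = []
        for s in range(300):
            ens = generate_tracks(fr.PulseSpec(N=2), params, seed=s)
            counts.append(sum(1 for x in ens.species if x == "OH_r"))
        g_oh = np.mean(counts) * 100 / 600  # 2 tracks x 300 eV
        se = np.std(counts, ddof=1) / math.sqrt(len(counts)) * 100 / 600
        assert abs(g_oh - params.per_spur_yields["OH_r"]) < 3 * se

    def test_every_realization_is_electroneutral(self, scheme):
        charges = {n: sp.charge for n, sp in scheme.species.items()}
        for s in range(10):
            ens = generate_tracks(fr.PulseSpec(N=5), SpurParams(), seed=s)
            assert sum(charges[x] for x in ens.species) == 0

    def test_entry_points_inside_beam_radius(self):
        ens = generate_tracks(fr.PulseSpec(N=50), SpurParams(spur_sigma=0.01, electron_sigma=0.01), seed=2)
        radial = np.linalg.norm(ens.positions[:, :2], axis=1)
        assert radial.max() < 0.11e-6  # R_o plus a little spur width


def _two_particle_ensemble(species, separation_nm):
    pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, separation_nm * 1e-9]])
    return SpurEnsemble(pos, list(species), fr.PulseSpec(N=1))


def _empty_composition():
    return fr.CellComposition(o2=0, rh=0, gsh=0, ah=0, no=0, toh=0)


class TestIrtSimulate:
    def test_isolated_radical_never_reacts(self, scheme):
        ens = SpurEnsemble(np.zeros((1, 3)), ["OH_r"], fr.PulseSpec(N=1))
        res = irt_simulate(ens, scheme, _empty_composition(), t_end=1.0, seed=0)
        assert res.event_log == []
        assert res.count("OH_r")[-1] == 1

    def test_hydroxyl_pair_reacts_with_smoluchowski_probability(self, scheme):
        # two OH at r0 = 2 R react in half of the realizations
        d_sum = 2 * scheme.species["OH_r"].diffusion_coefficient
        R = reaction_radius(scheme.reaction("W7").k, d_sum)
        n = 4000
        hits = 0
        for s in range(n):
            ens = _two_particle_ensemble(["OH_r", "OH_r"], 2 * R)
            res = irt_simulate(ens, scheme, _empty_composition(), t_end=10.0, seed=s)
            hits += len(res.event_log)
        sigma = math.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * sigma

    def test_substrate_scavenging_dominates_hydroxyl_fate(self, scheme):
        # 1 M RH captures OH within ~2 ns; <5% survive to 10 ns
        params = SpurParams(seed=3)
        ens = generate_tracks(fr.PulseSpec(N=10), params, seed=3)
        res = irt_simulate(ens, scheme, fr.CellComposition(), t_end=1e-8, seed=3)
        i10 = int(np.argmin(np.abs(res.times - 1e-8)))
        assert res.count("OH_r")[i10] < 0.05 * res.count("OH_r")[0]

    def test_moiety_counts_conserved_exactly(self, scheme):
        ens = generate_tracks(fr.PulseSpec(N=5), SpurParams(seed=4), seed=4)
        res = irt_simulate(ens, scheme, fr.CellComposition(), t_end=0.2e-6, seed=4)
        for moiety in scheme.moiety_maps:
            v = scheme.moiety_vector(moiety)
            totals = res.counts @ v
            assert np.all(totals == totals[0]), moiety

    def test_finite_oxygen_pool_never_negative(self, scheme):
        comp = fr.CellComposition()
        ens = generate_tracks(fr.PulseSpec(N=20), SpurParams(seed=5), seed=5)
        res = irt_simulate(ens, scheme, comp, t_end=1e-5, seed=5)
        assert res.count("O2").min() >= 0

    def test_slower_diffusion_increases_radical_survival(self, scheme):
        # pair recombination stretches ~x100 in time while substrate
        # scavenging (activation-controlled) is unchanged
        survive = {}
        for scale in (1.0, 0.01):
            tot = 0.0
            for s in range(5):
                ens = generate_tracks(fr.PulseSpec(N=10), SpurParams(seed=6), seed=60 + s)
                res = irt_simulate(
                    ens, scheme, _empty_composition(), t_end=1e-7, seed=s,
                    diffusion_scale=scale,
                )
                radicals = ["e_aq", "OH_r", "H_r"]
                tot += sum(res.count(r)[-1] for r in radicals)
            survive[scale] = tot
        assert survive[0.01] >= survive[1.0]


class TestEnsembleYields:
    def test_single_realization_flags_undefined_se(self, scheme):
        ens = generate_tracks(fr.PulseSpec(N=2), SpurParams(seed=7), seed=7)
        res = irt_simulate(ens, scheme, fr.CellComposition(), t_end=1e-9, seed=7)
        ys = ensemble_yields([res])
        assert np.isnan(ys.se).all()

    def test_standard_error_shrinks_with_replicates(self, scheme):
        comp = fr.CellComposition()
        params = SpurParams(seed=8, replicates=16)
        runs = [
            irt_simulate(e, scheme, comp, t_end=1e-9, seed=80 + e.realization_id)
            for e in generate_ensembles(fr.PulseSpec(N=5), params)
        ]
        se_16 = np.nanmean(ensemble_yields(runs).se)
        se_4 = np.nanmean(ensemble_yields(runs[:4]).se)
        assert se_16 < se_4

    def test_handoff_charge_balances_with_buffered_protons(self, scheme):
        # the radiolytic charge perturbation equals exactly the implicit H+
        # drawn from (or released to) the buffered pool by the event history
        comp = fr.CellComposition()
        ens = generate_tracks(fr.PulseSpec(N=10), SpurParams(seed=9), seed=9)
        res = irt_simulate(ens, scheme, comp, t_end=1e-9, seed=9)
        charges = {n: sp.charge for n, sp in scheme.species.items()}
        state = res.concentrations_at(1e-9)
        per_molecule = 1.0 / (6.02214076e23 * ens.pulse.volume_l)
        # resting pools are integer molecule counts in the cylinder volume
        resting = {
            n: round(c / per_molecule) * per_molecule for n, c in comp.as_dict().items()
        }
        radiolytic = sum(
            charges[n] * (c - resting.get(n, 0.0)) for n, c in state.items()
        )
        expected = per_molecule * sum(
            scheme.reaction(label).implicit_protons for _, label in res.event_log
        )
        assert radiolytic == pytest.approx(expected, abs=per_molecule * 1e-6)
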