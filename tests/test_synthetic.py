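"""Synthetic spectra, assay scenarios, and Poisson TCSPC simulation."""

import json

import numpy as np
import pytest

from fretcascade.decay_fitting import fit_decay, read_decay_csv
from fretcascade.kinetics import DeltaPulse, solve_populations
from fretcascade.spectra import overlap_integral, read_spectrum_csv
from fretcascade.synthetic import (
    ScenarioSpec, SyntheticError, build_scenario, fluorophore,
    make_vibronic_spectrum, network_state_mixture, preset_forster_distances,
    simulate_tcspc, table1_model, tamra_gain_demo, write_fixture_set)


class TestVibronicSpectra:
    def test_cp_emission_has_published_peak_structure(self):
        """CP emission peaks at 426.6 nm with a secondary maximum at 451 nm."""
        cp = fluorophore("CP")
        em = cp.emission
        assert em.peak_nm == pytest.approx(426.6, abs=0.5)
        # secondary vibronic maximum near 451 nm: local max within ±5 nm
        sel = np.abs(em.wavelengths_nm - 451.0) < 5.0
        local_peak = em.wavelengths_nm[sel][np.argmax(em.values[sel])]
        assert abs(local_peak - 451.0) < 5.0

    def test_fam_absorption_preset(self):
        """6-FAM absorption peaks at 490.4 nm with ε_max = 1.25e4."""
        fam = fluorophore("FAM")
        assert fam.absorption.peak_nm == pytest.approx(490.4, abs=0.5)
        assert fam.absorption.values.max() == pytest.approx(1.25e4, rel=1e-9)

    def test_tamra_absorption_preset(self):
        tamra = fluorophore("TAMRA")
        assert tamra.absorption.peak_nm == pytest.approx(567.6, abs=0.5)
        assert tamra.absorption.values.max() == pytest.approx(1.96e4, rel=1e-9)

    def test_mirror_twice_is_involution(self):
        spec = make_vibronic_spectrum("emission", [514.4], 15.0)
        m1 = make_vibronic_spectrum("absorption", [], 15.0, mirror_of=spec,
                                    zero_zero_nm=502.0)
        m2 = make_vibronic_spectrum("emission", [], 15.0, mirror_of=m1,
                                    zero_zero_nm=502.0)
        inside = (spec.wavelengths_nm > 350) & (spec.wavelengths_nm < 750)
        np.testing.assert_allclose(m2.values[inside], spec.values[inside],
                                   atol=1e-6)

    def test_peaks_outside_range_rejected(self):
        with pytest.raises(SyntheticError):
            make_vibronic_spectrum("emission", [250.0], 15.0)

    def test_overlap_ratio_calibrated_to_published_value(self):
        """J(CP/6-FAM)/J(CP/TAMRA) of the preset spectra falls within 20% of
        the published 3.09 ratio."""
        cp, fam, tamra = (fluorophore(n) for n in ("CP", "FAM", "TAMRA"))
        J_cf = overlap_integral(cp.emission, fam.absorption).J
        J_ct = overlap_integral(cp.emission, tamra.absorption).J
        ratio = J_cf / J_ct
        assert ratio == pytest.approx(2.47e-26 / 8.00e-27, rel=0.20)


class TestScenarios:
    def test_free_scenario_has_no_transfer(self):
        net = build_scenario(ScenarioSpec.preset("free"))
        assert net.transfers == {}
        assert 1.0 / net.outflow_rate("FAM") == pytest.approx(3.72, rel=1e-9)

    def test_potassium_shortens_fam_tamra_distance_and_raises_rate(self):
        no_k = build_scenario(ScenarioSpec.preset("complex_no_K"))
        with_k = build_scenario(ScenarioSpec.preset("complex_with_K"))
        assert (with_k.transfers[("FAM", "TAMRA")]
                > no_k.transfers[("FAM", "TAMRA")])
        assert (ScenarioSpec.preset("complex_with_K").R_fam_tamra
                < ScenarioSpec.preset("complex_no_K").R_fam_tamra)

    def test_invalid_distances_rejected(self):
        with pytest.raises(SyntheticError):
            ScenarioSpec(tag="complex_with_K", R_cp_fam=-3.0)

    def test_calibrated_with_K_reproduces_fast_cp_lifetime(self):
        """The with-K⁺ scenario, simulated and refitted, recovers a CP fast
        lifetime within 15% of the published 0.19 ns."""
        net = build_scenario(ScenarioSpec.preset("complex_with_K"))
        trace = simulate_tcspc(net, state="CP", pulse=DeltaPulse({"CP": 1.0}),
                               total_counts=1_000_000, seed=21)
        fit = fit_decay(trace, 1)
        assert fit.model.lifetimes_ns[0] == pytest.approx(0.19, rel=0.15)

    def test_network_state_mixture_matches_solver(self):
        net = build_scenario(ScenarioSpec.preset("complex_with_K"))
        amps, taus = network_state_mixture(net, "TAMRA",
                                           DeltaPulse({"CP": 1.0}))
        t = np.linspace(0.0, 10.0, 1001)
        mixture = sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))
        traj = solve_populations(net, DeltaPulse({"CP": 1.0}), t)
        np.testing.assert_allclose(mixture, traj.population("TAMRA"),
                                   atol=1e-10)

    def test_forster_distances_are_plausible(self):
        r0 = preset_forster_distances()
        assert 20.0 < r0["CP/TAMRA"] < r0["CP/FAM"] < r0["FAM/TAMRA"] < 60.0


class TestSimulateTcspc:
    def test_same_seed_is_bit_identical(self):
        a = simulate_tcspc(table1_model("cp_with_K"), total_counts=50_000,
                           seed=9)
        b = simulate_tcspc(table1_model("cp_with_K"), total_counts=50_000,
                           seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_different_seed_differs(self):
        a = simulate_tcspc(table1_model("cp_with_K"), total_counts=50_000,
                           seed=9)
        b = simulate_tcspc(table1_model("cp_with_K"), total_counts=50_000,
                           seed=10)
        assert not np.array_equal(a.counts, b.counts)

    def test_counts_budget_respected(self):
        n = 1_000_000
        trace = simulate_tcspc(table1_model("fam_free"), total_counts=n,
                               seed=3)
        assert abs(trace.total_counts - n) < 4 * np.sqrt(n)

    def test_replicate_mean_converges_to_expected_curve(self):
        """The mean of 200 replicates tracks the expected curve within
        3σ/√200 per bin."""
        n_rep, counts = 200, 20_000
        model = table1_model("tamra_no_K")
        traces = [simulate_tcspc(model, total_counts=counts, n_bins=256,
                                 seed=s) for s in range(n_rep)]
        stack = np.stack([tr.counts for tr in traces])
        mean = stack.mean(axis=0)
        from fretcascade.decay_fitting import multi_exp_reconvolve
        t = traces[0].time_ns
        irf = traces[0].irf
        sig = multi_exp_reconvolve(model.amplitudes, model.lifetimes_ns, irf,
                                   t, traces[0].rep_period_ns)
        sig = sig / sig.sum()
        bg = 1e-4 * sig.max() * np.ones_like(sig)
        expected = (sig + bg) * counts / (sig + bg).sum()
        sigma = np.sqrt(np.maximum(expected, 1e-12))
        assert np.all(np.abs(mean - expected) < 4 * sigma / np.sqrt(n_rep) + 1e-9)


class TestGainDemo:
    def test_calibration_reproduces_published_readout(self):
        """The calibrated TAMRA curves give exactly 100 and 330 at 2 ns, a
        4-fold initial enhancement, and a decreasing efficiency transient."""
        t = np.linspace(0.0, 4.0, 4001)
        I_wo, I_with = tamra_gain_demo(t)
        assert np.interp(2.0, t, I_wo) == pytest.approx(100.0, rel=1e-9)
        assert np.interp(2.0, t, I_with) == pytest.approx(330.0, rel=1e-9)
        assert I_with[0] / I_wo[0] == pytest.approx(4.0, rel=1e-9)
        # initial efficiency exceeds the 2 ns plateau value
        eta0 = I_with[0] / I_wo[0] - 1.0
        eta2 = np.interp(2.0, t, I_with) / np.interp(2.0, t, I_wo) - 1.0
        assert eta0 > eta2
        assert eta0 == pytest.approx(3.0, rel=1e-9)


class TestFixtureSet:
    def test_manifest_enumerates_full_suite(self, tmp_path):
        manifest = write_fixture_set(tmp_path, seed=1, total_counts=20_000)
        assert len(manifest["spectra"]) == 6
        assert len(manifest["decays"]) >= 11

    def test_regeneration_is_byte_identical(self, tmp_path):
        m1 = write_fixture_set(tmp_path / "a", seed=4, total_counts=10_000)
        m2 = write_fixture_set(tmp_path / "b", seed=4, total_counts=10_000)
        h1 = {d["file"]: d["sha256"] for d in m1["decays"]}
        h2 = {d["file"]: d["sha256"] for d in m2["decays"]}
        assert h1 == h2

    def test_fixtures_round_trip_through_readers(self, tmp_path):
        manifest = write_fixture_set(tmp_path, seed=2, total_counts=10_000)
        for entry in manifest["spectra"][:2]:
            spec = read_spectrum_csv(tmp_path / entry["file"],
                                     kind=entry["kind"])
            assert spec.wavelengths_nm.size > 100
        irf_file = next(d["irf"] for d in manifest["decays"] if "irf" in d)
        entry = manifest["decays"][0]
        trace = read_decay_csv(tmp_path / entry["file"],
                               irf_path=tmp_path / irf_file,
                               meta_path=tmp_path / entry["meta"])
        assert trace.total_counts > 0
        with open(tmp_path / "manifest.json") as fh:
            assert json.load(fh)["seed"] == 2
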