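"""Synthetic-run generator: determinism, planted-signal recovery, and the
statistical structure it is supposed to emulate."""

import math

import numpy as np
import pandas as pd
import pytest

from hrmscreen import chem, simgen
from hrmscreen.msdata import extract_eic
from hrmscreen.screen import ScreenConfig, detect_peaks, screen_batch
from hrmscreen.simgen import (
    AnalyteModel,
    Interference,
    MatrixProfile,
    SimConfig,
    make_demo_db,
    make_panel,
    simulate_run,
    truth_two_ion_detectable,
)


class TestDemoDb:
    def test_deterministic(self):
        a = make_demo_db(10, seed=5)
        b = make_demo_db(10, seed=5)
        assert [e.name for e in a] == [e.name for e in b]

    def test_secondary_ions_resolve_within_scan_range(self):
        for entry in make_demo_db(12, seed=0):
            assert 55.0 <= entry.primary_mz() <= 1000.0
            assert 55.0 <= entry.secondary_mz() <= 1000.0

    def test_contains_imazalil_with_dichloro_fragment(self):
        db = make_demo_db(10, seed=3)
        imazalil = next(e for e in db if e.name == "imazalil")
        assert imazalil.secondary_kind == "fragment"
        assert chem.parse_formula(imazalil.secondary_value) == {"C": 7, "H": 5, "Cl": 2}

    def test_contains_rrt_reference_compound(self):
        assert any(e.name == "diuron" for e in make_demo_db(4, seed=9))

    def test_bounds(self):
        with pytest.raises(ValueError):
            make_demo_db(0)
        with pytest.raises(ValueError):
            make_demo_db(99)


class TestPanel:
    def test_response_factors_span_the_configured_range(self, panel):
        rfs = [m.response_factor for m in panel]
        assert max(rfs) / min(rfs) == pytest.approx(600.0, rel=1e-6)

    def test_m1_bias_tracks_carbon_count(self, panel):
        for m in panel:
            n_c = m.entry.formula.get("C", 0)
            assert 0.47 <= m.m1_bias <= 1.0
            if n_c <= 5:
                assert m.m1_bias == pytest.approx(0.47)

    def test_m2_bias_range(self, panel):
        assert all(0.8 <= m.m2_bias <= 1.0 for m in panel)


class TestSimulateRun:
    def test_same_seed_is_bit_identical(self, panel):
        m = MatrixProfile("m", suppression=2.0)
        r1, t1 = simulate_run(panel, m, 0.05, SimConfig(), seed=11)
        r2, t2 = simulate_run(panel, m, 0.05, SimConfig(), seed=11)
        assert len(r1.spectra) == len(r2.spectra)
        for a, b in zip(r1.spectra, r2.spectra):
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)
        pd.testing.assert_frame_equal(t1, t2)

    def test_blank_run_contains_no_analytes(self, panel, demo_db, screen_config):
        clean = MatrixProfile("clean", spike_rate=0.0, leakage_fraction=0.0)
        run, truth = simulate_run(panel, clean, 0.0, SimConfig(), seed=4)
        assert truth.empty
        table = screen_batch([run], demo_db, screen_config, strategy="two-ion")
        assert not table["detected"].any()

    def test_negative_level_rejected(self, panel):
        with pytest.raises(ValueError):
            simulate_run(panel, MatrixProfile("m"), -0.01, SimConfig(), seed=0)

    def test_events_alternate_at_one_hertz(self, panel):
        run, _ = simulate_run(panel[:2], MatrixProfile("m"), 0.05, SimConfig(run_length_min=2.0), seed=0)
        events = [s.event for s in run.spectra]
        assert events[:4] == [1, 2, 1, 2]
        dt = run.spectra[2].time_min - run.spectra[0].time_min
        assert dt == pytest.approx(1.0 / 60.0)

    def test_planted_area_recovered_within_ten_percent(self, panel, screen_config):
        clean = MatrixProfile("clean", suppression=2.5, spike_rate=0.0)
        run, truth = simulate_run(panel, clean, 0.20, SimConfig(), seed=8)
        for _, row in truth.iterrows():
            entry = next(m.entry for m in panel if m.entry.name == row["analyte"])
            eic = extract_eic(run, entry.primary_mz(), 5.0, event=1)
            peaks = detect_peaks(eic, (entry.rt_min - 0.5, entry.rt_min + 0.5), screen_config)
            assert peaks, entry.name
            best = max(peaks, key=lambda p: p.area)
            assert best.area == pytest.approx(row["area_primary"], rel=0.10)

    def test_planted_mass_errors_stay_within_five_ppm(self, panel):
        run, truth = simulate_run(panel, MatrixProfile("m", spike_rate=0.0), 0.20, SimConfig(), seed=3)
        for m in panel:
            eic = extract_eic(run, m.entry.primary_mz(), 5.0, event=1)
            sel = np.isfinite(eic.mz_observed) & (eic.intensity > 1000)
            if sel.any():
                err = np.abs(eic.mz_observed[sel] - m.entry.primary_mz()) / m.entry.primary_mz() * 1e6
                assert err.max() <= 5.0 + 1e-6


class TestValidationSet:
    def test_cardinality(self, validation_set, sim_config):
        runs, design, truth, profiles = validation_set
        assert len(runs) == sim_config.n_commodities * (1 + len(sim_config.levels)) == 84
        assert len(design.commodities) == 21
        assert len(profiles) == 21

    def test_suppression_within_declared_range(self, validation_set):
        _, _, _, profiles = validation_set
        for p in profiles:
            assert 1.0 <= p.suppression <= 10.0

    def test_truth_lists_every_spiked_combination(self, validation_set, panel):
        _, design, truth, _ = validation_set
        expected = len(panel) * len(design.commodities) * len(design.nonzero_levels)
        assert len(truth) == expected

    def test_response_factor_recovery(self, validation_set, demo_db, panel, screen_config, two_ion_results):
        """Regressing recovered areas (corrected for the known suppression)
        against spike level returns each configured response factor."""
        _, _, _, profiles = validation_set
        supp = {p.label: p.suppression for p in profiles}
        detected = two_ion_results[two_ion_results["detected"] & (two_ion_results["level"] > 0)].copy()
        detected["supp"] = detected["matrix"].map(supp)
        for m in panel:
            sub = detected[detected["analyte"] == m.entry.name]
            if len(sub) < 10:
                continue
            x = sub["level"].to_numpy()
            y = (sub["response_primary"] * sub["supp"]).to_numpy()
            rf_est = float((x * y).sum() / (x * x).sum())
            assert rf_est == pytest.approx(m.response_factor, rel=0.15), m.entry.name

    def test_isotope_ratio_matches_biased_theory(self, validation_set, panel, two_ion_results):
        """Measured isotope/monoisotopic ratios equal theoretical RIA times
        the configured bias factor, within 3 RSDs."""
        detected = two_ion_results[two_ion_results["detected"] & (two_ion_results["level"] > 0)]
        checked = 0
        for m in panel:
            if m.entry.secondary_kind != "isotope":
                continue
            sub = detected[detected["analyte"] == m.entry.name]
            ratios = (sub["response_secondary"] / sub["response_primary"]).dropna()
            if len(ratios) < 10:
                continue
            k = int(m.entry.secondary_value[2:])
            ion = chem.combine_formulas(m.entry.formula, m.entry.adduct.delta)
            ria = chem.isotope_pattern(ion, 4).relative_abundance(k)
            bias = m.m1_bias if k == 1 else m.m2_bias
            expected = ria * bias
            assert abs(ratios.mean() - expected) <= 3 * ratios.std(), m.entry.name
            checked += 1
        assert checked >= 3

    def test_fragment_ratio_attenuated_in_matrix(self, validation_set, panel, two_ion_results):
        """Fragment/precursor ratios in matrix average ~0.83 of solvent."""
        detected = two_ion_results[two_ion_results["detected"] & (two_ion_results["level"] > 0)]
        factors = []
        for m in panel:
            if m.entry.secondary_kind != "fragment":
                continue
            sub = detected[detected["analyte"] == m.entry.name]
            ratios = (sub["response_secondary"] / sub["response_primary"]).dropna()
            if len(ratios) >= 20:
                factors.append(ratios.mean() / m.frag_ratio_solvent)
        assert factors
        assert np.mean(factors) == pytest.approx(0.83, abs=0.08)

    def test_isotope_ratios_less_variable_than_fragment_ratios(self, panel, two_ion_results):
        detected = two_ion_results[two_ion_results["detected"] & (two_ion_results["level"] > 0)]
        rsds = {"isotope": [], "fragment": []}
        for m in panel:
            sub = detected[detected["analyte"] == m.entry.name]
            ratios = (sub["response_secondary"] / sub["response_primary"]).dropna()
            if len(ratios) >= 20:
                rsds[m.entry.secondary_kind].append(ratios.std() / ratios.mean())
        assert np.mean(rsds["isotope"]) < np.mean(rsds["fragment"])


class TestBlankSet:
    def test_has_enough_interferences(self, blank_set):
        runs, profiles = blank_set
        assert len(runs) == 21
        assert sum(len(p.interferences) for p in profiles) >= 5
        assert all(r.metadata.extra["level"] == 0.0 for r in runs)


class TestDetectabilityOracle:
    def test_clean_strong_signal_is_detectable(self, panel, screen_config):
        clean = MatrixProfile("clean", spike_rate=0.0)
        _, truth = simulate_run(panel, clean, 0.20, SimConfig(), seed=2)
        tt = truth_two_ion_detectable(truth, screen_config, [clean], panel)
        strong = tt[tt["height_secondary"] > 10 * screen_config.min_height]
        assert strong["detectable_two_ion"].all()

    def test_subfloor_signal_is_not_detectable(self, panel, screen_config):
        clean = MatrixProfile("weak", suppression=10.0, spike_rate=0.0)
        _, truth = simulate_run(panel, clean, 0.01, SimConfig(), seed=2)
        tt = truth_two_ion_detectable(truth, screen_config, [clean], panel)
        weak = tt[tt["height_secondary"] < 0.5 * screen_config.min_height]
        assert not weak["detectable_two_ion"].any()
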