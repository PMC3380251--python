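"""Peak detection and the screening strategies."""

import math

import numpy as np
import pandas as pd
import pytest

from hrmscreen import chem, screen, simgen
from hrmscreen.msdata import EIC, extract_eic
from hrmscreen.screen import (
    DbEntry,
    PeakDetection,
    ScreenConfig,
    ScreenHit,
    apply_threshold,
    compute_individual_thresholds,
    detect_peaks,
    read_db_csv,
    screen_batch,
    screen_max_scan,
    screen_one_ion,
    screen_two_ion,
    write_db_csv,
)
from .conftest import gaussian_run


def _eic(times, values):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    return EIC(200.0, 5.0, 1, times, values, np.full(times.size, 200.0))


def _entry(name="toy", rt=2.0, formula="C8H14ClN5", kind="isotope", value="M+2"):
    return DbEntry(
        name=name,
        rt_min=rt,
        formula=chem.parse_formula(formula),
        adduct=chem.ADDUCTS["[M+H]+"],
        secondary_kind=kind,
        secondary_value=value,
    )


class TestDetectPeaks:
    def test_flat_zero_trace(self):
        t = np.arange(100) / 60.0
        assert detect_peaks(_eic(t, np.zeros(100)), (0.0, 2.0)) == []

    def test_single_scan_spike_rejected(self):
        t = np.arange(100) / 60.0
        y = np.zeros(100)
        y[50] = 5e4
        assert detect_peaks(_eic(t, y), (0.0, 2.0)) == []

    def test_gaussian_area_matches_closed_form(self):
        sigma_s, height = 3.0, 1e6
        t = np.arange(240) / 60.0
        y = height * np.exp(-0.5 * ((t - 2.0) / (sigma_s / 60.0)) ** 2)
        peaks = detect_peaks(_eic(t, y), (1.0, 3.0))
        assert len(peaks) == 1
        expected = height * (sigma_s / 60.0) * math.sqrt(2 * math.pi)
        assert peaks[0].area == pytest.approx(expected, rel=0.05)
        assert peaks[0].rt_min == pytest.approx(2.0, abs=0.02)

    def test_shoulder_peak_next_to_larger_one_is_resolved(self):
        t = np.arange(240) / 60.0
        s = 3.0 / 60.0
        y = 4e4 * np.exp(-0.5 * ((t - 2.15) / s) ** 2) + 5e3 * np.exp(-0.5 * ((t - 1.95) / s) ** 2)
        rts = sorted(p.rt_min for p in detect_peaks(_eic(t, y), (1.0, 3.0)))
        assert len(rts) == 2
        assert rts[0] == pytest.approx(1.95, abs=0.03)
        assert rts[1] == pytest.approx(2.15, abs=0.03)

    def test_peak_below_noise_floor_ignored(self):
        t = np.arange(240) / 60.0
        y = 50.0 * np.exp(-0.5 * ((t - 2.0) / (3.0 / 60.0)) ** 2)
        assert detect_peaks(_eic(t, y), (1.0, 3.0), ScreenConfig(min_height=100.0)) == []


class TestMaxScanVsPeak:
    def test_lone_spike_hits_in_max_scan_mode_only(self):
        entry = _entry()
        mz = entry.primary_mz()
        run = gaussian_run([], run_length_min=4.0)
        # inject a single-scan spike at the target mass inside the window
        for s in run.spectra:
            if s.event == 1 and abs(s.time_min - 2.0) < 1e-6:
                s.mz = np.array([mz])
                s.intensity = np.array([5e4])
        hit = screen_max_scan(run, entry, ScreenConfig(mode="max_scan"))
        assert hit is not None
        assert hit.primary.height == pytest.approx(5e4)
        assert screen_one_ion(run, entry, ScreenConfig(mode="peak")) is None

    def test_all_zero_window_no_hit(self):
        entry = _entry()
        run = gaussian_run([(1, 300.0, 2.0, 1e5)], run_length_min=4.0)
        assert screen_max_scan(run, entry, ScreenConfig(mode="max_scan")) is None


class TestThresholds:
    def _hits(self, responses):
        return [
            ScreenHit(f"a{i}", PeakDetection("primary", 1.0, r, r, 100.0, 0.0))
            for i, r in enumerate(responses)
        ]

    def test_zero_threshold_is_identity(self):
        hits = self._hits([5e4, 2e5, 9e5])
        cfg = ScreenConfig(threshold_mode="fixed", fixed_threshold=0.0)
        assert len(apply_threshold(hits, cfg)) == 3

    def test_fixed_threshold_is_strict(self):
        hits = self._hits([5e4, 2e5, 9e5])
        cfg = ScreenConfig(threshold_mode="fixed", fixed_threshold=2e5)
        kept = apply_threshold(hits, cfg)
        assert [h.response for h in kept] == [9e5]

    def test_individual_threshold_boundary_dropped(self):
        hits = self._hits([1e5])
        cfg = ScreenConfig(threshold_mode="individual")
        kept = apply_threshold(hits, cfg, individual={"a0": 1e5})
        assert kept == []

    def test_missing_individual_threshold_drops_with_warning(self, caplog):
        hits = self._hits([1e5])
        cfg = ScreenConfig(threshold_mode="individual")
        with caplog.at_level("WARNING"):
            kept = apply_threshold(hits, cfg, individual={})
        assert kept == []
        assert "no individual threshold" in caplog.text

    def test_individual_thresholds_are_half_the_minimum_response(self):
        entry = _entry()
        mz = entry.primary_mz()
        runs = [
            gaussian_run([(1, mz, 2.0, h)], run_length_min=4.0, run_id=f"m{i}")
            for i, h in enumerate((1e5, 4e5, 2e5))
        ]
        thresholds = compute_individual_thresholds(runs, [entry], ScreenConfig())
        areas = [screen_one_ion(r, entry, ScreenConfig()).response for r in runs]
        assert thresholds[entry.name] == pytest.approx(0.5 * min(areas))

    def test_undetected_analyte_gets_no_threshold(self, caplog):
        entry = _entry()
        runs = [gaussian_run([], run_length_min=4.0)]
        with caplog.at_level("WARNING"):
            thresholds = compute_individual_thresholds(runs, [entry], ScreenConfig())
        assert entry.name not in thresholds


class TestTwoIon:
    def _run(self, entry, delta_rt=0.0, with_secondary=True, height=1e5, ratio=0.3):
        ions = [(1, entry.primary_mz(), entry.rt_min, height)]
        if with_secondary:
            ions.append(
                (entry.secondary_event, entry.secondary_mz(), entry.rt_min + delta_rt, height * ratio)
            )
        return gaussian_run(ions, run_length_min=4.0)

    def test_coincident_ions_hit(self):
        entry = _entry()
        hit = screen_two_ion(self._run(entry), entry, ScreenConfig())
        assert hit is not None
        assert hit.delta_rt_min <= 0.05
        assert hit.secondary.area > 0

    def test_secondary_shifted_beyond_tolerance_misses(self):
        entry = _entry()
        assert screen_two_ion(self._run(entry, delta_rt=0.1), entry, ScreenConfig()) is None

    def test_primary_only_interference_misses(self):
        entry = _entry()
        run = self._run(entry, with_secondary=False)
        assert screen_one_ion(run, entry, ScreenConfig()) is not None
        assert screen_two_ion(run, entry, ScreenConfig()) is None

    def test_fragment_secondary_requires_event_two(self):
        entry = _entry(kind="fragment", value="C7H5Cl2")
        from hrmscreen.msdata import CentroidSpectrum, Run, RunMetadata

        run = Run(
            [CentroidSpectrum(i / 60.0, 1, np.array([100.0]), np.array([1.0])) for i in range(5)],
            RunMetadata(),
        )
        with pytest.raises(ValueError, match="one scan event"):
            screen_two_ion(run, entry, ScreenConfig())

    def test_two_ion_hits_subset_of_one_ion(self, validation_set, demo_db, screen_config, two_ion_results):
        runs, _, _, _ = validation_set
        one = screen_batch(runs, demo_db, screen_config, strategy="one-ion")
        merged = two_ion_results.merge(one, on=["analyte", "run"], suffixes=("_two", "_one"))
        assert not (merged["detected_two"] & ~merged["detected_one"]).any()

    def test_tightening_ppm_never_adds_hits(self, panel, demo_db):
        cfg = simgen.SimConfig()
        run, _ = simgen.simulate_run(panel, simgen.MatrixProfile("m", suppression=2.0), 0.05, cfg, seed=7)
        wide = {e.name for e in demo_db if screen_two_ion(run, e, ScreenConfig(ppm=5.0)) is not None}
        tight = {e.name for e in demo_db if screen_two_ion(run, e, ScreenConfig(ppm=2.0)) is not None}
        assert tight <= wide


class TestScreenBatch:
    def test_empty_db_gives_empty_table(self):
        run = gaussian_run([], run_length_min=2.0)
        table = screen_batch([run], [], ScreenConfig())
        assert len(table) == 0

    def test_cardinality(self, panel, demo_db):
        cfg = simgen.SimConfig()
        runs = [
            simgen.simulate_run(panel, simgen.MatrixProfile(f"m{i}"), 0.05, cfg, seed=i)[0]
            for i in range(4)
        ]
        table = screen_batch(runs, demo_db, ScreenConfig())
        assert len(table) == 4 * len(demo_db)

    def test_deterministic(self, panel, demo_db):
        cfg = simgen.SimConfig()
        run, _ = simgen.simulate_run(panel, simgen.MatrixProfile("m"), 0.05, cfg, seed=3)
        a = screen_batch([run], demo_db, ScreenConfig())
        b = screen_batch([run], demo_db, ScreenConfig())
        pd.testing.assert_frame_equal(a, b)


class TestDbCsv:
    def test_round_trip(self, demo_db, tmp_path):
        path = tmp_path / "db.csv"
        write_db_csv(demo_db, path)
        back = read_db_csv(path)
        assert [e.name for e in back] == [e.name for e in demo_db]
        for a, b in zip(demo_db, back):
            assert b.primary_mz() == pytest.approx(a.primary_mz(), abs=1e-9)
            assert b.secondary_mz() == pytest.approx(a.secondary_mz(), abs=1e-9)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "name,rt_min,formula,adduct,secondary_kind,secondary_value,threshold\n"
            "x,5.0,Qq3,[M+H]+,isotope,M+1,\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_db_csv(path)
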