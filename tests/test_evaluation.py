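"""Evaluation experiments: window widening, coverage, trendlines, accuracy."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import timsscreen as ts
from timsscreen import evaluation as ev


@pytest.fixture(scope="module")
def widened_scenario():
    # analytes absent, interferences deliberately outside the baseline
    # ±0.25 min window but inside the ×10 (±2.5 min) window
    cfg = dataclasses.replace(
        ts.ScenarioConfig(seed=3),
        analyte_absent_fraction=1.0,
        interference_fraction=1.0,
        interference_rt_offset_range=(0.3, 2.4),
    )
    lib, spectra = ts.generate_library(cfg)
    cloud, truth = ts.generate_peak_cloud(lib, cfg, spectra=spectra)
    cal = ts.fit_ccs_calibration(ts.calibrant_table(cfg))
    return cfg, lib, cloud, truth, cal


class TestRtWindowSensitivity:
    def test_factor_one_equals_baseline_screen(self, widened_scenario):
        _, lib, cloud, _, cal = widened_scenario
        win = ts.ScreeningWindows()
        baseline = ev.count_categories(ts.screen(cloud, lib, win, cal))
        out = ev.rt_window_sensitivity(cloud, lib, win, cal, [1.0])
        assert out[1.0] == baseline["false_positive"]

    def test_counts_non_decreasing_and_factor_ten_matches_ledger(self, widened_scenario):
        _, lib, cloud, truth, cal = widened_scenario
        win = ts.ScreeningWindows()
        counts = ev.rt_window_sensitivity(cloud, lib, win, cal, [1, 2, 5, 10])
        vals = [counts[f] for f in (1.0, 2.0, 5.0, 10.0)]
        assert vals == sorted(vals)
        placed = int(
            (
                truth.entries.has_interference
                & (truth.entries.interference_rt_offset.abs() > 0.25)
                & (truth.entries.interference_rt_offset.abs() <= 2.5)
            ).sum()
        )
        assert counts[10.0] == placed

    def test_factor_below_one_rejected(self, widened_scenario):
        _, lib, cloud, _, cal = widened_scenario
        with pytest.raises(ts.InvalidInputError):
            ev.rt_window_sensitivity(cloud, lib, ts.ScreeningWindows(), cal, [0.5])


class TestSpectralCoverage:
    def _record(self, category, matched, score, level):
        entry = ts.LibraryEntry(compound_id=f"C{id(object())}",
                                theoretical_mz=300.0, reference_ccs=150.0)
        from timsscreen.extraction import DetectedPeak

        pk = DetectedPeak(0.8, 100.0, 50.0, 0.79, 0.81, ccs=150.0) if matched else None
        return ts.AnnotationRecord(
            entry=entry, category=category, matched_peak=pk,
            ms2_score=score, confidence_level=level,
        )

    def test_all_confirmed_gives_hundred_percent(self):
        recs = [self._record("true_annotation", True, 0.9, 1) for _ in range(5)]
        out = ev.spectral_coverage(recs)
        assert out.defined and out.coverage_pct == pytest.approx(100.0)

    def test_none_confirmed_gives_zero_with_empty_distribution(self):
        recs = [self._record("true_annotation", True, None, 4) for _ in range(5)]
        out = ev.spectral_coverage(recs)
        assert out.coverage_pct == pytest.approx(0.0)
        assert out.score_mean is None

    def test_no_matched_peaks_is_explicitly_undefined(self):
        recs = [self._record("not_detected", False, None, None)]
        out = ev.spectral_coverage(recs)
        assert not out.defined and out.coverage_pct is None

    def test_coverage_matches_closed_form_expectation(self):
        # event probability 0.8, 10% of events contaminated below threshold
        # -> expected coverage 0.8 x 0.9 = 72%, binomial error at n = 500
        cfg = dataclasses.replace(
            ts.ScenarioConfig(seed=17),
            n_analytes=500,
            n_matrix_features=0,
            interference_fraction=0.0,
            analyte_absent_fraction=0.0,
            ms2_event_rate=0.8,
            ms2_contamination_rate=0.1,
        )
        lib, spectra = ts.generate_library(cfg)
        cloud, truth = ts.generate_peak_cloud(lib, cfg, spectra=spectra)
        cal = ts.fit_ccs_calibration(ts.calibrant_table(cfg))
        recs = ts.screen(cloud, lib, ts.ScreeningWindows(), cal, spectra=spectra)
        out = ev.spectral_coverage(recs)
        # ledger-exact expectation for this seed
        exp = truth.entries.has_ms2_event & ~truth.entries.ms2_contaminated
        assert out.coverage_pct == pytest.approx(100.0 * exp.mean(), abs=1e-9)
        # and the closed form within 3 binomial standard errors
        se = 100 * np.sqrt(0.72 * 0.28 / 500)
        assert abs(out.coverage_pct - 72.0) < 3 * se


class TestTrendlines:
    def test_exact_power_law_recovered_with_r2_one(self):
        rng = np.random.default_rng(0)
        mz = rng.uniform(150, 900, 50)
        feats = pd.DataFrame(
            {"mz": mz, "ccs": 7.6 * mz**0.52, "charge": np.ones(50, dtype=int)}
        )
        fits = ev.fit_trendlines(feats)
        assert fits[1].coeff_a == pytest.approx(7.6, rel=1e-9)
        assert fits[1].exponent_b == pytest.approx(0.52, rel=1e-9)
        assert fits[1].r_squared == pytest.approx(1.0)

    def test_sparse_charge_states_skipped(self):
        feats = pd.DataFrame(
            {"mz": [300, 400, 500, 350, 450], "ccs": [150, 170, 190, 300, 330],
             "charge": [1, 1, 1, 2, 2]}
        )
        fits = ev.fit_trendlines(feats)
        assert 1 in fits and 2 not in fits

    def test_generator_truth_recovered_within_scatter(self):
        cfg = ts.ScenarioConfig(seed=5, n_analytes=0, n_matrix_features=400)
        _, truth = ts.generate_peak_cloud([], cfg)
        feats = truth.peaks[truth.peaks.role == "matrix_feature"]
        fits = ev.fit_trendlines(feats[["mz", "ccs", "charge"]])
        fit = fits[1]
        assert fit.coeff_a == pytest.approx(cfg.trendline_coeff_A[0], rel=0.15)
        assert fit.exponent_b == pytest.approx(cfg.trendline_exponent_B[0], rel=0.1)


class TestAlignFeatures:
    def test_self_alignment_recovers_every_feature(self):
        cfg = ts.ScenarioConfig(seed=9)
        tables, _ = ts.generate_feature_tables(cfg, n_tables=2)
        out = ev.align_features([tables[0], tables[0].copy()])
        assert out[(0, 1)] == len(tables[0])

    def test_disjoint_mz_ranges_share_nothing(self):
        a = pd.DataFrame({"mz": [200.0, 300.0], "rt": [5, 6], "ccs": [150, 160]})
        b = pd.DataFrame({"mz": [500.0, 600.0], "rt": [5, 6], "ccs": [150, 160]})
        assert ev.align_features([a, b])[(0, 1)] == 0

    def test_configured_overlap_recovered_exactly(self):
        cfg = ts.ScenarioConfig(seed=11)
        tables, overlap = ts.generate_feature_tables(cfg, n_tables=3, shared_fraction=0.3)
        out = ev.align_features(tables)
        assert out == overlap


class TestPredictionAccuracy:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        out = ev.prediction_accuracy(obs, obs)
        assert out.r_squared == pytest.approx(1.0)
        assert out.rmse == 0.0 and out.mae == 0.0

    def test_constant_predictor_has_undefined_r2(self):
        out = ev.prediction_accuracy([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert out.r_squared is None
        assert out.rmse > 0

    def test_rmse_converges_to_noise_sd(self):
        rng = np.random.default_rng(1)
        obs = rng.uniform(100, 300, 10_000)
        pred = obs + rng.normal(0, 7.27, obs.size)
        out = ev.prediction_accuracy(obs, pred)
        assert out.rmse == pytest.approx(7.27, rel=0.03)
        assert out.mae == pytest.approx(7.27 * np.sqrt(2 / np.pi), rel=0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ts.InvalidInputError):
            ev.prediction_accuracy([1.0, 2.0], [1.0])


class TestReport:
    def test_statistics_are_pure_functions(self, small_scenario, calibration):
        _, lib, spectra, cloud, _ = small_scenario
        recs = ts.screen(cloud, lib, ts.ScreeningWindows(), calibration, spectra=spectra)
        a = ev.count_categories(recs)
        b = ev.count_categories(recs)
        assert a == b
        assert sum(a.values()) == len(lib)

    def test_report_serializes_to_json_and_text(self, tmp_path):
        report = ev.EvaluationReport(
            counts={"true_annotation": 5},
            spectral_coverage_pct=80.0,
            rt_window_false_positives={1.0: 0, 10.0: 3},
        )
        payload = report.to_json()
        assert '"spectral_coverage_pct": 80.0' in payload
        assert "80.0%" in report.to_text()

    def test_plots_written(self, tmp_path, small_scenario, calibration):
        _, lib, spectra, cloud, _ = small_scenario
        recs = ts.screen(cloud, lib, ts.ScreeningWindows(), calibration, spectra=spectra)
        ev.plot_category_bars(ev.count_categories(recs), tmp_path / "bars.png")
        cov = ev.spectral_coverage(recs)
        ev.plot_score_violin({"sample": cov.scores}, tmp_path / "violin.png")
        assert (tmp_path / "bars.png").stat().st_size > 0
        assert (tmp_path / "violin.png").stat().st_size > 0
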