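"""Window classification, characteristic-peak selection, dimer assessment."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import timsscreen as ts
from timsscreen.evaluation import confusion_matrix, count_categories, n_misclassified
from timsscreen.extraction import DetectedPeak


def peak(ccs, intensity=1000.0, area=1000.0):
    k0 = ccs / 1000.0  # position irrelevant for classification
    return DetectedPeak(
        apex_position=k0, apex_intensity=intensity, area=area,
        left_bound=k0 - 0.01, right_bound=k0 + 0.01, ccs=ccs,
    )


class TestClassifyEimPeaks:
    def test_exact_match_alone_is_true_annotation(self):
        # simazine's tabulated CCS of 142.98 recovered exactly
        matched, interf, amb, cat = ts.classify_eim_peaks([peak(142.98)], 142.98)
        assert cat == "true_annotation"
        assert matched.ccs == 142.98 and not interf and not amb

    def test_fourteen_percent_companion_is_interference(self):
        matched, interf, amb, cat = ts.classify_eim_peaks(
            [peak(100.0), peak(114.0)], 100.0
        )
        assert cat == "true_with_interference"
        assert len(interf) == 1 and interf[0].ccs == 114.0

    def test_buffer_band_peak_is_ambiguous(self):
        matched, interf, amb, cat = ts.classify_eim_peaks([peak(104.0)], 100.0)
        assert cat == "ambiguous"
        assert matched is None and not interf and len(amb) == 1

    def test_interference_without_match_is_false_positive(self):
        matched, interf, amb, cat = ts.classify_eim_peaks([peak(129.0)], 100.0)
        assert cat == "false_positive"

    def test_no_peaks_is_not_detected(self):
        *_, cat = ts.classify_eim_peaks([], 100.0)
        assert cat == "not_detected"

    def test_most_intense_in_window_wins(self):
        matched, *_ = ts.classify_eim_peaks(
            [peak(100.5, intensity=500), peak(99.0, intensity=900)], 100.0
        )
        assert matched.ccs == 99.0

    @given(
        offsets=st.lists(
            st.floats(-0.4, 0.4).filter(
                lambda o: not (0.0295 <= abs(o) <= 0.0305) and not (0.049 <= abs(o) <= 0.051)
            ),
            max_size=6,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_classification_is_total_and_exclusive(self, offsets):
        ref = 150.0
        peaks = [peak(ref * (1 + o)) for o in offsets]
        matched, interf, amb, cat = ts.classify_eim_peaks(peaks, ref)
        assert cat in (
            "true_annotation", "true_with_interference", "false_positive",
            "ambiguous", "not_detected",
        )
        # every peak lands in exactly one bucket
        n_in_true = sum(1 for o in offsets if abs(o) < 0.03)
        assert (matched is not None) == (n_in_true > 0)
        assert len(interf) == sum(1 for o in offsets if abs(o) > 0.05)


class TestScreen:
    def test_uncalibrated_screening_rejected(self, small_scenario):
        _, lib, _, cloud, _ = small_scenario
        with pytest.raises(ts.UncalibratedDataError):
            ts.screen(cloud, lib, ts.ScreeningWindows(), None)

    def test_polarity_mismatch_rejected(self, small_scenario, calibration):
        _, lib, _, cloud, _ = small_scenario
        neg = dataclasses.replace(lib[0], polarity="-")
        with pytest.raises(ts.PolarityMismatchError):
            ts.screen(cloud, [neg], ts.ScreeningWindows(), calibration)

    def test_confusion_matrix_is_exact_on_default_scenario(
        self, small_scenario, calibration
    ):
        _, lib, spectra, cloud, truth = small_scenario
        records = ts.screen(cloud, lib, ts.ScreeningWindows(), calibration, spectra=spectra)
        conf = confusion_matrix(records, truth.expected_categories(0.25))
        assert n_misclassified(conf) == 0

    def test_categories_partition_the_library(self, small_scenario, calibration):
        _, lib, spectra, cloud, _ = small_scenario
        records = ts.screen(cloud, lib, ts.ScreeningWindows(), calibration)
        assert sum(count_categories(records).values()) == len(lib)

    def test_shrinking_true_window_never_creates_true_annotations(
        self, small_scenario, calibration
    ):
        _, lib, _, cloud, _ = small_scenario
        wide = ts.screen(cloud, lib, ts.ScreeningWindows(ccs_true_pct=3), calibration)
        narrow = ts.screen(cloud, lib, ts.ScreeningWindows(ccs_true_pct=1), calibration)
        true_wide = {r.entry.compound_id for r in wide if r.category == "true_annotation"}
        true_narrow = {
            r.entry.compound_id for r in narrow if r.category == "true_annotation"
        }
        assert true_narrow <= true_wide

    def test_enlarging_rt_window_never_loses_chromatographic_peaks(
        self, small_scenario, calibration
    ):
        _, lib, _, cloud, _ = small_scenario
        base = ts.screen(cloud, lib, ts.ScreeningWindows(), calibration)
        wide = ts.screen(
            cloud, lib, ts.ScreeningWindows().widen_rt(10), calibration
        )
        n_base = sum(1 for r in base if r.chromatographic_peak is not None)
        n_wide = sum(1 for r in wide if r.chromatographic_peak is not None)
        assert n_wide >= n_base

    def test_blank_subtraction_flags_background_annotations(
        self, small_scenario, calibration
    ):
        cfg, lib, spectra, cloud, _ = small_scenario
        # a "blank" identical to the sample must flag nothing…
        records = ts.screen(
            cloud, lib, ts.ScreeningWindows(), calibration, blanks=[cloud]
        )
        assert not any(r.blank_filtered for r in records)
        # …whereas a blank with doubled intensities flags everything detected
        blank = ts.PeakCloud.from_arrays(
            cloud.rt, cloud.inv_k0, cloud.mz, cloud.intensity * 2.0,
            metadata=dict(cloud.metadata),
        )
        records = ts.screen(
            cloud, lib, ts.ScreeningWindows(), calibration, blanks=[blank]
        )
        assert all(
            r.blank_filtered for r in records if r.category != "not_detected"
        )

    def test_tabulated_isomer_pair_reported_non_separable(self, clean_config):
        # simazine (142.98 Å², RT 11.98) vs desethyl-tebuthylazine
        # (144.23 Å², RT 11.98): 0.87% apart, inside each other's 3% window
        cfg = clean_config
        cal = ts.true_calibration(cfg)
        mz, rt = 202.0854, 11.98
        e1 = ts.LibraryEntry(
            compound_id="simazine", theoretical_mz=mz, expected_rt=rt,
            reference_ccs=142.98,
        )
        e2 = ts.LibraryEntry(
            compound_id="desethyl-tebuthylazine", theoretical_mz=mz,
            expected_rt=rt, reference_ccs=144.23,
        )
        from timsscreen.simulate import _gaussian_peak_points

        rng = np.random.default_rng(1)
        pts = []
        for e in (e1, e2):
            k0 = ts.ccs_to_inv_k0(e.reference_ccs, mz, 1, cal)
            pts.append(_gaussian_peak_points(cfg, rng, mz, rt, k0, 1e5))
        cloud = ts.PeakCloud.from_arrays(
            *[np.concatenate([p[i] for p in pts]) for i in range(4)],
            metadata={"rt_range": cfg.rt_range},
        )
        records = ts.screen(cloud, [e1, e2], ts.ScreeningWindows(), cal)
        # both ions confirmed, neither sees the other as interference
        assert {r.category for r in records} == {"true_annotation"}
        groups = ts.isomer_groups([e1, e2])
        assert len(groups) == 1 and len(groups[0]) == 2


class TestCharacteristicPeak:
    def test_single_linear_cluster_selected_with_r2_one(self):
        levels = {c: [peak(150.0, area=100.0 * c)] for c in (1.0, 5.0, 10.0)}
        out = ts.select_characteristic_peak(levels)
        assert out.qualified and out.ccs == pytest.approx(150.0)
        assert out.response_r2 == pytest.approx(1.0)

    def test_poorly_responding_low_ccs_cluster_skipped(self):
        rng = np.random.default_rng(0)
        levels = {}
        for c in (1.0, 2.0, 5.0, 10.0, 20.0):
            # low-CCS peak: area uncorrelated with concentration
            bad_area = float(rng.uniform(50, 1500))
            levels[c] = [peak(140.0, area=bad_area), peak(180.0, area=100.0 * c)]
        out = ts.select_characteristic_peak(levels)
        assert out.ccs == pytest.approx(180.0)
        assert out.qualified
        assert 140.0 in [pytest.approx(c, abs=1.5) for c in out.additional_ccs]

    def test_nothing_qualifies_returns_lowest_ccs_flagged(self):
        rng = np.random.default_rng(1)
        levels = {
            c: [peak(140.0, area=float(rng.uniform(50, 1500)))]
            for c in (1.0, 5.0, 10.0, 20.0, 50.0)
        }
        out = ts.select_characteristic_peak(levels)
        assert not out.qualified and out.ccs == pytest.approx(140.0)

    def test_two_levels_rejected(self):
        levels = {1.0: [peak(150.0)], 10.0: [peak(150.0)]}
        with pytest.raises(ts.InsufficientLevelsError):
            ts.select_characteristic_peak(levels)


class TestAssessDimer:
    def test_quadratic_high_ccs_peak_consistent_with_dimer(self):
        conc = (1.0, 5.0, 10.0, 50.0)
        low = {c: 100.0 * c for c in conc}
        high = {c: 2.0 * c**2 for c in conc}
        out = ts.assess_dimer(low, high)
        assert out.label == "consistent_with_dimer"
        assert out.slope_low_ccs == pytest.approx(1.0, abs=1e-9)
        assert out.slope_high_ccs == pytest.approx(2.0, abs=1e-9)

    def test_both_linear_is_not_concentration_dependent(self):
        conc = (1.0, 5.0, 10.0)
        out = ts.assess_dimer({c: 10 * c for c in conc}, {c: 3 * c for c in conc})
        assert out.label == "not_concentration_dependent"

    def test_intermediate_slopes_inconclusive(self):
        conc = (1.0, 5.0, 10.0)
        out = ts.assess_dimer(
            {c: 10 * c**1.0 for c in conc}, {c: 3 * c**1.3 for c in conc}
        )
        assert out.label == "inconclusive"

    def test_non_positive_areas_rejected(self):
        conc = (1.0, 5.0, 10.0)
        with pytest.raises(ts.InvalidInputError):
            ts.assess_dimer({c: 0.0 for c in conc}, {c: c for c in conc})
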