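"""Mobility-gated MS² extraction and cosine library matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import timsscreen as ts
from timsscreen.cloud import Ms2Event
from timsscreen.ms2 import (
    Ms2Spectrum,
    assign_confidence,
    cosine_score,
    extract_ms2,
)
from timsscreen.screening import AnnotationRecord, LibraryEntry
from timsscreen.extraction import DetectedPeak


def spectrum(frags, precursor=300.0, **kw):
    mz = np.array([f[0] for f in frags], dtype=float)
    inten = np.array([f[1] for f in frags], dtype=float)
    return Ms2Spectrum(precursor_mz=precursor, fragment_mz=mz, fragment_intensity=inten, **kw)


def exhaustive_best_pairing_score(query, reference, tol=0.01):
    """Oracle: maximize Σ√(Ia·Ib) over ALL valid one-to-one pairings."""
    qa, qi = query.fragment_mz, query.fragment_intensity
    ra, ri = reference.fragment_mz, reference.fragment_intensity
    if qa.size == 0 or ra.size == 0:
        return 0.0
    best = 0.0
    idx_r = list(range(ra.size)) + [None] * qa.size  # None = unmatched
    for perm in itertools.permutations(idx_r, qa.size):
        used = [j for j in perm if j is not None]
        if len(used) != len(set(used)):
            continue
        total = 0.0
        ok = True
        for i, j in enumerate(perm):
            if j is None:
                continue
            if abs(qa[i] - ra[j]) > tol:
                ok = False
                break
            total += np.sqrt(qi[i] * ri[j])
        if ok:
            best = max(best, total)
    return float(best**2 / (qi.sum() * ri.sum()))


class TestExtractMs2:
    def _cloud(self, events):
        return ts.PeakCloud.from_arrays(
            rt=[5.0], inv_k0=[0.8], mz=[300.0], intensity=[10.0],
            ms2_events=events, metadata={"rt_range": (0.0, 10.0)},
        )

    def test_single_matching_event_returned_unchanged(self):
        ev = Ms2Event(300.0, 0.78, 0.82, 5.0, np.array([100.0, 150.0]), np.array([10.0, 20.0]))
        out = extract_ms2(self._cloud([ev]), 300.0, (0.75, 0.85))
        assert out is not None
        assert np.allclose(out.fragment_mz, [100.0, 150.0])
        assert np.allclose(out.fragment_intensity, [10.0, 20.0])

    def test_disjoint_gates_separate_coisolated_species(self):
        ev_a = Ms2Event(300.0, 0.78, 0.82, 5.0, np.array([100.0]), np.array([10.0]))
        ev_b = Ms2Event(300.3, 0.95, 0.99, 5.0, np.array([200.0]), np.array([30.0]))
        cloud = self._cloud([ev_a, ev_b])
        only_a = extract_ms2(cloud, 300.0, (0.78, 0.82))
        assert np.allclose(only_a.fragment_mz, [100.0])
        merged = extract_ms2(cloud, 300.0, None)
        assert np.allclose(merged.fragment_mz, [100.0, 200.0])

    def test_no_matching_event_returns_none(self):
        ev = Ms2Event(300.0, 0.78, 0.82, 5.0, np.array([100.0]), np.array([10.0]))
        assert extract_ms2(self._cloud([ev]), 350.0) is None
        assert extract_ms2(self._cloud([ev]), 300.0, (1.2, 1.3)) is None
        assert extract_ms2(self._cloud([ev]), 300.0, rt_window=(8.0, 9.0)) is None


class TestCosineScore:
    def test_identical_spectra_score_one(self):
        s = spectrum([(100.0, 50.0), (150.0, 80.0), (200.0, 10.0)])
        assert cosine_score(s, s).score == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        a = spectrum([(100.0, 50.0)])
        b = spectrum([(200.0, 50.0)])
        assert cosine_score(a, b).score == 0.0

    def test_empty_side_scores_zero(self):
        a = spectrum([(100.0, 50.0)])
        empty = spectrum([])
        assert cosine_score(a, empty).score == 0.0
        assert cosine_score(empty, a).score == 0.0

    @given(
        st.lists(
            st.tuples(st.floats(50, 500), st.floats(1, 100)),
            min_size=1, max_size=4,
        ),
        st.lists(
            st.tuples(st.floats(50, 500), st.floats(1, 100)),
            min_size=1, max_size=4,
        ),
    )
    @settings(max_examples=150, deadline=None)
    def test_greedy_matches_exhaustive_oracle_on_toys(self, fa, fb):
        a, b = spectrum(fa), spectrum(fb)
        ours = cosine_score(a, b).score
        oracle = exhaustive_best_pairing_score(a, b)
        # greedy pairing is optimal whenever pairings don't conflict;
        # random m/z values at 0.01 Th tolerance essentially never conflict
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_seeded_toy_pairs_match_oracle_exactly(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n_a, n_b = rng.integers(1, 6, size=2)
            base = np.sort(rng.uniform(50, 400, size=max(n_a, n_b)))
            a = spectrum([(m, rng.uniform(1, 100)) for m in base[:n_a]])
            b = spectrum(
                [(m + rng.normal(0, 0.004), rng.uniform(1, 100)) for m in base[:n_b]]
            )
            assert cosine_score(a, b).score == pytest.approx(
                exhaustive_best_pairing_score(a, b), abs=1e-9
            )

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = spectrum([(m, rng.uniform(1, 100)) for m in rng.uniform(50, 400, 5)])
            b = spectrum([(m, rng.uniform(1, 100)) for m in rng.uniform(50, 400, 5)])
            assert cosine_score(a, b).score == pytest.approx(
                cosine_score(b, a).score, abs=1e-12
            )
            scaled = spectrum(
                list(zip(a.fragment_mz, a.fragment_intensity * 37.0))
            )
            assert cosine_score(scaled, b).score == pytest.approx(
                cosine_score(a, b).score, abs=1e-12
            )

    def test_contamination_never_raises_score(self):
        rng = np.random.default_rng(4)
        ref = spectrum([(m, rng.uniform(10, 100)) for m in rng.uniform(50, 400, 6)])
        clean = spectrum(list(zip(ref.fragment_mz, ref.fragment_intensity)))
        base = cosine_score(clean, ref).score
        for _ in range(100):
            extra_mz = rng.uniform(50, 450, size=rng.integers(1, 5))
            extra_in = rng.uniform(10, 200, size=extra_mz.size)
            contaminated = spectrum(
                list(zip(clean.fragment_mz, clean.fragment_intensity))
                + list(zip(extra_mz, extra_in))
            )
            assert cosine_score(contaminated, ref).score <= base + 1e-12

    def test_agrees_with_matchms_on_conflict_free_spectra(self):
        # independent cross-check against the community implementation
        from matchms import Spectrum as MSpectrum
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(8)
        for _ in range(10):
            mz = np.sort(rng.uniform(50, 400, size=6))
            ia = rng.uniform(1, 100, size=6)
            ib = rng.uniform(1, 100, size=6)
            keep = rng.random(6) > 0.3
            a = spectrum(list(zip(mz, ia)))
            b = spectrum(list(zip(mz[keep], ib[keep])))
            ours = cosine_score(a, b).score
            ma = MSpectrum(mz=mz, intensities=np.sqrt(ia),
                           metadata={}, metadata_harmonization=False)
            mb = MSpectrum(mz=mz[keep], intensities=np.sqrt(ib[keep]),
                           metadata={}, metadata_harmonization=False)
            theirs = float(CosineGreedy(tolerance=0.01).pair(ma, mb)["score"])
            # our score is the squared cosine of the √-scaled intensity
            # vectors, so it equals the matchms greedy cosine squared
            assert ours == pytest.approx(theirs**2, abs=1e-9)


class TestGatingProperty:
    def test_gated_beats_ungated_for_every_seeded_coisolation(self, calibration):
        from timsscreen.extraction import detect_peaks, extract_eim, mobility_peaks_to_ccs

        for seed in range(100):
            cloud, entry, ref = ts.generate_coisolation_fixture(seed)
            eim = extract_eim(
                cloud, entry.theoretical_mz, 5,
                (entry.expected_rt - 0.2, entry.expected_rt + 0.2),
            )
            peaks = mobility_peaks_to_ccs(
                detect_peaks(eim, 50), entry.theoretical_mz, 1,
                ts.true_calibration(ts.ScenarioConfig()),
            )
            match = min(peaks, key=lambda p: abs(p.ccs - entry.reference_ccs))
            gated = extract_ms2(
                cloud, entry.theoretical_mz,
                (match.apex_position - 0.015, match.apex_position + 0.015),
            )
            ungated = extract_ms2(cloud, entry.theoretical_mz, None)
            assert cosine_score(gated, ref).score > cosine_score(ungated, ref).score


class TestAssignConfidence:
    def _annotation(self, category):
        entry = LibraryEntry(compound_id="X", theoretical_mz=300.0, reference_ccs=150.0)
        pk = DetectedPeak(0.8, 100.0, 50.0, 0.79, 0.81, ccs=150.0)
        return AnnotationRecord(
            entry=entry, category=category,
            matched_peak=pk if category.startswith("true") else None,
        )

    def test_passing_score_gives_level_one(self):
        match = ts.SpectralMatch("X", 0.9, 5)
        assert assign_confidence(self._annotation("true_annotation"), match, 0.7) == 1

    def test_no_spectrum_gives_level_four(self):
        assert assign_confidence(self._annotation("true_annotation"), None) == 4

    def test_low_score_gives_level_four(self):
        match = ts.SpectralMatch("X", 0.4, 2)
        assert assign_confidence(self._annotation("true_with_interference"), match) == 4

    @pytest.mark.parametrize("category", ["not_detected", "false_positive"])
    def test_invalid_categories_rejected(self, category):
        with pytest.raises(ts.InvalidStateError):
            assign_confidence(self._annotation(category), None)
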