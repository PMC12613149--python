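"""Annotation windows, EIM interference classification and library rules.

A library ion is annotated in a sample when a chromatographic peak appears
within the m/z window (5 ppm) and RT window (±0.25 min) of its expected
values.  The mobilogram of that integrated chromatographic peak then decides
the outcome: an EIM peak whose calibrated CCS lies within 3% of the library
reference confirms the analyte, while any EIM peak offset by more than 5%
is counted as a distinct, matrix-derived interference.  The deliberate gap
between the two thresholds (3%–5%] is a conservative buffer: peaks falling
inside it are recorded but counted toward neither side.

Categories:

``true_annotation``
    CCS-confirmed peak, no interference in the mobilogram.
``true_with_interference``
    CCS-confirmed peak co-occurring with >5%-offset EIM peak(s); without
    ion mobility these cases risk distorted isotope patterns and MS²
    spectra (false negatives or inconclusive calls).
``false_positive``
    m/z and RT match, but every EIM peak is >5% off the reference — the
    chromatographic peak belongs to something else.
``ambiguous``
    Only buffer-band peaks ((3%, 5%]) present.
``not_detected``
    No chromatographic peak in the RT window, or an empty mobilogram.

ΔCCS is computed relative to the library reference (signed, thresholded on
its absolute value) and taken at the EIM peak apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cloud import PeakCloud
from .errors import (
    InsufficientLevelsError,
    InvalidInputError,
    PolarityMismatchError,
    UncalibratedDataError,
)
from .extraction import (
    DEFAULT_EIC_BIN,
    DEFAULT_EIM_BIN,
    DetectedPeak,
    detect_peaks,
    extract_eic,
    extract_eim,
    mobility_peaks_to_ccs,
)
from .ms2 import DEFAULT_SCORE_THRESHOLD, assign_confidence, best_match, extract_ms2
from .physics import CcsCalibration

CATEGORIES = (
    "true_annotation",
    "true_with_interference",
    "false_positive",
    "ambiguous",
    "not_detected",
)

#: Default apex threshold (counts) for peak detection during screening.
DEFAULT_MIN_PEAK_INTENSITY = 50.0


@dataclass(frozen=True)
class LibraryEntry:
    """One screenable ion of the suspect/target library."""

    compound_id: str
    name: str = ""
    formula: str = ""
    adduct: str = "[M+H]+"
    charge: int = 1
    polarity: str = "+"
    theoretical_mz: float = 0.0
    expected_rt: float = 0.0
    reference_ccs: float = 0.0
    additional_ccs: tuple[float, ...] = ()
    response_r2: float | None = None

    def __post_init__(self) -> None:
        if self.theoretical_mz <= 0:
            raise InvalidInputError(
                f"{self.compound_id}: theoretical m/z must be positive"
            )
        if self.reference_ccs <= 0:
            raise InvalidInputError(f"{self.compound_id}: reference CCS must be positive")
        if self.charge < 1:
            raise InvalidInputError(f"{self.compound_id}: charge must be >= 1")
        for extra in self.additional_ccs:
            if abs(extra - self.reference_ccs) <= 0.005 * self.reference_ccs:
                raise InvalidInputError(
                    f"{self.compound_id}: additional CCS {extra} within 0.5% of reference"
                )


@dataclass(frozen=True)
class ScreeningWindows:
    """Annotation windows: 5 ppm, ±0.25 min, <3% true / >5% interference."""

    mz_ppm: float = 5.0
    rt_min: float = 0.25
    ccs_true_pct: float = 3.0
    ccs_interference_pct: float = 5.0

    def __post_init__(self) -> None:
        if min(self.mz_ppm, self.rt_min, self.ccs_true_pct, self.ccs_interference_pct) <= 0:
            raise InvalidInputError("all screening windows must be positive")
        if self.ccs_true_pct > self.ccs_interference_pct:
            raise InvalidInputError(
                "true-annotation CCS window must not exceed the interference boundary"
            )

    def widen_rt(self, factor: float) -> "ScreeningWindows":
        """Scale the RT window (suspect-screening style), all else fixed."""
        if factor < 1:
            raise InvalidInputError("RT widening factor must be >= 1")
        return replace(self, rt_min=self.rt_min * factor)


@dataclass
class AnnotationRecord:
    """Per library ion, per sample: deltas, peaks, category, confidence."""

    entry: LibraryEntry
    category: str = "not_detected"
    chromatographic_peak: DetectedPeak | None = None
    matched_peak: DetectedPeak | None = None
    interference_peaks: list[DetectedPeak] = field(default_factory=list)
    ambiguous_peaks: list[DetectedPeak] = field(default_factory=list)
    eim_peaks: list[DetectedPeak] = field(default_factory=list)
    delta_ppm: float | None = None
    delta_rt: float | None = None
    delta_ccs_pct: float | None = None
    ms2_score: float | None = None
    confidence_level: int | None = None
    blank_filtered: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidInputError(f"unknown category {self.category!r}")


def classify_eim_peaks(
    peaks_with_ccs: Sequence[DetectedPeak],
    reference_ccs: float,
    windows: ScreeningWindows = ScreeningWindows(),
) -> tuple[DetectedPeak | None, list[DetectedPeak], list[DetectedPeak], str]:
    """Classify mobilogram peaks against a reference CCS.

    Returns ``(matched_peak, interference_peaks, ambiguous_peaks, category)``.
    The match is the most intense peak within the true window (ties broken
    by smallest |ΔCCS|); interferences are all peaks beyond the >5%
    boundary; buffer-band peaks are recorded separately.
    """
    if reference_ccs <= 0:
        raise InvalidInputError("reference CCS must be positive")
    in_true: list[DetectedPeak] = []
    interferences: list[DetectedPeak] = []
    in_between: list[DetectedPeak] = []
    for p in peaks_with_ccs:
        if p.ccs is None:
            raise UncalibratedDataError("EIM peak without CCS; convert peaks first")
        rel = 100.0 * abs(p.ccs - reference_ccs) / reference_ccs
        if rel < windows.ccs_true_pct:
            in_true.append(p)
        elif rel > windows.ccs_interference_pct:
            interferences.append(p)
        else:
            in_between.append(p)
    matched = None
    if in_true:
        matched = max(
            in_true,
            key=lambda p: (p.apex_intensity, -abs(p.ccs - reference_ccs)),
        )
    if matched is not None:
        category = "true_with_interference" if interferences else "true_annotation"
    elif interferences:
        category = "false_positive"
    elif in_between:
        category = "ambiguous"
    else:
        category = "not_detected"
    return matched, interferences, in_between, category


def _weighted_mean_mz(cloud: PeakCloud, mz: float, ppm: float, rt_bounds) -> float | None:
    lo = mz * (1 - ppm * 1e-6)
    hi = mz * (1 + ppm * 1e-6)
    sl = cloud.mz_slice(lo, hi)
    rt = cloud.rt[sl]
    keep = (rt >= rt_bounds[0]) & (rt <= rt_bounds[1])
    w = cloud.intensity[sl][keep]
    if w.sum() <= 0:
        return None
    return float(np.average(cloud.mz[sl][keep], weights=w))


def _window_mean_intensity(cloud: PeakCloud, entry: LibraryEntry, windows) -> float:
    lo = entry.theoretical_mz * (1 - windows.mz_ppm * 1e-6)
    hi = entry.theoretical_mz * (1 + windows.mz_ppm * 1e-6)
    sl = cloud.mz_slice(lo, hi)
    rt = cloud.rt[sl]
    keep = (rt >= entry.expected_rt - windows.rt_min) & (
        rt <= entry.expected_rt + windows.rt_min
    )
    vals = cloud.intensity[sl][keep]
    return float(vals.mean()) if vals.size else 0.0


def screen(
    cloud: PeakCloud,
    library: Sequence[LibraryEntry],
    windows: ScreeningWindows = ScreeningWindows(),
    cal: CcsCalibration | None = None,
    spectra: Mapping[str, list] | None = None,
    blanks: Sequence[PeakCloud] = (),
    min_peak_intensity: float = DEFAULT_MIN_PEAK_INTENSITY,
    ms2_score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    ms2_gate_halfwidth: float = 0.015,
    eic_bin: float = DEFAULT_EIC_BIN,
    eim_bin: float = DEFAULT_EIM_BIN,
) -> list[AnnotationRecord]:
    """Run the full annotation workflow for every library ion.

    For each entry: extract the EIC, take the chromatographic peak nearest
    the expected RT within ±rt_min (none → ``not_detected``), extract the
    EIM over that peak's integration bounds, convert mobility peaks to CCS
    and classify them.  When an MS² library is supplied, confirmed
    annotations additionally receive a mobility-gated spectral match and a
    Schymanski confidence level.
    """
    if cal is None:
        raise UncalibratedDataError("screening requires a fitted CCS calibration")
    cloud_pol = cloud.metadata.get("polarity", "+")
    for entry in library:
        if entry.polarity != cloud_pol:
            raise PolarityMismatchError(
                f"{entry.compound_id}: library polarity {entry.polarity!r} "
                f"does not match cloud polarity {cloud_pol!r}"
            )

    records: list[AnnotationRecord] = []
    for entry in library:
        eic = extract_eic(cloud, entry.theoretical_mz, windows.mz_ppm, eic_bin)
        chrom_peaks = detect_peaks(eic, min_intensity=min_peak_intensity)
        candidates = [
            p
            for p in chrom_peaks
            if abs(p.apex_position - entry.expected_rt) <= windows.rt_min
        ]
        if not candidates:
            records.append(AnnotationRecord(entry=entry, category="not_detected"))
            continue
        # anchor on RT agreement, not abundance
        chrom = min(candidates, key=lambda p: abs(p.apex_position - entry.expected_rt))

        eim = extract_eim(
            cloud,
            entry.theoretical_mz,
            windows.mz_ppm,
            (chrom.left_bound, chrom.right_bound),
            eim_bin,
        )
        mob_peaks = detect_peaks(eim, min_intensity=min_peak_intensity)
        mob_peaks = mobility_peaks_to_ccs(mob_peaks, entry.theoretical_mz, entry.charge, cal)
        matched, interferences, in_between, category = classify_eim_peaks(
            mob_peaks, entry.reference_ccs, windows
        )

        mean_mz = _weighted_mean_mz(
            cloud, entry.theoretical_mz, windows.mz_ppm, (chrom.left_bound, chrom.right_bound)
        )
        rec = AnnotationRecord(
            entry=entry,
            category=category,
            chromatographic_peak=chrom,
            matched_peak=matched,
            interference_peaks=interferences,
            ambiguous_peaks=in_between,
            eim_peaks=mob_peaks,
            delta_ppm=(
                None
                if mean_mz is None
                else 1e6 * (mean_mz - entry.theoretical_mz) / entry.theoretical_mz
            ),
            delta_rt=chrom.apex_position - entry.expected_rt,
            delta_ccs_pct=(
                None
                if matched is None
                else 100.0 * (matched.ccs - entry.reference_ccs) / entry.reference_ccs
            ),
        )

        if spectra is not None and matched is not None:
            refs = spectra.get(entry.compound_id, [])
            gate = (
                matched.apex_position - ms2_gate_halfwidth,
                matched.apex_position + ms2_gate_halfwidth,
            )
            pad = 0.05
            query = extract_ms2(
                cloud,
                entry.theoretical_mz,
                mobility_gate=gate,
                rt_window=(chrom.left_bound - pad, chrom.right_bound + pad),
            )
            match = best_match(query, refs) if query is not None else None
            rec.ms2_score = match.score if match is not None else None
            rec.confidence_level = assign_confidence(rec, match, ms2_score_threshold)
        records.append(rec)

    if blanks:
        for rec in records:
            sample_mean = _window_mean_intensity(cloud, rec.entry, windows)
            blank_mean = float(
                np.mean([_window_mean_intensity(b, rec.entry, windows) for b in blanks])
            )
            if blank_mean > sample_mean:
                rec.blank_filtered = True
    return records


@dataclass(frozen=True)
class CharacteristicPeak:
    """Outcome of characteristic-peak selection over a dilution series."""

    ccs: float
    response_r2: float
    qualified: bool
    additional_ccs: tuple[float, ...]


def _cluster_by_ccs(observations, rel_tol: float = 0.01):
    """Link (level, ccs, area) observations across levels within 1% CCS."""
    obs = sorted(observations, key=lambda t: t[1])
    clusters: list[list[tuple[float, float, float]]] = []
    for o in obs:
        if clusters and abs(o[1] - np.mean([x[1] for x in clusters[-1]])) <= rel_tol * o[1]:
            clusters[-1].append(o)
        else:
            clusters.append([o])
    return clusters


def select_characteristic_peak(
    per_level_eim_peaks: Mapping[float, Sequence[DetectedPeak]],
    r2_threshold: float = 0.8,
) -> CharacteristicPeak:
    """Choose the database CCS from multi-peak mobilograms over a series.

    Candidate CCS clusters are formed by linking peaks across concentration
    levels within 1% relative CCS; each cluster's peak area is regressed
    against concentration.  The chosen peak is the lowest-CCS cluster whose
    signal response has R² above ``r2_threshold`` (0.8 by default); if none
    qualifies, the lowest-CCS cluster is returned flagged unqualified.
    Remaining cluster CCS values become the entry's additional CCS list.
    """
    levels = sorted(per_level_eim_peaks)
    if len(levels) < 3:
        raise InsufficientLevelsError(
            f"need >= 3 concentration levels, got {len(levels)}"
        )
    observations = [
        (level, p.ccs, p.area)
        for level in levels
        for p in per_level_eim_peaks[level]
        if p.ccs is not None
    ]
    if not observations:
        raise InvalidInputError("no CCS-assigned peaks supplied")
    clusters = _cluster_by_ccs(observations)

    summaries = []
    for cl in clusters:
        ccs = float(np.mean([c for _, c, _ in cl]))
        conc = np.array([lv for lv, _, _ in cl], dtype=float)
        area = np.array([a for _, _, a in cl], dtype=float)
        if np.unique(conc).size < 2:
            r2 = -np.inf
        else:
            coeffs = np.polyfit(conc, area, 1)
            resid = area - np.polyval(coeffs, conc)
            sst = float(np.sum((area - area.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else -np.inf
        summaries.append((ccs, r2))

    qualified = [s for s in summaries if s[1] > r2_threshold]
    if qualified:
        ccs, r2 = min(qualified, key=lambda s: s[0])
        ok = True
    else:
        ccs, r2 = min(summaries, key=lambda s: s[0])
        ok = False
    extras = tuple(c for c, _ in summaries if c != ccs)
    return CharacteristicPeak(ccs=ccs, response_r2=float(r2), qualified=ok, additional_ccs=extras)


@dataclass(frozen=True)
class DimerAssessment:
    """Concentration-dependence hypothesis for a two-peak mobilogram."""

    label: str  # consistent_with_dimer | not_concentration_dependent | inconclusive
    slope_low_ccs: float
    slope_high_ccs: float


def assess_dimer(
    per_level_areas_low_ccs: Mapping[float, float],
    per_level_areas_high_ccs: Mapping[float, float],
) -> DimerAssessment:
    """Test whether a higher-CCS companion peak behaves like an ESI dimer.

    Dimer formation during ionization is concentration dependent: on a
    log(area) vs log(concentration) fit a monomer responds with slope ≈ 1
    while a dimer responds super-linearly (slope ≈ 2).  The label is
    ``consistent_with_dimer`` when the high-CCS slope exceeds the low-CCS
    slope by > 0.5 and itself exceeds 1.5; ``not_concentration_dependent``
    when both slopes are within 1 ± 0.25; otherwise ``inconclusive``.
    """
    common = sorted(set(per_level_areas_low_ccs) & set(per_level_areas_high_ccs))
    if len(common) < 3:
        raise InsufficientLevelsError("need >= 3 shared concentration levels")
    for lv in common:
        if per_level_areas_low_ccs[lv] <= 0 or per_level_areas_high_ccs[lv] <= 0:
            raise InvalidInputError("areas must be positive for log-log regression")
    log_c = np.log(np.array(common, dtype=float))
    s_low = float(np.polyfit(log_c, np.log([per_level_areas_low_ccs[lv] for lv in common]), 1)[0])
    s_high = float(np.polyfit(log_c, np.log([per_level_areas_high_ccs[lv] for lv in common]), 1)[0])
    if (s_high - s_low) > 0.5 and s_high > 1.5:
        label = "consistent_with_dimer"
    elif abs(s_low - 1.0) <= 0.25 and abs(s_high - 1.0) <= 0.25:
        label = "not_concentration_dependent"
    else:
        label = "inconclusive"
    return DimerAssessment(label=label, slope_low_ccs=s_low, slope_high_ccs=s_high)


def isomer_groups(
    library: Sequence[LibraryEntry],
    windows: ScreeningWindows = ScreeningWindows(),
) -> list[tuple[LibraryEntry, ...]]:
    """Groups of library ions that screening cannot tell apart.

    Two entries are non-separable when their m/z, expected RT and reference
    CCS all lie within each other's annotation windows — their 3% CCS match
    windows collapse onto a single cluster, as for the simazine /
    desethyl-tebuthylazine isomer pair.  Returns only groups of size >= 2
    (transitive closure).
    """
    n = len(library)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = library[i], library[j]
            if (
                abs(a.theoretical_mz - b.theoretical_mz)
                <= windows.mz_ppm * 1e-6 * max(a.theoretical_mz, b.theoretical_mz)
                and abs(a.expected_rt - b.expected_rt) <= windows.rt_min
                and 100.0 * abs(a.reference_ccs - b.reference_ccs)
                / min(a.reference_ccs, b.reference_ccs)
                < windows.ccs_true_pct
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[LibraryEntry]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(library[i])
    return [tuple(g) for g in groups.values() if len(g) > 1]
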