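"""Extracted ion chromatograms (EIC), mobilograms (EIM) and peak detection.

An EIC collects intensity versus retention time for all points inside a
ppm-relative m/z window; an EIM collects intensity versus 1/K0 for the
points additionally restricted to the RT bounds of an integrated
chromatographic peak.  Peak detection is the same in either dimension:
moving-average smoothing, local maxima above a threshold, apex refinement
by three-point quadratic interpolation, bounds at the nearest valley (or
the first bin below 10% of the apex) and trapezoidal area.

Overlapping peaks are not deconvolved: the downstream interference
classification works on apex positions, not fitted peak models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .cloud import PeakCloud
from .errors import InvalidInputError
from .physics import CcsCalibration, inv_k0_to_ccs

DEFAULT_EIC_BIN = 0.02  # minutes
DEFAULT_EIM_BIN = 0.002  # V·s/cm²
DEFAULT_SMOOTH = 3  # bins


@dataclass(frozen=True)
class Eic:
    """Extracted ion chromatogram on a uniform RT grid (bin centers)."""

    target_mz: float
    ppm_window: float
    rt_grid: np.ndarray
    intensity: np.ndarray


@dataclass(frozen=True)
class Eim:
    """Extracted ion mobilogram on a uniform 1/K0 grid (bin centers)."""

    target_mz: float
    rt_bounds: tuple[float, float]
    inv_k0_grid: np.ndarray
    intensity: np.ndarray


@dataclass(frozen=True)
class DetectedPeak:
    """A detected peak in one trace dimension.

    ``apex_position`` is in minutes for chromatographic peaks and V·s/cm²
    for mobility peaks; ``ccs`` is set only after calibration conversion.
    """

    apex_position: float
    apex_intensity: float
    area: float
    left_bound: float
    right_bound: float
    ccs: float | None = None


def _ppm_bounds(mz: float, ppm: float) -> tuple[float, float]:
    half = mz * ppm * 1e-6
    return mz - half, mz + half


def _bin_trace(values, weights, lo, hi, bin_width):
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    hist, _ = np.histogram(values, bins=edges, weights=weights)
    centers = edges[:-1] + 0.5 * bin_width
    return centers, hist


def extract_eic(
    cloud: PeakCloud,
    mz: float,
    ppm: float = 5.0,
    bin_width: float = DEFAULT_EIC_BIN,
) -> Eic:
    """Sum point intensities within ±ppm of ``mz`` into uniform RT bins.

    An empty window yields an all-zero trace, not an error.
    """
    if ppm <= 0 or bin_width <= 0:
        raise InvalidInputError("ppm window and bin width must be positive")
    lo, hi = _ppm_bounds(mz, ppm)
    sl = cloud.mz_slice(lo, hi)
    rt_lo, rt_hi = cloud.rt_span()
    centers, hist = _bin_trace(
        cloud.rt[sl], cloud.intensity[sl], rt_lo, rt_hi, bin_width
    )
    return Eic(target_mz=mz, ppm_window=ppm, rt_grid=centers, intensity=hist)


def extract_eim(
    cloud: PeakCloud,
    mz: float,
    ppm: float = 5.0,
    rt_bounds: tuple[float, float] = (0.0, np.inf),
    bin_width: float = DEFAULT_EIM_BIN,
) -> Eim:
    """Sum intensities inside the m/z window and RT bounds into 1/K0 bins."""
    if ppm <= 0 or bin_width <= 0:
        raise InvalidInputError("ppm window and bin width must be positive")
    if rt_bounds[0] >= rt_bounds[1]:
        raise InvalidInputError("rt_bounds must be well ordered")
    lo, hi = _ppm_bounds(mz, ppm)
    sl = cloud.mz_slice(lo, hi)
    rt = cloud.rt[sl]
    keep = (rt >= rt_bounds[0]) & (rt <= rt_bounds[1])
    k_lo, k_hi = cloud.metadata.get("mobility_range", (0.45, 1.45))
    centers, hist = _bin_trace(
        cloud.inv_k0[sl][keep], cloud.intensity[sl][keep], k_lo, k_hi, bin_width
    )
    return Eim(
        target_mz=mz,
        rt_bounds=(float(rt_bounds[0]), float(rt_bounds[1])),
        inv_k0_grid=centers,
        intensity=hist,
    )


def _auto_threshold(y: np.ndarray) -> float:
    """Noise threshold: 5x the median nonzero bin, capped at half the max.

    The cap keeps the heuristic usable on sparse traces where nearly every
    nonzero bin belongs to a real peak (the uncapped rule can then exceed
    the apex itself).
    """
    nz = y[y > 0]
    if nz.size == 0:
        return np.inf
    return float(min(5.0 * np.median(nz), 0.5 * np.max(y)))


def detect_peaks(
    trace: Eic | Eim,
    min_intensity: float | None = None,
    smooth_window: int = DEFAULT_SMOOTH,
) -> list[DetectedPeak]:
    """Detect peaks in a 1D trace; empty result is valid.

    Parameters
    ----------
    min_intensity:
        Apex threshold in counts; ``None`` selects the automatic noise
        threshold (5x median nonzero bin, capped at half the trace maximum).
    smooth_window:
        Width of the moving-average filter (bins).
    """
    grid = trace.rt_grid if isinstance(trace, Eic) else trace.inv_k0_grid
    raw = np.asarray(trace.intensity, dtype=float)
    if grid.size == 0 or not np.any(raw > 0):
        return []
    if smooth_window > 1:
        kernel = np.ones(int(smooth_window)) / int(smooth_window)
        y = np.convolve(raw, kernel, mode="same")
    else:
        y = raw.copy()
    threshold = _auto_threshold(y) if min_intensity is None else float(min_intensity)

    idx, _ = find_peaks(y, height=threshold)
    if idx.size == 0:
        return []
    bin_width = float(grid[1] - grid[0]) if grid.size > 1 else 1.0

    peaks: list[DetectedPeak] = []
    for k, i in enumerate(idx):
        # three-point quadratic apex refinement on the smoothed trace
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            shift = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom < 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
        else:
            shift = 0.0
        apex_pos = float(grid[i] + shift * bin_width)

        # left bound: valley toward previous peak, else first bin < 10% apex
        floor = 0.1 * y[i]
        lo_limit = idx[k - 1] if k > 0 else 0
        j = i
        while j > lo_limit:
            if y[j - 1] < floor or y[j - 1] > y[j]:
                break
            j -= 1
        left = j
        hi_limit = idx[k + 1] if k < idx.size - 1 else y.size - 1
        j = i
        while j < hi_limit:
            if y[j + 1] < floor or y[j + 1] > y[j]:
                break
            j += 1
        right = j
        if right <= left:
            continue
        area = float(np.trapezoid(raw[left : right + 1], grid[left : right + 1]))
        if area <= 0:
            continue
        peaks.append(
            DetectedPeak(
                apex_position=apex_pos,
                apex_intensity=float(raw[i]),
                area=area,
                left_bound=float(grid[left]),
                right_bound=float(grid[right]),
            )
        )
    peaks.sort(key=lambda p: p.apex_position)
    return peaks


def mobility_peaks_to_ccs(
    peaks: list[DetectedPeak],
    mz: float,
    charge: int,
    cal: CcsCalibration,
) -> list[DetectedPeak]:
    """Attach calibrated CCS values to mobility peaks (ordering preserved)."""
    return [
        replace(p, ccs=inv_k0_to_ccs(p.apex_position, mz, charge, cal)) for p in peaks
    ]
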