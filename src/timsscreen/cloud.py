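"""In-memory containers for 4D centroided peak data and MS² events.

A :class:`PeakCloud` is the central dataset of the pipeline: one row per
centroided point with retention time (min), inverse reduced mobility
1/K0 (V·s/cm²), m/z (Th) and intensity (counts), plus the list of
data-dependent MS² events recorded during the run.  Points are kept sorted
by m/z so that narrow-ppm extractions can slice with a binary search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

#: Default scanned mobility range of the TIMS ramp (V·s/cm²).
MOBILITY_RANGE = (0.45, 1.45)


@dataclass
class Ms2Event:
    """One data-dependent PASEF MS² event.

    The precursor was isolated within a quadrupole window (1 m/z wide by
    default) while the TIMS cell released only ions inside the mobility
    gate ``[inv_k0_low, inv_k0_high]``.
    """

    precursor_mz: float
    inv_k0_low: float
    inv_k0_high: float
    rt_min: float
    fragment_mz: np.ndarray
    fragment_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.fragment_mz = np.asarray(self.fragment_mz, dtype=float)
        self.fragment_intensity = np.asarray(self.fragment_intensity, dtype=float)
        if self.inv_k0_low >= self.inv_k0_high:
            raise InvalidInputError("MS2 mobility gate must be well ordered")
        if self.fragment_mz.shape != self.fragment_intensity.shape:
            raise InvalidInputError("fragment arrays must have equal length")
        order = np.argsort(self.fragment_mz, kind="stable")
        self.fragment_mz = self.fragment_mz[order]
        self.fragment_intensity = self.fragment_intensity[order]


@dataclass
class PeakCloud:
    """A 4D centroided dataset, sorted by m/z.

    ``source_index`` (optional) attributes each point to a row of the
    generating truth ledger (−1 for background noise); it is produced by the
    synthetic generator, never written to disk by default, and absent for
    data read from files.
    """

    rt: np.ndarray
    inv_k0: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    ms2_events: list[Ms2Event] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    source_index: np.ndarray | None = None

    @classmethod
    def from_arrays(
        cls,
        rt,
        inv_k0,
        mz,
        intensity,
        ms2_events: list[Ms2Event] | None = None,
        metadata: dict | None = None,
        source_index=None,
    ) -> "PeakCloud":
        rt = np.asarray(rt, dtype=float)
        inv_k0 = np.asarray(inv_k0, dtype=float)
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if not (rt.shape == inv_k0.shape == mz.shape == intensity.shape):
            raise InvalidInputError("peak cloud columns must have equal length")
        if np.any(intensity <= 0):
            raise InvalidInputError("intensities must be positive")
        order = np.argsort(mz, kind="stable")
        src = None
        if source_index is not None:
            src = np.asarray(source_index, dtype=int)[order]
        meta = dict(metadata or {})
        meta.setdefault("mobility_range", MOBILITY_RANGE)
        meta.setdefault("polarity", "+")
        return cls(
            rt=rt[order],
            inv_k0=inv_k0[order],
            mz=mz[order],
            intensity=intensity[order],
            ms2_events=list(ms2_events or []),
            metadata=meta,
            source_index=src,
        )

    @property
    def n_points(self) -> int:
        return int(self.mz.size)

    def mz_slice(self, lo: float, hi: float) -> slice:
        """Index slice of all points with lo <= m/z <= hi (binary search)."""
        i = int(np.searchsorted(self.mz, lo, side="left"))
        j = int(np.searchsorted(self.mz, hi, side="right"))
        return slice(i, j)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rt_min": self.rt,
                "inv_k0": self.inv_k0,
                "mz": self.mz,
                "intensity": self.intensity,
            }
        )

    def rt_span(self) -> tuple[float, float]:
        rng = self.metadata.get("rt_range")
        if rng is not None:
            return float(rng[0]), float(rng[1])
        if self.n_points == 0:
            return (0.0, 1.0)
        return float(self.rt.min()), float(self.rt.max())
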