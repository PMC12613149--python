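"""Readers and writers for the pipeline's plain-text formats.

Formats (all tab- or comma-separated text, documented headers):

* 4D peak cloud TSV: ``rt_min  inv_k0  mz  intensity``, one centroided
  point per row; companion MS² event TSV ``precursor_mz  inv_k0_low
  inv_k0_high  rt_min  fragments`` with fragments as ``mz:intensity``
  pairs joined by semicolons.
* Screening library CSV: ``compound_id,name,formula,adduct,charge,
  polarity,mz,rt_min,ccs,additional_ccs`` (additional_ccs
  semicolon-separated).
* Calibrant CSV: ``name,mz,charge,ccs,inv_k0``.
* Truth-ledger CSV: the peak table of :class:`SyntheticTruth` (and its
  per-entry flag table alongside).
* MSP spectral library (NAME / PRECURSORMZ / NUM PEAKS), via matchms.
* Annotation report CSV: one row per library ion with category and deltas.

Every writer formats floats with ``repr`` so that write → read → write is
byte-identical.
"""

from __future__ import annotations

import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .cloud import Ms2Event, PeakCloud
from .errors import IOFormatError
from .ms2 import Ms2Spectrum
from .physics import CalibrantIon
from .screening import AnnotationRecord, LibraryEntry
from .simulate import SyntheticTruth

logger = logging.getLogger("timsscreen")

CLOUD_COLUMNS = ["rt_min", "inv_k0", "mz", "intensity"]
LIBRARY_COLUMNS = [
    "compound_id",
    "name",
    "formula",
    "adduct",
    "charge",
    "polarity",
    "mz",
    "rt_min",
    "ccs",
    "additional_ccs",
]
CALIBRANT_COLUMNS = ["name", "mz", "charge", "ccs", "inv_k0"]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise IOFormatError(f"{path}: missing columns {missing}")


# -- 4D peak cloud ----------------------------------------------------------


def write_peak_cloud(cloud: PeakCloud, path, events_path=None) -> None:
    cloud.to_frame().to_csv(path, sep="\t", index=False)
    if events_path is not None:
        write_ms2_events(cloud.ms2_events, events_path)


def read_peak_cloud(path, events_path=None, metadata: dict | None = None) -> PeakCloud:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, CLOUD_COLUMNS, path)
    events = read_ms2_events(events_path) if events_path is not None else []
    return PeakCloud.from_arrays(
        df["rt_min"].to_numpy(),
        df["inv_k0"].to_numpy(),
        df["mz"].to_numpy(),
        df["intensity"].to_numpy(),
        ms2_events=events,
        metadata=metadata,
    )


def write_ms2_events(events: Sequence[Ms2Event], path) -> None:
    rows = []
    for ev in events:
        frags = ";".join(
            f"{repr(float(m))}:{repr(float(i))}"
            for m, i in zip(ev.fragment_mz, ev.fragment_intensity)
        )
        rows.append(
            {
                "precursor_mz": ev.precursor_mz,
                "inv_k0_low": ev.inv_k0_low,
                "inv_k0_high": ev.inv_k0_high,
                "rt_min": ev.rt_min,
                "fragments": frags,
            }
        )
    pd.DataFrame(
        rows, columns=["precursor_mz", "inv_k0_low", "inv_k0_high", "rt_min", "fragments"]
    ).to_csv(path, sep="\t", index=False)


def read_ms2_events(path) -> list[Ms2Event]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(
        df, ["precursor_mz", "inv_k0_low", "inv_k0_high", "rt_min", "fragments"], path
    )
    events = []
    for row in df.itertuples():
        frag_mz, frag_in = [], []
        if isinstance(row.fragments, str) and row.fragments:
            for pair in row.fragments.split(";"):
                m, i = pair.split(":")
                frag_mz.append(float(m))
                frag_in.append(float(i))
        events.append(
            Ms2Event(
                precursor_mz=float(row.precursor_mz),
                inv_k0_low=float(row.inv_k0_low),
                inv_k0_high=float(row.inv_k0_high),
                rt_min=float(row.rt_min),
                fragment_mz=np.array(frag_mz),
                fragment_intensity=np.array(frag_in),
            )
        )
    return events


# -- screening library ------------------------------------------------------


def write_library(entries: Sequence[LibraryEntry], path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "compound_id": e.compound_id,
                "name": e.name,
                "formula": e.formula,
                "adduct": e.adduct,
                "charge": e.charge,
                "polarity": e.polarity,
                "mz": e.theoretical_mz,
                "rt_min": e.expected_rt,
                "ccs": e.reference_ccs,
                "additional_ccs": ";".join(repr(float(c)) for c in e.additional_ccs),
            }
        )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, index=False)


def read_library(path) -> list[LibraryEntry]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require_columns(df, LIBRARY_COLUMNS, path)
    entries = []
    for row in df.itertuples():
        extras = tuple(
            float(c) for c in str(row.additional_ccs).split(";") if c not in ("", "nan")
        )
        entries.append(
            LibraryEntry(
                compound_id=str(row.compound_id),
                name=str(row.name),
                formula=str(row.formula),
                adduct=str(row.adduct),
                charge=int(row.charge),
                polarity=str(row.polarity),
                theoretical_mz=float(row.mz),
                expected_rt=float(row.rt_min),
                reference_ccs=float(row.ccs),
                additional_ccs=extras,
            )
        )
    return entries


# -- calibrants -------------------------------------------------------------


def write_calibrants(calibrants: Sequence[CalibrantIon], path) -> None:
    pd.DataFrame(
        [
            {
                "name": c.name,
                "mz": c.mz,
                "charge": c.charge,
                "ccs": c.reference_ccs,
                "inv_k0": c.measured_inv_k0,
            }
            for c in calibrants
        ],
        columns=CALIBRANT_COLUMNS,
    ).to_csv(path, index=False)


def read_calibrants(path) -> list[CalibrantIon]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require_columns(df, CALIBRANT_COLUMNS, path)
    return [
        CalibrantIon(
            mz=float(r.mz),
            charge=int(r.charge),
            reference_ccs=float(r.ccs),
            measured_inv_k0=float(r.inv_k0),
            name=str(r.name),
        )
        for r in df.itertuples()
    ]


# -- truth ledger -----------------------------------------------------------


def write_truth(truth: SyntheticTruth, peaks_path, entries_path=None) -> None:
    truth.peaks.to_csv(peaks_path, index=False)
    if entries_path is not None:
        truth.entries.to_csv(entries_path, index=False)


def read_truth(peaks_path, entries_path=None) -> SyntheticTruth:
    peaks = pd.read_csv(peaks_path, keep_default_na=False, float_precision="round_trip")
    peaks["interference_target"] = peaks["interference_target"].astype(str)
    entries = (
        pd.read_csv(entries_path, float_precision="round_trip") if entries_path is not None else pd.DataFrame()
    )
    return SyntheticTruth(peaks=peaks, entries=entries)


# -- MSP spectral library (via matchms) -------------------------------------


def write_spectra_msp(spectra: Sequence[Ms2Spectrum], path) -> None:
    """Write spectra in NIST-style MSP (NAME / PRECURSORMZ / NUM PEAKS)."""
    import matchms
    from matchms.exporting import save_as_msp

    ms = []
    for s in spectra:
        ms.append(
            matchms.Spectrum(
                mz=np.asarray(s.fragment_mz, dtype=float),
                intensities=np.asarray(s.fragment_intensity, dtype=float),
                metadata={
                    "compound_name": s.compound_id or s.name,
                    "precursor_mz": float(s.precursor_mz),
                },
                metadata_harmonization=False,
            )
        )
    if os.path.exists(path):
        os.remove(path)  # matchms appends to existing files
    save_as_msp(ms, str(path), style="nist")


def read_spectra_msp(path) -> list[Ms2Spectrum]:
    from matchms.importing import load_from_msp

    out = []
    for s in load_from_msp(str(path), metadata_harmonization=False):
        name = s.metadata.get("compound_name") or s.metadata.get("name") or ""
        out.append(
            Ms2Spectrum(
                precursor_mz=float(
                    s.metadata.get("precursor_mz") or s.metadata.get("precursormz")
                ),
                fragment_mz=s.peaks.mz,
                fragment_intensity=s.peaks.intensities,
                compound_id=str(name),
                name=str(name),
            )
        )
    return out


# -- annotation report ------------------------------------------------------


def annotations_to_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.entry.compound_id,
                "name": r.entry.name,
                "adduct": r.entry.adduct,
                "polarity": r.entry.polarity,
                "theoretical_mz": r.entry.theoretical_mz,
                "expected_rt": r.entry.expected_rt,
                "reference_ccs": r.entry.reference_ccs,
                "category": r.category,
                "delta_ppm": r.delta_ppm,
                "delta_rt": r.delta_rt,
                "delta_ccs_pct": r.delta_ccs_pct,
                "matched_ccs": None if r.matched_peak is None else r.matched_peak.ccs,
                "n_interference_peaks": len(r.interference_peaks),
                "interference_ccs": ";".join(
                    f"{p.ccs:.2f}" for p in r.interference_peaks
                ),
                "n_ambiguous_peaks": len(r.ambiguous_peaks),
                "ms2_score": r.ms2_score,
                "confidence_level": r.confidence_level,
                "blank_filtered": r.blank_filtered,
            }
        )
    return pd.DataFrame(rows)


def write_annotations(records: Sequence[AnnotationRecord], path) -> None:
    annotations_to_frame(records).to_csv(path, index=False)
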