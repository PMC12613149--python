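#!/usr/bin/env python
"""Calibrate CCS from the tune-mix table and screen the reference scenario.

Refits the Mason-Schamp constant from the six tune-mix calibrants, runs the
full annotation workflow (EIC -> chromatographic peak -> EIM -> CCS
classification -> mobility-gated MS² match -> confidence level) and checks
the outcome against the truth ledger.  Expected finding: the confusion
matrix is exact — every interference placed beyond the 5% CCS boundary is
caught and no true annotation is lost.

Requires 01_simulate_scenario.py to have run.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import timsscreen as ts  # noqa: E402
from timsscreen import evaluation as ev  # noqa: E402
from timsscreen import io as tio  # noqa: E402


def main() -> None:
    results = ROOT / "results"
    scratch = ROOT / "scratch" / "scenario"

    cal = ts.fit_ccs_calibration(tio.read_calibrants(results / "calibrants.csv"))
    print(f"calibration: slope={cal.slope:.4f} A^2*cm^2*sqrt(Da)/(V*s), "
          f"residual RMS={cal.residual_rms:.2e} A^2 (n={cal.n_calibrants})")

    library = tio.read_library(results / "library.csv")
    spectra = {}
    for s in tio.read_spectra_msp(results / "spectra.msp"):
        spectra.setdefault(s.compound_id, []).append(s)
    cloud = tio.read_peak_cloud(
        scratch / "cloud.tsv", events_path=scratch / "ms2_events.tsv"
    )
    truth = tio.read_truth(results / "truth_peaks.csv", results / "truth_entries.csv")

    records = ts.screen(cloud, library, ts.ScreeningWindows(), cal, spectra=spectra)
    tio.write_annotations(records, results / "02_annotations.csv")

    counts = ev.count_categories(records)
    conf = ev.confusion_matrix(records, truth.expected_categories(0.25))
    mis = ev.n_misclassified(conf)
    cov = ev.spectral_coverage(records)
    ev.plot_category_bars(counts, results / "02_category_bars.png")

    print("categories:", counts)
    print("confusion matrix (expected rows x observed columns):")
    print(conf.to_string())
    print(f"misclassified vs truth ledger: {mis}")
    print(f"spectral coverage: {cov.coverage_pct:.1f}% of {cov.n_annotated} annotated ions")

    payload = {
        "calibration_slope": cal.slope,
        "counts": counts,
        "n_misclassified": mis,
        "spectral_coverage_pct": cov.coverage_pct,
    }
    (results / "02_screening_summary.json").write_text(json.dumps(payload, indent=2) + "\n")


if __name__ == "__main__":
    main()
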