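#!/usr/bin/env python
"""Generate the reference synthetic screening scenario and write it to disk.

One mid-complexity matrix at 10 ng/mL: 100 analytes on the z=1 CCS-vs-m/z
trendline, 200 matrix features over three charge states, 20% of analytes
shadowed by a matrix interference (CCS offset 6-35%), uniform background
noise, and dd-MS² events with per-species mobility gates.

Bulky outputs (the 4D point cloud) go to scratch/; the library, truth
ledger and a role summary go to results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import timsscreen as ts  # noqa: E402
from timsscreen import io as tio  # noqa: E402

SEED = 1


def main() -> None:
    results = ROOT / "results"
    scratch = ROOT / "scratch" / "scenario"
    results.mkdir(exist_ok=True)
    scratch.mkdir(parents=True, exist_ok=True)

    config = ts.ScenarioConfig(seed=SEED)
    library, spectra = ts.generate_library(config)
    cloud, truth = ts.generate_peak_cloud(library, config, spectra=spectra)

    tio.write_peak_cloud(cloud, scratch / "cloud.tsv", scratch / "ms2_events.tsv")
    tio.write_library(library, results / "library.csv")
    tio.write_spectra_msp(
        [s for v in spectra.values() for s in v], results / "spectra.msp"
    )
    tio.write_truth(truth, results / "truth_peaks.csv", results / "truth_entries.csv")
    tio.write_calibrants(ts.calibrant_table(config), results / "calibrants.csv")

    summary = {
        "seed": SEED,
        "n_points": cloud.n_points,
        "n_ms2_events": len(cloud.ms2_events),
        "roles": truth.peaks["role"].value_counts().to_dict(),
        "n_noise_points": truth.n_noise_points,
        "expected_categories": truth.expected_categories(0.25).value_counts().to_dict(),
    }
    (results / "01_scenario_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print("scenario written:", json.dumps(summary, indent=2))
    print(f"cloud -> {scratch/'cloud.tsv'}; library/truth -> {results}/")


if __name__ == "__main__":
    main()
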