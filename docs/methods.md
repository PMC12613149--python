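# Methods

## The screening problem

Target and suspect screening by LC-HRMS annotates library compounds from
their expected m/z and retention time.  In complex matrices (urine, serum,
breastmilk, dust, wastewater influent) coeluting isomeric and isobaric
matrix constituents fall inside those windows and produce false positives
at the MS¹ level, or contaminate dd-MS² spectra and isotope patterns when
the analyte is present.  Trapped ion mobility spectrometry (TIMS) adds a
third, matrix-independent coordinate — the collision cross section (CCS) —
that separates such interferences whenever their gas-phase structure
differs enough.  `timsscreen` implements that workflow end to end and
quantifies what the mobility dimension buys, using synthetic 4D data with
an exact ground-truth ledger in place of instrument raw files.

## CCS calibration

TIMS measures the inverse reduced mobility 1/K0 (V·s/cm²).  The
Mason–Schamp relation links it to the CCS Ω (Å²):

    Ω = C · z · (1/K0) / √μ,    μ = m·M / (m + M)

with z the charge, μ the reduced mass (Da) of the ion (m = z·(m/z)) and
drift gas (N₂, 28.0134 Da), and C a constant absorbing temperature,
pressure and physical prefactors.  Single-field practice does not evaluate
C from first principles; it is fitted by ordinary least squares against
reference ions — here the six Agilent ESI tune-mix ions with
drift-tube-compendium nitrogen CCS values.  Assumptions made explicit:

* the calibration is **proportional** (zero intercept) in the predictor
  x = z·(1/K0)/√μ, the conventional single-field TIMS form; an optional
  intercept is available for robustness but off by default;
* the electron mass is neglected in the ion mass (≈2·10⁻⁶ relative at
  m/z 300, far below calibration residuals);
* no weighting across calibrants;
* the mobility axis is assumed already expressed in 1/K0 units; the
  vendor's scan-to-mobility mapping is out of scope.

The default generating constant, 1059.94 Å²·√Da·cm²/(V·s), is the
single-field value 18509.86/√T at T ≈ 305 K — it places the tune-mix ions
at 1/K0 0.55–1.57 V·s/cm² and typical small-molecule analytes inside the
0.45–1.45 V·s/cm² analyte ramp, matching instrument-realistic numbers.

## Annotation windows and interference classification

A library ion is looked up in its EIC (5 ppm m/z window) for the
chromatographic peak nearest the expected RT within ±0.25 min; the EIM of
that integrated peak is converted to CCS and classified against the
library reference:

| region (|ΔCCS| rel. to reference) | meaning |
|---|---|
| < 3% | confirms the analyte ("true" window) |
| (3%, 5%] | conservative buffer — recorded, counted toward neither side |
| > 5% | a distinct, matrix-derived interference |

Categories follow from the presence/absence of a confirming peak and of
interference peaks: `true_annotation`, `true_with_interference`,
`false_positive` (m/z+RT hit whose mobilogram contains only >5% peaks),
`ambiguous` (only buffer-band peaks), `not_detected`.  Conventions chosen
where the procedure was genuinely open:

* ΔCCS is signed, computed with the **library reference as denominator**,
  thresholded on its absolute value, and taken at the **EIM peak apex**
  (classification never uses fitted peak models);
* if several peaks fall inside the 3% window the **most intense** one is
  the match, ties broken by smallest |ΔCCS|;
* the chromatographic candidate is the peak **nearest the expected RT**,
  not the most intense — RT agreement anchors the annotation;
* blank subtraction is an optional pre-filter: a record whose mean window
  intensity in blank runs exceeds the sample mean is flagged.

Library ions whose m/z, RT and reference CCS all fall inside each other's
windows (e.g. the simazine / desethyl-tebuthylazine isomer pair, 0.87%
apart in CCS) are reported as a non-separable group: the screen can
confirm either but cannot tell them apart.

## Extraction and peak detection

EIC bins are 0.02 min wide, EIM bins 0.002 V·s/cm² (≈500 bins over the
ramp) — resolution-matched to the synthetic acquisition grid and
config-exposed.  Peak detection is deliberately simple: 3-bin
moving-average smoothing, local maxima above a threshold, apex refined by
three-point quadratic interpolation (error < half a bin on noise-free
peaks), bounds at the valley toward the neighbouring peak or the first bin
below 10% of the apex, trapezoidal areas over the raw trace.  The
automatic threshold is 5× the median nonzero bin **capped at half the
trace maximum**: the uncapped median rule, designed for noise-dominated
traces, exceeds the apex itself on sparse mobilograms where nearly every
nonzero bin belongs to a real peak.  During screening a fixed absolute
floor of 50 counts is used instead, comfortably above the background point
intensities (exponential, mean 5 counts) and far below any generated peak
apex.  Overlapping peaks are not deconvolved.

## MS² extraction, scoring, confidence

dd-MS² events carry the 1/K0 gate the TIMS cell released during
fragmentation.  Extraction merges all events whose precursor lies within
the 1 m/z isolation window (±0.5 Th), whose gate overlaps the requested
mobility interval and whose RT falls inside the chromatographic bounds;
requesting the gate of the matched mobility peak excludes co-isolated
species with disjoint gates — the mechanism behind the spectral-quality
gain, verified as a strict property over seeded co-isolation fixtures.

The match score is a square-root-intensity cosine with greedy one-to-one
fragment pairing inside a 0.01 Th tolerance, taken in order of descending
intensity product:

    score = (Σ √(Ia·Ib))² / (Σ Ia · Σ Ib)

It is 1 for identical spectra, 0 for disjoint ones, symmetric and
scale-invariant, and equals the exhaustive best-pairing optimum whenever
pairings do not conflict (tested against a brute-force oracle; also equal
to the squared matchms greedy cosine on √-scaled intensities).  Vendor
library-search scores are not public; this form is isolated behind one
operation so it can be swapped.  Identification confidence is binary on
the Schymanski scale as used for coverage counting: level 1 when a match
scores ≥ 0.7 (default, config-exposed, sensitivity-scanned in the MS²
quality study), level 4 otherwise.

## What the synthetic generator emulates

Each scenario is drawn from a seeded `ScenarioConfig`; identical seed and
config reproduce byte-identical outputs, and per-compound properties are
keyed to a hash of the compound id so they persist across the clouds of a
dilution series while jitter and background noise follow a per-cloud noise
seed.

* **Trendlines.**  Features lie on per-charge power laws
  CCS = A·(m/z)^B·(1+ε), ε ~ N(0, 3%): z = 1 analytes around
  7.6·(m/z)^0.52 (≈148 Å² at m/z 300), matrix features over three charge
  states (85/10/5%), the z = 2 and z = 3 lines placed so multiply charged
  features occupy the 300–500 and 500–700 Å² bands seen in real matrix
  feature maps.
* **Peaks.**  Gaussian in RT (σ 0.05 min) and mobility (FWHM =
  (1/K0)/R at resolving power R = 200, the conservative low edge of the
  instrument's 200–400), delta-like in m/z with ≤2 ppm jitter (σ 0.7 ppm,
  clipped), sampled onto a 0.01 min × 0.001 V·s/cm² acquisition grid with
  5% multiplicative intensity jitter; grid points below half a count are
  trimmed, keeping integrated areas within 1% of the ledger.
* **Interferences.**  A configurable fraction of analytes (default 20%)
  receives a matrix peak inside the m/z window (≤2.5 ppm offset) and RT
  window (≤0.1 min offset by default), with relative CCS offset drawn
  uniformly from ±[6%, 35%] — strictly outside the 5% boundary (the
  config validator enforces > 5%) and bracketing observed real-world
  offsets of 14%, 29% and 32%; the sign is chosen among those keeping the
  peak inside the mobility ramp, and the RT-offset sign among those
  keeping it inside the run.  10% of analytes are absent altogether, so
  scenarios contain genuine false-positive cases.
* **Response.**  Area = 10⁴ counts per ng/mL × a per-compound log-normal
  response factor (σ 0.3, emulating unequal ionization efficiency) ×
  concentration; dilution series (0.5, 1, 5, 10, 500 ng/mL) are exactly
  linear, optional ESI dimer artifacts (same m/z, +25% CCS) exactly
  quadratic, and matrix peaks concentration-independent.
* **MS².**  Spectra are reproducible 3–12-fragment stand-ins drawn from a
  seeded hash of the compound id — no fragmentation chemistry.  Events
  fire for 90% of present analytes with a ±0.015 V·s/cm² gate;
  a configurable fraction is contaminated by junk fragments carrying
  0.6–2× the analyte's summed intensity, which pushes the squared-cosine
  score to 1/(1+r) < 0.7 — contaminated events are what coverage loses.
  Near-isobaric library compounds (within 1.2 Th) are forced ≥0.5 min
  apart in RT, since unresolved co-isolation among reference compounds
  would contaminate each other's events in a way no ledger flag tracks;
  co-isolation is studied with dedicated two-species fixtures instead.
* **Noise.**  Uniform background points at 0.4 points per min·Th·(V·s/cm²)
  (≈5,000 per run — an order-of-magnitude guess for a mid-complexity
  matrix, config-exposed), exponential intensities of mean 5 counts.

What it deliberately does **not** emulate: isotope patterns, adduct and
in-source-fragment networks, protomer chemistry, realistic fragmentation,
RT drift, detector saturation, profile-mode m/z, or vendor file formats.
Passing tests therefore demonstrate the correctness and calibration of the
*decision logic* under instrument-realistic geometry and noise — not
performance on real raw data, where peak shapes, co-elution structure and
spectral similarity are all harsher.

## Numerical choices and degenerate inputs

Calibration requires ≥2 calibrants with non-degenerate predictors
(singular fits raise).  Empty extraction windows give all-zero traces, not
errors; all-zero traces give empty peak lists.  Coverage over zero matched
peaks is an explicit undefined result, not NaN.  Characteristic-peak
selection links peaks across ≥3 concentration levels within 1% relative
CCS, regresses area on concentration and picks the lowest-CCS cluster with
R² > 0.8 (flagged unqualified if none passes).  The dimer test fits
log-log slopes: consistent with a dimer when the high-CCS slope exceeds
the low-CCS slope by >0.5 and itself exceeds 1.5; not
concentration-dependent when both lie within 1 ± 0.25; else inconclusive.
R² for external predictor comparisons is the squared Pearson correlation,
with 1 − SSE/SST reported alongside where they differ; a constant
predictor yields an explicit undefined R².  Feature alignment is greedy
nearest-neighbour in ascending m/z, one-to-one, within all three
tolerances at once.

## Problem sizes

The test suite and the acceptance script use: 6 calibrants (exact and
0.5 Å²-noise recovery over 100 seeds); 100 seeded screening scenarios of
100 analytes + 200 matrix features each for the exactness check; single
500-analyte scenarios for coverage statistics; 100 co-isolation fixtures
for the gating property; 300–600 matrix features for trendline recovery.
A full scenario generates in ≈0.2 s and screens in ≈0.1 s, so the whole
battery runs in well under a minute per hundred scenarios.

## Known limitations

* The 3%/5% thresholds are applied to apex CCS; peak-shape-aware
  classification might behave differently on asymmetric real peaks.
* Exact confusion matrices rely on generator invariants (interference
  offsets strictly outside 5%, analytes exactly on their reference CCS);
  real data adds CCS bias between matrices (~0.3%) that the generator can
  emulate only via the trendline scatter.
* The MS² score is one fixed functional form; absolute coverage numbers
  depend on it and on the synthetic contamination model, so only relative
  comparisons (gated vs ungated, clean vs contaminated) transfer.
* Mobility resolving power is constant across the ramp; real TIMS
  resolving power varies with 1/K0 and ramp time.
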