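"""Evaluation experiments: window sensitivity, coverage, trendlines, accuracy.

These operations reproduce, at desk scale on synthetic scenarios, the
evaluation design of the screening study: counting annotation categories,
re-screening with an RT window widened as a suspect-screening workflow
would (up to the ×10 factor that turns ±0.25 min into ±2.5 min), MS²
spectral coverage and score distributions, per-charge CCS-vs-m/z trendline
fits, cross-matrix feature alignment, and generic prediction-accuracy
statistics (R², RMSE, MAE) for external CCS/RT predictors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cloud import PeakCloud
from .errors import InvalidInputError
from .screening import (
    CATEGORIES,
    AnnotationRecord,
    LibraryEntry,
    ScreeningWindows,
    screen,
)


def count_categories(records: Sequence[AnnotationRecord]) -> dict[str, int]:
    """Per-category counts; always partitions the record list."""
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    return counts


def rt_window_sensitivity(
    cloud: PeakCloud,
    library: Sequence[LibraryEntry],
    windows: ScreeningWindows,
    cal,
    factors: Sequence[float],
    **screen_kwargs,
) -> dict[float, int]:
    """False-positive count as a function of the RT-window widening factor.

    Factor 1 reproduces the baseline screen bit-identically; factors > 1
    emulate the broader windows needed when RT values are predicted rather
    than measured.
    """
    for f in factors:
        if f < 1:
            raise InvalidInputError(f"widening factor must be >= 1, got {f}")
    out: dict[float, int] = {}
    for f in factors:
        records = screen(cloud, library, windows.widen_rt(f), cal, **screen_kwargs)
        out[float(f)] = count_categories(records)["false_positive"]
    return out


@dataclass(frozen=True)
class CoverageResult:
    """Spectral coverage with an explicit undefined state.

    Coverage = 100 × (# level-1 annotations) / (# annotations with a
    matched peak); undefined when no annotation carries a matched peak.
    """

    defined: bool
    coverage_pct: float | None
    n_annotated: int
    n_level1: int
    score_mean: float | None
    score_median: float | None
    score_q1: float | None
    score_q3: float | None
    scores: tuple[float, ...] = ()


def spectral_coverage(records: Sequence[AnnotationRecord]) -> CoverageResult:
    """MS² annotation coverage and matching-score distribution summary."""
    annotated = [r for r in records if r.matched_peak is not None]
    if not annotated:
        return CoverageResult(False, None, 0, 0, None, None, None, None)
    n_level1 = sum(1 for r in annotated if r.confidence_level == 1)
    scores = np.array([r.ms2_score for r in annotated if r.ms2_score is not None])
    if scores.size:
        q1, med, q3 = np.percentile(scores, [25, 50, 75])
        summary = (float(scores.mean()), float(med), float(q1), float(q3))
    else:
        summary = (None, None, None, None)
    return CoverageResult(
        True,
        100.0 * n_level1 / len(annotated),
        len(annotated),
        n_level1,
        *summary,
        scores=tuple(float(s) for s in scores),
    )


@dataclass(frozen=True)
class TrendlineFit:
    """Power-law fit CCS = A·(m/z)^B for one charge state."""

    charge: int
    coeff_a: float
    exponent_b: float
    r_squared: float
    n: int


def fit_trendlines(features: pd.DataFrame) -> dict[int, TrendlineFit]:
    """Per-charge log-log least-squares CCS-vs-m/z fits.

    ``features`` needs columns mz, ccs, charge.  Charge states with fewer
    than 3 features are skipped.
    """
    out: dict[int, TrendlineFit] = {}
    for z, grp in features.groupby("charge"):
        if len(grp) < 3:
            continue
        lx = np.log(grp["mz"].to_numpy(dtype=float))
        ly = np.log(grp["ccs"].to_numpy(dtype=float))
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (slope * lx + intercept)
        sst = float(np.sum((ly - ly.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        out[int(z)] = TrendlineFit(
            charge=int(z),
            coeff_a=float(np.exp(intercept)),
            exponent_b=float(slope),
            r_squared=r2,
            n=len(grp),
        )
    return out


def align_features(
    feature_tables: Sequence[pd.DataFrame],
    mz_ppm: float = 5.0,
    rt_tol: float = 0.25,
    ccs_pct: float = 1.0,
) -> dict[tuple[int, int], int]:
    """Pairwise shared-feature counts between matrices.

    Greedy nearest-neighbour matching in ascending m/z order, one-to-one,
    requiring agreement within all three tolerances simultaneously.
    """
    if len(feature_tables) < 2:
        raise InvalidInputError("need >= 2 feature tables to align")
    out: dict[tuple[int, int], int] = {}
    for i in range(len(feature_tables)):
        for j in range(i + 1, len(feature_tables)):
            a = feature_tables[i].sort_values("mz", ignore_index=True)
            b = feature_tables[j].sort_values("mz", ignore_index=True)
            b_mz = b["mz"].to_numpy(dtype=float)
            used = np.zeros(len(b), dtype=bool)
            n = 0
            for row in a.itertuples():
                tol = row.mz * mz_ppm * 1e-6
                lo = int(np.searchsorted(b_mz, row.mz - tol, side="left"))
                hi = int(np.searchsorted(b_mz, row.mz + tol, side="right"))
                best, best_d = -1, np.inf
                for k in range(lo, hi):
                    if used[k]:
                        continue
                    if abs(b["rt"].iat[k] - row.rt) > rt_tol:
                        continue
                    if 100.0 * abs(b["ccs"].iat[k] - row.ccs) / row.ccs > ccs_pct:
                        continue
                    d = abs(b_mz[k] - row.mz)
                    if d < best_d:
                        best, best_d = k, d
                if best >= 0:
                    used[best] = True
                    n += 1
            out[(i, j)] = n
    return out


@dataclass(frozen=True)
class PredictionStats:
    """Goodness of external predictions against measured values.

    ``r_squared`` is the squared Pearson correlation (the convention of
    predictor-comparison studies); ``r_squared_residual`` is 1 − SSE/SST,
    reported alongside because the two differ for biased predictors.
    ``r_squared`` is None (undefined) for a constant predictor.
    """

    r_squared: float | None
    r_squared_residual: float
    rmse: float
    mae: float
    n: int


def prediction_accuracy(observed, predicted) -> PredictionStats:
    """R², RMSE and MAE of predicted vs observed values (input units)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InvalidInputError("observed and predicted must have equal length")
    if obs.size < 2:
        raise InvalidInputError("need at least 2 value pairs")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2_resid = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else 0.0
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        r2 = None
    else:
        r2 = float(stats.pearsonr(obs, pred).statistic ** 2)
    return PredictionStats(
        r_squared=r2, r_squared_residual=r2_resid, rmse=rmse, mae=mae, n=obs.size
    )


def confusion_matrix(
    records: Sequence[AnnotationRecord],
    expected: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Observed vs expected category cross-tabulation (truth-ledger oracle)."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.entry.compound_id,
                "expected": expected[r.entry.compound_id],
                "observed": r.category,
            }
        )
    df = pd.DataFrame(rows)
    return pd.crosstab(df["expected"], df["observed"]).reindex(
        index=list(CATEGORIES), columns=list(CATEGORIES), fill_value=0
    )


def n_misclassified(confusion: pd.DataFrame) -> int:
    off_diag = confusion.to_numpy().sum() - np.diag(confusion.to_numpy()).sum()
    return int(off_diag)


@dataclass
class EvaluationReport:
    """Aggregate of one scenario's evaluation experiments."""

    counts: dict[str, int] = field(default_factory=dict)
    spectral_coverage_pct: float | None = None
    score_summary: dict | None = None
    rt_window_false_positives: dict[float, int] = field(default_factory=dict)
    trendlines: dict[int, TrendlineFit] = field(default_factory=dict)
    alignment: dict[str, int] = field(default_factory=dict)
    n_misclassified: int | None = None

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "spectral_coverage_pct": self.spectral_coverage_pct,
            "score_summary": self.score_summary,
            "rt_window_false_positives": {
                str(k): v for k, v in self.rt_window_false_positives.items()
            },
            "trendlines": {str(z): asdict(t) for z, t in self.trendlines.items()},
            "alignment": self.alignment,
            "n_misclassified": self.n_misclassified,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["Evaluation report", "================="]
        if self.counts:
            lines.append("annotation categories:")
            for k, v in self.counts.items():
                lines.append(f"  {k:24s} {v}")
        if self.spectral_coverage_pct is not None:
            lines.append(f"spectral coverage: {self.spectral_coverage_pct:.1f}%")
        if self.score_summary:
            lines.append(f"score summary: {self.score_summary}")
        for f, n in self.rt_window_false_positives.items():
            lines.append(f"false positives at RT window x{f:g}: {n}")
        for z, t in self.trendlines.items():
            lines.append(
                f"trendline z={z}: CCS = {t.coeff_a:.3f} * mz^{t.exponent_b:.4f}"
                f" (R2={t.r_squared:.4f}, n={t.n})"
            )
        for pair, n in self.alignment.items():
            lines.append(f"shared features {pair}: {n}")
        if self.n_misclassified is not None:
            lines.append(f"misclassified vs truth: {self.n_misclassified}")
        return "\n".join(lines) + "\n"


def plot_category_bars(counts: dict[str, int], path) -> None:
    """Bar chart of annotation categories (Fig-3C-style layout)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(counts)
    ax.bar(names, [counts[k] for k in names], color="#4878a8")
    ax.set_ylabel("library ions")
    ax.set_xticks(range(len(names)), names, rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_score_violin(scores_by_group: Mapping[str, Sequence[float]], path) -> None:
    """Violin plot of spectral matching scores per condition (Fig-4-style)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = {k: list(v) for k, v in scores_by_group.items() if len(v) > 0}
    fig, ax = plt.subplots(figsize=(6, 4))
    if groups:
        ax.violinplot(list(groups.values()), showmeans=True, showmedians=True)
        ax.set_xticks(range(1, len(groups) + 1), list(groups), rotation=30, ha="right")
    ax.set_ylabel("spectral matching score")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
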