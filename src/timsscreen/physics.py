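"""Ion-mobility physics: reduced mass and single-field CCS calibration.

Trapped ion mobility spectrometry measures the inverse reduced mobility
1/K0 (V·s/cm²) at which an ion elutes from the mobility ramp.  The
Mason–Schamp relation links mobility to the rotationally averaged collision
cross section Ω (CCS, Å²),

    Ω = C · z · (1/K0) / sqrt(μ),        μ = m·M / (m + M),

where z is the charge, μ the ion/drift-gas reduced mass (Da) and C a
constant absorbing temperature, pressure and the physical prefactors.
Rather than evaluating C from first principles, single-field TIMS practice
fits it against reference ions of known CCS (here: the Agilent ESI tune
mix with drift-tube nitrogen CCS values from the "CCS compendium").  This
module implements that calibration and the forward/inverse conversion.

The proportional (zero-intercept) form is the default; an intercept can be
fitted for robustness but is conventionally zero for single-field TIMS.
The electron mass is neglected when forming the ion mass from m/z·z — the
effect (~0.0002% at m/z 300) is far below calibration residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientCalibrantsError,
    InvalidInputError,
    SingularFitError,
    UncalibratedDataError,
)

#: Molecular mass of nitrogen drift gas (Da).
N2_MASS = 28.0134

#: Agilent ESI-L low-concentration tune mix, positive mode: (m/z, CCS in Å²)
#: with nitrogen drift-tube CCS values from the CCS compendium.
TUNE_MIX_POSITIVE: tuple[tuple[float, float], ...] = (
    (118.086255, 121.30),
    (322.048121, 153.73),
    (622.028960, 202.96),
    (922.009798, 243.64),
    (1221.990637, 282.20),
    (1521.971475, 316.96),
)


@dataclass(frozen=True)
class CalibrantIon:
    """A reference ion with known CCS and a measured inverse reduced mobility.

    Parameters
    ----------
    mz:
        Mass-to-charge ratio (Th).
    charge:
        Positive integer charge state.
    reference_ccs:
        Literature collision cross section (Å²).
    measured_inv_k0:
        Measured inverse reduced mobility (V·s/cm²).
    name:
        Optional identifier.
    """

    mz: float
    charge: int
    reference_ccs: float
    measured_inv_k0: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise InvalidInputError(f"calibrant m/z must be positive, got {self.mz}")
        if self.charge < 1:
            raise InvalidInputError(f"calibrant charge must be >= 1, got {self.charge}")
        if self.reference_ccs <= 0:
            raise InvalidInputError("calibrant reference CCS must be positive")
        if self.measured_inv_k0 <= 0:
            raise InvalidInputError("calibrant 1/K0 must be positive")


@dataclass(frozen=True)
class CcsCalibration:
    """Fitted proportionality between z·(1/K0)/√μ and CCS.

    ``slope`` carries units Å²·cm²·√Da/(V·s); ``intercept`` is in Å² and is
    zero for the conventional proportional fit.  ``residual_rms`` is the
    root-mean-square CCS residual of the calibrants (Å²).
    """

    slope: float
    intercept: float = 0.0
    gas_mass: float = N2_MASS
    n_calibrants: int = 0
    residual_rms: float = 0.0
    calibrant_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidInputError("calibration slope must be positive")
        if self.residual_rms < 0:
            raise InvalidInputError("residual RMS cannot be negative")


def reduced_mass(ion_mass: float, gas_mass: float) -> float:
    """Reduced mass μ = m·M/(m+M) in Da.

    Symmetric in its arguments and strictly smaller than either input.
    """
    m = np.asarray(ion_mass, dtype=float)
    M = np.asarray(gas_mass, dtype=float)
    if np.any(m <= 0) or np.any(M <= 0):
        raise InvalidInputError("masses must be positive")
    out = m * M / (m + M)
    return float(out) if out.ndim == 0 else out


def _predictor(mz, charge, inv_k0, gas_mass: float):
    """Mason–Schamp predictor x = z·(1/K0)/√μ for ion mass m = z·(m/z)."""
    mz = np.asarray(mz, dtype=float)
    charge = np.asarray(charge, dtype=float)
    inv_k0 = np.asarray(inv_k0, dtype=float)
    mu = reduced_mass(mz * charge, gas_mass)
    return charge * inv_k0 / np.sqrt(mu)


def fit_ccs_calibration(
    calibrants: Sequence[CalibrantIon],
    gas_mass: float = N2_MASS,
    fit_intercept: bool = False,
) -> CcsCalibration:
    """Least-squares fit of reference CCS against the Mason–Schamp predictor.

    Parameters
    ----------
    calibrants:
        At least two reference ions with distinct predictor values.
    gas_mass:
        Drift-gas molecular mass (Da); nitrogen by default.
    fit_intercept:
        Fit an additive offset (Å²).  Default is the pure proportional form.

    Returns
    -------
    CcsCalibration
        With ``residual_rms`` the RMS of the CCS fit residuals.
    """
    if len(calibrants) < 2:
        raise InsufficientCalibrantsError(
            f"need >= 2 calibrant ions, got {len(calibrants)}"
        )
    x = _predictor(
        [c.mz for c in calibrants],
        [c.charge for c in calibrants],
        [c.measured_inv_k0 for c in calibrants],
        gas_mass,
    )
    y = np.array([c.reference_ccs for c in calibrants], dtype=float)
    if np.ptp(x) < 1e-12 * np.max(np.abs(x)):
        raise SingularFitError("calibrant predictors are degenerate (all equal)")

    if fit_intercept:
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    if slope <= 0:
        raise SingularFitError("fitted slope is non-positive; check calibrant table")
    resid = y - (slope * x + intercept)
    return CcsCalibration(
        slope=slope,
        intercept=intercept,
        gas_mass=gas_mass,
        n_calibrants=len(calibrants),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        calibrant_names=tuple(c.name for c in calibrants),
    )


def inv_k0_to_ccs(inv_k0, mz, charge, cal: CcsCalibration):
    """Convert inverse reduced mobility to CCS (Å²) through a calibration.

    CCS = slope · z · (1/K0) / √μ + intercept, with μ formed from the full
    ion mass z·(m/z) and the calibration's drift-gas mass.  Accepts scalars
    or arrays; strictly increasing in 1/K0.
    """
    if cal is None:
        raise UncalibratedDataError("no CCS calibration supplied")
    inv_k0_arr = np.asarray(inv_k0, dtype=float)
    if np.any(inv_k0_arr <= 0):
        raise InvalidInputError("1/K0 must be positive")
    if np.any(np.asarray(charge) < 1):
        raise InvalidInputError("charge must be >= 1")
    out = cal.slope * _predictor(mz, charge, inv_k0_arr, cal.gas_mass) + cal.intercept
    return float(out) if out.ndim == 0 else out


def ccs_to_inv_k0(ccs, mz, charge, cal: CcsCalibration):
    """Exact inverse of :func:`inv_k0_to_ccs`.

    Used by the synthetic generator to place peaks in mobility space.
    """
    if cal is None:
        raise UncalibratedDataError("no CCS calibration supplied")
    ccs_arr = np.asarray(ccs, dtype=float)
    if np.any(ccs_arr <= cal.intercept):
        raise InvalidInputError("CCS must exceed the calibration intercept")
    mz_arr = np.asarray(mz, dtype=float)
    charge_arr = np.asarray(charge, dtype=float)
    mu = reduced_mass(mz_arr * charge_arr, cal.gas_mass)
    out = (ccs_arr - cal.intercept) * np.sqrt(mu) / (cal.slope * charge_arr)
    return float(out) if out.ndim == 0 else out


def tune_mix_calibrants(
    true_constant: float,
    gas_mass: float = N2_MASS,
    rng: np.random.Generator | None = None,
    inv_k0_noise_sd: float = 0.0,
    ccs_noise_sd: float = 0.0,
) -> list[CalibrantIon]:
    """Forward-generate a tune-mix calibrant table through a known constant.

    The measured 1/K0 of each tune-mix ion is what an instrument governed by
    ``true_constant`` would report for its compendium CCS; optional Gaussian
    noise emulates measurement scatter.  Refitting the returned table should
    recover ``true_constant`` (exactly in the noise-free case).
    """
    if true_constant <= 0:
        raise InvalidInputError("true constant must be positive")
    cal = CcsCalibration(slope=true_constant, gas_mass=gas_mass, n_calibrants=6)
    out = []
    for i, (mz, ccs) in enumerate(TUNE_MIX_POSITIVE):
        inv_k0 = ccs_to_inv_k0(ccs, mz, 1, cal)
        if rng is not None and inv_k0_noise_sd > 0:
            inv_k0 += rng.normal(0.0, inv_k0_noise_sd)
        ref = ccs
        if rng is not None and ccs_noise_sd > 0:
            ref += rng.normal(0.0, ccs_noise_sd)
        out.append(
            CalibrantIon(
                mz=mz,
                charge=1,
                reference_ccs=ref,
                measured_inv_k0=inv_k0,
                name=f"tunemix_{int(round(mz))}",
            )
        )
    return out
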