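"""GTPase kinetics, critical concentration, pellet fractions, molar ratios.

The malachite-green assay reads inorganic phosphate (Pi) released by GTP
hydrolysis as absorbance at 620 nm.  A linear standard curve maps
absorbance to µM Pi; the fitted intercept doubles as the assay blank, so
inversion through the curve is blank-corrected by construction.  Reactions
quenched with an equal volume of perchloric acid are diluted twofold before
the read-out; the dilution factor is applied when converting back to
reaction-tube concentrations (see ``dilution``).

The GTP turnover rate is the slope of Pi versus time over the linear range
of the curve, divided by the enzyme concentration (GTP per enzyme per
minute).  Because early-time points are linear and later points saturate as
GTP is depleted, the linear range is selected automatically: among all
contiguous windows of at least three points, take those maximizing r²,
prefer the longest, and break remaining ties toward the earliest window.
A manual range override is available.

The critical concentration of polymerization (Cc) is the x-intercept of the
regression of GTPase rate on total protein concentration: below Cc no
polymer forms and no polymer-dependent turnover occurs.  Its 95% CI comes
from first-order (delta-method) propagation of the OLS coefficient
covariance with a t critical value on n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from sephkit.synth import QUENCH_DILUTION

__all__ = [
    "StandardCurve",
    "KineticsSeries",
    "RateEstimate",
    "CcEstimate",
    "fit_standard",
    "gtpase_rate",
    "critical_concentration",
    "pellet_fraction",
    "molar_ratio",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration: signal = slope * quantity + intercept."""

    slope: float
    intercept: float
    r2: float
    x_range: tuple[float, float] = (-np.inf, np.inf)

    def invert(self, signal: np.ndarray | float) -> np.ndarray:
        """Map signal back to quantity: (signal - intercept) / slope."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class KineticsSeries:
    """Timed absorbance measurements for one enzyme concentration."""

    times: np.ndarray  # minutes, strictly increasing, starting >= 0
    absorbance: np.ndarray  # AU at 620 nm
    enzyme_conc: float  # µM

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)
        if t.size < 3 or t.size != a.size:
            raise ValueError("need >= 3 matched (time, absorbance) points")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """GTP turnover rate with the fitting window that produced it."""

    rate: float  # GTP · enzyme⁻¹ · min⁻¹
    slope_pi: float  # µM Pi · min⁻¹ in the reaction tube
    linear_range: tuple[int, int]  # (first, last) time indices, inclusive
    r2: float


@dataclass(frozen=True)
class CcEstimate:
    """Critical concentration (x-intercept of rate vs concentration)."""

    cc: float  # µM
    slope: float  # rate per µM
    ci95_cc: tuple[float, float]


def fit_standard(standards) -> StandardCurve:
    """Ordinary least squares calibration line from (quantity, signal) pairs.

    ``standards`` is any two-column structure (array, DataFrame, list of
    pairs).  Requires at least three distinct quantities; a single repeated
    quantity is a rank-deficient design and is rejected.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (quantity, signal) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("rank-deficient design: all quantities identical")
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        x_range=(float(x.min()), float(x.max())),
    )


def _window_r2(t: np.ndarray, y: np.ndarray) -> float:
    """r² of the OLS line through (t, y); a flat series fits exactly."""
    if np.ptp(y) == 0:
        return 1.0
    return float(stats.linregress(t, y).rvalue ** 2)


def gtpase_rate(
    series: KineticsSeries,
    curve: StandardCurve,
    range_mode: str = "auto",
    manual_range: tuple[int, int] | None = None,
    dilution: float = QUENCH_DILUTION,
) -> RateEstimate:
    """Turnover rate from the linear range of a phosphate-release series.

    Absorbance is inverted through ``curve`` to quenched-sample Pi, scaled
    by ``dilution`` back to reaction-tube Pi, and fitted over the selected
    window; the rate is the fitted Pi slope divided by the enzyme
    concentration.  ``range_mode='auto'`` applies the max-r² window rule
    described in the module docstring; ``'manual'`` uses ``manual_range``
    (inclusive index pair).
    """
    t = series.times
    pi = curve.invert(series.absorbance) * dilution
    n = len(t)
    if range_mode == "manual":
        if manual_range is None:
            raise ValueError("manual range_mode requires manual_range")
        first, last = manual_range
        if not (0 <= first <= last < n) or last - first + 1 < 3:
            raise ValueError("manual_range must span >= 3 points in bounds")
    elif range_mode == "auto":
        best = None
        for length in range(n, 2, -1):
            for first in range(0, n - length + 1):
                last = first + length - 1
                r2 = round(_window_r2(t[first:last + 1], pi[first:last + 1]), 10)
                # maximize r2, then window length, then earliness
                key = (-r2, -(last - first), first)
                if best is None or key < best[0]:
                    best = (key, (first, last))
        if best is None:
            raise ValueError("no contiguous window of >= 3 points")
        first, last = best[1]
    else:
        raise ValueError("range_mode must be 'auto' or 'manual'")
    sl = slice(first, last + 1)
    if np.ptp(pi[sl]) == 0:
        slope, r2 = 0.0, 1.0
    else:
        res = stats.linregress(t[sl], pi[sl])
        slope, r2 = float(res.slope), float(res.rvalue**2)
    return RateEstimate(
        rate=slope / series.enzyme_conc,
        slope_pi=slope,
        linear_range=(first, last),
        r2=r2,
    )


def critical_concentration(rate_vs_conc) -> CcEstimate:
    """Critical concentration by backward extrapolation to the x-axis.

    ``rate_vs_conc`` is any two-column structure of (concentration µM,
    rate µM Pi·min⁻¹) pairs; replicate measurements at the same
    concentration are fine.  Fits rate = b0 + b1·conc by OLS; the critical
    concentration is -b0/b1, defined only for a positive slope.  The 95% CI
    uses the delta method on (b0, b1) with t(n-2) critical values.

    Shifting every concentration by Δ shifts the estimate by exactly Δ.
    """
    arr = np.asarray(rate_vs_conc, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("need a two-column (conc, rate) table")
    if np.unique(arr[:, 0]).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    x, y = arr[:, 0], arr[:, 1]
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    b0, b1 = beta
    if b1 <= 0:
        raise ValueError("non-positive slope: critical concentration undefined")
    resid = y - X @ beta
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    cc = -b0 / b1
    grad = np.array([-1.0 / b1, b0 / b1**2])
    se = float(np.sqrt(grad @ cov @ grad))
    tcrit = stats.t.ppf(0.975, dof)
    return CcEstimate(
        cc=float(cc),
        slope=float(b1),
        ci95_cc=(float(cc - tcrit * se), float(cc + tcrit * se)),
    )


def pellet_fraction(supernatant_intensity: float, pellet_intensity: float) -> float:
    """Percent of total band intensity found in the pellet: 100·P/(S+P)."""
    s, p = float(supernatant_intensity), float(pellet_intensity)
    if s < 0 or p < 0:
        raise ValueError("band intensities must be non-negative")
    if s + p == 0:
        raise ValueError("both fractions empty: percentage undefined")
    return 100.0 * p / (s + p)


def molar_ratio(
    signal_a: float,
    signal_b: float,
    curve_a: StandardCurve,
    curve_b: StandardCurve,
    mw_a: float,
    mw_b: float,
) -> tuple[float, dict]:
    """Molar ratio of protein A to protein B from calibrated blot signals.

    Each signal is inverted through its protein's calibration curve to a
    mass-scale quantity, divided by the molecular weight to get moles, and
    the A:B mole ratio returned.  Flags (second return value) record
    signals outside the calibrated range (extrapolation) — the ratio is
    still computed, but non-positive inverted masses are an error.
    """
    flags = {}
    masses = {}
    for label, sig, curve in (("a", signal_a, curve_a), ("b", signal_b, curve_b)):
        mass = float(curve.invert(sig))
        lo, hi = curve.x_range
        flags[f"extrapolated_{label}"] = not (lo <= mass <= hi)
        if mass <= 0:
            raise ValueError(
                f"signal {label} at or below the curve blank: non-positive mass"
            )
        masses[label] = mass
    if mw_a <= 0 or mw_b <= 0:
        raise ValueError("molecular weights must be positive")
    ratio = (masses["a"] / mw_a) / (masses["b"] / mw_b)
    return ratio, flags
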