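"""Assay-level quantification for two-hybrid characterization.

Covers the orthogonal readouts used to validate the selection system:
normalized mean fluorescence intensity (MFI) on a low/high interaction
scale, signal-to-noise ratios, MIC50 dose-response fitting (antibiotic
concentration at 50% growth inhibition), Kd-signal correlation, Pearson
comparison of variant frequencies across conditions, and NMR chemical
shift perturbation (CSP) with its interface bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Mic50Fit",
    "normalize_mfi",
    "signal_to_noise",
    "dose_response",
    "fit_mic50",
    "kd_signal_r2",
    "pearson_conditions",
    "chemical_shift_perturbation",
    "classify_csp",
    "CSP_BINS",
]

#: CSP bin edges in ppm: background <= 0.09 < low < 0.18 <= medium < 0.26 <= high
CSP_BINS = (0.09, 0.18, 0.26)


def normalize_mfi(mfi_x: float, mfi_low: float, mfi_high: float) -> float:
    """Anchor an MFI on a 0-100 scale between low/high reference strains.

    The low anchor is a non-interacting control, the high anchor a strong
    interaction; values outside [0, 100] are legitimate (conditions dimmer
    than the negative control or brighter than the reference).
    """
    if not mfi_high > mfi_low:
        raise ValueError("MFI_high must exceed MFI_low")
    return 100.0 * (mfi_x - mfi_low) / (mfi_high - mfi_low)


def signal_to_noise(high: float, noise: float) -> float:
    """Ratio of the strong-interaction signal to the no-interaction signal."""
    if not noise > 0:
        raise ValueError("noise must be positive")
    return high / noise


def dose_response(conc: np.ndarray, mic50: float, hill: float) -> np.ndarray:
    """Two-parameter log-logistic growth curve, top 100 and bottom 0.

    G(c) = 100 / (1 + (c / MIC50)^h); G(0) = 100 by construction.
    """
    conc = np.asarray(conc, dtype=float)
    out = np.full(conc.shape, 100.0)
    pos = conc > 0
    out[pos] = 100.0 / (1.0 + (conc[pos] / mic50) ** hill)
    return out


@dataclass(frozen=True)
class Mic50Fit:
    mic50: float  # ug/ml
    hill: float
    residual: float  # sum of squared residuals
    extrapolated: bool  # MIC50 outside the tested concentration range


def _interpolate_50(conc: np.ndarray, od: np.ndarray) -> float:
    order = np.argsort(conc)
    c, g = conc[order], od[order]
    for i in range(len(c) - 1):
        lo, hi = g[i], g[i + 1]
        if (lo - 50.0) * (hi - 50.0) <= 0 and lo != hi:
            frac = (lo - 50.0) / (lo - hi)
            return float(c[i] + frac * (c[i + 1] - c[i]))
    return float(np.median(c[c > 0])) if (c > 0).any() else 1.0


def fit_mic50(
    concentrations: Sequence[float],
    normalized_od: Sequence[float],
    four_parameter: bool = False,
) -> Mic50Fit:
    """Least-squares MIC50 fit to (concentration, % growth) points.

    OD values are percent of the no-antibiotic culture (concentration 0 is
    100% growth by definition). Initialization: MIC50 by linear
    interpolation at 50% growth, Hill slope 1. Requires the data to
    bracket the 50% level — an all-resistant or all-dead profile carries
    no information about MIC50. With ``four_parameter`` the top and bottom
    asymptotes are fitted too.
    """
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray(normalized_od, dtype=float)
    if conc.shape != od.shape or len(conc) < 4:
        raise ValueError("need >= 4 paired (concentration, OD) points")
    if od.min() > 80.0 or od.max() < 20.0:
        raise ValueError("range not bracketed: growth never crosses 50%")

    m0 = _interpolate_50(conc, od)
    if four_parameter:
        def model(c, mic50, hill, top, bottom):
            base = dose_response(c, mic50, hill) / 100.0
            return bottom + (top - bottom) * base
        p0 = [m0, 1.0, 100.0, 0.0]
        bounds = ([1e-9, 1e-3, 50.0, -50.0], [np.inf, 50.0, 200.0, 50.0])
    else:
        model = dose_response
        p0 = [m0, 1.0]
        bounds = ([1e-9, 1e-3], [np.inf, 50.0])
    popt, _ = optimize.curve_fit(model, conc, od, p0=p0, bounds=bounds,
                                 maxfev=20000)
    resid = float(np.sum((model(conc, *popt) - od) ** 2))
    mic50, hill = float(popt[0]), float(popt[1])
    tested = conc[conc > 0]
    extrapolated = bool(tested.size == 0 or mic50 < tested.min()
                        or mic50 > tested.max())
    return Mic50Fit(mic50=mic50, hill=hill, residual=resid,
                    extrapolated=extrapolated)


def kd_signal_r2(kd_nm: Sequence[float], signal: Sequence[float]) -> float:
    """R² of ordinary least squares of signal on log10(Kd).

    Censored affinities (NaN/inf, e.g. "Kd > 100,000 nM" entries) are
    excluded; at least 3 finite pairs are required. Kd spans orders of
    magnitude, hence the log10 predictor.
    """
    kd = np.asarray(kd_nm, dtype=float)
    y = np.asarray(signal, dtype=float)
    mask = np.isfinite(kd) & np.isfinite(y)
    kd, y = kd[mask], y[mask]
    if len(kd) < 3:
        raise ValueError("need >= 3 finite (Kd, signal) pairs")
    if (kd <= 0).any():
        raise ValueError("Kd values must be positive")
    if np.ptp(y) == 0:
        return 0.0
    res = stats.linregress(np.log10(kd), y)
    return float(res.rvalue**2)


def pearson_conditions(freqs_a: Sequence[float], freqs_b: Sequence[float]
                       ) -> tuple[float, float]:
    """Pearson r and two-sided p between matched variant frequency vectors."""
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must cover the same variants")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a frequency vector")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def chemical_shift_perturbation(
    dhn_free: float, dhn_bound: float, dn_free: float, dn_bound: float,
    scale: float = 0.17, form: str = "scale_inside",
) -> float:
    """Combined amide CSP in ppm.

    Default combines proton and nitrogen shift changes as
    sqrt(ΔHN² + (scale·ΔN)²) with scale 0.17 normalizing the wider
    nitrogen ppm range; ``form="scale_outside"`` uses
    sqrt(ΔHN² + scale·ΔN²) instead.
    """
    for v in (dhn_free, dhn_bound, dn_free, dn_bound):
        if v is None or not math.isfinite(v):
            raise ValueError("all four chemical shifts must be present")
    dhn = dhn_bound - dhn_free
    dn = dn_bound - dn_free
    if form == "scale_inside":
        return math.sqrt(dhn**2 + (scale * dn) ** 2)
    if form == "scale_outside":
        return math.sqrt(dhn**2 + scale * dn**2)
    raise ValueError(f"unknown form {form!r}")


def classify_csp(delta: float) -> str:
    """Bin a CSP value: background <=0.09 < low < 0.18 <= medium < 0.26 <= high."""
    if delta < 0:
        raise ValueError("CSP must be >= 0")
    lo, mid, hi = CSP_BINS
    if delta >= hi:
        return "high"
    if delta >= mid:
        return "medium"
    if delta > lo:
        return "low"
    return "background"
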