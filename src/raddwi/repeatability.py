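"""Test-retest repeatability statistics for a quantitative imaging
biomarker (QIBA-style).

For n paired measurements with per-pair difference dD = test - retest and
per-pair mean m:

    SD_ws = sqrt( sum(dD^2)  / (2 n) )        within-subject SD
    CV_ws = sqrt( sum((dD/m)^2) / (2 n) )     within-subject CV
    RC    = 1.96 * sqrt(2) * SD_ws  (~ 2.77 * SD_ws)

Bland-Altman limits are placed at bias +/- RC (rather than the conventional
1.96 * SD of the differences), matching how repeatability coefficients are
reported for imaging biomarkers.  The unrounded 1.96*sqrt(2) is used
internally; "2.77" is a display rounding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RC_FACTOR",
    "sd_ws",
    "cv_ws",
    "rc",
    "bland_altman",
    "pdf_estimate",
    "correlate_protocols",
    "sum_sq_delta_from_summary",
    "sd_ws_from_summary",
    "summarize_cohort",
]

#: 95% repeatability-coefficient factor 1.96 * sqrt(2).
RC_FACTOR = 1.96 * np.sqrt(2.0)


def _pairs(test, retest) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(test, float)
    r = np.asarray(retest, float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("test and retest must be 1-D arrays of equal length")
    if t.size == 0:
        raise ValueError("at least one pair is required")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("pair values must be finite")
    return t, r


def sd_ws(test, retest) -> float:
    """Within-subject standard deviation sqrt(sum(dD^2) / 2n)."""
    t, r = _pairs(test, retest)
    d = t - r
    return float(np.sqrt(np.sum(d**2) / (2 * d.size)))


def cv_ws(test, retest) -> float:
    """Within-subject coefficient of variation sqrt(sum((dD/m)^2) / 2n)."""
    t, r = _pairs(test, retest)
    m = (t + r) / 2.0
    if np.any(m <= 0):
        raise ValueError("every pair mean must be > 0")
    d = t - r
    return float(np.sqrt(np.sum((d / m) ** 2) / (2 * d.size)))


def rc(sd_ws_value: float) -> float:
    """Repeatability coefficient at 95% confidence: 1.96*sqrt(2) * SD_ws."""
    if sd_ws_value < 0:
        raise ValueError("sd_ws must be >= 0")
    return float(RC_FACTOR * sd_ws_value)


def bland_altman(test, retest) -> dict:
    """Bland-Altman summary with agreement limits at bias +/- RC.

    Sign convention: differences are test minus retest.
    """
    t, r = _pairs(test, retest)
    if t.size < 2:
        raise ValueError("need at least 2 pairs")
    d = t - r
    bias = float(d.mean())
    rc_val = rc(sd_ws(t, r))
    return {
        "bias": bias,
        "upper": bias + rc_val,
        "lower": bias - rc_val,
        "rc": rc_val,
        "means": (t + r) / 2.0,
        "deltas": d,
    }


def pdf_estimate(pixel_values, grid) -> np.ndarray:
    """Gaussian kernel density estimate on ``grid`` (Silverman bandwidth)."""
    x = np.asarray(pixel_values, float)
    if x.size < 30:
        raise ValueError("need at least 30 pixels for a density estimate")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    return kde(np.asarray(grid, float))


def correlate_protocols(adc_rad, adc_epi) -> tuple[float, float, float]:
    """OLS of radial-protocol ADC on EPI-protocol ADC for matched subjects.

    Returns (slope, intercept, R^2).
    """
    y = np.asarray(adc_rad, float)
    x = np.asarray(adc_epi, float)
    if y.size != x.size:
        raise ValueError("protocols must supply matched subjects")
    if y.size < 3:
        raise ValueError("need at least 3 subjects")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# Summary-statistics helpers
# ---------------------------------------------------------------------------

def sum_sq_delta_from_summary(mean: float, sd: float, n: int,
                              ddof: int = 1) -> float:
    """Reconstruct sum(dD^2) from the mean and (sample) SD of dD."""
    return (n - ddof) * sd**2 + n * mean**2


def sd_ws_from_summary(mean: float, sd: float, n: int, ddof: int = 1) -> float:
    """SD_ws computed from printed dD summary statistics."""
    return float(np.sqrt(sum_sq_delta_from_summary(mean, sd, n, ddof)
                         / (2 * n)))


def summarize_cohort(df: pd.DataFrame,
                     value_scale: float = 1.0) -> pd.DataFrame:
    """Repeatability table from a cohort of paired ROI measurements.

    ``df`` needs columns: subject, tissue, protocol, test, retest.  One row
    per (tissue, protocol) with ADC and dD summaries plus SD_ws, CV_ws, RC.
    ``value_scale`` rescales the stored values for reporting (e.g. 1e3 to
    report mm^2/s values in 1e-3 mm^2/s).
    """
    rows = []
    for (tissue, protocol), g in df.groupby(["tissue", "protocol"],
                                            sort=False):
        t = g["test"].to_numpy() * value_scale
        r = g["retest"].to_numpy() * value_scale
        d = t - r
        s = sd_ws(t, r)
        rows.append({
            "tissue": tissue,
            "protocol": protocol,
            "n": len(g),
            "test_mean": t.mean(),
            "test_sd": t.std(ddof=1) if t.size > 1 else 0.0,
            "retest_mean": r.mean(),
            "retest_sd": r.std(ddof=1) if r.size > 1 else 0.0,
            "delta_mean": d.mean(),
            "delta_sd": d.std(ddof=1) if d.size > 1 else 0.0,
            "sd_ws": s,
            "cv_ws": cv_ws(t, r),
            "rc": rc(s),
        })
    return pd.DataFrame(rows)
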