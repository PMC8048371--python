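"""Pixel-wise ADC mapping.

Images acquired with positive and negative diffusion-gradient polarity are
combined by their geometric mean, which cancels the cross term between the
diffusion gradient and any background/imaging gradients.  The combined
magnitudes are then fit pixel-wise to the three-parameter model

    S(b) = S0 * exp(-b * D) + A,   S0, D, A >= 0

where A absorbs the Rician noise floor (and slowly diffusing contributions)
of magnitude data.  ADC values are stored in mm^2/s; reporting layers scale
to 1e-3 mm^2/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.optimize import least_squares

from .recon import DwiImageStack

__all__ = [
    "FitResult",
    "ParameterMaps",
    "combine_polarities",
    "fit_pixel",
    "fit_stack",
    "roi_stats",
]

#: Upper bound on D during optimization, mm^2/s.  Free water at body
#: temperature is ~3.2e-3; a fit pushed to this bound is not trustworthy.
D_UPPER_BOUND = 0.1


@dataclass
class FitResult:
    s0: float
    d: float
    a: float
    rss: float
    ok: bool


@dataclass
class ParameterMaps:
    """Pixel-wise S0, D (ADC) and A maps with a fit-validity mask."""

    s0_map: np.ndarray
    d_map: np.ndarray
    a_map: np.ndarray
    rss_map: np.ndarray
    valid_mask: np.ndarray
    pixel_mm: float = 1.0

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.s0_map, self.d_map, self.a_map,
                                    self.rss_map, self.valid_mask)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")
        if np.any(np.isnan(self.d_map[self.valid_mask])):
            raise ValueError("d_map must be NaN-free inside valid_mask")

    def to_nifti(self, path: str | Path) -> None:
        path = Path(path)
        vol = np.stack([self.s0_map, self.d_map, self.a_map, self.rss_map,
                        self.valid_mask.astype(float)], axis=-1)
        aff = np.diag([self.pixel_mm, self.pixel_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(vol[:, :, None, :], aff), str(path))
        name = path.name
        for suf in (".nii.gz", ".nii"):
            if name.endswith(suf):
                name = name[: -len(suf)]
                break
        path.with_name(name + ".json").write_text(json.dumps(
            {"volumes": ["s0", "d", "a", "rss", "valid"],
             "d_units": "mm^2/s"}, indent=2))


def combine_polarities(img_plus: np.ndarray,
                       img_minus: np.ndarray) -> np.ndarray:
    """Geometric mean sqrt(S+ * S-) of opposite-polarity magnitude images."""
    img_plus = np.asarray(img_plus, float)
    img_minus = np.asarray(img_minus, float)
    if img_plus.shape != img_minus.shape:
        raise ValueError("polarity images must share one shape")
    if np.any(img_plus < 0) or np.any(img_minus < 0):
        raise ValueError("magnitude images must be non-negative")
    return np.sqrt(img_plus * img_minus)


def _model(params: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, d, a = params
    # exponent clipped so a wandering unconstrained step (large negative d)
    # yields a huge-but-finite residual instead of overflowing
    return s0 * np.exp(np.clip(-b * d, None, 50.0)) + a


def fit_pixel(signal: np.ndarray, b_values: np.ndarray) -> FitResult:
    """Nonlinear least-squares fit of one pixel's decay curve.

    Initialization: A0 = min(S); D0 from the log-linear slope of (S - A0)
    over the first three b-values, clipped to [1e-5, 1e-2] mm^2/s;
    S0_0 = S(b_min) - A0.  The Levenberg-Marquardt fit is unconstrained:
    a one-sided A >= 0 bound would skew the A-D tradeoff and bias D upward
    for shallow decays, since the offset only absorbs the noise floor.
    Physicality is enforced post hoc: the fit is flagged invalid when the
    optimizer fails, S0 or D comes out negative, D reaches the free-water
    ceiling, or the signal carries no decay information.
    """
    s = np.asarray(signal, float)
    b = np.asarray(b_values, float)
    if s.size != b.size or s.size < 4:
        raise ValueError("need >= 4 (b, S) points")
    if not np.all(np.diff(b) > 0):
        raise ValueError("b_values must be strictly increasing")

    if not np.any(s):
        return FitResult(0.0, 0.0, 0.0, 0.0, False)
    if np.ptp(s) == 0.0:
        # constant positive signal: S0/A split is not identifiable
        return FitResult(0.0, 0.0, float(s[0]), 0.0, False)

    a0 = float(np.min(s))
    resid0 = np.clip(s[:3] - a0, 1e-12 * max(1.0, s.max()), None)
    slope = np.polyfit(b[:3], np.log(resid0), 1)[0]
    d0 = float(np.clip(-slope, 1e-5, 1e-2))
    s00 = max(float(s[0] - a0), 1e-12)
    x0 = np.array([s00, d0, min(a0, s00)])

    def fun(p):
        return _model(p, b) - s

    def jac(p):
        s0, d, _ = p
        e = np.exp(np.clip(-b * d, None, 50.0))
        return np.stack([e, -s0 * b * e, np.ones_like(b)], axis=1)

    try:
        res = least_squares(fun, x0, jac=jac, method="lm",
                            ftol=1e-10, xtol=1e-12, gtol=1e-12,
                            max_nfev=200)
    except Exception:
        return FitResult(0.0, 0.0, 0.0, float(np.sum(s**2)), False)
    s0_hat, d_hat, a_hat = res.x
    rss = float(np.sum(res.fun**2))
    # The unconstrained problem has a degenerate ridge (d -> 0, s0 -> inf,
    # a -> -inf: the model collapsing to a straight line in b) on which the
    # optimizer stops without formally converging but with d pinned at ~0;
    # such pixels carry no resolvable decay and enter the map as d ~ 0.
    # Only runaway or non-finite estimates are flagged invalid; censoring
    # asymmetrically (e.g. dropping d < 0) would bias ROI means of shallow
    # decays upward.
    finite = np.all(np.isfinite(res.x)) and np.isfinite(rss)
    ok = bool(finite and abs(d_hat) < D_UPPER_BOUND)
    return FitResult(float(s0_hat), float(d_hat), float(a_hat), rss, ok)


def _estimate_background_sd(image: np.ndarray, border: int = 3) -> float:
    """Background noise SD from the border frame of a magnitude image."""
    mask = np.zeros(image.shape, bool)
    mask[:border, :] = mask[-border:, :] = True
    mask[:, :border] = mask[:, -border:] = True
    return float(np.std(image[mask]))


def fit_stack(stack: DwiImageStack,
              noise_threshold_factor: float = 3.0,
              mask: np.ndarray | None = None) -> ParameterMaps:
    """Combine polarity pairs and fit every sufficiently bright pixel.

    Pixels whose maximum combined signal does not exceed
    ``noise_threshold_factor`` times a background-SD estimate (taken from
    the border frame of the lowest-b image) are excluded from the validity
    mask and left at zero.  An optional ``mask`` restricts fitting to a
    region of interest (e.g. when only ROI statistics are needed).
    """
    if len(stack.polarities) != 2:
        raise ValueError("stack must contain both polarities for every b")
    n_b = len(stack.b_values)
    combined = np.stack([
        combine_polarities(stack.images[ib, 0], stack.images[ib, 1])
        for ib in range(n_b)])
    b = np.asarray(stack.b_values, float)

    sd_bg = _estimate_background_sd(combined[0])
    bright = combined.max(axis=0) > noise_threshold_factor * sd_bg
    if mask is not None:
        bright &= np.asarray(mask, bool)

    shape = combined.shape[1:]
    s0 = np.zeros(shape)
    d = np.zeros(shape)
    a = np.zeros(shape)
    rss = np.zeros(shape)
    valid = np.zeros(shape, bool)
    for iy, ix in zip(*np.nonzero(bright)):
        fr = fit_pixel(combined[:, iy, ix], b)
        s0[iy, ix] = fr.s0
        d[iy, ix] = fr.d
        a[iy, ix] = fr.a
        rss[iy, ix] = fr.rss
        valid[iy, ix] = fr.ok
    return ParameterMaps(s0_map=s0, d_map=d, a_map=a, rss_map=rss,
                         valid_mask=valid, pixel_mm=stack.pixel_mm)


def roi_stats(maps, roi_mask) -> tuple[float, float, int]:
    """Mean and SD of the ADC over an ROI, pooled across slices.

    ``maps`` may be one ParameterMaps or a sequence (one per slice);
    likewise ``roi_mask``.  Only pixels inside the fit-validity mask count.
    Returns (mean, sd, n_pixels) with ADC in mm^2/s.
    """
    if isinstance(maps, ParameterMaps):
        maps = [maps]
        roi_mask = [roi_mask]
    values = []
    for m, roi in zip(maps, roi_mask):
        sel = np.asarray(roi, bool) & m.valid_mask
        values.append(m.d_map[sel])
    pooled = np.concatenate(values) if values else np.array([])
    if pooled.size == 0:
        raise ValueError("ROI does not intersect the fit-validity mask")
    return float(pooled.mean()), float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0, int(pooled.size)
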